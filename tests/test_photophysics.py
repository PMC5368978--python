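"""Decay models: closed forms vs brute-force/quadrature oracles, probe response."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import redoxflim as rf
from redoxflim.photophysics import (bin_expected_counts, decay_bin_profile,
                                    periodic_decay_value_bruteforce)

ALL_LIFETIMES = [0.5, 2.5, 4.3, 5.5, 6.0, 90.5, 146.0, 225.0]


class TestDecayValue:
    def test_value_at_origin_equals_amplitude(self):
        p = rf.DecayParams(1.0, 0.0, 1.0, 1.0)
        assert rf.decay_value(0.0, p) == pytest.approx(1.0)

    def test_value_at_one_lifetime_is_inverse_e(self):
        p = rf.DecayParams(1.0, 0.0, 3.7, 3.7)
        assert rf.decay_value(3.7, p) == pytest.approx(math.exp(-1.0))

    def test_biexponential_matches_term_by_term_sum(self):
        # independent evaluation of each exponential term at t = 3 ns
        p = rf.DecayParams(0.5, 0.5, 6.0, 225.0)
        expected = 0.5 * math.exp(-3.0 / 6.0) + 0.5 * math.exp(-3.0 / 225.0)
        assert rf.decay_value(3.0, p) == pytest.approx(expected, rel=1e-14)

    def test_strictly_decreasing(self):
        p = rf.DecayParams(0.6, 0.4, 2.0, 50.0, offset_c=0.3)
        t = np.linspace(0.0, 40.0, 200)
        assert np.all(np.diff(rf.decay_value(t, p)) < 0)

    @pytest.mark.parametrize("kwargs", [
        dict(alpha1=0.7, alpha2=0.3, tau1=-1.0, tau2=5.0),
        dict(alpha1=0.7, alpha2=0.3, tau1=5.0, tau2=2.0),
        dict(alpha1=0.5, alpha2=0.6, tau1=1.0, tau2=5.0),
        dict(alpha1=0.5, alpha2=0.5, tau1=1.0, tau2=5.0, offset_c=-0.1),
        dict(alpha1=0.5, alpha2=0.5, tau1=math.nan, tau2=5.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rf.DecayParams(**kwargs)

    def test_negative_time_rejected(self):
        p = rf.DecayParams.mono(5.0)
        with pytest.raises(ValueError):
            rf.decay_value(-0.1, p)


class TestPeriodicDecay:
    @pytest.mark.parametrize("tau", ALL_LIFETIMES)
    def test_closed_form_matches_pulse_train_sum(self, tau, acq):
        p = rf.DecayParams.mono(tau)
        t = np.linspace(0.0, acq.period_ns * (1 - 1e-9), 23)
        closed = rf.periodic_decay_value(t, p, acq)
        brute = periodic_decay_value_bruteforce(t, p, acq, n_pulses=10_000)
        assert np.max(np.abs(closed - brute) / brute) <= 1e-10

    def test_fast_decay_reduces_to_plain(self, acq):
        # tau = T/100 completes within one period: wrap factor ~ 1
        p = rf.DecayParams.mono(acq.period_ns / 100.0)
        t = np.array([0.0, 0.05, 0.1])
        assert rf.periodic_decay_value(t, p, acq) == pytest.approx(
            rf.decay_value(t, p), rel=1e-12)

    def test_slow_tail_wrap_factor(self, acq):
        # single exponential tau = 225 ns at t = 0: value is the geometric
        # wrap factor, checked against the 10^4-pulse brute-force sum
        p = rf.DecayParams.mono(225.0)
        expected = 1.0 / (1.0 - math.exp(-12.5 / 225.0))
        assert rf.periodic_decay_value(0.0, p, acq) == pytest.approx(expected, rel=1e-12)
        assert periodic_decay_value_bruteforce(0.0, p, acq, 10_000) == pytest.approx(
            expected, rel=1e-10)

    def test_reacted_probe_curve_flatter_than_unreacted(self, acq, probes):
        # relative drop across the window shrinks as lifetime grows (P-HA)
        spec = probes["P-HA"]
        t = np.array([0.0, acq.period_ns * 0.999])
        drops = []
        for tau in (spec.tau_unreacted, spec.tau_reacted):
            v = rf.periodic_decay_value(t, rf.DecayParams.mono(tau), acq)
            drops.append((v[0] - v[1]) / v[0])
        assert drops[1] < drops[0]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(alpha2=st.floats(0.0, 1.0), tau1=st.floats(0.3, 12.0),
           ratio=st.floats(1.0, 50.0), t=st.floats(0.0, 12.49))
    def test_periodic_at_least_plain(self, alpha2, tau1, ratio, t):
        acq = rf.AcquisitionSpec()
        p = rf.DecayParams(1 - alpha2, alpha2, tau1, tau1 * ratio)
        assert rf.periodic_decay_value(t, p, acq) >= rf.decay_value(t, p) - 1e-15

    def test_converges_to_plain_as_period_grows(self):
        # T = 10^4 * tau2: wrap factors indistinguishable from 1
        p = rf.DecayParams(0.5, 0.5, 6.0, 225.0)
        acq = rf.AcquisitionSpec(rep_rate_mhz=1000.0 / (1e4 * 225.0), n_bins=16)
        t = np.array([0.0, 5.0, 12.0])
        assert rf.periodic_decay_value(t, p, acq) == pytest.approx(
            rf.decay_value(t, p), rel=1e-12)

    def test_time_outside_window_rejected(self, acq):
        with pytest.raises(ValueError):
            rf.periodic_decay_value(12.5, rf.DecayParams.mono(5.0), acq)


class TestBinIntegrals:
    def test_bin_counts_match_quadrature(self, acq):
        p = rf.DecayParams(0.4, 0.6, 2.5, 90.5, offset_c=0.7, amplitude=3.0)
        edges = acq.bin_edges()
        expected = bin_expected_counts(p, acq)
        for i in (0, 1, 100, 255):
            q, _ = quad(lambda t: rf.periodic_decay_value(t, p, acq) - p.offset_c,
                        edges[i], edges[i + 1], epsabs=1e-13, epsrel=1e-12)
            assert expected[i] == pytest.approx(q + p.offset_c, rel=1e-9)

    def test_total_integral_identity(self, acq):
        # sum over the window = amplitude*(a1*tau1 + a2*tau2) + n_bins*C
        p = rf.DecayParams(0.4, 0.6, 2.5, 90.5, offset_c=0.7, amplitude=3.0)
        total = bin_expected_counts(p, acq).sum()
        analytic = 3.0 * (0.4 * 2.5 + 0.6 * 90.5) + acq.n_bins * 0.7
        assert total == pytest.approx(analytic, rel=1e-12)

    def test_profile_normalized(self, acq):
        p = rf.DecayParams(0.3, 0.7, 4.3, 146.0)
        assert decay_bin_profile(p, acq).sum() == pytest.approx(1.0, abs=1e-12)


class TestReactedFraction:
    def test_zero_at_zero(self, probes):
        assert rf.reacted_fraction(0.0, probes["P-GSH"]) == 0.0

    def test_saturates_at_saturation_concentration(self, probes):
        spec = probes["P-GSH"]
        assert rf.reacted_fraction(spec.saturation_conc, spec) == 1.0
        assert rf.reacted_fraction(spec.saturation_conc * 3, spec) == 1.0

    def test_linear_segment_proportionality(self, probes):
        spec = probes["P-GSH"]
        f5, f10 = rf.reacted_fraction(5.0, spec), rf.reacted_fraction(10.0, spec)
        assert f5 / f10 == pytest.approx(0.5, rel=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(a=st.floats(0.0, 60.0), b=st.floats(0.0, 60.0))
    def test_monotone_nondecreasing(self, probes, a, b):
        spec = probes["P-HA"]
        lo, hi = min(a, b), max(a, b)
        assert rf.reacted_fraction(lo, spec) <= rf.reacted_fraction(hi, spec) + 1e-15

    def test_negative_concentration_rejected(self, probes):
        with pytest.raises(ValueError):
            rf.reacted_fraction(-1.0, probes["P-GSH"])


class TestMixDecay:
    def test_no_reaction_gives_pure_fast(self, probes):
        p = rf.mix_decay(0.0, probes["P-GSH"])
        assert p.alpha2 == 0.0
        assert p.tau1 == probes["P-GSH"].tau_unreacted

    def test_full_reaction_no_background_is_single_slow(self, probes):
        p = rf.mix_decay(1.0, probes["P-GSH"])
        assert p.alpha2 == 1.0
        assert p.tau2 == probes["P-GSH"].tau_reacted

    def test_half_reacted_matches_published_lifetimes(self, probes):
        p = rf.mix_decay(0.5, probes["P-GSH"])
        assert (p.alpha1, p.alpha2) == (0.5, 0.5)
        assert (p.tau1, p.tau2) == (6.0, 225.0)

    def test_background_pools_into_fast_component(self, probes):
        p = rf.mix_decay(0.5, probes["P-GSH"], background_fraction=0.2,
                         background_tau=2.5)
        # fast pool: 0.4 unreacted @ 6 ns + 0.2 background @ 2.5 ns
        assert p.alpha2 == pytest.approx(0.4)
        assert p.tau1 == pytest.approx((0.4 * 6.0 + 0.2 * 2.5) / 0.6)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(reacted=st.floats(0.0, 1.0), bg=st.floats(0.0, 0.9))
    def test_amplitude_fractions_always_sum_to_one(self, probes, reacted, bg):
        p = rf.mix_decay(reacted, probes["P-HP"], background_fraction=bg)
        assert p.alpha1 + p.alpha2 == pytest.approx(1.0, abs=1e-12)
        assert p.tau1 <= p.tau2

    def test_out_of_range_fraction_rejected(self, probes):
        with pytest.raises(ValueError):
            rf.mix_decay(1.2, probes["P-GSH"])


def test_acquisition_spec_window():
    assert rf.AcquisitionSpec(rep_rate_mhz=80.0).period_ns == 12.5
    with pytest.raises(ValueError):
        rf.AcquisitionSpec(n_bins=8)


def test_probe_table_invariants(probes):
    assert set(probes) == {"P-GSH", "P-HP", "P-HA"}
    for spec in probes.values():
        assert spec.tau_reacted > spec.tau_unreacted
        assert spec.linear_limit <= spec.saturation_conc
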