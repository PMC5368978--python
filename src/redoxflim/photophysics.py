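"""Two-state probe photophysics and TCSPC decay models.

The optical readout of the Ru(II)-complex redox probes is a bi-exponential
fluorescence decay

    F(t) = A (alpha1 e^(-t/tau1) + alpha2 e^(-t/tau2)) + C,

with a fast component (unreacted probe pooled with tissue autofluorescence,
a few ns) and a slow component (analyte-reacted probe, ~90-225 ns).  Under
pulsed excitation at repetition period ``T`` (12.5 ns at 80 MHz) the slow
component does not finish decaying between pulses; the histogram recorded by
a TCSPC board is the steady-state superposition of the tails of all
preceding pulses.  Summing the geometric pulse-train series in closed form
gives the periodic ("incomplete decay") model

    F_per(t) = A [ alpha1 e^(-t/tau1) / (1 - e^(-T/tau1))
                 + alpha2 e^(-t/tau2) / (1 - e^(-T/tau2)) ] + C,

for t in [0, T).  This module provides both forms, the per-bin integrals
used by the simulator and the fitter, a brute-force pulse-train oracle, and
the two-state dose-response model of the probes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "DecayParams",
    "AcquisitionSpec",
    "ProbeSpec",
    "load_probe",
    "load_probe_table",
    "decay_value",
    "periodic_decay_value",
    "periodic_decay_value_bruteforce",
    "bin_expected_counts",
    "decay_bin_profile",
    "reacted_fraction",
    "mix_decay",
]

_ALPHA_TOL = 1e-12


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the bi-exponential decay model.

    ``alpha1``/``alpha2`` are the relative amplitude fractions of the fast
    and slow lifetimes ``tau1`` <= ``tau2`` (ns) and must sum to one;
    ``offset_c`` is the constant baseline in expected counts per time bin;
    ``amplitude`` is the overall scale (total expected decay photons per
    excitation window for normalized per-bin profiles).
    """

    alpha1: float
    alpha2: float
    tau1: float
    tau2: float
    offset_c: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.alpha1, self.alpha2, self.tau1, self.tau2,
                self.offset_c, self.amplitude)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite decay parameter in {vals}")
        if abs(self.alpha1 + self.alpha2 - 1.0) > _ALPHA_TOL:
            raise ValueError(
                f"alpha1 + alpha2 must equal 1, got {self.alpha1 + self.alpha2!r}")
        if not (0.0 < self.tau1 <= self.tau2):
            raise ValueError(
                f"lifetimes must satisfy 0 < tau1 <= tau2, got {self.tau1}, {self.tau2}")
        if self.offset_c < 0.0:
            raise ValueError("offset_c must be >= 0")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be >= 0")

    @classmethod
    def mono(cls, tau: float, *, offset_c: float = 0.0,
             amplitude: float = 1.0) -> "DecayParams":
        """Single-exponential decay expressed in the bi-exponential form."""
        return cls(0.0, 1.0, tau, tau, offset_c=offset_c, amplitude=amplitude)


@dataclass(frozen=True)
class AcquisitionSpec:
    """TCSPC acquisition geometry: laser repetition rate and time binning.

    ``period_ns`` is derived as 1000 / ``rep_rate_mhz`` so that
    period x rate = 1000 holds exactly (12.5 ns at the default 80 MHz).
    """

    rep_rate_mhz: float = 80.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rep_rate_mhz) and self.rep_rate_mhz > 0):
            raise ValueError("rep_rate_mhz must be positive and finite")
        if int(self.n_bins) != self.n_bins or self.n_bins < 16:
            raise ValueError("n_bins must be an integer >= 16")

    @property
    def period_ns(self) -> float:
        return 1000.0 / self.rep_rate_mhz

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_bins

    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.period_ns, self.n_bins + 1)

    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges()
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class ProbeSpec:
    """A two-state turn-on probe: unreacted vs analyte-reacted lifetimes.

    ``linear_limit`` is the analyte concentration (uM) up to which the
    intensity response is linear; the response saturates at
    ``saturation_conc``.
    """

    name: str
    tau_unreacted: float
    tau_reacted: float
    linear_limit: float
    saturation_conc: float
    analyte: str = ""

    def __post_init__(self) -> None:
        if not self.tau_reacted > self.tau_unreacted > 0:
            raise ValueError("require tau_reacted > tau_unreacted > 0")
        if not (0 < self.linear_limit <= self.saturation_conc):
            raise ValueError("require 0 < linear_limit <= saturation_conc")


def load_probe_table() -> dict[str, ProbeSpec]:
    """Load the packaged table of the three published probes."""
    text = resources.files("redoxflim").joinpath("data/probes.json").read_text()
    raw = json.loads(text)
    return {name: ProbeSpec(name=name, **fields) for name, fields in raw.items()}


def load_probe(name: str) -> ProbeSpec:
    table = load_probe_table()
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown probe {name!r}; available: {sorted(table)}") from None


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if np.any(t < 0):
        raise ValueError("time values must be >= 0")
    return t


def decay_value(t, params: DecayParams):
    """Plain (single-pulse) bi-exponential decay A(a1 e^-t/t1 + a2 e^-t/t2) + C."""
    t = _check_times(t)
    out = params.amplitude * (
        params.alpha1 * np.exp(-t / params.tau1)
        + params.alpha2 * np.exp(-t / params.tau2)
    ) + params.offset_c
    return out if out.ndim else float(out)


def _wrap_factor(tau: float, period: float) -> float:
    # 1 / (1 - e^(-T/tau)); -expm1 keeps precision when T/tau is small
    return 1.0 / (-math.expm1(-period / tau))


def periodic_decay_value(t, params: DecayParams, acq: AcquisitionSpec):
    """Steady-state pulse-train superposition of the decay, t in [0, T).

    Each exponential picks up the geometric wrap factor 1/(1 - e^(-T/tau)),
    the closed form of sum_k e^(-(t + kT)/tau).
    """
    t = _check_times(t)
    period = acq.period_ns
    if np.any(t >= period):
        raise ValueError(f"t must lie in [0, {period}) ns")
    w1 = _wrap_factor(params.tau1, period)
    w2 = _wrap_factor(params.tau2, period)
    out = params.amplitude * (
        params.alpha1 * w1 * np.exp(-t / params.tau1)
        + params.alpha2 * w2 * np.exp(-t / params.tau2)
    ) + params.offset_c
    return out if out.ndim else float(out)


def periodic_decay_value_bruteforce(t, params: DecayParams, acq: AcquisitionSpec,
                                    n_pulses: int = 10_000):
    """Truncated pulse-train sum sum_{k<n} F(t + kT); oracle for the closed form.

    Terms are accumulated from the smallest (largest k) upward to limit
    floating-point summation error.
    """
    t = _check_times(t)
    period = acq.period_ns
    if np.any(t >= period):
        raise ValueError(f"t must lie in [0, {period}) ns")
    ks = np.arange(n_pulses - 1, -1, -1, dtype=float)
    shifted = t[..., None] + ks * period if np.ndim(t) else t + ks * period
    total = params.amplitude * (
        params.alpha1 * np.exp(-shifted / params.tau1).sum(axis=-1)
        + params.alpha2 * np.exp(-shifted / params.tau2).sum(axis=-1)
    ) + params.offset_c
    return total if np.ndim(total) else float(total)


def _component_bin_profile(tau: float, acq: AcquisitionSpec) -> np.ndarray:
    """Fraction of one component's photons landing in each bin (sums to 1).

    Integral of the periodic exponential over bin [a, b) divided by its
    integral over the full period:  (e^(-a/tau) - e^(-b/tau)) / (1 - e^(-T/tau)).
    """
    edges = acq.bin_edges()
    lo = edges[:-1]
    width = acq.bin_width_ns
    num = np.exp(-lo / tau) * (-np.expm1(-width / tau))
    return num / (-math.expm1(-acq.period_ns / tau))


def decay_bin_profile(params: DecayParams, acq: AcquisitionSpec) -> np.ndarray:
    """Normalized per-bin photon fractions of the mixed periodic decay."""
    p = (params.alpha1 * _component_bin_profile(params.tau1, acq)
         + params.alpha2 * _component_bin_profile(params.tau2, acq))
    return p


def bin_expected_counts(params: DecayParams, acq: AcquisitionSpec) -> np.ndarray:
    """Exact integral of the periodic decay over each bin, plus per-bin offset.

    Summed over the period this equals amplitude*(alpha1*tau1 + alpha2*tau2)
    + n_bins*offset_c (the wrap factors cancel against the truncated
    integration window).
    """
    w1 = _wrap_factor(params.tau1, acq.period_ns)
    w2 = _wrap_factor(params.tau2, acq.period_ns)
    edges = acq.bin_edges()
    lo, width = edges[:-1], acq.bin_width_ns

    def integral(tau, w):
        return w * tau * np.exp(-lo / tau) * (-np.expm1(-width / tau))

    return params.amplitude * (
        params.alpha1 * integral(params.tau1, w1)
        + params.alpha2 * integral(params.tau2, w2)
    ) + params.offset_c


def reacted_fraction(conc, probe: ProbeSpec):
    """Fraction of probe molecules converted at analyte concentration ``conc`` (uM).

    Linear on [0, linear_limit], continues linearly to 1 at
    ``saturation_conc`` and stays saturated above it.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0) or not np.all(np.isfinite(conc)):
        raise ValueError("concentration must be finite and >= 0")
    f_limit = probe.linear_limit / probe.saturation_conc
    out = np.interp(conc, [0.0, probe.linear_limit, probe.saturation_conc],
                    [0.0, f_limit, 1.0])
    return out if out.ndim else float(out)


def mix_decay(reacted_frac: float, probe: ProbeSpec, *,
              background_fraction: float = 0.0, background_tau: float = 2.5,
              amplitude: float = 1.0, offset_c: float = 0.0) -> DecayParams:
    """Express reacted + unreacted probe + autofluorescence as one bi-exponential.

    The slow component is the reacted probe lifetime with weight
    ``(1 - background_fraction) * reacted_frac``; the unreacted probe and the
    mono-exponential tissue background (default 2.5 ns, midpoint of the
    2-3 ns range typical of liver autofluorescence) are pooled into a single
    fast component at their amplitude-weighted mean lifetime.
    """
    if not 0.0 <= reacted_frac <= 1.0:
        raise ValueError("reacted_frac must lie in [0, 1]")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must lie in [0, 1)")
    if background_tau <= 0:
        raise ValueError("background_tau must be positive")

    alpha2 = (1.0 - background_fraction) * reacted_frac
    w_unreacted = (1.0 - background_fraction) * (1.0 - reacted_frac)
    w_fast = w_unreacted + background_fraction
    if w_fast > 0:
        tau1 = (w_unreacted * probe.tau_unreacted
                + background_fraction * background_tau) / w_fast
    else:  # fully reacted, no background: single exponential at tau_reacted
        tau1 = probe.tau_unreacted
    return DecayParams(alpha1=1.0 - alpha2, alpha2=alpha2, tau1=tau1,
                       tau2=probe.tau_reacted, offset_c=offset_c,
                       amplitude=amplitude)
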