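"""Maximum-likelihood fitting of the incomplete-decay model to TCSPC histograms.

Photon counts in TCSPC bins are Poisson distributed, so the fitter maximizes
the Poisson likelihood of the periodic ("incomplete") bi-exponential decay

    mu_i = A * [alpha1 p_i(tau1) + alpha2 p_i(tau2)] + C,

where p_i(tau) is the fraction of a periodic exponential's photons landing
in bin i (closed form, sums to 1 over the 12.5 ns window) and A is the total
expected number of decay photons.  Amplitudes satisfy alpha1 + alpha2 = 1
and lifetimes are ordered tau1 <= tau2 after optimization.  The baseline C
(the 'offset') can be fit jointly or held fixed; fixing it is required for
well-identified recovery of lifetimes much longer than the inter-pulse
period, where a nearly flat slow component trades off against a constant.

The entry points follow the model/results idiom: build an
:class:`IncompleteDecayModel` from a histogram, call :meth:`fit`, inspect
the returned :class:`DecayFitResult` (parameters, log-likelihood, reduced
chi-square, curvature-based standard error of tau2, ``summary()``).
:func:`fit_stack` maps the fitter over every sufficiently bright pixel of a
:class:`~redoxflim.simulate.FLIMStack`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.special import gammaln

from .photophysics import AcquisitionSpec, DecayParams
from .simulate import FLIMStack

__all__ = [
    "IncompleteDecayModel", "DecayFitResult", "LifetimeMaps",
    "fit_histogram", "fit_histogram_auto", "fit_stack", "roi_decay",
]

_LOG = math.log


@dataclass
class DecayFitResult:
    """Result of one incomplete-decay fit.

    ``params`` is None for masked results (histogram below ``min_photons``).
    ``stderr_tau2`` is the curvature (observed-information) standard error of
    the slow lifetime in ns; it inflates as tau2 grows past the laser period
    and the decay becomes flat within the observation window.
    """

    params: DecayParams | None
    loglik: float
    chisq_reduced: float
    n_photons: float
    converged: bool
    stderr_tau2: float
    masked: bool = False
    n_components: int = 2
    message: str = ""
    nfev: int = 0
    n_free: int = 0

    @property
    def aic(self) -> float:
        """Akaike information criterion 2k - 2 loglik of this fit."""
        return 2.0 * self.n_free - 2.0 * self.loglik

    @property
    def tau2(self) -> float:
        if self.params is None:
            return math.nan
        return self.params.tau2 if self.params.alpha2 > 0 else self.params.tau1

    def summary(self) -> str:
        if self.masked or self.params is None:
            return "Incomplete-decay fit: masked (insufficient photons)\n"
        p = self.params
        lines = [
            "Incomplete-decay bi-exponential fit (Poisson ML)",
            "=" * 48,
            f"components        {self.n_components}",
            f"photons           {self.n_photons:.0f}",
            f"converged         {self.converged}",
            f"tau1 [ns]         {p.tau1:.4g}",
            f"tau2 [ns]         {p.tau2:.4g}  (s.e. {self.stderr_tau2:.3g})",
            f"alpha1 / alpha2   {p.alpha1:.4f} / {p.alpha2:.4f}",
            f"offset C [cts/bin]{p.offset_c:10.4g}",
            f"amplitude [cts]   {p.amplitude:.6g}",
            f"log-likelihood    {self.loglik:.4f}",
            f"reduced chi-sq    {self.chisq_reduced:.4f}",
        ]
        return "\n".join(lines) + "\n"


def _masked_result(n_photons: float, n_components: int) -> DecayFitResult:
    return DecayFitResult(params=None, loglik=math.nan, chisq_reduced=math.nan,
                          n_photons=n_photons, converged=False,
                          stderr_tau2=math.nan, masked=True,
                          n_components=n_components,
                          message="below min_photons")


class IncompleteDecayModel:
    """Poisson likelihood model for one TCSPC decay histogram.

    Parameters
    ----------
    counts : array of length ``acq.n_bins``
        Photon counts per bin (ROI sums or single-pixel histograms).
    acq : AcquisitionSpec
        Laser period and binning.
    n_components : {1, 2}
        Mono- or bi-exponential decay.
    fix_offset : float or None
        Hold the baseline C at this value (counts/bin); None fits it.
    """

    def __init__(self, counts, acq: AcquisitionSpec, *, n_components: int = 2,
                 fix_offset: float | None = None,
                 tau1_bounds: tuple[float, float] = (0.05, 12.5),
                 tau2_bounds: tuple[float, float] = (0.05, 2000.0),
                 min_photons: float = 100.0):
        counts = np.asarray(counts, dtype=float).ravel()
        if counts.size != acq.n_bins:
            raise ValueError(f"histogram length {counts.size} != n_bins {acq.n_bins}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and nonnegative")
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if fix_offset is not None and fix_offset < 0:
            raise ValueError("fix_offset must be >= 0")
        self.counts = counts
        self.acq = acq
        self.n_components = n_components
        self.fix_offset = fix_offset
        self.tau1_bounds = tau1_bounds
        self.tau2_bounds = tau2_bounds
        self.min_photons = min_photons
        edges = acq.bin_edges()
        self._lo = edges[:-1]
        self._hi = edges[1:]
        self._T = acq.period_ns
        self.n_photons = float(counts.sum())

    # -- model pieces ------------------------------------------------------

    def _profile_and_dlogtau(self, log_tau: float):
        """Normalized bin profile p(tau) and its derivative wrt log(tau)."""
        tau = math.exp(log_tau)
        e_lo = np.exp(-self._lo / tau)
        e_hi = np.exp(-self._hi / tau)
        N = e_lo - e_hi
        D = -math.expm1(-self._T / tau)
        p = N / D
        dN = (self._lo * e_lo - self._hi * e_hi) / tau**2
        dD = -(self._T / tau**2) * math.exp(-self._T / tau)
        dp_dtau = (dN * D - N * dD) / D**2
        return p, tau * dp_dtau

    def _unpack(self, x):
        if self.n_components == 1:
            log_amp, log_tau = x[0], x[1]
            alpha2, log_tau1, log_tau2 = 1.0, log_tau, log_tau
            k = 2
        else:
            log_amp, alpha2, log_tau1, log_tau2 = x[0], x[1], x[2], x[3]
            k = 4
        offset = self.fix_offset if self.fix_offset is not None else x[k]
        return log_amp, alpha2, log_tau1, log_tau2, offset

    def expected_counts(self, x) -> np.ndarray:
        log_amp, alpha2, log_t1, log_t2, offset = self._unpack(x)
        amp = math.exp(log_amp)
        if self.n_components == 1:
            p, _ = self._profile_and_dlogtau(log_t2)
            mix = p
        else:
            p1, _ = self._profile_and_dlogtau(log_t1)
            p2, _ = self._profile_and_dlogtau(log_t2)
            mix = (1.0 - alpha2) * p1 + alpha2 * p2
        return amp * mix + offset

    def nll_and_grad(self, x):
        """Poisson negative log-likelihood (up to a constant) and gradient."""
        log_amp, alpha2, log_t1, log_t2, offset = self._unpack(x)
        amp = math.exp(log_amp)
        if self.n_components == 1:
            p2, d2 = self._profile_and_dlogtau(log_t2)
            mix = p2
        else:
            p1, d1 = self._profile_and_dlogtau(log_t1)
            p2, d2 = self._profile_and_dlogtau(log_t2)
            mix = (1.0 - alpha2) * p1 + alpha2 * p2
        mu = amp * mix + offset
        mu = np.maximum(mu, 1e-300)
        n = self.counts
        nll = float(np.sum(mu) - np.sum(n * np.log(mu)))
        w = 1.0 - n / mu
        grad = []
        grad.append(float(np.sum(w * amp * mix)))          # d/dlog_amp
        if self.n_components == 2:
            grad.append(float(np.sum(w * amp * (p2 - p1))))           # d/dalpha2
            grad.append(float(np.sum(w * amp * (1.0 - alpha2) * d1)))  # d/dlog_tau1
            grad.append(float(np.sum(w * amp * alpha2 * d2)))          # d/dlog_tau2
        else:
            grad.append(float(np.sum(w * amp * d2)))       # d/dlog_tau
        if self.fix_offset is None:
            grad.append(float(np.sum(w)))                  # d/doffset
        return nll, np.asarray(grad)

    def loglike(self, x) -> float:
        """Full Poisson log-likelihood (with the factorial constant)."""
        mu = np.maximum(self.expected_counts(x), 1e-300)
        n = self.counts
        return float(np.sum(n * np.log(mu) - mu - gammaln(n + 1.0)))

    # -- initialization ----------------------------------------------------

    def _log_slope_tau(self, sl: slice, floor: float, cap: float,
                       baseline: float = 0.0) -> float:
        """Crude lifetime from a log-linear fit over a slice of bins."""
        t = self.acq.bin_centers()[sl]
        y = np.log(np.maximum(self.counts[sl] - baseline, 0.5))
        slope = np.polyfit(t, y, 1)[0]
        tau = -1.0 / slope if slope < -1e-12 else cap
        return float(np.clip(tau, floor, cap))

    def _base_start(self, c0: float) -> np.ndarray:
        nb = self.acq.n_bins
        total = max(self.n_photons, 1.0)
        amp0 = max(total - c0 * nb, 1.0)
        tau_fast = self._log_slope_tau(slice(0, nb // 4),
                                       self.tau1_bounds[0] * 1.05,
                                       self.tau1_bounds[1] * 0.95)
        tau_slow = self._log_slope_tau(slice(nb // 2, nb),
                                       self.tau2_bounds[0] * 1.05,
                                       self.tau2_bounds[1] * 0.95,
                                       baseline=c0)
        if self.n_components == 1:
            base = [_LOG(amp0), _LOG(math.sqrt(tau_fast * tau_slow))]
        else:
            tau_slow = max(tau_slow, tau_fast * 1.5)
            base = [_LOG(amp0), 0.3, _LOG(tau_fast), _LOG(tau_slow)]
        if self.fix_offset is None:
            base.append(c0)
        return np.asarray(base, dtype=float)

    def _starts(self, n_restarts: int, seed: int):
        if self.fix_offset is None:
            # the baseline trades off against flat slow tails: seed the
            # search from both a zero and a tail-level baseline guess
            c0_tail = float(max(self.counts.min(), 0.0))
            bases = [self._base_start(0.0), self._base_start(0.5 * c0_tail),
                     self._base_start(c0_tail)]
        else:
            bases = [self._base_start(self.fix_offset)]
        starts = list(bases)
        rng = np.random.default_rng(seed)
        for _ in range(max(n_restarts - 1, 0)):
            for base in bases:
                x = base.copy()
                if self.n_components == 1:
                    x[1] += rng.uniform(-0.7, 0.7)
                else:
                    x[1] = rng.uniform(0.1, 0.9)
                    x[2] += rng.uniform(-0.7, 0.7)
                    x[3] += rng.uniform(-0.7, 0.7)
                starts.append(x)
        return starts

    def _bounds(self):
        b = [(-30.0, 60.0)]
        lo1, hi1 = self.tau1_bounds
        lo2, hi2 = self.tau2_bounds
        if self.n_components == 2:
            b += [(0.0, 1.0), (_LOG(lo1), _LOG(hi1)), (_LOG(lo2), _LOG(hi2))]
        else:
            b += [(_LOG(min(lo1, lo2)), _LOG(hi2))]
        if self.fix_offset is None:
            b.append((0.0, None))
        return b

    # -- optimization ------------------------------------------------------

    def _newton_polish(self, x, bounds, max_steps: int = 8):
        """A few damped Newton steps (finite-difference Hessian of the
        analytic gradient) to sharpen the optimum beyond L-BFGS-B tolerance.

        Returns the polished point and whether the final Newton step was
        negligible in parameter space (a convergence certificate that is
        robust to line-search breakdown at float precision).
        """
        f, g = self.nll_and_grad(x)
        at_optimum = False
        for _ in range(max_steps):
            H = self._num_hessian(x)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            x_new = x - step
            for i, (lo, hi) in enumerate(bounds):
                if lo is not None:
                    x_new[i] = max(x_new[i], lo)
                if hi is not None:
                    x_new[i] = min(x_new[i], hi)
            rel_step = float(np.max(np.abs(x_new - x)
                                    / np.maximum(np.abs(x), 1.0)))
            if rel_step < 1e-6:     # KKT: projected Newton step negligible
                at_optimum = True
                break
            f_new, g_new = self.nll_and_grad(x_new)
            if not math.isfinite(f_new) or f_new > f + 1e-9 * (abs(f) + 1):
                break
            x, f, g = x_new, f_new, g_new
            if np.max(np.abs(g)) < 1e-10 * (abs(f) + 1):
                at_optimum = True
                break
        return x, f, at_optimum

    def _num_hessian(self, x, rel_step: float = 1e-5) -> np.ndarray:
        n = len(x)
        H = np.empty((n, n))
        for i in range(n):
            h = rel_step * max(abs(x[i]), 1e-3)
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            _, gp = self.nll_and_grad(xp)
            _, gm = self.nll_and_grad(xm)
            H[i] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    def fit(self, *, n_restarts: int = 3, seed: int = 0, polish: bool = True,
            compute_stderr: bool = True) -> DecayFitResult:
        """Maximize the Poisson likelihood; multi-start L-BFGS-B with an
        optional Newton polish.  Returns a masked result below min_photons."""
        if self.n_photons < self.min_photons:
            return _masked_result(self.n_photons, self.n_components)
        bounds = self._bounds()
        best = None
        nfev = 0
        for x0 in self._starts(n_restarts, seed):
            res = optimize.minimize(self.nll_and_grad, x0, jac=True,
                                    method="L-BFGS-B", bounds=bounds,
                                    options=dict(maxiter=500, ftol=1e-13,
                                                 gtol=1e-9))
            nfev += res.nfev
            if best is None or res.fun < best.fun:
                best = res
        x = np.asarray(best.x, dtype=float)
        converged = bool(best.success)
        if polish:
            x, _, at_optimum = self._newton_polish(x, bounds)
            converged = converged or at_optimum
        return self._build_result(x, converged, best.message, nfev,
                                  compute_stderr)

    def _build_result(self, x, converged: bool, message: str, nfev: int,
                      compute_stderr: bool) -> DecayFitResult:
        log_amp, alpha2, log_t1, log_t2, offset = self._unpack(x)
        amp = math.exp(log_amp)
        tau1, tau2 = math.exp(log_t1), math.exp(log_t2)
        i_logtau2 = 1 if self.n_components == 1 else 3
        if self.n_components == 2 and tau1 > tau2:   # enforce ordering
            tau1, tau2 = tau2, tau1
            alpha2 = 1.0 - alpha2
            i_logtau2 = 2
        if self.n_components == 1:
            params = DecayParams.mono(tau2, offset_c=offset, amplitude=amp)
        else:
            params = DecayParams(1.0 - alpha2, alpha2, tau1, tau2,
                                 offset_c=offset, amplitude=amp)
        mu = self.expected_counts(x)
        n_free = len(x)
        dof = max(self.acq.n_bins - n_free, 1)
        chisq = float(np.sum((self.counts - mu) ** 2 / np.maximum(mu, 1e-12)))
        stderr = math.nan
        if compute_stderr:
            H = self._num_hessian(x)
            try:
                cov = np.linalg.pinv(H)
                var = cov[i_logtau2, i_logtau2]
                stderr = tau2 * math.sqrt(var) if var > 0 else math.inf
            except np.linalg.LinAlgError:
                stderr = math.inf
        return DecayFitResult(params=params, loglik=self.loglike(x),
                              chisq_reduced=chisq / dof,
                              n_photons=self.n_photons, converged=converged,
                              stderr_tau2=stderr,
                              n_components=self.n_components,
                              message=str(message), nfev=nfev, n_free=len(x))


def fit_histogram(hist, acq: AcquisitionSpec, *, n_components: int = 2,
                  fix_offset: float | None = None, min_photons: float = 100.0,
                  n_restarts: int = 3, seed: int = 0,
                  compute_stderr: bool = True, **model_kw) -> DecayFitResult:
    """Fit one decay histogram; see :class:`IncompleteDecayModel`."""
    model = IncompleteDecayModel(hist, acq, n_components=n_components,
                                 fix_offset=fix_offset,
                                 min_photons=min_photons, **model_kw)
    return model.fit(n_restarts=n_restarts, seed=seed,
                     compute_stderr=compute_stderr)


def fit_histogram_auto(hist, acq: AcquisitionSpec, *,
                       alpha_floor: float = 0.05, **kw) -> DecayFitResult:
    """Fit mono- and bi-exponential incomplete-decay models and keep the one
    with the lower AIC (ties favor the mono model).

    Guards the slow lifetime against spurious components: on effectively
    mono-exponential data the extra component fits noise, so the AIC penalty
    rejects it, and a bi-exponential whose smaller amplitude fraction falls
    below ``alpha_floor`` is treated as physically negligible and replaced
    by the mono fit (which reports tau1 = tau2 = tau).
    """
    kw.pop("n_components", None)
    bi = fit_histogram(hist, acq, n_components=2, **kw)
    if bi.masked:
        return bi
    mono = fit_histogram(hist, acq, n_components=1, **kw)
    use_bi = (bi.aic < mono.aic and bi.params is not None
              and min(bi.params.alpha1, bi.params.alpha2) >= alpha_floor)
    return bi if use_bi else mono


@dataclass
class LifetimeMaps:
    """Per-pixel fitted decay parameters; ``mask`` marks excluded pixels
    (too few photons or failed fits)."""

    tau1: np.ndarray
    tau2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    offset: np.ndarray
    chisq: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def fit_stack(stack: FLIMStack, *, n_components: int = 2,
              fix_offset: float | None = None, min_photons: float = 100.0,
              binning: int = 0, auto_mono: bool = True,
              n_restarts: int = 1, seed: int = 0) -> LifetimeMaps:
    """Fit the incomplete-decay model at every sufficiently bright pixel.

    ``binning`` pools each pixel's histogram with its square neighborhood of
    radius b ((2b+1)^2 pixels) before fitting, as TCSPC software does to
    trade spatial resolution for photons.  With ``auto_mono`` (default) each
    pixel is fit both mono- and bi-exponentially and the lower-AIC model is
    kept, so effectively mono-exponential pixels report tau1 = tau2 instead
    of a spurious low-amplitude slow component.
    """
    counts = stack.counts
    acq = stack.acq
    if binning > 0:
        w = 2 * binning + 1
        counts = ndimage.uniform_filter(counts.astype(float),
                                        size=(w, w, 1), mode="constant") * w * w
        counts = np.rint(counts)
    rows, cols = counts.shape[:2]
    shape = (rows, cols)
    nan = np.full(shape, np.nan)
    maps = LifetimeMaps(tau1=nan.copy(), tau2=nan.copy(), alpha1=nan.copy(),
                        alpha2=nan.copy(), offset=nan.copy(),
                        chisq=nan.copy(), mask=np.ones(shape, dtype=bool),
                        provenance=dict(n_components=n_components,
                                        fix_offset=fix_offset,
                                        min_photons=min_photons,
                                        binning=binning,
                                        auto_mono=auto_mono,
                                        seed=seed))
    totals = counts.sum(axis=2)
    fit_kw = dict(fix_offset=fix_offset, min_photons=min_photons,
                  n_restarts=n_restarts, seed=seed, compute_stderr=False)
    for r, c in zip(*np.nonzero(totals >= min_photons)):
        hist = counts[r, c]
        if auto_mono and n_components == 2:
            res = fit_histogram_auto(hist, acq, **fit_kw)
        else:
            res = fit_histogram(hist, acq, n_components=n_components, **fit_kw)
        if res.params is None or not res.converged:
            continue
        p = res.params
        maps.tau1[r, c] = p.tau1
        maps.tau2[r, c] = p.tau2
        maps.alpha1[r, c] = p.alpha1
        maps.alpha2[r, c] = p.alpha2
        maps.offset[r, c] = p.offset_c
        maps.chisq[r, c] = res.chisq_reduced
        maps.mask[r, c] = False
    return maps


def roi_decay(stack: FLIMStack, region) -> np.ndarray:
    """Bin-wise photon sum over a region (boolean mask or (rows, cols) index
    arrays); the pooled decay histogram of that ROI."""
    region = np.asarray(region) if not isinstance(region, tuple) else region
    if isinstance(region, tuple):
        rows, cols = region
        if len(rows) == 0:
            raise ValueError("empty region")
        return stack.counts[rows, cols].sum(axis=0)
    if region.dtype != bool:
        raise ValueError("region must be a boolean mask or (rows, cols) tuple")
    if region.shape != stack.counts.shape[:2]:
        raise ValueError("region mask shape mismatch")
    if not region.any():
        raise ValueError("empty region")
    return stack.counts[region].sum(axis=0)
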