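"""Subpopulation modeling of per-cell intensities: 1- vs 2-component
Gaussian mixtures selected by AIC.

Heterogeneous injury shows up as multimodal per-cell probe intensity: the
histogram of positive-cell intensities is fitted with a single Gaussian and
with a two-component Gaussian mixture (maximum likelihood on the raw
values, via EM for k=2), and the Akaike information criterion

    AIC_k = 2 p_k - 2 loglik_k,     p_k = 3k - 1

(k means + k SDs + k-1 free weights) picks the number of populations; ties
go to the simpler model.  Densities are reported normalized to unit area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MixtureFit", "IntensityMixture", "SubpopModel",
           "fit_mixture", "select_components"]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class MixtureFit:
    """Maximum-likelihood k-component Gaussian fit (components sorted by mean)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: list[float] = field(default_factory=list, repr=False)
    sd_floored: bool = False

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * _SQRT2PI)
        return out


def _loglik(values, weights, means, sds) -> float:
    dens = np.zeros_like(values)
    for w, m, s in zip(weights, means, sds):
        dens += w * np.exp(-0.5 * ((values - m) / s) ** 2) / (s * _SQRT2PI)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


class IntensityMixture:
    """Gaussian mixture model over a 1D sample of per-cell intensities.

    ``fit(k)`` returns the ML solution: closed-form for k=1, EM with a
    quantile-split initialization plus seeded random restarts for k=2.  An
    SD floor (1e-3 of the data range) guards against likelihood blow-up
    when a component collapses onto a single point.
    """

    def __init__(self, values, sd_floor_frac: float = 1e-3):
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0 or not np.all(np.isfinite(values)):
            raise ValueError("values must be a nonempty finite sample")
        self.values = values
        rng_range = float(values.max() - values.min())
        self.sd_floor = max(sd_floor_frac * rng_range, 1e-12)

    def fit(self, k: int, *, seed: int = 0, n_restarts: int = 5,
            max_iter: int = 500, tol: float = 1e-10) -> MixtureFit:
        v = self.values
        if v.size < 5 * k:
            raise ValueError(f"need at least {5 * k} values for k={k}, got {v.size}")
        if k == 1:
            mean = float(v.mean())
            sd = max(float(v.std(ddof=0)), self.sd_floor)
            ll = _loglik(v, np.array([1.0]), np.array([mean]), np.array([sd]))
            return MixtureFit(1, np.array([1.0]), np.array([mean]),
                              np.array([sd]), ll, True, 0, [ll],
                              sd_floored=sd > v.std(ddof=0))
        if k != 2:
            raise ValueError("only k in {1, 2} is supported")

        best: MixtureFit | None = None
        rng = np.random.default_rng(seed)
        for init in self._inits(rng, n_restarts):
            fit = self._em(init, max_iter=max_iter, tol=tol)
            if best is None or fit.loglik > best.loglik:
                best = fit
        return best

    def _inits(self, rng: np.random.Generator, n_restarts: int):
        v = self.values
        med = np.median(v)
        lo, hi = v[v <= med], v[v > med]
        if lo.size and hi.size:
            yield (np.array([lo.size / v.size, hi.size / v.size]),
                   np.array([lo.mean(), hi.mean()]),
                   np.maximum([lo.std(ddof=0), hi.std(ddof=0)], self.sd_floor))
        sd0 = max(v.std(ddof=0), self.sd_floor)
        for _ in range(n_restarts):
            m = np.sort(rng.choice(v, size=2, replace=False))
            yield (np.array([0.5, 0.5]), m.astype(float),
                   np.array([sd0, sd0]))

    def _em(self, init, *, max_iter: int, tol: float) -> MixtureFit:
        v = self.values
        w, m, s = (np.array(a, dtype=float) for a in init)
        floored = False
        path: list[float] = []
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: responsibilities in a numerically safe log formulation
            logp = (np.log(np.maximum(w, 1e-300))[:, None]
                    - np.log(s)[:, None] - math.log(_SQRT2PI)
                    - 0.5 * ((v[None, :] - m[:, None]) / s[:, None]) ** 2)
            mx = logp.max(axis=0)
            p = np.exp(logp - mx)
            norm = p.sum(axis=0)
            resp = p / norm
            ll = float(np.sum(np.log(norm) + mx))
            path.append(ll)
            if ll - ll_old < tol * (abs(ll) + 1.0) and it > 1:
                converged = True
                break
            ll_old = ll
            # M-step
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-12)
            w = nk / v.size
            m = (resp @ v) / nk
            var = (resp @ (v**2)) / nk - m**2
            s_new = np.sqrt(np.maximum(var, 0.0))
            if np.any(s_new < self.sd_floor):
                floored = True
            s = np.maximum(s_new, self.sd_floor)
        order = np.argsort(m)
        return MixtureFit(2, w[order], m[order], s[order],
                          _loglik(v, w, m, s), converged, it, path,
                          sd_floored=floored)


def fit_mixture(values, k: int, seed: int = 0, **kw) -> MixtureFit:
    """Functional entry point: ML Gaussian mixture fit with ``k`` components."""
    return IntensityMixture(values).fit(k, seed=seed, **kw)


@dataclass
class SubpopModel:
    """1- vs 2-component mixture fits with AIC-based selection."""

    fits: dict[int, MixtureFit]
    selected_k: int

    @property
    def selected(self) -> MixtureFit:
        return self.fits[self.selected_k]

    @property
    def aic(self) -> dict[int, float]:
        return {k: f.aic for k, f in self.fits.items()}

    def density(self, grid=None, n_grid: int = 512):
        """Probability density of the selected model on a grid, normalized
        to unit trapezoid area."""
        fit = self.selected
        if grid is None:
            lo = float((fit.means - 6 * fit.sds).min())
            hi = float((fit.means + 6 * fit.sds).max())
            grid = np.linspace(lo, hi, n_grid)
        grid = np.asarray(grid, dtype=float)
        dens = fit.pdf(grid)
        area = np.trapezoid(dens, grid)
        if area <= 0:
            raise ValueError("degenerate density grid")
        return grid, dens / area

    def to_dict(self) -> dict:
        return {
            "selected_k": self.selected_k,
            "models": {
                str(k): dict(weights=f.weights.tolist(), means=f.means.tolist(),
                             sds=f.sds.tolist(), loglik=f.loglik, aic=f.aic,
                             converged=f.converged)
                for k, f in self.fits.items()
            },
        }


def select_components(values, seed: int = 0,
                      k_candidates=(1, 2)) -> SubpopModel:
    """Fit each candidate component count and select the lowest AIC
    (ties resolved toward fewer components)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 10:
        raise ValueError("need at least 10 values for model selection")
    mixer = IntensityMixture(values)
    fits = {k: mixer.fit(k, seed=seed) for k in sorted(k_candidates)}
    selected_k = min(fits)      # smallest k wins ties
    for k in sorted(fits):
        if fits[k].aic < fits[selected_k].aic:
            selected_k = k
    return SubpopModel(fits=fits, selected_k=selected_k)
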