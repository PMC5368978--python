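"""Synthetic intravital FLIM scene generator with planted ground truth.

Emulates the liver-injury imaging scenes: round hepatocyte-like cells on a
dim autofluorescent background, imaged as a TCSPC photon-count cube under
80 MHz pulsed excitation.  Three templates mirror the experimental arms:

``control``
    one bright population of probe-positive cells;
``injury``
    two intensity subpopulations of positive cells (differentially injured
    hepatocytes), both dimmer than control;
``treated``
    a single recovered population.

Each template parameterizes both a GSH-probe and an ROS-probe channel so
parallel scenes for the oxidative-stress index can be generated from one
template.  Every scene carries a :class:`GroundTruth` with planted labels,
per-cell true decay parameters and subpopulation assignments, which is the
oracle for every downstream stage of the pipeline.

Intensities are expected photons per pixel over the whole acquisition;
photon noise is Poisson per time bin.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.draw import disk

from .photophysics import (AcquisitionSpec, DecayParams, ProbeSpec,
                           decay_bin_profile, load_probe, mix_decay)

__all__ = [
    "PlantedCell", "SyntheticScene", "GroundTruth", "FLIMStack",
    "TEMPLATES", "make_scene", "render_flim", "render_intensity",
    "simulate_decay_histogram",
]

#: Per-template, per-channel intensity populations of probe-POSITIVE cells
#: (expected photons/pixel) and the fraction of planted cells that are
#: probe-positive.  Injury plants a two-component GSH mixture (both means
#: below control) and elevated ROS; treatment restores a single brighter GSH
#: population and lowers ROS.
TEMPLATES: dict[str, dict[str, dict]] = {
    "control": {
        "gsh": dict(means=(6000.0,), sds=(450.0,), weights=(1.0,), positive_fraction=0.9),
        "ros": dict(means=(1200.0,), sds=(180.0,), weights=(1.0,), positive_fraction=0.3),
    },
    "injury": {
        "gsh": dict(means=(2100.0, 3900.0), sds=(270.0, 270.0), weights=(0.5, 0.5),
                    positive_fraction=0.8),
        "ros": dict(means=(4800.0,), sds=(360.0,), weights=(1.0,), positive_fraction=0.8),
    },
    "treated": {
        "gsh": dict(means=(4800.0,), sds=(360.0,), weights=(1.0,), positive_fraction=0.9),
        "ros": dict(means=(2100.0,), sds=(270.0,), weights=(1.0,), positive_fraction=0.4),
    },
}

#: Intensity of probe-negative cells (unreacted probe + autofluorescence).
NEGATIVE_INTENSITY = (1500.0, 180.0)

#: Lifetime assigned to background autofluorescence photons (ns).
BACKGROUND_TAU = 2.5

_DEFAULT_PROBE = {"gsh": "P-GSH", "ros": "P-HP"}


@dataclass(frozen=True)
class PlantedCell:
    cell_id: int
    row: float
    col: float
    diameter_px: float
    subpop: int              # population index; -1 for probe-negative cells
    reacted_frac: float
    intensity: float         # expected photons per pixel
    positive: bool


@dataclass(frozen=True)
class SyntheticScene:
    shape: tuple[int, int]
    cells: tuple[PlantedCell, ...]
    background_level: float
    template: str
    probe_target: str
    seed: int


@dataclass
class GroundTruth:
    """Planted truth for a scene: the oracle for segmentation, fitting,
    positivity and subpopulation recovery."""

    label_map: np.ndarray                       # 0 = background
    params_by_label: dict[int, DecayParams]     # includes key 0 (background)
    subpop_labels: dict[int, int]
    true_means: tuple[float, ...]
    background_params: DecayParams = field(repr=False, default=None)

    def tau2_map(self) -> np.ndarray:
        out = np.empty(self.label_map.shape, dtype=float)
        for lab, p in self.params_by_label.items():
            out[self.label_map == lab] = p.tau2 if p.alpha2 > 0 else p.tau1
        return out

    def positive_map(self) -> np.ndarray:
        out = np.zeros(self.label_map.shape, dtype=bool)
        for lab, p in self.params_by_label.items():
            if lab and p.alpha2 > 0:
                out[self.label_map == lab] = True
        return out


@dataclass
class FLIMStack:
    """Photon-count cube (rows x cols x time bins) with acquisition metadata."""

    counts: np.ndarray
    acq: AcquisitionSpec
    channel: str = "515-620 nm"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != self.acq.n_bins:
            raise ValueError(
                f"counts must be (rows, cols, n_bins={self.acq.n_bins}), "
                f"got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")


def _place_cells(rng: np.random.Generator, shape, n_cells, diameter_range,
                 gap_px: float = 8.0, max_tries: int = 20_000):
    """Rejection-sample non-touching disc centers with a border margin."""
    placed: list[tuple[float, float, float]] = []
    diam_lo, diam_hi = diameter_range
    for _ in range(n_cells):
        d = float(rng.uniform(diam_lo, diam_hi))
        margin = d / 2 + 4.0
        for attempt in range(max_tries):
            r = float(rng.uniform(margin, shape[0] - margin))
            c = float(rng.uniform(margin, shape[1] - margin))
            ok = all((r - r2) ** 2 + (c - c2) ** 2
                     >= ((d + d2) / 2 + gap_px) ** 2
                     for r2, c2, d2 in placed)
            if ok:
                placed.append((r, c, d))
                break
        else:
            raise RuntimeError(
                f"infeasible packing: could not place cell {len(placed) + 1} "
                f"of {n_cells} (shape={shape}, diameters={diameter_range})")
    return placed


def make_scene(template: str, *, probe_target: str = "gsh",
               probe: ProbeSpec | None = None, n_cells: int = 18,
               shape: tuple[int, int] = (320, 320),
               diameter_range: tuple[float, float] = (32.0, 46.0),
               background_level: float = 40.0, reacted_frac: float = 1.0,
               background_fraction: float = 0.15, seed: int = 0,
               subpop_config: Mapping | None = None,
               ) -> tuple[SyntheticScene, GroundTruth]:
    """Plant a scene for one experimental arm and one probe channel.

    Returns the scene description plus its ground truth.  Deterministic for
    a fixed seed.  ``subpop_config`` overrides the template's intensity
    populations (keys ``means``, ``sds``, ``weights``, ``positive_fraction``).
    """
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; choose from {sorted(TEMPLATES)}")
    if probe_target not in _DEFAULT_PROBE:
        raise ValueError(f"probe_target must be one of {sorted(_DEFAULT_PROBE)}")
    cfg = copy.deepcopy(TEMPLATES[template][probe_target])
    if subpop_config:
        cfg.update(subpop_config)
    if probe is None:
        probe = load_probe(_DEFAULT_PROBE[probe_target])

    rng = np.random.default_rng(seed)
    placed = _place_cells(rng, shape, n_cells, diameter_range)

    weights = np.asarray(cfg["weights"], dtype=float)
    weights = weights / weights.sum()
    means, sds = cfg["means"], cfg["sds"]

    cells: list[PlantedCell] = []
    label_map = np.zeros(shape, dtype=np.int32)
    params_by_label: dict[int, DecayParams] = {
        0: DecayParams.mono(BACKGROUND_TAU)}
    subpop_labels: dict[int, int] = {}

    pos_params = mix_decay(reacted_frac, probe,
                           background_fraction=background_fraction)
    neg_params = mix_decay(0.0, probe, background_fraction=background_fraction)

    for i, (r, c, d) in enumerate(placed, start=1):
        positive = bool(rng.random() < cfg["positive_fraction"])
        if positive:
            pop = int(rng.choice(len(weights), p=weights))
            intensity = float(max(rng.normal(means[pop], sds[pop]), 1.0))
        else:
            pop = -1
            intensity = float(max(rng.normal(*NEGATIVE_INTENSITY), 1.0))
        cells.append(PlantedCell(i, r, c, d, pop,
                                 reacted_frac if positive else 0.0,
                                 intensity, positive))
        rr, cc = disk((r, c), d / 2, shape=shape)
        label_map[rr, cc] = i
        params_by_label[i] = pos_params if positive else neg_params
        subpop_labels[i] = pop

    scene = SyntheticScene(shape=tuple(shape), cells=tuple(cells),
                           background_level=background_level,
                           template=template, probe_target=probe_target,
                           seed=seed)
    truth = GroundTruth(label_map=label_map, params_by_label=params_by_label,
                        subpop_labels=subpop_labels,
                        true_means=tuple(means),
                        background_params=params_by_label[0])
    return scene, truth


def render_flim(scene: SyntheticScene, truth: GroundTruth,
                acq: AcquisitionSpec | None = None, *, seed: int = 0,
                exposure: float = 1.0, channel: str = "515-620 nm") -> FLIMStack:
    """Render a scene into a Poisson TCSPC photon-count cube.

    Each pixel's per-bin counts are independent Poisson draws with mean
    equal to the pixel's expected photon total (cell intensity inside cells,
    ``background_level`` outside, times ``exposure``) distributed over bins
    according to the periodic decay profile of the pixel's true parameters.
    """
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed)

    totals = np.full(scene.shape, scene.background_level, dtype=float)
    for cell in scene.cells:
        totals[truth.label_map == cell.cell_id] = cell.intensity
    totals *= exposure

    # group labels sharing identical decay parameters: one profile per class
    class_of: dict[DecayParams, list[int]] = {}
    for lab, p in truth.params_by_label.items():
        class_of.setdefault(p, []).append(lab)

    counts = np.zeros(scene.shape + (acq.n_bins,), dtype=np.int32)
    for params, labels in class_of.items():
        profile = decay_bin_profile(params, acq)
        sel = np.isin(truth.label_map, labels)
        lam = totals[sel, None] * profile[None, :]
        counts[sel] = rng.poisson(lam)
    return FLIMStack(counts=counts, acq=acq, channel=channel)


def render_intensity(stack: FLIMStack) -> np.ndarray:
    """Time-integrated intensity image: per-pixel sum over all time bins."""
    return stack.counts.sum(axis=2)


def simulate_decay_histogram(params: DecayParams, acq: AcquisitionSpec,
                             n_photons: float, seed=None) -> np.ndarray:
    """Poisson TCSPC histogram of one ROI with ``n_photons`` expected decay
    photons (plus ``params.offset_c`` expected background counts per bin)."""
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = n_photons * decay_bin_profile(params, acq) + params.offset_c
    return rng.poisson(lam)
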