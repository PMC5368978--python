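"""Optical oxidative-stress index (OSI) and group comparisons.

The OSI is the ratio of the mean per-cell ROS-probe intensity to the mean
per-cell GSH-probe intensity, taken over probe-positive cells of parallel
scenes (the ROS and GSH probes are injected in separate animals, so the two
channels come from matched experimental arms rather than co-stained cells).
A rising OSI means ROS production is outpacing the antioxidant pool.

Group comparisons use the classic two-sided Student's t test with a
Bonferroni correction over the number of pairwise comparisons performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OSIResult", "compute_osi", "compare_groups"]


@dataclass(frozen=True)
class OSIResult:
    """OSI for one experimental group/timepoint; ``osi`` is exactly
    mean_ros_intensity / mean_gsh_intensity."""

    mean_ros_intensity: float
    mean_gsh_intensity: float
    osi: float
    n_cells_ros: int
    n_cells_gsh: int
    group: str | None = None
    timepoint: str | None = None


def _cell_intensities(records: pd.DataFrame, positive_only: bool,
                      which: str) -> np.ndarray:
    if len(records) == 0:
        raise ValueError(f"empty {which} record list")
    sel = records
    if positive_only:
        sel = records[records["classifiable"] & records["positive"]]
    vals = np.asarray(sel["mean_intensity"], dtype=float)
    if vals.size == 0:
        raise ValueError(f"no usable {which} cells for the OSI denominator/numerator")
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite {which} intensities")
    return vals


def compute_osi(ros_cells: pd.DataFrame, gsh_cells: pd.DataFrame, *,
                positive_only: bool = True, group: str | None = None,
                timepoint: str | None = None) -> OSIResult:
    """OSI = mean(per-cell ROS intensity) / mean(per-cell GSH intensity).

    By default only probe-positive (FLIM-confirmed) cells enter the means,
    which is what suppresses intensity-only false positives.
    """
    ros = _cell_intensities(ros_cells, positive_only, "ROS")
    gsh = _cell_intensities(gsh_cells, positive_only, "GSH")
    mean_ros = float(ros.mean())
    mean_gsh = float(gsh.mean())
    if mean_gsh <= 0:
        raise ValueError("GSH mean intensity must be positive")
    return OSIResult(mean_ros_intensity=mean_ros, mean_gsh_intensity=mean_gsh,
                     osi=mean_ros / mean_gsh, n_cells_ros=ros.size,
                     n_cells_gsh=gsh.size, group=group, timepoint=timepoint)


def compare_groups(groups: Mapping[str, Sequence[float]], *,
                   alpha: float = 0.05, equal_var: bool = True,
                   n_comparisons: int | None = None) -> pd.DataFrame:
    """All pairwise two-sample t tests with a Bonferroni correction.

    ``equal_var=True`` is the classic Student's t test; set False for
    Welch's.  The Bonferroni multiplier defaults to the number of pairs
    tested but can be overridden when the comparisons reported are a subset
    of a larger family.  Returns one row per pair with the t statistic, raw
    and adjusted p-values, and the significance flag at ``alpha``.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(clean, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    if m < 1:
        raise ValueError("n_comparisons must be >= 1")
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(clean[a], clean[b], equal_var=equal_var)
        p_adj = min(1.0, float(p) * m)
        rows.append((a, b, float(t), float(p), p_adj,
                     clean[a].size, clean[b].size, p_adj < alpha))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_raw",
                                       "p_bonferroni", "n_a", "n_b",
                                       "significant"])
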