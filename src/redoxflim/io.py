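"""File formats: FLIM stacks (multi-page TIFF + JSON sidecar), intensity and
label images, lifetime maps, cell tables, and the pseudo-color tau2 export.

A FLIM stack is stored as one TIFF page per time bin with a JSON sidecar
carrying the acquisition metadata (repetition rate, bin count, channel);
the pair round-trips losslessly.  The sidecar lives next to the TIFF with a
``.json`` suffix unless an explicit path is given.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib import colormaps, colors
from PIL import Image

from .fitting import LifetimeMaps
from .photophysics import AcquisitionSpec
from .segmentation import CellLabelMap
from .simulate import FLIMStack

__all__ = [
    "write_flim_stack", "read_flim_stack",
    "write_image", "read_image",
    "write_label_map", "read_label_map",
    "write_cells", "read_cells",
    "write_lifetime_maps", "read_lifetime_maps",
    "save_tau2_png",
]


def _sidecar_path(tif_path: Path, sidecar_path=None) -> Path:
    return Path(sidecar_path) if sidecar_path else Path(tif_path).with_suffix(".json")


def write_flim_stack(stack: FLIMStack, tif_path, sidecar_path=None) -> None:
    """Write counts as a multi-page TIFF (one page per bin) + JSON sidecar."""
    tif_path = Path(tif_path)
    counts = np.asarray(stack.counts)
    dtype = np.uint16 if counts.max(initial=0) < 2**16 else np.uint32
    pages = np.transpose(counts, (2, 0, 1)).astype(dtype)
    tifffile.imwrite(tif_path, pages, photometric="minisblack")
    meta = {
        "rep_rate_mhz": stack.acq.rep_rate_mhz,
        "n_bins": stack.acq.n_bins,
        "period_ns": stack.acq.period_ns,
        "channel": stack.channel,
        "shape": list(counts.shape[:2]),
    }
    _sidecar_path(tif_path, sidecar_path).write_text(json.dumps(meta, indent=1))


def read_flim_stack(tif_path, sidecar_path=None) -> FLIMStack:
    """Read a stack written by :func:`write_flim_stack`; validates that the
    TIFF page count matches the sidecar's ``n_bins``."""
    tif_path = Path(tif_path)
    sidecar = _sidecar_path(tif_path, sidecar_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(tif_path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != meta["n_bins"]:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but sidecar says "
            f"n_bins={meta['n_bins']}")
    if list(pages.shape[1:]) != list(meta["shape"]):
        raise ValueError("TIFF page shape disagrees with sidecar")
    acq = AcquisitionSpec(rep_rate_mhz=meta["rep_rate_mhz"],
                          n_bins=meta["n_bins"])
    counts = np.transpose(pages, (1, 2, 0)).astype(np.int64)
    return FLIMStack(counts=counts, acq=acq, channel=meta.get("channel", ""))


def write_image(image, path) -> None:
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.uint32 if image.max(initial=0) >= 2**16
                             else np.uint16)
    else:
        image = image.astype(np.float32)
    tifffile.imwrite(Path(path), image, photometric="minisblack")


def read_image(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_label_map(labels, path) -> None:
    lab = labels.labels if isinstance(labels, CellLabelMap) else np.asarray(labels)
    if lab.max(initial=0) >= 2**16:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(Path(path), lab.astype(np.uint16), photometric="minisblack")
    if isinstance(labels, CellLabelMap) and labels.provenance:
        Path(path).with_suffix(".json").write_text(
            json.dumps(labels.provenance, indent=1, default=str))


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_cells(records: pd.DataFrame, path) -> None:
    records.to_csv(Path(path), index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


_MAP_CHANNELS = ("tau1", "tau2", "alpha1", "alpha2", "offset", "chisq")


def write_lifetime_maps(maps: LifetimeMaps, directory) -> None:
    """Lifetime maps as a 6-channel float TIFF + mask TIFF + provenance JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = np.stack([getattr(maps, name) for name in _MAP_CHANNELS])
    tifffile.imwrite(directory / "maps.tif", channels.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(directory / "mask.tif", maps.mask.astype(np.uint8),
                     photometric="minisblack")
    (directory / "maps.json").write_text(
        json.dumps({"channels": list(_MAP_CHANNELS),
                    "provenance": maps.provenance}, indent=1, default=str))


def read_lifetime_maps(directory) -> LifetimeMaps:
    directory = Path(directory)
    channels = tifffile.imread(directory / "maps.tif").astype(float)
    mask = tifffile.imread(directory / "mask.tif").astype(bool)
    meta = json.loads((directory / "maps.json").read_text())
    kwargs = {name: channels[i] for i, name in enumerate(meta["channels"])}
    return LifetimeMaps(mask=mask, provenance=meta.get("provenance", {}), **kwargs)


def save_tau2_png(maps: LifetimeMaps | np.ndarray, path, *, vmin: float = 0.0,
                  vmax: float = 250.0, cmap: str = "viridis",
                  mask: np.ndarray | None = None) -> None:
    """Pseudo-color slow-lifetime image with a fixed color range so scenes
    are visually comparable; masked pixels are black."""
    if isinstance(maps, LifetimeMaps):
        tau2, mask = maps.tau2, maps.mask
    else:
        tau2 = np.asarray(maps, dtype=float)
    norm = colors.Normalize(vmin=vmin, vmax=vmax, clip=True)
    rgba = colormaps[cmap](norm(np.nan_to_num(tau2, nan=vmin)))
    if mask is not None:
        rgba[mask] = (0.0, 0.0, 0.0, 1.0)
    Image.fromarray((rgba * 255).astype(np.uint8)).save(Path(path))
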