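"""Reductions of fluence grids to the study's reported quantities.

* :func:`depth_profile` — fluence averaged over the 0.5 mm x 20 mm region of
  interest centered on the imaging plane, per depth layer.
* :func:`peak_fluence` — the profile maximum and its depth (shallower depth
  wins ties).
* :func:`species_ratio` — max-over-angles peak fluence of the thin-skin
  (mouse) runs divided by that of the thick-skin (human) runs.
* :func:`snr_score` — Monte Carlo convergence score: mean/std of the fluence
  over a 0.5 mm x 0.5 mm sliding kernel on the imaging-plane slice, averaged
  over the plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mc_engine import FluenceGrid

__all__ = [
    "DepthProfile",
    "RoiSpec",
    "SnrResult",
    "depth_profile",
    "peak_fluence",
    "roi_band_slice",
    "snr_score",
    "species_ratio",
]


@dataclass(frozen=True)
class RoiSpec:
    """Averaging region centered on the imaging plane.

    x_half_width: half-extent across the plane (total 0.5 mm by default);
    y_half_extent: half-extent along the array (total 20 mm by default).
    """

    x_half_width: float = 0.25
    y_half_extent: float = 10.0


@dataclass
class DepthProfile:
    """ROI-averaged fluence (1/mm^2) per depth layer."""

    depth: np.ndarray        # mm, voxel-center depths
    mean_fluence: np.ndarray

    def __post_init__(self) -> None:
        if len(self.depth) != len(self.mean_fluence):
            raise ValueError("depth and mean_fluence must have equal length")


@dataclass(frozen=True)
class SnrResult:
    """Plane-averaged and minimum kernel SNR; NaN when every kernel is flat."""

    mean: float
    min: float
    n_voxels: int
    n_excluded: int


def _roi_masks(grid: FluenceGrid, roi: RoiSpec) -> tuple[np.ndarray, np.ndarray]:
    nx, ny, _ = grid.values.shape
    p = grid.pitch
    x_centers = (np.arange(nx) + 0.5) * p - nx * p / 2.0
    y_centers = (np.arange(ny) + 0.5) * p - ny * p / 2.0
    mx = np.abs(x_centers) <= roi.x_half_width
    my = np.abs(y_centers) <= roi.y_half_extent
    if not mx.any() or not my.any():
        raise ValueError(
            f"ROI ({2 * roi.x_half_width} x {2 * roi.y_half_extent} mm) covers "
            f"no voxel centers at pitch {p} mm"
        )
    return mx, my


def depth_profile(grid: FluenceGrid, roi: RoiSpec | None = None) -> DepthProfile:
    """Average the fluence over the ROI cross-section at every depth."""
    roi = roi or RoiSpec()
    mx, my = _roi_masks(grid, roi)
    sub = grid.values[np.ix_(mx, my)]
    prof = sub.mean(axis=(0, 1))
    nz = grid.values.shape[2]
    depth = (np.arange(nz) + 0.5) * grid.pitch
    return DepthProfile(depth=depth, mean_fluence=prof)


def peak_fluence(profile: DepthProfile) -> tuple[float, float]:
    """(max fluence, depth of max); ties resolved toward the shallower depth."""
    if len(profile.mean_fluence) == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(profile.mean_fluence))  # argmax returns first maximum
    return float(profile.mean_fluence[i]), float(profile.depth[i])


def species_ratio(mouse_peaks, human_peaks) -> float:
    """Max-over-angles peak fluence, thin skin over thick skin.

    Both inputs are the per-angle peak fluences of one condition; the ratio
    of their maxima quantifies how much more light the imaging plane receives
    through mouse-thickness skin than human-thickness skin.
    """
    mouse = np.asarray(list(mouse_peaks), dtype=float)
    human = np.asarray(list(human_peaks), dtype=float)
    if mouse.size == 0 or human.size == 0:
        raise ValueError("empty peak inputs")
    if mouse.size != human.size:
        raise ValueError("mouse and human sweeps must cover the same angle grid")
    hmax = human.max()
    if hmax <= 0:
        raise ValueError("zero maximum fluence in the thick-skin sweep")
    return float(mouse.max() / hmax)


def roi_band_slice(grid: FluenceGrid, roi: RoiSpec | None = None) -> np.ndarray:
    """Imaging-plane slice: the ROI x-band collapsed by averaging.

    Returns a 2-D (y, z) array.  Collapsing the thin band instead of taking a
    single one-voxel plane keeps the kernel statistics meaningful at coarse
    pitch.
    """
    roi = roi or RoiSpec()
    mx, _ = _roi_masks(grid, roi)
    return grid.values[mx].mean(axis=0)


def snr_score(
    grid: FluenceGrid,
    kernel_mm: float = 0.5,
    roi: RoiSpec | None = None,
) -> SnrResult:
    """Kernel SNR (mean/std) over the imaging-plane slice.

    A square kernel of ``kernel_mm`` per side slides over the (y, z) plane
    slice; each voxel's SNR is the kernel mean divided by the kernel standard
    deviation.  Voxels whose kernel is exactly flat (std = 0, e.g. untouched
    deep regions) are excluded from the average; if everything is excluded
    both statistics are NaN.
    """
    plane = roi_band_slice(grid, roi)
    k = round(kernel_mm / grid.pitch)
    if k < 2:
        raise ValueError(
            f"{kernel_mm} mm kernel spans {k} voxel(s) at pitch {grid.pitch} mm; "
            "need at least 2"
        )
    mean = ndimage.uniform_filter(plane, size=k, mode="nearest")
    meansq = ndimage.uniform_filter(plane * plane, size=k, mode="nearest")
    var = np.maximum(meansq - mean * mean, 0.0)
    std = np.sqrt(var)
    valid = std > 0
    if not valid.any():
        return SnrResult(mean=math.nan, min=math.nan,
                         n_voxels=plane.size, n_excluded=plane.size)
    snr = mean[valid] / std[valid]
    return SnrResult(
        mean=float(snr.mean()),
        min=float(snr.min()),
        n_voxels=plane.size,
        n_excluded=int(plane.size - valid.sum()),
    )
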