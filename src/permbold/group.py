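"""Group-level BOLD response map: Gaussian smoothing + voxelwise median.

Subject maps (already in a common voxel space) are smoothed with a 3-D
isotropic Gaussian of a given standard deviation in millimetres, then
combined by the voxelwise median.  The median is preferred over the mean
for robustness to outlying subjects; the pipeline order is fixed as
smooth-then-median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

__all__ = ["GroupBoldMap", "smooth_map", "median_map"]


@dataclass(frozen=True)
class GroupBoldMap:
    """Voxelwise median of smoothed subject maps."""

    median_map: np.ndarray
    n_subjects: int
    smoothing_sd_mm: float
    mask: np.ndarray | None = None


def smooth_map(
    volume: np.ndarray,
    sd_mm: float,
    voxel_size_mm: Sequence[float],
    mask: np.ndarray | None = None,
    truncate: float = 4.0,
) -> np.ndarray:
    """Separable Gaussian smoothing with per-axis SD = sd_mm / voxel size.

    Outside-grid (and, when ``mask`` is given, outside-mask) voxels are
    treated as absent: the data are zero-padded and the kernel is
    renormalised over the available support, which avoids edge
    attenuation.  ``sd_mm = 0`` returns the input unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    if sd_mm < 0:
        raise ConfigurationError("smoothing SD must be >= 0")
    if any(v <= 0 for v in voxel_size_mm):
        raise ConfigurationError("voxel sizes must be positive")
    if sd_mm == 0:
        return volume.copy()
    sigma_vox = [sd_mm / v for v in voxel_size_mm]
    if mask is not None:
        support = np.asarray(mask, dtype=float)
        data = np.where(mask, volume, 0.0)
    else:
        support = np.ones_like(volume)
        data = volume
    num = ndimage.gaussian_filter(data, sigma_vox, mode="constant",
                                  truncate=truncate)
    den = ndimage.gaussian_filter(support, sigma_vox, mode="constant",
                                  truncate=truncate)
    out = np.zeros_like(volume)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = 0.0
    return out


def smoothing_normalizer(mask_or_shape, sd_mm, voxel_size_mm, truncate=4.0):
    """Precomputable denominator field for repeated smoothing with the
    same mask (used by the permutation engine)."""
    if isinstance(mask_or_shape, tuple):
        support = np.ones(mask_or_shape)
    else:
        support = np.asarray(mask_or_shape, dtype=float)
    sigma_vox = [sd_mm / v for v in voxel_size_mm]
    return ndimage.gaussian_filter(support, sigma_vox, mode="constant",
                                   truncate=truncate)


def median_map(
    maps: Sequence[np.ndarray],
    smoothing_sd_mm: float = 0.0,
    mask: np.ndarray | None = None,
    masks: Sequence[np.ndarray] | None = None,
    min_subjects: int | None = None,
) -> GroupBoldMap:
    """Voxelwise sample median across subject maps.

    Even subject counts use the midpoint of the two central order
    statistics.  When per-subject ``masks`` are given, out-of-mask values
    are treated as absent and the median is taken over available values;
    voxels with fewer than ``min_subjects`` contributors (default: all
    subjects) are set to 0.
    """
    if len(maps) == 0:
        raise ConfigurationError("median of an empty map list")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    if masks is None:
        med = np.median(stack, axis=0)
    else:
        avail = np.stack([np.asarray(m, dtype=bool) for m in masks])
        need = len(maps) if min_subjects is None else min_subjects
        data = np.where(avail, stack, np.nan)
        with np.errstate(invalid="ignore"):
            med = np.nanmedian(np.where(avail.sum(axis=0) >= need, data, 0.0),
                               axis=0)
        med = np.nan_to_num(med)
    if mask is not None:
        med = np.where(mask, med, 0.0)
    return GroupBoldMap(median_map=med, n_subjects=len(maps),
                        smoothing_sd_mm=smoothing_sd_mm, mask=mask)
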