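"""Intensity preprocessing and body-mask extraction.

HU volumes are clipped to [-1000, 3000] and divided by 1000 before entering
the network; the inverse map returns to HU. Resampling preserves the physical
extent of the grid and uses a separable not-a-knot cubic spline by default
(which reproduces polynomials up to degree 3 exactly, boundaries included);
masks must be resampled with nearest-neighbour interpolation.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline

from .core import SemanticsError, Volume

HU_MIN, HU_MAX = -1000.0, 3000.0
NORM_FACTOR = 1000.0


def clip_and_normalize(volume: Volume) -> Volume:
    """Clip to [-1000, 3000] HU and divide by 1000 (range becomes [-1, 3])."""
    volume.require_semantics("HU")
    vals = np.clip(volume.values.astype(np.float64), HU_MIN, HU_MAX) / NORM_FACTOR
    return volume.like(vals, semantics="normalized")


def denormalize(volume: Volume) -> Volume:
    """Multiply by 1000, back to HU."""
    volume.require_semantics("normalized")
    return volume.like(volume.values.astype(np.float64) * NORM_FACTOR, semantics="HU")


def _resample_axis(arr: np.ndarray, new_n: int, axis: int, order: int) -> np.ndarray:
    n = arr.shape[axis]
    if new_n == n:
        return arr
    # cell-centred target positions in source index space (extent preserved)
    pos = (np.arange(new_n) + 0.5) * (n / new_n) - 0.5
    if order == 0:
        idx = np.clip(np.rint(pos).astype(int), 0, n - 1)
        return np.take(arr, idx, axis=axis)
    spline = make_interp_spline(np.arange(n, dtype=float), arr, k=order, axis=axis)
    return spline(pos)


def resample(volume: Volume, target_shape: Sequence[int], order: int = 3) -> Volume:
    """Resample onto ``target_shape`` voxels, rescaling spacing to keep extent.

    ``order`` 0 (nearest, required for masks), 1 (linear) or 3 (cubic spline,
    default for images).
    """
    if order not in (0, 1, 3):
        raise ValueError(f"interpolation order must be 0, 1 or 3, got {order}")
    if volume.semantics == "mask" and order != 0:
        raise SemanticsError("masks must be resampled with order 0")
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValueError(f"invalid target shape {target_shape}")
    vals = volume.values.astype(np.float64)
    for axis in range(3):
        vals = _resample_axis(vals, target_shape[axis], axis, order)
    new_spacing = tuple(
        s * volume.shape[i] / target_shape[i] for i, s in enumerate(volume.spacing)
    )
    new_origin = tuple(
        o - volume.spacing[i] / 2.0 + new_spacing[i] / 2.0
        for i, o in enumerate(volume.origin)
    )
    return Volume(vals, new_spacing, new_origin, volume.semantics)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r ** 2


def external_body_mask(volume: Volume, threshold: float = -400.0,
                       closing_radius: int = 2,
                       exclude: Optional[Volume] = None) -> Volume:
    """Threshold-based external body contour.

    Largest connected component of ``values > threshold`` (default -400 HU,
    standard air/tissue separation), morphologically closed and hole-filled.
    ``exclude`` subtracts a fixation-device mask before the component search —
    a no-op on phantoms, exposed for real data.
    """
    volume.require_semantics("HU")
    fg = volume.values > threshold
    if exclude is not None:
        volume.check_geometry(exclude)
        fg &= exclude.values == 0
    if not fg.any():
        raise ValueError(f"no voxels above {threshold} HU")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=_ball(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    return volume.like(fg.astype(np.float32), semantics="mask")


def crop_to_mask(volume: Volume, mask: Volume, margin: int = 0) -> Volume:
    """Crop to the bounding box of a mask plus a voxel margin (utility)."""
    volume.check_geometry(mask)
    mask.require_semantics("mask")
    idx = np.argwhere(mask.values > 0)
    if idx.size == 0:
        raise ValueError("empty mask")
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, volume.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    new_origin = tuple(
        o + int(lo[i]) * volume.spacing[i] for i, o in enumerate(volume.origin)
    )
    return Volume(volume.values[sl], volume.spacing, new_origin, volume.semantics)
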