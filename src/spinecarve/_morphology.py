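"""Physical (millimetre) mathematical morphology on anisotropic lattices.

Erosion and dilation by a Euclidean ball of physical radius ``r`` are
computed through exact Euclidean distance transforms: a voxel survives
erosion iff no background voxel lies within distance ``r`` of it, and a
voxel joins the dilation iff some foreground voxel lies within ``r``.
On a lattice these are exactly the classical operations with the ball
structuring element ``{o : ||o * spacing|| <= r}``, but cost O(N)
instead of O(N * |ball|).

Outside the array is treated as background (border_value = 0), matching
the convention that a bounding box erodes from its faces.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["erode_ball", "dilate_ball", "ball_offsets"]


def ball_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Integer offsets of the physical ball structuring element.

    Returns the (M, 3) array of offsets ``o`` with ``||o * spacing|| <=
    radius_mm``; used by tests and anywhere an explicit element is needed.
    """
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    ax = [np.arange(-h, h + 1) for h in half]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    norms2 = ((grid * spacing) ** 2).sum(axis=1)
    return grid[norms2 <= radius_mm**2 + 1e-9]

def erode_ball(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Erode a boolean array by a physical ball of ``radius_mm``."""
    if radius_mm <= 0:
        return mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=spacing)
    return dist[1:-1, 1:-1, 1:-1] > radius_mm + 1e-9


def dilate_ball(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Dilate a boolean array by a physical ball, clipped to the array."""
    if radius_mm <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm + 1e-9
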