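"""ROI construction and the invertible volume-to-chain spiral transform.

A hidden Markov *chain* needs the 3D region of interest linearized into
a 1D sequence, and the segmentation quality depends on consecutive
chain elements being spatial neighbors (few spurious state
transitions). Raster sweeps distort badly and Hilbert curves still jump
across anatomical boundaries, so the chain follows the shape found by
the coarse stage instead: each axial slice of the ROI is peeled into
concentric perimeters (iterative 2D erosion), each perimeter is walked
in a deterministic contour order, and the walk alternates
inward / outward from slice to slice so that the chain never makes a
long jump at a slice boundary.

The path is a bijection with the ROI voxels, so the MPM label sequence
maps back to a mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._morphology import dilate_ball
from .errors import EmptyMaskError
from .volume_io import BinaryMask, ScalarVolume

__all__ = ["Chain", "build_roi", "spiral_transform", "inverse_spiral_transform"]

_STRUCT2D = np.ones((3, 3), dtype=bool)
_NEIGHBORS8 = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               if (dx, dy) != (0, 0)]


@dataclass(eq=False)
class Chain:
    """A 1D observation sequence plus the invertible voxel path.

    ``y[n]`` is the observation at voxel ``path[n]``; the path visits
    each ROI voxel exactly once. ``slice_breaks`` holds the chain
    indices at which a new axial slice starts, and ``directions`` the
    traversal sense ("inward"/"outward") of each visited slice.
    """

    y: np.ndarray
    path: np.ndarray  # (N, 3) int voxel coordinates
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    slice_breaks: list[int] = field(default_factory=list)
    directions: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


def build_roi(coarse: BinaryMask, radius_mm: float = 10.0) -> BinaryMask:
    """Dilate the coarse mask by a physical ball (default 10 mm).

    The ROI is guaranteed to contain the coarse mask and, by design,
    enough non-vertebral voxels for the two-class mixture to be
    estimable.
    """
    if not coarse.data.any():
        raise EmptyMaskError("cannot build an ROI from an empty coarse mask")
    return coarse.like(dilate_ball(coarse.data, radius_mm, coarse.spacing))


def _walk_ring(
    ring: set[tuple[int, int]],
    start_ref: tuple[float, float] | None,
    spacing2d: np.ndarray,
) -> list[tuple[int, int]]:
    """Deterministic walk visiting every ring pixel exactly once.

    Starts at the pixel nearest ``start_ref`` (lexicographic smallest if
    None), prefers unvisited 8-neighbors (nearest physical first, then
    lexicographic), and jumps to the nearest remaining pixel when stuck
    (disconnected ring components).
    """

    def _phys(p):
        return (p[0] * spacing2d[0], p[1] * spacing2d[1])

    def _closest(candidates, ref):
        rx, ry = ref
        return min(
            candidates,
            key=lambda p: ((p[0] * spacing2d[0] - rx) ** 2
                           + (p[1] * spacing2d[1] - ry) ** 2, p),
        )

    remaining = set(ring)
    order: list[tuple[int, int]] = []
    if start_ref is None:
        cur = min(remaining)
    else:
        cur = _closest(remaining, start_ref)
    remaining.discard(cur)
    order.append(cur)
    while remaining:
        nbrs = [(cur[0] + dx, cur[1] + dy) for dx, dy in _NEIGHBORS8]
        nbrs = [p for p in nbrs if p in remaining]
        if nbrs:
            cur = _closest(nbrs, _phys(cur))
        else:
            cur = _closest(remaining, _phys(cur))
        remaining.discard(cur)
        order.append(cur)
    return order


def _slice_rings(section: np.ndarray) -> list[np.ndarray]:
    """Concentric perimeters by iterative 8-connected 2D erosion;
    index 0 is the outermost ring."""
    rings = []
    cur = section
    while cur.any():
        inner = ndimage.binary_erosion(cur, structure=_STRUCT2D,
                                       border_value=0)
        rings.append(cur & ~inner)
        cur = inner
    return rings


def spiral_transform(volume: ScalarVolume, roi: BinaryMask) -> Chain:
    """Linearize the ROI along a shape-adapted spiral.

    Axial slices are processed in ascending z. Odd-numbered nonempty
    slices are traversed outermost ring to innermost, even-numbered
    ones innermost to outermost, each ring starting next to the
    previous ring's endpoint, so consecutive spiral extremities stay
    spatially close across slices.
    """
    if not roi.data.any():
        raise EmptyMaskError("spiral transform requires a non-empty ROI")
    if roi.shape != volume.shape:
        raise ValueError("ROI and volume shapes differ")
    spacing2d = np.asarray(roi.spacing[:2], dtype=float)

    path: list[tuple[int, int, int]] = []
    slice_breaks: list[int] = []
    directions: list[str] = []
    prev_end: tuple[float, float] | None = None
    n_nonempty = 0
    for z in range(roi.shape[2]):
        section = roi.data[:, :, z]
        if not section.any():
            continue
        n_nonempty += 1
        rings = _slice_rings(section)
        if n_nonempty % 2 == 1:
            directions.append("inward")
        else:
            rings = rings[::-1]
            directions.append("outward")
        slice_breaks.append(len(path))
        for ring_arr in rings:
            ring = set(map(tuple, np.argwhere(ring_arr)))
            order = _walk_ring(ring, prev_end, spacing2d)
            path.extend((x, y, z) for x, y in order)
            end = order[-1]
            prev_end = (end[0] * spacing2d[0], end[1] * spacing2d[1])

    path_arr = np.asarray(path, dtype=np.int64)
    y = np.asarray(volume.data, float)[tuple(path_arr.T)]
    return Chain(y=y, path=path_arr, shape=volume.shape,
                 spacing=roi.spacing, slice_breaks=slice_breaks,
                 directions=directions)


def inverse_spiral_transform(
    labels: np.ndarray, chain: Chain, shape: tuple[int, int, int] | None = None
) -> BinaryMask:
    """Re-build a mask from a class sequence along the chain path.

    ``labels[n]`` (0/1 or bool) lands at ``chain.path[n]``; voxels
    outside the ROI are False.
    """
    labels = np.asarray(labels)
    if len(labels) != len(chain):
        raise ValueError(
            f"label sequence length {len(labels)} != chain length {len(chain)}"
        )
    shape = shape or chain.shape
    out = np.zeros(shape, dtype=bool)
    out[tuple(chain.path.T)] = labels.astype(bool)
    return BinaryMask(out, chain.spacing)
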