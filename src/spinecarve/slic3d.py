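"""SLIC supervoxels on masked 3D gray-level data.

This generalizes simple linear iterative clustering (SLIC) from 2D
color images to 3D scalar volumes restricted to an arbitrary voxel
mask. A voxel ``i`` is represented by its physical coordinates
``(x_i, y_i, z_i) = index * spacing`` (mm) and its luminance ``l_i``
(HU). A cluster centroid ``C_k`` is the mean of its members along
those four features, and voxels are assigned by the mixed distance

    D_m(C_k, i) = sqrt((d_c / m)^2 + (d_s / S)^2)

where ``d_s`` is the 3D Euclidean distance (mm), ``d_c = |l_k - l_i|``
(HU), ``S`` is the expected cluster spacing in millimetres (physical,
so anisotropic voxels are handled correctly) and ``m`` weighs luminance
coherence against spatial compactness.

The clustering is local: each centroid only competes for voxels inside
a cubic window of physical side 2S centred on it, which makes the sweep
linear in the volume size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError
from .volume_io import BinaryMask, ScalarVolume

__all__ = [
    "Centroid",
    "ClusterLabelMap",
    "SlicParams",
    "mixed_distance",
    "init_centroid_grid",
    "run_slic3d",
]


@dataclass(frozen=True)
class Centroid:
    """Cluster centroid: mean physical position (mm), mean luminance (HU),
    and member count."""

    position: tuple[float, float, float]
    luminance: float
    size: int


@dataclass(eq=False)
class ClusterLabelMap:
    """A supervoxel partition of a masked region.

    ``labels`` holds the cluster id (>= 0) for in-mask voxels and -1
    outside. ``positions`` (K, 3), ``luminances`` (K,) and ``sizes``
    (K,) form the centroid table indexed by cluster id.
    """

    labels: np.ndarray
    positions: np.ndarray
    luminances: np.ndarray
    sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def centroid(self, k: int) -> Centroid:
        return Centroid(tuple(self.positions[k]), float(self.luminances[k]),
                        int(self.sizes[k]))

    def cluster_mask(self, k: int) -> np.ndarray:
        return self.labels == k


@dataclass
class SlicParams:
    """S: expected cluster spacing (mm); m: luminance-vs-space weight (HU);
    n_iter: assignment/update repetitions; enforce_connectivity: split
    spatially disconnected clusters into separate labels at the end."""

    S: float
    m: float
    n_iter: int = 5
    enforce_connectivity: bool = False

    def __post_init__(self) -> None:
        if self.S <= 0 or self.m <= 0:
            raise ValueError(f"S and m must be positive, got S={self.S}, m={self.m}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def mixed_distance(c: Centroid, voxel: tuple, m: float, S: float) -> float:
    """Mixed space–luminance distance between a centroid and a voxel.

    ``voxel`` is ``(position_mm, luminance_hu)`` with position a length-3
    sequence. Both weights must be positive.
    """
    if m <= 0 or S <= 0:
        raise ValueError("m and S must be positive")
    pos, lum = voxel
    d_s = float(np.linalg.norm(np.asarray(c.position, float) - np.asarray(pos, float)))
    d_c = abs(c.luminance - float(lum))
    return float(np.hypot(d_c / m, d_s / S))


class _SlicState:
    """Internal working state: crops to the mask bounding box for speed."""

    def __init__(self, volume: ScalarVolume, mask: BinaryMask, params: SlicParams):
        if not mask.data.any():
            raise EmptyMaskError("SLIC-3D requires a non-empty mask")
        if mask.shape != volume.shape:
            raise ValueError("mask and volume shapes differ")
        self.params = params
        self.spacing = np.asarray(volume.spacing, dtype=float)
        self.full_shape = volume.shape

        idx = np.argwhere(mask.data)
        self.lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        self.box = tuple(slice(a, b) for a, b in zip(self.lo, hi))
        self.mask = mask.data[self.box]
        self.intensity = np.asarray(volume.data, float)[self.box]
        self.shape = self.mask.shape
        # physical coordinates of the crop, in the full volume's frame
        self.coords1d = [
            (np.arange(a, b) * s)
            for (a, b), s in zip(zip(self.lo, hi), self.spacing)
        ]
        self.mask_idx = np.argwhere(self.mask)
        self.mask_pos = self.mask_idx * self.spacing + self.lo * self.spacing
        self.mask_lum = self.intensity[self.mask]

    def seed(self) -> None:
        """Seed centroids on a regular physical grid of step S, snapping
        grid points that miss the mask to the nearest in-mask voxel."""
        S = self.params.S
        lo_mm = self.lo * self.spacing
        extent = np.asarray(self.shape) * self.spacing
        axes = [lo_mm[a] + np.arange(S / 2, extent[a], S) for a in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

        tree = cKDTree(self.mask_pos)
        dist, nearest = tree.query(grid)
        seeds: dict[tuple, None] = {}
        for d, ni, g in zip(dist, nearest, grid):
            iv = np.rint(g / self.spacing).astype(int) - self.lo
            if (
                np.all(iv >= 0)
                and np.all(iv < self.shape)
                and self.mask[tuple(iv)]
            ):
                seeds[tuple(iv)] = None
            elif d <= S:  # snap to the mask; thin shells may miss every grid node
                seeds[tuple(self.mask_idx[ni])] = None
        if not seeds:
            center = self.mask_pos.mean(axis=0)
            _, ni = tree.query(center)
            seeds[tuple(self.mask_idx[ni])] = None
        seed_idx = np.array(sorted(seeds), dtype=int)
        self.positions = (seed_idx + self.lo) * self.spacing
        self.luminances = self.intensity[tuple(seed_idx.T)].astype(float)
        self.sizes = np.zeros(len(seed_idx), dtype=int)

    def assign(self) -> None:
        """One assignment sweep: windowed nearest-centroid under the mixed
        distance, ties to the lower cluster id, then an orphan sweep."""
        S, m = self.params.S, self.params.m
        best = np.full(self.shape, np.inf)
        labels = np.full(self.shape, -1, dtype=np.int32)
        half = S  # window: cubic, physical side 2S centred on the centroid
        lo_mm = self.lo * self.spacing
        for k in range(len(self.positions)):
            pos = self.positions[k]
            ivox = (pos - lo_mm) / self.spacing
            w_lo = np.maximum(0, np.floor(ivox - half / self.spacing)).astype(int)
            w_hi = np.minimum(
                self.shape, np.ceil(ivox + half / self.spacing).astype(int) + 1
            )
            if np.any(w_lo >= w_hi):
                continue
            sl = tuple(slice(a, b) for a, b in zip(w_lo, w_hi))
            sub_mask = self.mask[sl]
            if not sub_mask.any():
                continue
            dx = self.coords1d[0][sl[0]] - pos[0]
            dy = self.coords1d[1][sl[1]] - pos[1]
            dz = self.coords1d[2][sl[2]] - pos[2]
            d_s2 = (
                dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            )
            d_c = self.intensity[sl] - self.luminances[k]
            dist = (d_c / m) ** 2 + d_s2 / S**2
            upd = sub_mask & (dist < best[sl])
            best[sl][upd] = dist[upd]
            labels[sl][upd] = k
        # orphans: in-mask voxels no window covered
        orphan = self.mask & (labels == -1)
        if orphan.any():
            opos = np.argwhere(orphan) * self.spacing + lo_mm
            olum = self.intensity[orphan]
            d = ((opos[:, None, :] - self.positions[None, :, :]) ** 2).sum(-1) / S**2
            d += ((olum[:, None] - self.luminances[None, :]) / m) ** 2
            labels[orphan] = np.argmin(d, axis=1)
        self.labels = labels

    def update(self) -> None:
        """Recompute centroids as member means; drop empty clusters."""
        flat = self.labels[self.mask]
        K = len(self.positions)
        counts = np.bincount(flat, minlength=K)
        sums = np.stack(
            [np.bincount(flat, weights=self.mask_pos[:, a], minlength=K)
             for a in range(3)],
            axis=1,
        )
        lsum = np.bincount(flat, weights=self.mask_lum, minlength=K)
        live = counts > 0
        if not live.all():
            remap = -np.ones(K, dtype=np.int32)
            remap[live] = np.arange(live.sum())
            self.labels[self.mask] = remap[flat]
            counts, sums, lsum = counts[live], sums[live], lsum[live]
        self.positions = sums / counts[:, None]
        self.luminances = lsum / counts
        self.sizes = counts

    def split_disconnected(self) -> None:
        struct = np.ones((3, 3, 3), dtype=bool)
        out = np.full(self.shape, -1, dtype=np.int32)
        next_id = 0
        for k in range(len(self.positions)):
            comp, n = ndimage.label(self.labels == k, structure=struct)
            for c in range(1, n + 1):
                out[comp == c] = next_id
                next_id += 1
        self.labels = out
        self.positions = np.zeros((next_id, 3))
        self.luminances = np.zeros(next_id)
        self.sizes = np.zeros(next_id, dtype=int)
        self.update()

    def result(self) -> ClusterLabelMap:
        full = np.full(self.full_shape, -1, dtype=np.int32)
        full[self.box] = self.labels
        return ClusterLabelMap(full, self.positions.copy(),
                               self.luminances.copy(), self.sizes.copy())


def init_centroid_grid(
    volume: ScalarVolume, mask: BinaryMask, S: float, m: float = 10.0
) -> ClusterLabelMap:
    """Seed centroids on a regular physical grid of step S and assign every
    in-mask voxel to its nearest seed under the mixed distance."""
    state = _SlicState(volume, mask, SlicParams(S=S, m=m, n_iter=1))
    state.seed()
    state.assign()
    state.update()
    return state.result()


def run_slic3d(
    volume: ScalarVolume, mask: BinaryMask, params: SlicParams
) -> ClusterLabelMap:
    """Cluster the in-mask voxels into supervoxels.

    Performs grid seeding, then ``n_iter`` rounds of windowed assignment
    and centroid update. The returned label map partitions the mask and
    its centroid table equals the member means of the final assignment.
    """
    state = _SlicState(volume, mask, params)
    state.seed()
    state.assign()
    state.update()
    for _ in range(params.n_iter):
        state.assign()
        state.update()
    if params.enforce_connectivity:
        state.split_disconnected()
    return state.result()
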