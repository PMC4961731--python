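"""Coarse vertebra segmentation by iterative supervoxel carving.

The bounding-box volume is peeled layer by layer, from the outside in.
Each iteration:

1. *Layer construction* — the current outer shell is isolated with
   physical-ball morphology: the first layer is ``V0 - (V0 erode I1)``;
   later layers are ``(V dilate Oj) - (V erode Ij)`` where ``V`` is the
   not-yet-excluded volume, so boundary regions are re-examined.
2. *Layer clustering* — the shell is partitioned into supervoxels with
   SLIC-3D, coarse (large S, large m) first and finer later.
3. *Cluster selection* — each cluster is kept or dropped by the
   vertebral predicate: either its mean luminance is within a
   statistical merging threshold of the reference bone luminance
   ``l0`` (the bone predicate, a statistical-region-merging bound), or
   it lies deeper toward the remaining-volume centre than an accepted
   neighbor (the interiority predicate, propagated to a fixed point).

Rejected clusters are removed from the remaining volume; after the
scheduled number of iterations the still-unprocessed core is kept,
vertebrae being compact. The stage is fully deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._morphology import dilate_ball, erode_ball
from .errors import ConfigError
from .slic3d import ClusterLabelMap, SlicParams, run_slic3d
from .volume_io import BinaryMask, BoundingBox, ScalarVolume

__all__ = [
    "CarvingConfig",
    "SelectionRecord",
    "SelectionReport",
    "CarvingRun",
    "build_layer",
    "merging_threshold",
    "select_clusters",
    "compute_num_iterations",
    "carve",
    "run_carving",
]


@dataclass
class CarvingConfig:
    """Parameters of the carving stage.

    ``S_schedule`` (mm) gives the supervoxel spacing per iteration with
    the first two entries coarser than the rest; the last entry repeats
    for any further iteration. ``m_schedule`` (HU) decreases so early
    iterations exclude spatially coherent clusters and later ones
    intensity-coherent clusters. Layer depths are tied to S:
    ``I_j = S_j`` and ``O_j = S_j / 2`` for j > 1. ``l0`` is the
    reference bone luminance (HU). The statistical parameters of the
    bone predicate are derived per layer/cluster: ``Q = Q_fraction * g``
    with g the layer intensity range, and ``delta = 1/|k|`` clamped to
    0.5. The default ``Q = g/64`` keeps the luminance tolerance of a
    typical 10^3-voxel supervoxel at 10-20 HU: wide enough that a few
    contaminated boundary voxels cannot veto a bone cluster, narrow
    enough (far below the bone/soft-tissue contrast) that genuinely
    mixed clusters still fail the test.
    """

    S_schedule: tuple[float, ...] = (16.0, 12.0, 8.0)
    m_schedule: tuple[float, ...] = (40.0, 20.0, 10.0)
    l0: float = 400.0
    Q_fraction: float = 1.0 / 64.0
    slic_n_iter: int = 5
    keep_unprocessed_core: bool = True

    def __post_init__(self) -> None:
        self.S_schedule = tuple(float(s) for s in self.S_schedule)
        self.m_schedule = tuple(float(m) for m in self.m_schedule)
        if len(self.S_schedule) < 3:
            raise ConfigError("S_schedule needs >= 3 values (two coarse + generic)")
        if any(s <= 0 for s in self.S_schedule):
            raise ConfigError("S values must be positive")
        if any(b > a for a, b in zip(self.m_schedule, self.m_schedule[1:])):
            raise ConfigError("m_schedule must be non-increasing")
        if not 0 < self.Q_fraction:
            raise ConfigError("Q_fraction must be positive")

    def S_at(self, j: int) -> float:
        return self.S_schedule[min(j, len(self.S_schedule)) - 1]

    def m_at(self, j: int) -> float:
        return self.m_schedule[min(j, len(self.m_schedule)) - 1]

    def I_at(self, j: int) -> float:
        return self.S_at(j)

    def O_at(self, j: int) -> float:
        return 0.0 if j == 1 else self.S_at(j) / 2.0


@dataclass(frozen=True)
class SelectionRecord:
    cluster_id: int
    luminance: float
    size: int
    threshold: float
    accepted_by: str  # "bone" | "interiority" | "rejected"


@dataclass
class SelectionReport:
    records: list[SelectionRecord] = field(default_factory=list)

    def accepted_ids(self) -> list[int]:
        return [r.cluster_id for r in self.records if r.accepted_by != "rejected"]


def merging_threshold(cluster_size: int, g: float, Q: float, delta: float) -> float:
    """Statistical-region-merging threshold b (HU).

    ``b = g * sqrt(ln(1/delta) / (Q * |k|))`` — the luminance tolerance
    within which a cluster of ``|k|`` voxels is indistinguishable from
    the reference at error probability ``delta``, for a layer of
    intensity range ``g`` and statistical complexity ``Q``.
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    if g <= 0 or Q <= 0:
        raise ValueError("g and Q must be positive")
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    return g * math.sqrt(math.log(1.0 / delta) / (Q * cluster_size))


def compute_num_iterations(h: float, S1: float, S2: float, Sj: float) -> int:
    """Number of carving iterations J = 2 + ceil((h - S1 - S2) / Sj),
    floored at 2, for a box of physical height h."""
    if min(h, S1, S2, Sj) <= 0:
        raise ValueError("h, S1, S2, Sj must all be positive")
    return max(2, 2 + math.ceil((h - S1 - S2) / Sj))


def build_layer(
    prev_remaining: BinaryMask | None,
    V0: BinaryMask,
    j: int,
    I_j: float,
    O_j: float,
) -> BinaryMask:
    """Construct the j-th outer layer by physical-ball morphology.

    ``j = 1``: the depth-I1 shell of the initial box V0. ``j > 1``: the
    band between the O_j-dilation and the I_j-erosion of the remaining
    volume, clipped to V0. An empty result is valid and signals
    termination.
    """
    if j < 1:
        raise ValueError("iteration index j must be >= 1")
    spacing = V0.spacing
    if j == 1:
        layer = V0.data & ~erode_ball(V0.data, I_j, spacing)
    else:
        prev = prev_remaining.data
        layer = dilate_ball(prev, O_j, spacing) & ~erode_ball(prev, I_j, spacing)
        layer &= V0.data
    return V0.like(layer)


def _cluster_adjacency(labels: np.ndarray, n_clusters: int) -> list[set[int]]:
    """26-adjacency between clusters of a label array (-1 = outside)."""
    neigh: list[set[int]] = [set() for _ in range(n_clusters)]
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    offsets = [o for o in offsets if o > (0, 0, 0)]  # half the shell suffices
    for off in offsets:
        sl_a = tuple(slice(max(o, 0), labels.shape[i] + min(o, 0))
                     for i, o in enumerate(off))
        sl_b = tuple(slice(max(-o, 0), labels.shape[i] + min(-o, 0))
                     for i, o in enumerate(off))
        a, b = labels[sl_a], labels[sl_b]
        both = (a >= 0) & (b >= 0) & (a != b)
        if not both.any():
            continue
        pairs = np.unique(np.stack([a[both], b[both]], axis=1), axis=0)
        for p, q in pairs:
            neigh[p].add(int(q))
            neigh[q].add(int(p))
    return neigh


def select_clusters(
    clusters: ClusterLabelMap,
    v: np.ndarray,
    config: CarvingConfig,
    g: float,
) -> tuple[np.ndarray, SelectionReport]:
    """Apply the vertebral predicate to every cluster of a layer.

    A cluster is accepted if its mean luminance is within the merging
    threshold of ``l0`` (bone predicate), or — propagated to a fixed
    point — if some 26-adjacent accepted neighbor sits farther from the
    remaining-volume centre ``v`` (interiority predicate). Returns the
    boolean array of accepted voxels and a per-cluster report.

    ``g`` is the intensity range of the current layer; ``g = 0`` (a
    perfectly uniform layer) gives a zero threshold.
    """
    K = clusters.n_clusters
    if K == 0:
        raise ValueError("select_clusters requires a non-empty clustering")
    v = np.asarray(v, dtype=float)
    l0 = config.l0

    thresholds = np.zeros(K)
    accepted_by = np.full(K, "rejected", dtype=object)
    for k in range(K):
        size = int(clusters.sizes[k])
        delta = min(0.5, 1.0 / size)
        if g > 0:
            Q = config.Q_fraction * g
            thresholds[k] = merging_threshold(size, g, Q, delta)
        if abs(clusters.luminances[k] - l0) <= thresholds[k]:
            accepted_by[k] = "bone"

    # interiority: fixed-point propagation from bone-accepted seeds
    dist_v = np.linalg.norm(clusters.positions - v[None, :], axis=1)
    neigh = _cluster_adjacency(clusters.labels, K)
    frontier = [k for k in range(K) if accepted_by[k] == "bone"]
    while frontier:
        nxt = []
        for k in frontier:
            for q in neigh[k]:
                if accepted_by[q] == "rejected" and dist_v[q] <= dist_v[k]:
                    accepted_by[q] = "interiority"
                    nxt.append(q)
        frontier = nxt

    accepted_ids = np.flatnonzero(accepted_by != "rejected")
    lut = np.zeros(K + 1, dtype=bool)
    lut[accepted_ids] = True
    accepted = np.where(clusters.labels >= 0, lut[clusters.labels], False)

    report = SelectionReport(
        [
            SelectionRecord(k, float(clusters.luminances[k]),
                            int(clusters.sizes[k]), float(thresholds[k]),
                            str(accepted_by[k]))
            for k in range(K)
        ]
    )
    return accepted, report


@dataclass
class CarvingRun:
    """Detailed output of the carving loop."""

    mask: BinaryMask
    reports: list[SelectionReport]
    n_iterations_run: int
    n_iterations_planned: int
    warnings: list[str] = field(default_factory=list)


def carve(
    volume: ScalarVolume, box: BoundingBox, config: CarvingConfig | None = None
) -> CarvingRun:
    """Run the full carving loop inside one bounding box.

    The number of iterations follows ``J = 2 + ceil((h - S1 - S2) / Sj)``
    with ``h`` the box height along z (the shortest box dimension for
    vertebral volumes). The loop stops early if a layer comes out empty
    or the remaining volume is exhausted. The result is the union of
    accepted clusters and (by default) of the never-reached interior
    core, and is always contained in the box.
    """
    config = config or CarvingConfig()
    box.check_within(volume.shape)
    spacing = np.asarray(volume.spacing, dtype=float)

    sub = ScalarVolume(volume.data[box.slices], volume.spacing, volume.origin)
    V0 = BinaryMask(np.ones(sub.shape, dtype=bool), volume.spacing, volume.origin)

    h = box.shape[2] * spacing[2]
    S = config.S_schedule
    J = compute_num_iterations(h, S[0], S[1], config.S_at(3))

    remaining = V0.data.copy()
    accepted_total = np.zeros(sub.shape, dtype=bool)
    processed = np.zeros(sub.shape, dtype=bool)
    reports: list[SelectionReport] = []
    warns: list[str] = []
    lo_mm = np.asarray(box.lower) * spacing

    n_run = 0
    for j in range(1, J + 1):
        layer = build_layer(
            V0.like(remaining), V0, j, config.I_at(j), config.O_at(j)
        )
        if not layer.data.any():
            break
        n_run += 1
        params = SlicParams(S=config.S_at(j), m=config.m_at(j),
                            n_iter=config.slic_n_iter)
        clusters = run_slic3d(sub, layer, params)
        # shift centroid positions into the full-volume frame
        clusters.positions = clusters.positions + lo_mm

        layer_vals = sub.data[layer.data]
        g = float(layer_vals.max() - layer_vals.min())
        com = np.argwhere(remaining).mean(axis=0) * spacing + lo_mm
        accepted, report = select_clusters(clusters, com, config, g)
        reports.append(report)

        rejected = layer.data & ~accepted
        accepted_total |= accepted
        remaining = (remaining | accepted) & ~rejected & V0.data
        processed |= layer.data
        if not remaining.any():
            break

    result = accepted_total.copy()
    if config.keep_unprocessed_core:
        result |= remaining & ~processed
    if not result.any():
        warns.append("carving produced an empty mask: no cluster matched the "
                     "bone luminance and no interior seed existed")

    full = np.zeros(volume.shape, dtype=bool)
    full[box.slices] = result
    mask = BinaryMask(full, volume.spacing, volume.origin)
    return CarvingRun(mask, reports, n_run, J, warns)


def run_carving(
    volume: ScalarVolume, box: BoundingBox, config: CarvingConfig | None = None
) -> BinaryMask:
    """Coarse segmentation of one bounding box; see :func:`carve`."""
    run = carve(volume, box, config)
    for w in run.warnings:
        warnings.warn(w, stacklevel=2)
    return run.mask
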