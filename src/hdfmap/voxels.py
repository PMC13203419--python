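"""Voxel-level spatial aggregation with time-domain sparse sampling.

Sequential mapping over-samples complex regions and under-samples simple
ones; aggregating coordinate points into 2 mm voxel units over a 100 mm
bounding cube evens out the density and pools measurements of the same
tissue acquired minutes apart. Within a voxel, points are sparsely sampled
in time (balanced BST + breadth-first traversal, queue length 31) so DF is
computed only for an approximately equally spaced temporal subset, and the
voxel's DF is the trimmed mean of the valid per-point DFs:

    k = floor(alpha * n),   x_trim = mean(x_(k+1) ... x_(n-k))

over the ascending DF sequence, discarding the k smallest and largest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import AggregationConfig
from .data import MappingPoint
from .spectral import DFPoint

logger = logging.getLogger(__name__)

Index = tuple[int, int, int]


class EmptyModelError(RuntimeError):
    """No voxel met the minimum-valid-DF requirement."""


@dataclass
class VoxelGrid:
    """Uniform cubic grid: half-open cells over a cube of ``extent_mm``."""

    origin: np.ndarray            # (3,) minimum corner, mm
    voxel_size: float = 2.0
    extent: float = 100.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        n = self.extent / self.voxel_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("extent must be divisible by voxel_size")
        self.n_cells = int(round(n))

    @classmethod
    def from_points(cls, xyz: np.ndarray, voxel_size: float = 2.0,
                    extent: float = 100.0) -> "VoxelGrid":
        """Cube of fixed ``extent`` centered on the data's bounding box."""
        xyz = np.asarray(xyz, dtype=float)
        center = (xyz.min(axis=0) + xyz.max(axis=0)) / 2.0
        return cls(center - extent / 2.0, voxel_size, extent)

    def index_of(self, xyz: np.ndarray) -> np.ndarray:
        """Integer cell addresses, floor((p - origin)/size); no bounds check."""
        return np.floor((np.asarray(xyz, float) - self.origin) / self.voxel_size).astype(int)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < self.n_cells), axis=1)

    def centroid(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, float) + 0.5) * self.voxel_size


@dataclass
class VoxelUnit:
    """One voxel: its member points and trimmed-mean DF."""

    index: Index
    centroid: np.ndarray
    points: list[MappingPoint] = field(default_factory=list)
    sampled: list[DFPoint] = field(default_factory=list)
    df_sequence: np.ndarray | None = None     # ascending valid DFs
    trimmed_df: float | None = None
    n_trim: int = 0
    oi_mean: float | None = None


@dataclass
class VoxelModel:
    """Grid plus the per-voxel aggregation results and bookkeeping."""

    grid: VoxelGrid
    voxels: dict[Index, VoxelUnit]
    n_points_total: int = 0
    n_points_inbounds: int = 0
    n_points_sampled: int = 0
    n_points_valid_df: int = 0
    n_voxels_visited: int = 0
    n_voxels_saturated: int = 0

    @property
    def n_voxels_effective(self) -> int:
        return len(self.voxels)

    @property
    def reduction_fraction(self) -> float:
        """Share of in-voxel points skipped by sparse sampling."""
        if self.n_points_inbounds == 0:
            return 0.0
        return 1.0 - self.n_points_sampled / self.n_points_inbounds

    def arrays(self) -> tuple[list[Index], np.ndarray, np.ndarray]:
        """(indices, centroids, trimmed DFs) in sorted index order."""
        indices = sorted(self.voxels)
        cents = np.array([self.voxels[i].centroid for i in indices])
        dfs = np.array([self.voxels[i].trimmed_df for i in indices])
        return indices, cents, dfs


def assign_to_voxels(
    points: Sequence[MappingPoint], grid: VoxelGrid
) -> dict[Index, list[MappingPoint]]:
    """Partition points into grid cells; out-of-bounds points are dropped
    (with a logged count). Boundary points fall into the higher-index cell
    per the half-open convention."""
    out: dict[Index, list[MappingPoint]] = {}
    dropped = 0
    for p in points:
        idx = grid.index_of(p.position)
        if not grid.in_bounds(idx)[0]:
            dropped += 1
            continue
        out.setdefault(tuple(int(i) for i in idx), []).append(p)
    if dropped:
        logger.warning("dropped %d points outside the %g mm cube", dropped, grid.extent)
    return out


def sparse_sample_times(n: int, queue_len: int = 31) -> list[int]:
    """Ranks selected by BFS over a balanced BST of ``n`` time-sorted points.

    The tree is built by recursive midpoint splitting (lower middle on even
    splits); breadth-first traversal, left child before right, collects
    node ranks until ``queue_len`` is reached. The result is a deterministic,
    approximately equally spaced subset of ranks 0..n-1.
    """
    if n <= 0:
        return []
    selected: list[int] = []
    queue: list[tuple[int, int]] = [(0, n - 1)]   # inclusive rank ranges
    while queue and len(selected) < queue_len:
        lo, hi = queue.pop(0)
        mid = (lo + hi) // 2
        selected.append(mid)
        if lo <= mid - 1:
            queue.append((lo, mid - 1))
        if mid + 1 <= hi:
            queue.append((mid + 1, hi))
    return selected


def sparse_sample(points: Sequence, queue_len: int = 31, key=None) -> list:
    """Apply ``sparse_sample_times`` to a time-sorted sequence of points."""
    items = sorted(points, key=key) if key is not None else list(points)
    return [items[r] for r in sparse_sample_times(len(items), queue_len)]


def trimmed_mean_df(values: Sequence[float], alpha: float = 0.2) -> float:
    """Trimmed mean: discard the ``floor(alpha*n)`` smallest and largest.

    ``alpha < 0.5`` guarantees at least one value survives. Input order is
    irrelevant (the sequence is sorted internally).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("cannot take the trimmed mean of an empty sequence")
    if not 0 <= alpha < 0.5:
        raise ValueError("alpha must satisfy 0 <= alpha < 0.5")
    k = math.floor(alpha * n)
    return float(x[k : n - k].mean())


def build_voxel_model(
    points: Sequence[MappingPoint],
    grid: VoxelGrid,
    cfg: AggregationConfig | None = None,
    df_fn: Callable[[MappingPoint], DFPoint] | None = None,
) -> VoxelModel:
    """Assign -> sparse-sample -> DF -> trimmed mean, per voxel.

    ``df_fn`` computes the DF/OI measurement for one sampled point (the DF
    is evaluated only for the sampled subset, which is the point of sparse
    sampling). Voxels with fewer than ``cfg.min_points`` valid DFs are
    excluded; if none survive an :class:`EmptyModelError` is raised.
    """
    cfg = cfg or AggregationConfig()
    cfg.validate()
    if df_fn is None:
        raise ValueError("df_fn is required to measure sampled points")
    buckets = assign_to_voxels(points, grid)
    model = VoxelModel(grid=grid, voxels={})
    model.n_points_total = len(points)
    model.n_points_inbounds = sum(len(v) for v in buckets.values())
    model.n_voxels_visited = len(buckets)
    for idx, members in buckets.items():
        if len(members) >= cfg.queue_len:
            model.n_voxels_saturated += 1
        sampled_pts = sparse_sample(members, cfg.queue_len, key=lambda p: p.time_ms)
        model.n_points_sampled += len(sampled_pts)
        measured = [df_fn(p) for p in sampled_pts]
        valid = [m for m in measured if m.valid]
        model.n_points_valid_df += len(valid)
        if len(valid) < cfg.min_points:
            continue
        seq = np.sort([m.df_hz for m in valid])
        unit = VoxelUnit(
            index=idx,
            centroid=grid.centroid(idx),
            points=list(members),
            sampled=measured,
            df_sequence=seq,
            trimmed_df=trimmed_mean_df(seq, cfg.alpha),
            n_trim=math.floor(cfg.alpha * seq.size),
            oi_mean=float(np.mean([m.oi for m in valid])),
        )
        model.voxels[unit.index] = unit
    if not model.voxels:
        raise EmptyModelError(
            f"no voxel reached {cfg.min_points} valid DFs "
            f"({model.n_points_valid_df} valid points over "
            f"{model.n_voxels_visited} visited voxels)"
        )
    return model


def model_from_df_points(
    df_points: Sequence[DFPoint],
    grid: VoxelGrid,
    cfg: AggregationConfig | None = None,
) -> VoxelModel:
    """Convenience: build a model from already-measured DF points."""
    lookup = {(p.channel, p.time_ms): p for p in df_points}
    points = [MappingPoint(p.channel, p.time_ms, p.position) for p in df_points]
    return build_voxel_model(
        points, grid, cfg, df_fn=lambda mp: lookup[(mp.channel, mp.time_ms)]
    )
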