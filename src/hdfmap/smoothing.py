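"""Local neighborhood spatial filtering of the voxel DF model.

Poor electrode contact or residual interference can leave isolated
outlier DF values in single voxels. Each voxel's DF is replaced by the
arithmetic mean of its own value and those of its 10 nearest neighboring
voxel units (Euclidean distance between centroids), all computed from the
pre-smoothing snapshot so the result is order-independent. A kd-tree over
the centroids makes the neighbor searches efficient; ties at the k-th
distance are broken by lexicographic voxel index so the neighbor sets are
fully deterministic on the regular centroid lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .voxels import Index, VoxelModel


@dataclass
class SmoothedModel:
    """Raw and neighborhood-averaged DFs per voxel (sorted index order)."""

    indices: list[Index]
    centroids: np.ndarray
    df_raw: np.ndarray
    df_smoothed: np.ndarray
    neighbor_ids: list[list[Index]]

    def __len__(self) -> int:
        return len(self.indices)


def build_kdtree(centroids: np.ndarray) -> cKDTree:
    """Spatial index over voxel centroids."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] < 1:
        raise ValueError("need at least one centroid")
    return cKDTree(centroids)


def knn(
    tree: cKDTree,
    centroids: np.ndarray,
    indices: list[Index],
    query: int,
    k: int = 10,
) -> list[int]:
    """Positions of the ``k`` nearest voxels to ``centroids[query]``.

    Excludes the query voxel itself; if fewer than ``k`` other voxels
    exist, all are returned. Exactly the k smallest distances are kept,
    with ties at the boundary resolved by lexicographic voxel index. The
    tree supplies a candidate set (grown until the boundary tie group is
    fully covered); exact squared distances then decide membership.
    """
    n = len(indices)
    k_eff = min(k, n - 1)
    if k_eff <= 0:
        return []
    kq = min(n, k_eff + 9)
    while True:
        dists, cand = tree.query(centroids[query], k=kq)
        dists, cand = np.atleast_1d(dists), np.atleast_1d(cand)
        # grow until the last candidate is strictly beyond the k-th distance
        if kq >= n or dists[-1] > dists[min(k_eff, dists.size - 1)] + 1e-9:
            break
        kq = min(n, kq * 2)
    cand = [int(c) for c in cand if int(c) != query]
    d2 = np.sum((centroids[cand] - centroids[query]) ** 2, axis=1)
    order = sorted(range(len(cand)), key=lambda i: (d2[i], indices[cand[i]]))
    return [cand[i] for i in order[:k_eff]]


def smooth_model(model: VoxelModel, k: int = 10) -> SmoothedModel:
    """Replace each voxel DF by the mean over itself and its k neighbors.

    All averages use the raw snapshot; the smoothed field is a convex
    combination of raw values, so the global [min, max] never expands.
    """
    indices, centroids, df_raw = model.arrays()
    n = len(indices)
    if n == 1:
        warnings.warn("single-voxel model: smoothing leaves DF unchanged")
        return SmoothedModel(indices, centroids, df_raw, df_raw.copy(), [[]])
    tree = build_kdtree(centroids)
    smoothed = np.empty(n)
    neighbor_ids: list[list[Index]] = []
    for i in range(n):
        nbrs = knn(tree, centroids, indices, i, k)
        smoothed[i] = (df_raw[i] + df_raw[nbrs].sum()) / (1 + len(nbrs))
        neighbor_ids.append([indices[j] for j in nbrs])
    return SmoothedModel(indices, centroids, df_raw, smoothed, neighbor_ids)
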