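"""Non-differentiable geometric primitives of the set-abstraction pipeline:
farthest point sampling, K-nearest-neighbour grouping, and neighbourhood
density with its normalization and high/low partition.

These run on raw coordinates outside the autodiff graph; the network gathers
features along the index tables they produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

DENSITY_EPS = 1e-8


class PointOpsError(ValueError):
    pass


@dataclass
class Neighborhood:
    """M centre indices plus an M x K table of each centre's K nearest points.

    Neighbour indices point into the parent cloud; the centre is always its
    own nearest neighbour (distance 0). Ties are broken by lower index.
    """

    center_indices: np.ndarray
    neighbor_indices: np.ndarray
    neighbor_distances: np.ndarray

    @property
    def K(self) -> int:
        return self.neighbor_indices.shape[1]


def farthest_point_sample(
    coords: np.ndarray, m: int, seed: int = 0, start_index: int | None = None
) -> np.ndarray:
    """Greedy max-min subsampling: each pick maximizes the distance to the
    already-selected set. Start point is seeded-random unless given."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if not (1 <= m <= n):
        raise PointOpsError(f"m must be in [1, {n}], got {m}")
    if start_index is None:
        start_index = int(np.random.default_rng(seed).integers(0, n))
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start_index
    min_d2 = np.sum((coords - coords[start_index]) ** 2, axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(min_d2))
        selected[i] = nxt
        d2 = np.sum((coords - coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected


def knn_group(coords: np.ndarray, center_indices: np.ndarray, K: int) -> Neighborhood:
    """Exact K nearest neighbours of each centre within the parent cloud.

    Distance ties are resolved toward the lower point index, which the KD-tree
    query does not guarantee, so equal-distance runs are re-sorted explicitly.
    """
    coords = np.asarray(coords, dtype=np.float64)
    center_indices = np.asarray(center_indices, dtype=np.int64)
    n = len(coords)
    if K > n:
        raise PointOpsError(f"K={K} exceeds cloud size {n}")
    tree = cKDTree(coords)
    dists, idx = tree.query(coords[center_indices], k=K)
    if K == 1:
        dists, idx = dists[:, None], idx[:, None]
    # enforce deterministic tie-break: sort by (distance, index)
    order = np.lexsort((idx, np.round(dists, 12)), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    dists = np.take_along_axis(dists, order, axis=1)
    return Neighborhood(
        center_indices=center_indices,
        neighbor_indices=idx.astype(np.int64),
        neighbor_distances=dists,
    )


@dataclass
class DensityField:
    """Raw and min-max normalized neighbourhood densities of a point set."""

    raw: np.ndarray
    normalized: np.ndarray
    epsilon: float
    d_min: float
    d_max: float


def neighborhood_density(nbhd: Neighborhood, epsilon: float = DENSITY_EPS) -> np.ndarray:
    """Mean inverse neighbour distance per centre:
    D_i = (1/K) * sum_k 1 / (d(p_i, p_ik) + eps)."""
    if epsilon <= 0:
        raise PointOpsError("epsilon must be positive")
    return (1.0 / (nbhd.neighbor_distances + epsilon)).mean(axis=1)


def normalize_density(raw: np.ndarray, epsilon: float = DENSITY_EPS) -> DensityField:
    """Min-max normalize densities to [0, 1]; a constant field maps to zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    d_min, d_max = float(raw.min()), float(raw.max())
    if d_max > d_min:
        normalized = (raw - d_min) / (d_max - d_min)
    else:
        normalized = np.zeros_like(raw)
    return DensityField(raw, normalized, epsilon, d_min, d_max)


def partition_by_density(field: DensityField, nbhd: Neighborhood) -> np.ndarray:
    """High/low density split per centre.

    ``field.normalized`` must be defined for every parent point the
    neighbourhood indexes. A centre is high-density iff its normalized density
    strictly exceeds the mean normalized density of its K neighbours; the low
    mask is the complement.
    """
    center_density = field.normalized[nbhd.center_indices]
    neighbor_mean = field.normalized[nbhd.neighbor_indices].mean(axis=1)
    return center_density > neighbor_mean


def full_cloud_density(
    coords: np.ndarray, K: int, epsilon: float = DENSITY_EPS
) -> tuple[DensityField, Neighborhood]:
    """Density of every point of a cloud from its own K-NN, normalized over
    the whole cloud (the parent field the high/low partition compares against)."""
    all_idx = np.arange(len(coords))
    nbhd = knn_group(coords, all_idx, K)
    field = normalize_density(neighborhood_density(nbhd, epsilon), epsilon)
    return field, nbhd
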