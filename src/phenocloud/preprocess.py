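"""Ground removal, statistical denoising, and uniform downsampling.

The cleaning order is fixed: RANSAC ground removal, then statistical outlier
filtering, then stride downsampling. Defaults follow common field practice for
crop clouds at metre scale: ground threshold 0.2 m over 500 iterations,
50-neighbour filter at 1 standard deviation, downsampling rate 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import CloudValidationError, LabeledCloud


class GroundFitError(RuntimeError):
    """RANSAC could not fit any plane (all draws degenerate)."""


@dataclass
class PlaneModel:
    """Plane a*x + b*y + c*z + d = 0 with unit normal (a, b, c)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if norm == 0:
            raise CloudValidationError("plane normal must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            # accept unnormalized input but store the canonical form
            self.offset = float(self.offset) / norm
            self.normal = self.normal / norm
        self.offset = float(self.offset)


@dataclass
class RansacParams:
    distance_threshold: float = 0.2
    sample_size: int = 3
    n_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise CloudValidationError("distance_threshold must be positive")
        if self.sample_size < 3:
            raise CloudValidationError("sample_size must be >= 3")
        if self.n_iterations < 1:
            raise CloudValidationError("n_iterations must be >= 1")


def point_plane_distance(points: np.ndarray, plane: PlaneModel) -> np.ndarray:
    """Unsigned point-to-plane distance |a x + b y + c z + d| (normal is unit)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    return np.abs(points @ plane.normal + plane.offset)


def _plane_from_points(pts: np.ndarray) -> PlaneModel | None:
    """Exact plane through 3 points, or least-squares plane through more.

    Returns None for degenerate (collinear / coincident) samples.
    """
    if len(pts) == 3:
        v1, v2 = pts[1] - pts[0], pts[2] - pts[0]
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            return None
        normal = normal / norm
        return PlaneModel(normal, -float(normal @ pts[0]))
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[-2] < 1e-12:  # rank < 2: collinear
        return None
    normal = vt[-1]
    return PlaneModel(normal, -float(normal @ centroid))


def fit_ground_ransac(
    cloud: LabeledCloud, params: RansacParams | None = None
) -> tuple[PlaneModel, np.ndarray]:
    """RANSAC plane fit: the plane with the most inliers over the iterations.

    A point is an inlier when its distance to the candidate plane is strictly
    below the threshold. Degenerate sample draws count against the iteration
    budget. Returns the winning plane and its boolean inlier mask.
    """
    params = params or RansacParams()
    coords = cloud.coords
    n = len(coords)
    if n < 3:
        raise CloudValidationError("RANSAC needs at least 3 points")
    rng = np.random.default_rng(params.seed)
    best_plane = None
    best_count = -1
    best_mask = None
    for _ in range(params.n_iterations):
        idx = rng.choice(n, size=params.sample_size, replace=False)
        plane = _plane_from_points(coords[idx])
        if plane is None:
            continue
        dist = point_plane_distance(coords, plane)
        mask = dist < params.distance_threshold
        count = int(mask.sum())
        if count > best_count:
            best_plane, best_count, best_mask = plane, count, mask
    if best_plane is None:
        raise GroundFitError(
            f"no valid plane in {params.n_iterations} iterations (degenerate samples)"
        )
    return best_plane, best_mask


def remove_ground(
    cloud: LabeledCloud, plane: PlaneModel, threshold: float = 0.2
) -> LabeledCloud:
    """Keep the points at distance >= threshold from the ground plane."""
    dist = point_plane_distance(cloud.coords, plane)
    keep = dist >= threshold
    if not keep.any():
        raise CloudValidationError("ground removal left an empty cloud")
    return cloud.select(keep)


def statistical_outlier_filter(
    cloud: LabeledCloud, n_neighbors: int = 50, std_ratio: float = 1.0
) -> LabeledCloud:
    """Classic statistical outlier removal.

    For each point the mean distance to its ``n_neighbors`` nearest neighbours
    (excluding itself) is computed; points whose mean exceeds the global mean
    plus ``std_ratio`` standard deviations of those per-point means are dropped.
    """
    n = len(cloud)
    if n <= n_neighbors:
        raise CloudValidationError(
            f"need more than n_neighbors={n_neighbors} points, got {n}"
        )
    tree = cKDTree(cloud.coords)
    # k+1 because the query point is its own nearest neighbour at distance 0
    dists, _ = tree.query(cloud.coords, k=n_neighbors + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    cutoff = mean_dist.mean() + std_ratio * mean_dist.std()
    keep = mean_dist <= cutoff
    if not keep.any():
        raise CloudValidationError("statistical filter removed every point")
    return cloud.select(keep)


def uniform_downsample(cloud: LabeledCloud, rate: int = 2) -> LabeledCloud:
    """Index-stride decimation: keep every ``rate``-th point in order."""
    if int(rate) != rate or rate < 1:
        raise CloudValidationError("rate must be an integer >= 1")
    return cloud.select(slice(None, None, int(rate)))


def preprocess_pipeline(
    cloud: LabeledCloud,
    ransac: RansacParams | None = None,
    n_neighbors: int = 50,
    std_ratio: float = 1.0,
    rate: int = 2,
    skip_ground: bool = False,
) -> tuple[LabeledCloud, list[tuple[str, int]]]:
    """Ground removal -> statistical filter -> downsample; returns the cloud
    and the per-stage point counts for logging."""
    stages = [("input", len(cloud))]
    if not skip_ground:
        ransac = ransac or RansacParams()
        plane, _ = fit_ground_ransac(cloud, ransac)
        cloud = remove_ground(cloud, plane, ransac.distance_threshold)
        stages.append(("ground_removed", len(cloud)))
    if len(cloud) > n_neighbors:
        cloud = statistical_outlier_filter(cloud, n_neighbors, std_ratio)
        stages.append(("filtered", len(cloud)))
    cloud = uniform_downsample(cloud, rate)
    stages.append(("downsampled", len(cloud)))
    return cloud, stages
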