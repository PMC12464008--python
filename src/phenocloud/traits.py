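"""Phenotypic trait extraction from a segmented, metric-scale plant cloud.

Five parameters per plant: plant height (z-range), leaf number (Euclidean
connectivity clusters of leaf points), per-leaf length and width (minimum-area
bounding rectangle in the leaf's principal plane), and internode length (the
vertical distance between the bases of the upper and middle leaves). All
lengths are reported in centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree

from .cloud import LEAF, STEM, LabeledCloud
from .synthetic import M_TO_CM, TraitRecord, upper_middle_internode


class TraitError(ValueError):
    pass


@dataclass
class LeafInstance:
    """One leaf region: its point indices, the attachment (base) point proxy,
    and its measured dimensions in centimetres."""

    point_indices: np.ndarray
    base_point: np.ndarray
    length: float
    width: float
    degenerate: bool = False


def plant_height(cloud: LabeledCloud) -> float:
    """Plant height in cm: max z minus min z over all plant points."""
    if len(cloud) == 0:
        raise TraitError("empty cloud")
    z = cloud.coords[:, 2]
    return float(z.max() - z.min()) * M_TO_CM


def _connectivity_clusters(points: np.ndarray, eps: float) -> np.ndarray:
    """Component label per point under distance-<=eps connectivity."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    n = len(points)
    if len(pairs) == 0:
        return np.arange(n)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def leaf_dimensions(points: np.ndarray) -> tuple[float, float, bool]:
    """Leaf length and width in cm via PCA projection + minimum bounding
    rectangle.

    The points are projected onto the plane of their first two principal
    components; the minimum-area enclosing rectangle of the projection (one
    side collinear with a convex-hull edge) gives (longer side, shorter side).
    Returns (length, width, degenerate); collinear clusters are flagged
    degenerate with width 0.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        raise TraitError("leaf_dimensions needs at least 3 points")
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[:2].T  # N x 2 in the principal plane
    if s[1] < 1e-12 * max(s[0], 1.0):  # collinear
        length = float(proj[:, 0].max() - proj[:, 0].min())
        return length * M_TO_CM, 0.0, True
    hull = ConvexHull(proj)
    hull_pts = proj[hull.vertices]
    edges = np.diff(np.vstack([hull_pts, hull_pts[:1]]), axis=0)
    angles = np.arctan2(edges[:, 1], edges[:, 0])
    best = None
    for ang in angles:
        c, sn = np.cos(-ang), np.sin(-ang)
        rot = hull_pts @ np.array([[c, -sn], [sn, c]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        area = w * h
        if best is None or area < best[0]:
            best = (area, max(w, h), min(w, h))
    _, length, width = best
    return float(length) * M_TO_CM, float(width) * M_TO_CM, False


def extract_leaf_instances(
    cloud: LabeledCloud,
    cluster_eps: float = 0.03,
    min_cluster_size: int = 50,
) -> list[LeafInstance]:
    """Group leaf-labeled points into leaf regions by Euclidean connectivity.

    Clusters smaller than ``min_cluster_size`` are discarded. The base point of
    each leaf is its point nearest the stem axis (the vertical line through
    the stem-point centroid, or through the leaf centroid-of-centroids when no
    stem points exist). Instances are numbered bottom-up by base height.
    """
    if cloud.semantic_labels is None:
        raise TraitError("cloud must carry semantic labels")
    leaf_mask = cloud.semantic_labels == LEAF
    leaf_idx = np.flatnonzero(leaf_mask)
    if len(leaf_idx) == 0:
        return []
    leaf_pts = cloud.coords[leaf_idx]
    comp = _connectivity_clusters(leaf_pts, cluster_eps)

    stem_pts = cloud.coords[cloud.semantic_labels == STEM]
    if len(stem_pts) > 0:
        axis_xy = stem_pts[:, :2].mean(axis=0)
    else:
        axis_xy = leaf_pts[:, :2].mean(axis=0)

    instances: list[LeafInstance] = []
    for label in np.unique(comp):
        members = leaf_idx[comp == label]
        if len(members) < min_cluster_size:
            continue
        pts = cloud.coords[members]
        radial = np.linalg.norm(pts[:, :2] - axis_xy, axis=1)
        base = pts[int(np.argmin(radial))]
        length, width, degenerate = leaf_dimensions(pts)
        instances.append(
            LeafInstance(
                point_indices=members,
                base_point=base,
                length=length,
                width=width,
                degenerate=degenerate,
            )
        )
    instances.sort(key=lambda inst: inst.base_point[2])
    return instances


def internode_length(instances: Sequence[LeafInstance]) -> float:
    """Vertical distance (cm) between the bases of the upper and middle leaves
    (ranked by base height; upper = rank n, middle = rank ceil(n/2))."""
    if len(instances) < 2:
        raise TraitError("internode length needs at least 2 leaf instances")
    heights = [inst.base_point[2] for inst in instances]
    return upper_middle_internode(heights) * M_TO_CM


def extract_traits(
    cloud: LabeledCloud,
    cluster_eps: float = 0.03,
    min_cluster_size: int = 50,
) -> TraitRecord:
    """All five phenotypic parameters of one segmented, metric-scale cloud."""
    instances = extract_leaf_instances(cloud, cluster_eps, min_cluster_size)
    return TraitRecord(
        plant_height=plant_height(cloud),
        leaf_lengths=[inst.length for inst in instances],
        leaf_widths=[inst.width for inst in instances],
        leaf_number=len(instances),
        internode_length=internode_length(instances) if len(instances) >= 2 else None,
    )
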