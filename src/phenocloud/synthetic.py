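"""Synthetic tobacco-like plants with known ground-truth traits.

A plant is a vertical stem (cylinder surface) carrying 4-10 planar elliptical
leaves attached at strictly increasing heights. Every point carries a semantic
label (0 stem, 1 leaf, 2 ground, 3 outlier) and an instance id (0 stem,
1..n leaves), and the generator returns the exact trait values alongside the
cloud, so each downstream stage can be scored without any external data.

Leaves are flat elliptical discs on purpose: the minimum bounding rectangle of
an ellipse with semi-axes (a, b) is exactly 2a x 2b, which makes the
PCA-plus-bounding-rectangle leaf measurements analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .cloud import GROUND, LEAF, OUTLIER, STEM, LabeledCloud


class SpecValidationError(ValueError):
    """A PlantSpec field violates its contract; the message names the field."""


M_TO_CM = 100.0


@dataclass
class PlantSpec:
    """Geometry and sampling parameters of one synthetic plant (metres, radians)."""

    stem_height: float = 1.2
    stem_radius: float = 0.015
    n_leaves: int = 6
    leaf_lengths: Optional[Sequence[float]] = None
    leaf_widths: Optional[Sequence[float]] = None
    leaf_base_heights: Optional[Sequence[float]] = None
    leaf_azimuths: Optional[Sequence[float]] = None
    leaf_droop: float = 0.35
    points_per_organ: int = 2500
    noise_sigma: float = 0.0
    outlier_fraction: float = 0.0
    ground_extent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_height <= 0:
            raise SpecValidationError("stem_height must be positive")
        if self.stem_radius <= 0:
            raise SpecValidationError("stem_radius must be positive")
        if self.n_leaves < 1:
            raise SpecValidationError("n_leaves must be >= 1")
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise SpecValidationError("outlier_fraction must lie in [0, 1)")
        if self.ground_extent < 0:
            raise SpecValidationError("ground_extent must be >= 0")
        if self.points_per_organ < 10:
            raise SpecValidationError("points_per_organ must be >= 10")
        rng = np.random.default_rng(self.seed)
        n = self.n_leaves
        if self.leaf_lengths is None:
            self.leaf_lengths = list(rng.uniform(0.25, 0.55, n))
        if self.leaf_widths is None:
            self.leaf_widths = [
                min(0.8 * L, w) for L, w in zip(self.leaf_lengths, rng.uniform(0.12, 0.30, n))
            ]
        if self.leaf_base_heights is None:
            # regular vertical spacing along the upper stem, as on a real plant
            self.leaf_base_heights = list(
                np.linspace(0.25 * self.stem_height, 0.95 * self.stem_height, n)
            )
        if self.leaf_azimuths is None:
            # phyllotactic spread keeps neighbouring leaves spatially separated
            golden = 2.399963229728653
            self.leaf_azimuths = [(i * golden) % (2 * np.pi) for i in range(n)]
        for name in ("leaf_lengths", "leaf_widths", "leaf_base_heights", "leaf_azimuths"):
            vals = list(getattr(self, name))
            if len(vals) != n:
                raise SpecValidationError(f"{name} must have length n_leaves={n}")
            setattr(self, name, [float(v) for v in vals])
        if any(L <= 0 for L in self.leaf_lengths):
            raise SpecValidationError("leaf_lengths must be positive")
        if any(w <= 0 for w in self.leaf_widths):
            raise SpecValidationError("leaf_widths must be positive")
        if any(w > L for L, w in zip(self.leaf_lengths, self.leaf_widths)):
            raise SpecValidationError("leaf_widths must not exceed leaf_lengths")
        h = np.asarray(self.leaf_base_heights)
        if np.any(h <= 0) or np.any(h > self.stem_height):
            raise SpecValidationError(
                "leaf_base_heights must lie in (0, stem_height]"
            )
        if np.any(np.diff(h) <= 0):
            raise SpecValidationError("leaf_base_heights must be strictly increasing")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantSpec":
        return cls(**d)


@dataclass
class TraitRecord:
    """The five phenotypic parameters of one plant, in centimetres."""

    plant_height: float
    leaf_lengths: list[float]
    leaf_widths: list[float]
    leaf_number: int
    internode_length: Optional[float]

    def __post_init__(self) -> None:
        if self.leaf_number != len(self.leaf_lengths):
            raise SpecValidationError("leaf_number must equal len(leaf_lengths)")
        if len(self.leaf_widths) != len(self.leaf_lengths):
            raise SpecValidationError("leaf_widths length mismatch")

    def to_dict(self) -> dict:
        return asdict(self)


def upper_middle_internode(base_heights_m: Sequence[float]) -> float:
    """Vertical distance (m) between the bases of the upper and middle leaves.

    Leaves ranked by base height (ascending, 1-based); "upper" is rank n,
    "middle" is rank ceil(n/2).
    """
    z = np.sort(np.asarray(base_heights_m, dtype=float))
    n = len(z)
    if n < 2:
        raise ValueError("internode length needs at least 2 leaves")
    middle = z[int(np.ceil(n / 2)) - 1]
    return abs(z[-1] - middle)


def _leaf_frame(azimuth: float, droop: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors along the leaf midrib (drooping outward) and across it."""
    u = np.array(
        [np.cos(azimuth) * np.cos(droop), np.sin(azimuth) * np.cos(droop), -np.sin(droop)]
    )
    v = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    return u, v


def make_plant(spec: PlantSpec) -> tuple[LabeledCloud, TraitRecord]:
    """Sample one plant; returns the labeled cloud and its exact traits.

    Stem points lie on the cylinder surface, each leaf's points fill a planar
    elliptical disc whose proximal vertex touches the stem axis at its base
    height. Gaussian noise of scale ``noise_sigma`` is added after the traits
    are computed, so the returned TraitRecord holds the exact geometry values.
    """
    rng = np.random.default_rng(spec.seed)
    n_pts = spec.points_per_organ

    z = rng.uniform(0.0, spec.stem_height, n_pts)
    theta = rng.uniform(0.0, 2 * np.pi, n_pts)
    stem = np.column_stack(
        [spec.stem_radius * np.cos(theta), spec.stem_radius * np.sin(theta), z]
    )
    parts = [stem]
    labels = [np.full(n_pts, STEM)]
    instances = [np.zeros(n_pts, dtype=np.int64)]

    for i in range(spec.n_leaves):
        a = spec.leaf_lengths[i] / 2.0
        b = spec.leaf_widths[i] / 2.0
        u, v = _leaf_frame(spec.leaf_azimuths[i], spec.leaf_droop)
        base = np.array([0.0, 0.0, spec.leaf_base_heights[i]])
        # uniform sampling of the unit disc, stretched to the ellipse;
        # the disc centre sits one semi-major axis out so the proximal
        # vertex coincides with the leaf base on the stem axis
        r = np.sqrt(rng.uniform(0.0, 1.0, n_pts))
        phi = rng.uniform(0.0, 2 * np.pi, n_pts)
        xi = a * r * np.cos(phi)
        eta = b * r * np.sin(phi)
        pts = base + np.outer(xi + a, u) + np.outer(eta, v)
        parts.append(pts)
        labels.append(np.full(n_pts, LEAF))
        instances.append(np.full(n_pts, i + 1, dtype=np.int64))

    coords = np.vstack(parts)
    height_m = coords[:, 2].max() - coords[:, 2].min()
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)

    record = TraitRecord(
        plant_height=height_m * M_TO_CM,
        leaf_lengths=[L * M_TO_CM for L in spec.leaf_lengths],
        leaf_widths=[w * M_TO_CM for w in spec.leaf_widths],
        leaf_number=spec.n_leaves,
        internode_length=(
            upper_middle_internode(spec.leaf_base_heights) * M_TO_CM
            if spec.n_leaves >= 2
            else None
        ),
    )
    cloud = LabeledCloud(
        coords=coords,
        semantic_labels=np.concatenate(labels),
        instance_ids=np.concatenate(instances),
    )
    return cloud, record


def add_ground_and_outliers(cloud: LabeledCloud, spec: PlantSpec) -> LabeledCloud:
    """Append a ground plane at z=0 and uniform outlier noise to a plant cloud.

    Ground points cover a square of side ``ground_extent`` centred on the stem,
    jittered vertically by ``noise_sigma``; outliers are scattered uniformly in
    the bounding box, ``outlier_fraction`` of the total output count.
    """
    if cloud.semantic_labels is None:
        raise SpecValidationError("cloud must carry semantic labels")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    parts = [cloud.coords]
    labels = [cloud.semantic_labels]
    instances = [
        cloud.instance_ids
        if cloud.instance_ids is not None
        else np.zeros(len(cloud), dtype=np.int64)
    ]
    if spec.ground_extent > 0:
        # ground dominates a field scene: twice the plant's point count
        n_ground = max(2 * len(cloud), 200)
        half = spec.ground_extent / 2.0
        gx = rng.uniform(-half, half, n_ground)
        gy = rng.uniform(-half, half, n_ground)
        gz = rng.normal(0.0, spec.noise_sigma, n_ground) if spec.noise_sigma > 0 else np.zeros(n_ground)
        parts.append(np.column_stack([gx, gy, gz]))
        labels.append(np.full(n_ground, GROUND))
        instances.append(np.full(n_ground, -1, dtype=np.int64))
    n_so_far = sum(len(p) for p in parts)
    if spec.outlier_fraction > 0:
        # fraction is of the final total: n_out = f * (n_so_far + n_out)
        n_out = int(round(spec.outlier_fraction * n_so_far / (1 - spec.outlier_fraction)))
        if n_out > 0:
            stacked = np.vstack(parts)
            lo = stacked.min(axis=0) - 0.1
            hi = stacked.max(axis=0) + 0.1
            out = rng.uniform(lo, hi, (n_out, 3))
            parts.append(out)
            labels.append(np.full(n_out, OUTLIER))
            instances.append(np.full(n_out, -1, dtype=np.int64))
    if len(parts) == 1:
        return cloud
    return LabeledCloud(
        coords=np.vstack(parts),
        semantic_labels=np.concatenate(labels),
        instance_ids=np.concatenate(instances),
    )


DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    "stem_height": (0.6, 1.8),
    "stem_radius": (0.01, 0.025),
    "n_leaves": (4, 10),
    "leaf_length": (0.25, 0.55),
    "leaf_width": (0.12, 0.30),
    "leaf_droop": (0.2, 0.6),
}


def make_field(
    n_plants: int,
    spec_ranges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    **spec_overrides,
) -> list[tuple[LabeledCloud, TraitRecord]]:
    """Generate ``n_plants`` independent plants with specs drawn uniformly
    from ``spec_ranges`` (defaults emulate field tobacco: stems 0.6-1.8 m,
    4-10 leaves 0.25-0.55 m long).

    Leaf base heights are spaced evenly along the upper 80% of the stem and
    azimuths follow the golden-angle phyllotaxis, so degenerate ranges yield
    identical plants up to point-sampling noise.
    """
    if n_plants < 1:
        raise SpecValidationError("n_plants must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        for key, rg in spec_ranges.items():
            if key not in ranges:
                raise SpecValidationError(f"unknown spec range {key!r}")
            lo, hi = rg
            if hi < lo:
                raise SpecValidationError(f"empty range for {key!r}")
            ranges[key] = (float(lo), float(hi))
    rng = np.random.default_rng(seed)
    plants = []
    for _ in range(n_plants):
        n_leaves = int(rng.integers(ranges["n_leaves"][0], ranges["n_leaves"][1] + 1))
        stem_height = float(rng.uniform(*ranges["stem_height"]))
        lengths = rng.uniform(*ranges["leaf_length"], n_leaves)
        widths = np.minimum(rng.uniform(*ranges["leaf_width"], n_leaves), 0.8 * lengths)
        base_heights = np.linspace(0.2, 0.95, n_leaves) * stem_height
        spec = PlantSpec(
            stem_height=stem_height,
            stem_radius=float(rng.uniform(*ranges["stem_radius"])),
            n_leaves=n_leaves,
            leaf_lengths=list(lengths),
            leaf_widths=list(widths),
            leaf_base_heights=list(base_heights),
            leaf_droop=float(rng.uniform(*ranges["leaf_droop"])),
            seed=int(rng.integers(0, 2**31 - 1)),
            **spec_overrides,
        )
        plants.append(make_plant(spec))
    return plants
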