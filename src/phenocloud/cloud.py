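"""Point-cloud container and the min-max normalization used around the network.

Coordinates are metric (metres, z up). Semantic labels follow one convention
throughout the package: 0 = stem, 1 = leaf, 2 = ground, 3 = outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STEM, LEAF, GROUND, OUTLIER = 0, 1, 2, 3


class CloudValidationError(ValueError):
    """Raised when a cloud or a parameter violates its contract."""


@dataclass
class LabeledCloud:
    """N x 3 coordinates with optional per-point semantic labels / instance ids.

    ``semantic_labels`` holds the class of each point (stem/leaf/ground/outlier);
    ``instance_ids`` number the organs (0 = stem, 1..n = leaves) and exist only
    as ground truth for synthetic plants. ``features`` is an optional N x d
    block carried untouched by all geometric operations.
    """

    coords: np.ndarray
    semantic_labels: Optional[np.ndarray] = None
    instance_ids: Optional[np.ndarray] = None
    features: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise CloudValidationError(
                f"coords must be N x 3, got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise CloudValidationError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise CloudValidationError("coords contain non-finite values")
        n = len(self.coords)
        for name in ("semantic_labels", "instance_ids"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (n,):
                    raise CloudValidationError(
                        f"{name} must have length {n}, got shape {arr.shape}"
                    )
                setattr(self, name, arr)
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.ndim != 2 or self.features.shape[0] != n:
                raise CloudValidationError(
                    f"features must be N x d with N={n}, got {self.features.shape}"
                )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def select(self, index) -> "LabeledCloud":
        """Sub-cloud at the given indices/mask; labels travel with their points."""
        return LabeledCloud(
            coords=self.coords[index],
            semantic_labels=None
            if self.semantic_labels is None
            else self.semantic_labels[index],
            instance_ids=None if self.instance_ids is None else self.instance_ids[index],
            features=None if self.features is None else self.features[index],
        )

    def with_coords(self, coords: np.ndarray) -> "LabeledCloud":
        """Same labels, new coordinates (must keep N)."""
        if len(coords) != len(self.coords):
            raise CloudValidationError("with_coords must preserve point count")
        return LabeledCloud(
            coords=coords,
            semantic_labels=self.semantic_labels,
            instance_ids=self.instance_ids,
            features=self.features,
        )


@dataclass
class NormalizationState:
    """Per-axis minimum and range; inverting the unit-cube normalization is
    ``x_orig = x_norm * range + min`` applied per axis."""

    min_per_axis: np.ndarray
    range_per_axis: np.ndarray

    def __post_init__(self) -> None:
        self.min_per_axis = np.asarray(self.min_per_axis, dtype=np.float64).reshape(3)
        self.range_per_axis = np.asarray(self.range_per_axis, dtype=np.float64).reshape(3)
        if np.any(self.range_per_axis <= 0):
            raise CloudValidationError("range_per_axis must be positive on every axis")


def normalize(cloud: LabeledCloud) -> tuple[LabeledCloud, NormalizationState]:
    """Min-max normalize each axis to [0, 1], returning the exact inverse state.

    A degenerate axis (zero extent) is stored with range 1 and maps to 0, so
    the round trip stays exact. A cloud with zero extent on all three axes is
    rejected.
    """
    if len(cloud) < 2:
        raise CloudValidationError("normalization needs at least 2 points")
    mins = cloud.coords.min(axis=0)
    maxs = cloud.coords.max(axis=0)
    ranges = maxs - mins
    if np.all(ranges == 0):
        raise CloudValidationError("degenerate cloud: zero extent on all axes")
    safe_ranges = np.where(ranges > 0, ranges, 1.0)
    normed = (cloud.coords - mins) / safe_ranges
    return cloud.with_coords(normed), NormalizationState(mins, safe_ranges)


def denormalize(cloud: LabeledCloud, state: NormalizationState) -> LabeledCloud:
    """Restore metric coordinates: per axis, x_orig = x_norm * R + min."""
    if cloud.coords.shape[1] != 3:
        raise CloudValidationError("expected 3 coordinate axes")
    return cloud.with_coords(cloud.coords * state.range_per_axis + state.min_per_axis)


def resample_to_count(
    cloud: LabeledCloud, num_points: int = 8192, seed: int = 0
) -> LabeledCloud:
    """Random resample to a fixed network input size.

    Subsamples without replacement when the cloud is large enough, otherwise
    samples with replacement up to ``num_points``. Labels follow their points.
    """
    if num_points < 1:
        raise CloudValidationError("num_points must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(cloud)
    if n >= num_points:
        idx = rng.choice(n, size=num_points, replace=False)
    else:
        idx = rng.choice(n, size=num_points, replace=True)
    return cloud.select(idx)
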