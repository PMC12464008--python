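"""Segmentation and regression evaluation metrics.

Segmentation quality is scored from a k x k confusion matrix (rows true,
columns predicted): overall accuracy OA = trace / total, per-class
IoU_i = P_ii / (row_i + col_i - P_ii), and mIoU the mean of the defined
per-class IoUs. Trait agreement is scored by R^2 = 1 - SS_res / SS_tot and
RMSE. Percentages are on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MetricError(ValueError):
    pass


def confusion(pred_labels, true_labels, n_classes: int) -> np.ndarray:
    """Counts[t][p] = number of points with true class t predicted as p."""
    pred = np.asarray(pred_labels, dtype=np.int64).ravel()
    true = np.asarray(true_labels, dtype=np.int64).ravel()
    if pred.shape != true.shape:
        raise MetricError("pred and true label arrays must have equal length")
    if pred.size == 0:
        raise MetricError("empty label arrays")
    for name, arr in (("pred", pred), ("true", true)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise MetricError(f"{name} labels out of range [0, {n_classes})")
    cm = np.bincount(true * n_classes + pred, minlength=n_classes * n_classes)
    return cm.reshape(n_classes, n_classes)


def overall_accuracy(cm: np.ndarray) -> float:
    """100 * trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise MetricError("empty confusion matrix")
    return 100.0 * float(np.trace(cm)) / float(total)


def iou_per_class(cm: np.ndarray) -> list[float]:
    """Per-class IoU in percent; NaN for a class absent from truth and
    prediction alike (excluded from the mean)."""
    cm = np.asarray(cm, dtype=np.float64)
    if cm.sum() <= 0:
        raise MetricError("empty confusion matrix")
    ious = []
    for i in range(cm.shape[0]):
        union = cm[i, :].sum() + cm[:, i].sum() - cm[i, i]
        ious.append(100.0 * cm[i, i] / union if union > 0 else float("nan"))
    return ious


def mean_iou(cm: np.ndarray) -> float:
    """Mean of the defined per-class IoUs."""
    ious = np.asarray(iou_per_class(cm))
    defined = ious[~np.isnan(ious)]
    if defined.size == 0:
        raise MetricError("no class present in truth or prediction")
    return float(defined.mean())


@dataclass
class FitReport:
    """Agreement between measured and predicted values of one trait."""

    r_squared: float
    rmse: float
    n: int


def r_squared(measured, predicted) -> float:
    measured = np.asarray(measured, dtype=np.float64).ravel()
    predicted = np.asarray(predicted, dtype=np.float64).ravel()
    if measured.shape != predicted.shape:
        raise MetricError("measured and predicted must have equal length")
    if measured.size < 2:
        raise MetricError("R^2 needs at least 2 samples")
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("R^2 undefined for constant measured values")
    ss_res = float(np.sum((measured - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(measured, predicted) -> float:
    measured = np.asarray(measured, dtype=np.float64).ravel()
    predicted = np.asarray(predicted, dtype=np.float64).ravel()
    if measured.shape != predicted.shape:
        raise MetricError("measured and predicted must have equal length")
    if measured.size < 1:
        raise MetricError("RMSE needs at least 1 sample")
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def fit_report(measured, predicted) -> FitReport:
    return FitReport(
        r_squared=r_squared(measured, predicted),
        rmse=rmse(measured, predicted),
        n=len(np.asarray(measured).ravel()),
    )
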