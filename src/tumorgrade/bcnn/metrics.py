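"""Multiclass evaluation: accuracy and macro precision/recall/F-measure.

All metrics are computed from the 5x5 confusion matrix over the fixed
class order (Grade I-IV, Healthy) and reported on the percent scale.
Macro averaging gives every class equal weight; a class absent from both
the ground truth and the predictions contributes 0 to the macro averages
and triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..phantom import CLASSES
from .network import BCNNModel, prepare_inputs, _labels_to_indices

__all__ = ["Metrics", "metrics_from_labels", "evaluate"]


@dataclass(frozen=True)
class Metrics:
    """Percent-scale metric suite plus the raw confusion matrix."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "classes": list(CLASSES),
            "n": self.n,
        }


def metrics_from_labels(y_true: list[str] | np.ndarray,
                        y_pred: list[str] | np.ndarray) -> Metrics:
    """Metric suite from ground-truth and predicted class labels."""
    t = _labels_to_indices(list(y_true))
    p = _labels_to_indices(list(y_pred))
    if len(t) == 0:
        raise ValueError("cannot evaluate an empty set")
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    k = len(CLASSES)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (t, p), 1)

    tp = np.diag(confusion).astype(float)
    pred_tot = confusion.sum(axis=0).astype(float)
    true_tot = confusion.sum(axis=1).astype(float)
    absent = (pred_tot == 0) & (true_tot == 0)
    for ci in np.flatnonzero(absent):
        warnings.warn(
            f"class {CLASSES[ci]!r} absent from both truth and predictions; "
            "it contributes 0 to the macro averages", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / np.maximum(pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.maximum(true_tot, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return Metrics(
        accuracy=100.0 * tp.sum() / len(t),
        macro_precision=100.0 * float(precision.mean()),
        macro_recall=100.0 * float(recall.mean()),
        macro_f1=100.0 * float(f1.mean()),
        confusion=confusion,
        n=len(t),
    )


def evaluate(model: BCNNModel, masks: list[np.ndarray],
             labels: list[str]) -> Metrics:
    """Evaluate a trained model on labeled binary masks."""
    if len(masks) == 0:
        raise ValueError("cannot evaluate an empty set")
    x = prepare_inputs(masks, model.config.input_side)
    pred = [CLASSES[i] for i in model.predict_indices(x)]
    return metrics_from_labels(labels, pred)
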