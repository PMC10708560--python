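"""Evaluation statistics for rate regression and state classification.

Regression reports RMSE, MAE and the coefficient of determination R2 per
target (Fc, Fr), plus the adapted R2* = 1 - SSE / sum(y^2), appropriate when
a block of test records shares a single true label (the ordinary
between-record variance is then zero and R2 is undefined).

Classification reports the 3x3 confusion matrix, accuracy = trace/N, and
one-vs-rest precision, recall and F1 per class, macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "regression_metrics",
    "r2_star",
    "classification_metrics",
]


@dataclass
class MetricsReport:
    """Container for per-model evaluation metrics.

    ``values`` maps metric names (e.g. ``rmse_fc`` or ``accuracy``) to floats;
    ``per_class``/``confusion`` are filled for classification, ``mean``/``std``
    after repeated evaluation.
    """

    kind: str  # "regression" | "classification"
    values: Dict[str, float] = field(default_factory=dict)
    per_class: Optional[pd.DataFrame] = None
    confusion: Optional[np.ndarray] = None
    mean: Optional[Dict[str, float]] = None
    std: Optional[Dict[str, float]] = None
    n: int = 0

    def summary(self) -> pd.DataFrame:
        if self.mean is not None:
            return pd.DataFrame({"mean": self.mean, "std": self.std})
        return pd.DataFrame({"value": self.values})


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       targets=("fc", "fr")) -> Dict[str, float]:
    """Per-target RMSE, MAE and R2 for (n, 2) arrays of (Fc, Fr)."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    if y_true.shape[0] < 1:
        raise ValueError("need at least one sample")
    out: Dict[str, float] = {}
    for j, name in enumerate(targets):
        err = y_true[:, j] - y_pred[:, j]
        out[f"rmse_{name}"] = float(np.sqrt(np.mean(err**2)))
        out[f"mae_{name}"] = float(np.mean(np.abs(err)))
        sst = float(np.sum((y_true[:, j] - y_true[:, j].mean()) ** 2))
        sse = float(np.sum(err**2))
        if sst == 0.0:
            out[f"r2_{name}"] = np.nan if sse > 0 else 1.0  # zero-variance truth
        else:
            out[f"r2_{name}"] = 1.0 - sse / sst
    return out


def r2_star(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Adapted coefficient of determination 1 - SSE / sum(y^2).

    Unlike R2, the denominator is the raw energy of the true values, so the
    statistic stays defined for a block of records sharing one true label.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    denom = float(np.sum(y_true**2))
    if denom == 0.0:
        raise ValueError("r2_star undefined: sum(y_true^2) is zero")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / denom


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           n_classes: int = 3,
                           class_names=("drowsiness", "normal", "stress")
                           ) -> MetricsReport:
    """Confusion matrix, accuracy and macro precision/recall/F1.

    Labels are integer class indices. A class absent from ``y_true`` has
    undefined recall: it is reported as NaN and excluded from the macro
    averages.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    n = len(y_true)
    accuracy = float(np.trace(cm)) / n if n else np.nan
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = np.where(
            np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
            2 * precision * recall / (precision + recall),
            np.where(np.isnan(precision) | np.isnan(recall), np.nan, 0.0),
        )
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1,
         "support": cm.sum(axis=1)},
        index=list(class_names)[:n_classes],
    )
    values = {
        "accuracy": accuracy,
        "precision": float(np.nanmean(precision)),
        "recall": float(np.nanmean(recall)),
        "f1": float(np.nanmean(f1)),
    }
    return MetricsReport(kind="classification", values=values,
                         per_class=per_class, confusion=cm, n=n)
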