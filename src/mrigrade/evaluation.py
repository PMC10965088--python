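"""Multiclass evaluation: confusion matrices, per-class sensitivity and
precision, accuracy, one-vs-rest ROC/AUC, and ranked method comparison.

Conventions: confusion rows are true classes, columns predicted;
sensitivity is row-wise correctness (recall), precision column-wise;
the headline AUC of a 4-class report is the Non-Demented (class 1)
one-vs-rest AUC, with the macro average also reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .io import CLASS_NAMES

N_CLASSES = len(CLASS_NAMES)


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with entry (i, j) = true class i+1 predicted as j+1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"labels must lie in 1..{n_classes}")
    idx = (y_true - 1) * n_classes + (y_pred - 1)
    return np.bincount(idx, minlength=n_classes ** 2).reshape(n_classes, n_classes)


def per_class_metrics(confusion: np.ndarray):
    """(sensitivity, precision, accuracy) from a confusion matrix.

    sensitivity_c = diagonal / row sum, precision_c = diagonal / column
    sum, accuracy = trace / total; empty rows or columns give 0 with a
    warning.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix is all zeros")
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("empty row/column in confusion matrix; rate set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(row > 0, diag / row, 0.0)
        precision = np.where(col > 0, diag / col, 0.0)
    return sensitivity, precision, float(diag.sum() / n)


def roc_auc(y_true, scores, positive_class: int):
    """One-vs-rest ROC points and trapezoid AUC for one positive class.

    Thresholds sweep the unique scores in descending order with ties
    grouped; the curve runs from (0, 0) to (1, 1).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = (y_true == positive_class).astype(int)
    if pos.all() or not pos.any():
        raise ValueError("ROC needs both positive and negative samples")
    fpr, tpr, _ = _roc_curve(pos, scores)
    if fpr[0] > 0 or tpr[0] > 0:  # guarantee the (0,0) anchor
        fpr = np.insert(fpr, 0, 0.0)
        tpr = np.insert(tpr, 0, 0.0)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvaluationReport:
    """Evaluation of one classifier on one labelled test set."""

    method: str
    confusion: np.ndarray
    sensitivity: np.ndarray
    precision: np.ndarray
    accuracy: float
    roc: dict = field(default_factory=dict)    # class -> (n_points, 2) array
    auc: dict = field(default_factory=dict)    # class -> float
    class_names: tuple = CLASS_NAMES

    @property
    def headline_auc(self):
        """AUC with the Non-Demented class positive (None if no scores)."""
        return self.auc.get(1)

    @property
    def macro_auc(self):
        return float(np.mean(list(self.auc.values()))) if self.auc else None

    def to_json(self) -> str:
        return json.dumps({
            "method": self.method,
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "precision": self.precision.tolist(),
            "accuracy": self.accuracy,
            "auc": {str(k): v for k, v in self.auc.items()},
            "roc": {str(k): np.asarray(v).tolist() for k, v in self.roc.items()},
            "class_names": list(self.class_names),
        })

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            method=d["method"], confusion=np.array(d["confusion"]),
            sensitivity=np.array(d["sensitivity"]),
            precision=np.array(d["precision"]), accuracy=d["accuracy"],
            roc={int(k): np.array(v) for k, v in d["roc"].items()},
            auc={int(k): v for k, v in d["auc"].items()},
            class_names=tuple(d["class_names"]))

    def confusion_csv(self, path) -> None:
        pd.DataFrame(self.confusion, index=list(self.class_names),
                     columns=list(self.class_names)).to_csv(path)


def evaluate(method: str, y_true, y_pred, scores=None,
             class_names: tuple = CLASS_NAMES) -> EvaluationReport:
    """Build a full report; ``scores`` is an optional (n, C) score matrix
    whose columns feed the one-vs-rest ROC curves."""
    cm = confusion_matrix(y_true, y_pred, n_classes=len(class_names))
    sens, prec, acc = per_class_metrics(cm)
    roc, aucs = {}, {}
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        for c in range(1, len(class_names) + 1):
            present = np.any(np.asarray(y_true) == c)
            if present and not np.all(np.asarray(y_true) == c):
                roc[c], aucs[c] = roc_auc(y_true, scores[:, c - 1], c)
    return EvaluationReport(method, cm, sens, prec, acc, roc, aucs, class_names)


def comparison_report(reports) -> pd.DataFrame:
    """Methods ranked by accuracy (descending), with the Non-Demented
    one-vs-rest AUC and the macro average where scores were provided."""
    if not reports:
        raise ValueError("at least one report required")
    rows = [{
        "method": r.method,
        "accuracy": r.accuracy,
        "auc_non_demented": r.headline_auc,
        "auc_macro": r.macro_auc,
    } for r in reports]
    df = pd.DataFrame(rows).sort_values("accuracy", ascending=False, kind="stable")
    return df.reset_index(drop=True)
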