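"""Multiclass evaluation: per-class metrics, macro/weighted aggregates,
confusion matrix, one-vs-rest ROC and precision-recall curves.

Per-class metrics are one-vs-rest counts from the confusion matrix:
precision = TP/(TP+FP), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), F1 = harmonic mean of precision and sensitivity. The macro
aggregate is the unweighted mean over classes; the weighted aggregate uses
W_class = n_class / n_total, the class's share of the dataset. Zero
denominators yield 0 with an explicit flag (never NaN).

ROC AUC is the trapezoidal area under the one-vs-rest threshold sweep of
the class's softmax score; PR AUC is the step-wise threshold-sweep
integral (average precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .io import CLASSES

METRIC_COLUMNS = ["precision", "sensitivity", "specificity", "f1",
                  "auc_roc", "auc_pr"]


def confusion_matrix(true_labels, predicted_labels, classes=None) -> np.ndarray:
    """Entry (i, j): records of true class i predicted as class j."""
    classes = list(classes) if classes is not None else list(CLASSES)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true labels vs {len(predicted_labels)} predictions"
        )
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in classes:
            raise ValueError(f"label {lab!r} not in class set")
    return skm.confusion_matrix(true_labels, predicted_labels, labels=classes)


def per_class_metrics(confusion: np.ndarray, classes=None) -> pd.DataFrame:
    """One-vs-rest precision/sensitivity/specificity/F1 per class."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    n_cls = cm.shape[0]
    classes = list(classes) if classes is not None else list(CLASSES)[:n_cls]
    total = cm.sum()
    rows = []
    for i in range(n_cls):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den):
            return (num / den, False) if den > 0 else (0.0, True)

        prec, f_p = ratio(tp, tp + fp)
        sens, f_s = ratio(tp, tp + fn)
        spec, f_sp = ratio(tn, tn + fp)
        f1, f_f = ratio(2 * prec * sens, prec + sens)
        rows.append({
            "precision": prec, "sensitivity": sens, "specificity": spec,
            "f1": f1, "undefined": bool(f_p or f_s or f_sp or f_f),
        })
    return pd.DataFrame(rows, index=classes)


def aggregate(per_class: pd.DataFrame, class_counts
              ) -> tuple[pd.Series, pd.Series]:
    """(macro, weighted) rows: unweighted mean and W_class-weighted mean."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("class counts must be non-negative with a positive sum")
    numeric = per_class.select_dtypes(include=[np.number])
    macro = numeric.mean(axis=0)
    w = counts / counts.sum()
    weighted = pd.Series(numeric.to_numpy().T @ w, index=numeric.columns)
    macro.name, weighted.name = "macro", "weighted"
    return macro, weighted


def roc_pr_curves(true_labels, probability_matrix, classes=None) -> dict:
    """One-vs-rest ROC and PR curves with AUCs per class.

    Classes with no positive or no negative examples get ``auc = None``
    plus a ``degenerate`` flag instead of a number.
    """
    classes = list(classes) if classes is not None else list(CLASSES)
    proba = np.asarray(probability_matrix, dtype=float)
    if proba.ndim != 2 or proba.shape[1] != len(classes):
        raise ValueError(f"probability matrix shape {proba.shape} does not "
                         f"match {len(classes)} classes")
    if len(true_labels) != proba.shape[0]:
        raise ValueError("label / probability row count mismatch")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("probability rows must sum to 1")
    y = np.asarray([classes.index(lab) for lab in true_labels])
    out = {}
    for i, cls in enumerate(classes):
        pos = y == i
        if pos.all() or not pos.any():
            out[cls] = {"degenerate": True, "auc_roc": None, "auc_pr": None}
            continue
        fpr, tpr, _ = skm.roc_curve(pos, proba[:, i])
        prec, rec, _ = skm.precision_recall_curve(pos, proba[:, i])
        out[cls] = {
            "degenerate": False,
            "fpr": fpr, "tpr": tpr,
            "precision": prec, "recall": rec,
            "auc_roc": float(skm.auc(fpr, tpr)),
            "auc_pr": float(skm.average_precision_score(pos, proba[:, i])),
        }
    return out


@dataclass
class EvalReport:
    """Full metric suite for one prediction run."""

    per_class: pd.DataFrame
    confusion: np.ndarray
    macro: pd.Series
    weighted: pd.Series
    class_counts: np.ndarray
    classes: list[str] = field(default_factory=lambda: list(CLASSES))
    curves: dict = field(default_factory=dict)

    def round(self, ndigits: int = 2) -> pd.DataFrame:
        """Display table rounded like a results summary; full precision kept."""
        table = self.per_class.copy()
        table.loc["macro"] = self.macro
        table.loc["weighted"] = self.weighted
        return table.select_dtypes(include=[np.number]).round(ndigits)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "class_counts": self.class_counts.tolist(),
            "per_class": self.per_class.select_dtypes(include=[np.number])
                             .to_dict(orient="index"),
            "macro": self.macro.to_dict(),
            "weighted": self.weighted.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_report(true_labels, predicted_labels, probability_matrix=None,
                 classes=None) -> EvalReport:
    """Convenience constructor running the full metric suite."""
    classes = list(classes) if classes is not None else list(CLASSES)
    cm = confusion_matrix(true_labels, predicted_labels, classes)
    table = per_class_metrics(cm, classes)
    counts = cm.sum(axis=1)
    curves = {}
    if probability_matrix is not None:
        curves = roc_pr_curves(true_labels, probability_matrix, classes)
        table["auc_roc"] = [curves[c]["auc_roc"] if not curves[c]["degenerate"]
                            else 0.0 for c in classes]
        table["auc_pr"] = [curves[c]["auc_pr"] if not curves[c]["degenerate"]
                           else 0.0 for c in classes]
    macro, weighted = aggregate(table, counts)
    return EvalReport(per_class=table, confusion=cm, macro=macro,
                      weighted=weighted, class_counts=counts,
                      classes=classes, curves=curves)
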