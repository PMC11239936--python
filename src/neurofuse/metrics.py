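"""Multiclass evaluation: confusion matrix, accuracy/precision/recall/F1, ROC/AUC.

Scores follow the usual one-vs-rest decomposition of a K x K confusion
matrix whose entry (i, j) counts samples of true class i predicted as
class j.  For class c: TP is the diagonal entry, FP the rest of column c,
FN the rest of row c, TN everything else; accuracy = trace / total,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.
Macro averaging is the unweighted mean over classes (default here), micro
pools the counts first; for single-label multiclass data micro precision,
micro recall and accuracy coincide.

ROC curves and AUC are computed one-vs-rest per class on real-valued
scores (fused Sugeno scores are used raw; they need not sum to 1 —
ROC/AUC only depends on the score ordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionMatrix", "confusion_matrix", "scores", "roc_auc_ovr"]


@dataclass
class ConfusionMatrix:
    """K x K count matrix with its class-label order.

    ``counts[i, j]`` = number of samples of true class ``class_labels[i]``
    predicted as ``class_labels[j]``.
    """

    counts: np.ndarray
    class_labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.class_labels, columns=self.class_labels
        )

    def ovr_counts(self, label) -> dict:
        """One-vs-rest TP/FP/FN/TN for one class; sums to the total."""
        i = self.class_labels.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def confusion_matrix(
    true_labels: Sequence,
    predicted_labels: Sequence,
    class_labels: Sequence,
) -> ConfusionMatrix:
    """Count true-vs-predicted classes in the declared label order."""
    labels = list(class_labels)
    y_true = np.asarray(list(true_labels), dtype=object)
    y_pred = np.asarray(list(predicted_labels), dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"{y_true.size} true vs {y_pred.size} predicted labels"
        )
    known = set(labels)
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        unknown = sorted({str(v) for v in arr if v not in known})
        if unknown:
            raise ValueError(f"unknown {name} label(s): {unknown!r}")
    if y_true.size == 0:
        counts = np.zeros((len(labels), len(labels)), dtype=int)
    else:
        counts = _sk_confusion(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts=np.asarray(counts, dtype=int), class_labels=labels)


def scores(cm: ConfusionMatrix, averaging: str = "macro") -> dict:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    ``macro`` averages per-class one-vs-rest scores without weighting;
    ``micro`` pools TP/FP/FN counts over classes first.  Classes with a
    zero denominator contribute 0 with a warning.
    """
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    c = np.asarray(cm.counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty; no samples to score")
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    accuracy = float(tp.sum() / total)
    if averaging == "micro":
        precision = float(tp.sum() / (tp.sum() + fp.sum()))
        recall = float(tp.sum() / (tp.sum() + fn.sum()))
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            prec_c = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            rec_c = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
            f1_c = np.where(
                prec_c + rec_c > 0, 2 * prec_c * rec_c / (prec_c + rec_c), 0.0
            )
        if np.any(tp + fp == 0) or np.any(tp + fn == 0):
            warnings.warn(
                "zero-denominator class(es) contribute 0 to macro scores",
                stacklevel=2,
            )
        precision = float(prec_c.mean())
        recall = float(rec_c.mean())
        f1 = float(f1_c.mean())
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": float(f1),
    }


def roc_auc_ovr(
    true_labels: Sequence,
    per_class_scores: np.ndarray,
    class_labels: Sequence,
) -> dict:
    """One-vs-rest ROC curve and AUC per class, plus the macro average.

    Classes without both a positive and a negative sample are skipped with
    a warning; if every class is skipped a ``ValueError`` is raised.

    Returns
    -------
    dict
        ``per_class``: {label: {"fpr", "tpr", "auc"}} for evaluated
        classes; ``macro_auc``: unweighted mean AUC over them;
        ``skipped``: labels left out.
    """
    labels = list(class_labels)
    y = np.asarray(list(true_labels), dtype=object)
    s = np.asarray(per_class_scores, dtype=float)
    if s.ndim != 2 or s.shape != (y.size, len(labels)):
        raise ValueError(
            f"scores must have shape ({y.size}, {len(labels)}); got {s.shape}"
        )
    per_class: dict = {}
    skipped = []
    for j, lab in enumerate(labels):
        pos = y == lab
        if pos.sum() == 0 or pos.sum() == y.size:
            skipped.append(lab)
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), s[:, j])
        per_class[lab] = {"fpr": fpr, "tpr": tpr, "auc": float(_sk_auc(fpr, tpr))}
    if skipped:
        warnings.warn(
            f"skipped class(es) without both positives and negatives: {skipped!r}",
            stacklevel=2,
        )
    if not per_class:
        raise ValueError("no class had both positive and negative samples")
    macro = float(np.mean([v["auc"] for v in per_class.values()]))
    return {"per_class": per_class, "macro_auc": macro, "skipped": skipped}
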