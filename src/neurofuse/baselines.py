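"""Reference ensemble rules: majority voting, averaging, multiplication.

These are the standard combiners a fuzzy-integral fusion is benchmarked
against.  All three are stateless over the confidence inputs (``fit`` only
records shapes and labels) and permutation-invariant over classifiers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .fusion import FusionResult, _aligned_tables, validate_confidence_matrix

__all__ = [
    "majority_vote",
    "average_fuse",
    "product_fuse",
    "MajorityVoteClassifier",
    "AverageFusionClassifier",
    "ProductFusionClassifier",
    "fuse_dataset_with",
]

#: Floor applied per probability entry before taking logs in the product rule.
PRODUCT_EPS = 1e-12


def majority_vote(
    values: np.ndarray, class_labels: Sequence | None = None
) -> FusionResult:
    """Plurality vote of per-classifier argmax predictions.

    Ties break first by summed probability across classifiers, then by the
    lowest class index.  Fused scores are the vote fractions.
    """
    m = validate_confidence_matrix(values)
    n, k = m.shape
    labels = list(class_labels) if class_labels is not None else list(range(k))
    votes = np.argmax(m, axis=1)
    counts = np.bincount(votes, minlength=k).astype(float)
    scores = counts / n
    best = counts == counts.max()
    if best.sum() > 1:
        sums = m.sum(axis=0)
        masked = np.where(best, sums, -np.inf)
        winner = int(np.argmax(masked))
    else:
        winner = int(np.argmax(counts))
    return FusionResult(fused_scores=scores, predicted_label=labels[winner])


def average_fuse(
    values: np.ndarray, class_labels: Sequence | None = None
) -> FusionResult:
    """Arithmetic mean of the N probability vectors; argmax prediction."""
    m = validate_confidence_matrix(values)
    labels = (
        list(class_labels) if class_labels is not None else list(range(m.shape[1]))
    )
    scores = m.mean(axis=0)
    return FusionResult(
        fused_scores=scores, predicted_label=labels[int(np.argmax(scores))]
    )


def product_fuse(
    values: np.ndarray, class_labels: Sequence | None = None
) -> FusionResult:
    """Product of the N probability vectors, computed in log space.

    Each entry is floored at 1e-12 so a zero probability cannot zero out or
    NaN the product.
    """
    m = validate_confidence_matrix(values)
    labels = (
        list(class_labels) if class_labels is not None else list(range(m.shape[1]))
    )
    scores = np.exp(np.sum(np.log(np.maximum(m, PRODUCT_EPS)), axis=0))
    return FusionResult(
        fused_scores=scores, predicted_label=labels[int(np.argmax(scores))]
    )


class _BaseCombiner(BaseEstimator, ClassifierMixin):
    """Shared plumbing for the stateless baseline combiners."""

    def _stack(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            X = np.stack([np.asarray(x, dtype=float) for x in X], axis=1)
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                "X must have shape (n_samples, n_classifiers, n_classes); "
                f"got {X.shape}"
            )
        return X

    def fit(self, X, y=None):
        X = self._stack(X)
        self.n_sources_ = X.shape[1]
        k = X.shape[2]
        if y is not None and len(np.unique(np.asarray(y))) == k:
            self.classes_ = np.unique(np.asarray(y))
        else:
            self.classes_ = np.arange(k)
        return self

    def _fuse_one(self, matrix: np.ndarray) -> FusionResult:
        raise NotImplementedError

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = self._stack(X)
        return np.stack([self._fuse_one(X[i]).fused_scores for i in range(len(X))])

    def predict(self, X) -> np.ndarray:
        # via the per-sample rule so each baseline's tie-break chain applies
        check_is_fitted(self, "classes_")
        X = self._stack(X)
        labels = list(self.classes_)
        out = [self._fuse_one(X[i], labels).predicted_label for i in range(len(X))]
        return np.asarray(out)


class MajorityVoteClassifier(_BaseCombiner):
    """Plurality vote over classifier argmaxes (ties: summed probability)."""

    def _fuse_one(self, matrix, labels=None):
        return majority_vote(matrix, labels)


class AverageFusionClassifier(_BaseCombiner):
    """Mean of classifier probability vectors."""

    def _fuse_one(self, matrix, labels=None):
        return average_fuse(matrix, labels)


class ProductFusionClassifier(_BaseCombiner):
    """Product (log-space, floored) of classifier probability vectors."""

    def _fuse_one(self, matrix, labels=None):
        return product_fuse(matrix, labels)


_RULES = {
    "majority": majority_vote,
    "average": average_fuse,
    "product": product_fuse,
}


def fuse_dataset_with(method: str, tables: Sequence) -> pd.DataFrame:
    """Apply one baseline rule across N aligned prediction tables.

    Output frame matches :func:`neurofuse.fusion.fuse_dataset`.
    """
    if method not in _RULES:
        raise ValueError(f"unknown ensemble method {method!r}")
    rule = _RULES[method]
    ids, labels = _aligned_tables(tables)
    stack = np.stack(
        [validate_confidence_matrix(t.probabilities) for t in tables], axis=1
    )
    results = [rule(stack[i], labels) for i in range(len(ids))]
    out = pd.DataFrame({"sample_id": ids})
    first = tables[0]
    out["true_label"] = (
        list(first.true_labels) if first.true_labels is not None else None
    )
    scores = np.stack([r.fused_scores for r in results])
    for j, lab in enumerate(labels):
        out[f"p_{lab}"] = scores[:, j]
    out["predicted_label"] = [r.predicted_label for r in results]
    return out
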