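"""Max--min Sugeno fuzzy-integral fusion of classifier confidence outputs.

Given N base classifiers that each emit a probability vector over K classes
for a sample, the fused score of class k is the Sugeno integral of the N
class-k confidences with respect to a Sugeno lambda-measure over the
classifiers:

.. math::

   \\int f \\, d g = \\max_{i} \\min\\bigl(f_{(i)},\\; g(A_{(i)})\\bigr)

where the confidences are sorted ascending, :math:`f_{(1)} \\le \\dots \\le
f_{(N)}`, and :math:`A_{(i)}` is the set of classifiers whose confidence is
at least :math:`f_{(i)}` (a nested suffix chain).  The fused score always
lies between the smallest and largest input confidence; the predicted class
is the argmax of the fused scores.

The module exposes a functional surface (:func:`sugeno_integral`,
:func:`fuse_sample`, :func:`fuse_dataset`) and the scikit-learn style
:class:`SugenoFusionClassifier` that fits densities from validation
accuracy and fuses stacked confidence tensors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .measure import SugenoLambdaMeasure, validate_densities

logger = logging.getLogger(__name__)

__all__ = [
    "sugeno_integral",
    "sugeno_integral_batch",
    "fuse_sample",
    "fuse_dataset",
    "assign_densities",
    "validate_confidence_matrix",
    "FusionResult",
    "SugenoFusionClassifier",
]

#: Row sums may deviate from 1 by this much before renormalization kicks in.
ROW_SUM_TOL = 1e-3


@dataclass
class FusionResult:
    """Fused outcome for one sample.

    Attributes
    ----------
    fused_scores : ndarray of shape (K,)
        Sugeno-integral score per class, each within the span of that
        class's column of input confidences.
    predicted_label : object
        Argmax class; ties break toward the lowest class index in the
        declared label order.
    per_class_detail : list of (ndarray, ndarray)
        For each class, the ascending-sorted confidences and the matching
        nested chain measures used by the integral (audit trail).
    """

    fused_scores: np.ndarray
    predicted_label: object
    per_class_detail: list = field(default_factory=list)


def validate_confidence_matrix(values: np.ndarray) -> np.ndarray:
    """Validate an N x K confidence matrix; renormalize drifted rows.

    Entries must lie in [0, 1]; rows whose sum deviates from 1 by more than
    ``ROW_SUM_TOL`` are renormalized with a logged warning.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"confidence matrix must be 2-D, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("confidence matrix contains non-finite entries")
    if np.any(m < -1e-12) or np.any(m > 1.0 + 1e-12):
        raise ValueError("confidences must lie in [0, 1]")
    m = np.clip(m, 0.0, 1.0)
    sums = m.sum(axis=1)
    off = np.abs(sums - 1.0) > ROW_SUM_TOL
    if np.any(off):
        logger.warning(
            "renormalizing %d confidence row(s) with |sum - 1| > %g",
            int(off.sum()),
            ROW_SUM_TOL,
        )
        m = m.copy()
        m[off] = m[off] / sums[off, None]
    return m


def sugeno_integral(
    confidences: Sequence[float], m: SugenoLambdaMeasure
) -> float:
    """Sugeno integral of one confidence per source w.r.t. measure ``m``.

    Sources are sorted ascending by confidence (stable, so tied sources
    keep their original order); the result is the max over sorted positions
    of min(confidence, measure of the suffix set from that position).
    """
    f = np.asarray(confidences, dtype=float)
    if f.ndim != 1 or f.size != m.n_sources:
        raise ValueError(
            f"expected {m.n_sources} confidences, got shape {f.shape}"
        )
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("confidences must lie in [0, 1]")
    if m.n_sources == 1:
        return float(f[0])
    order = np.argsort(f, kind="stable")
    chain = m.nested_chain_measures(order)
    return float(np.max(np.minimum(f[order], chain)))


def sugeno_integral_batch(F: np.ndarray, m: SugenoLambdaMeasure) -> np.ndarray:
    """Vectorized Sugeno integral over rows of an (n, N) confidence array."""
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] != m.n_sources:
        raise ValueError(
            f"expected shape (n, {m.n_sources}), got {F.shape}"
        )
    n, N = F.shape
    if N == 1:
        return F[:, 0].copy()
    order = np.argsort(F, axis=1, kind="stable")
    f_sorted = np.take_along_axis(F, order, axis=1)
    g = m.densities[order]  # (n, N) densities in sorted order
    chain = np.empty_like(g)
    value = g[:, N - 1].copy()
    chain[:, N - 1] = value
    for pos in range(N - 2, -1, -1):
        gi = g[:, pos]
        value = value + gi + m.lam * value * gi
        chain[:, pos] = value
    np.clip(chain, 0.0, 1.0, out=chain)
    return np.max(np.minimum(f_sorted, chain), axis=1)


def fuse_sample(
    values: np.ndarray,
    m: SugenoLambdaMeasure,
    class_labels: Sequence | None = None,
) -> FusionResult:
    """Fuse one sample's N x K confidence matrix class by class.

    Each class column is aggregated independently with
    :func:`sugeno_integral`; the predicted label is the argmax of the fused
    scores (ties -> lowest class index in ``class_labels`` order).
    """
    matrix = validate_confidence_matrix(values)
    n, k = matrix.shape
    if n != m.n_sources:
        raise ValueError(
            f"matrix has {n} classifier rows but measure has "
            f"{m.n_sources} sources"
        )
    labels = list(class_labels) if class_labels is not None else list(range(k))
    if len(labels) != k:
        raise ValueError(
            f"{len(labels)} class labels for {k} confidence columns"
        )
    scores = np.empty(k)
    detail = []
    for j in range(k):
        col = matrix[:, j]
        order = np.argsort(col, kind="stable")
        chain = m.nested_chain_measures(order) if n > 1 else np.array([1.0])
        scores[j] = float(np.max(np.minimum(col[order], chain)))
        detail.append((col[order].copy(), chain.copy()))
    return FusionResult(
        fused_scores=scores,
        predicted_label=labels[int(np.argmax(scores))],
        per_class_detail=detail,
    )


def assign_densities(
    strategy: str,
    n_sources: int | None = None,
    accuracies: Sequence[float] | None = None,
    user_values: Sequence[float] | None = None,
) -> np.ndarray:
    """Build a density vector by the chosen strategy.

    ``uniform``: g_i = 1/N.  ``accuracy``: g_i = validation accuracy of
    classifier i, clipped into [1e-6, 1 - 1e-6] with a warning at the
    boundary.  ``user``: validated pass-through of explicit values.
    """
    if strategy == "uniform":
        if not n_sources or n_sources < 1:
            raise ValueError("uniform strategy requires n_sources >= 1")
        return np.full(n_sources, 1.0 / n_sources)
    if strategy == "accuracy":
        if accuracies is None:
            raise ValueError("accuracy strategy requires per-classifier accuracies")
        a = np.asarray(list(accuracies), dtype=float)
        if np.any(a <= 0.0) or np.any(a > 1.0):
            raise ValueError(f"accuracies must lie in (0, 1]; got {a.tolist()!r}")
        clipped = np.clip(a, 1e-6, 1.0 - 1e-6)
        if np.any(clipped != a):
            warnings.warn(
                "boundary accuracies clipped into (0, 1) for density use",
                stacklevel=2,
            )
        return clipped
    if strategy == "user":
        if user_values is None:
            raise ValueError("user strategy requires explicit density values")
        return validate_densities(user_values)
    raise ValueError(f"unknown density strategy {strategy!r}")


def _aligned_tables(tables: Sequence) -> tuple:
    """Check N prediction tables share sample ids and class labels."""
    if not tables:
        raise ValueError("at least one prediction table is required")
    ref = tables[0]
    ids = list(ref.sample_ids)
    if len(set(ids)) != len(ids):
        seen: set = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate sample ids: {dupes!r}")
    labels = list(ref.class_labels)
    for t in tables[1:]:
        if list(t.class_labels) != labels:
            raise ValueError(
                f"class labels differ across tables: {labels!r} vs "
                f"{list(t.class_labels)!r}"
            )
        if list(t.sample_ids) != ids:
            missing = sorted(set(ids) ^ set(t.sample_ids))
            raise ValueError(
                f"sample ids are not aligned across tables; "
                f"mismatched ids: {missing[:10]!r}"
            )
    return ids, labels


def fuse_dataset(
    tables: Sequence,
    m: SugenoLambdaMeasure | None = None,
    density_strategy: str = "accuracy",
    renormalize: bool = False,
) -> pd.DataFrame:
    """Fuse N aligned prediction tables into one fused prediction frame.

    Parameters
    ----------
    tables : sequence of PredictionTable
        One table per classifier, identical sample-id and class-label sets
        in identical order (see :mod:`neurofuse.io`).
    m : SugenoLambdaMeasure, optional
        The measure to fuse with.  When omitted it is built from
        ``density_strategy``: ``uniform`` needs nothing further;
        ``accuracy`` derives each classifier's density from its argmax
        accuracy against the tables' ``true_labels``.
    renormalize : bool
        Rescale fused scores to sum to 1 per sample (for ROC use); raw
        max--min scores are not a probability simplex point.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``true_label`` (passed through),
    one ``p_<class>`` fused-score column per class, and ``predicted_label``.
    """
    ids, labels = _aligned_tables(tables)
    n_sources = len(tables)
    stack = np.stack(
        [validate_confidence_matrix(t.probabilities) for t in tables], axis=1
    )  # (n_samples, N, K)
    if m is None:
        if density_strategy == "uniform":
            densities = assign_densities("uniform", n_sources=n_sources)
        elif density_strategy == "accuracy":
            accs = []
            for t in tables:
                if t.true_labels is None:
                    raise ValueError(
                        "accuracy density strategy needs true labels in the tables"
                    )
                pred = np.asarray(labels, dtype=object)[
                    np.argmax(t.probabilities, axis=1)
                ]
                accs.append(float(np.mean(pred == np.asarray(t.true_labels))))
            densities = assign_densities("accuracy", accuracies=accs)
        else:
            raise ValueError(
                f"density strategy {density_strategy!r} requires an explicit measure"
            )
        m = SugenoLambdaMeasure(densities) if n_sources > 1 else None
    if n_sources == 1:
        fused = stack[:, 0, :]
    else:
        fused = np.column_stack(
            [sugeno_integral_batch(stack[:, :, j], m) for j in range(stack.shape[2])]
        )
    if renormalize:
        sums = fused.sum(axis=1, keepdims=True)
        sums[sums == 0.0] = 1.0
        fused = fused / sums
    predicted = np.asarray(labels, dtype=object)[np.argmax(fused, axis=1)]
    out = pd.DataFrame({"sample_id": ids})
    first = tables[0]
    out["true_label"] = (
        list(first.true_labels) if first.true_labels is not None else None
    )
    for j, lab in enumerate(labels):
        out[f"p_{lab}"] = fused[:, j]
    out["predicted_label"] = predicted
    return out


class SugenoFusionClassifier(BaseEstimator, ClassifierMixin):
    """Sugeno fuzzy-integral combiner of pre-computed classifier confidences.

    The estimator consumes a stacked confidence tensor ``X`` of shape
    ``(n_samples, n_classifiers, n_classes)`` (or a list of per-classifier
    ``(n_samples, n_classes)`` arrays).  ``fit`` assigns one fuzzy density
    per base classifier and solves the lambda-measure; ``predict_proba``
    returns the fused per-class scores and ``predict`` their argmax.

    Parameters
    ----------
    density_strategy : {"accuracy", "uniform", "user"}
        How densities are assigned.  ``accuracy`` (default) scores each
        classifier's argmax accuracy on the fit data, so ``fit`` requires
        ``y``; ``uniform`` uses 1/N; ``user`` takes ``densities`` verbatim.
    densities : sequence of float, optional
        Explicit densities for the ``user`` strategy.
    renormalize : bool
        If True, ``predict_proba`` rescales fused scores to sum to 1.

    Attributes
    ----------
    densities_ : ndarray of shape (n_classifiers,)
        Fitted fuzzy densities.
    lambda_ : float
        Solved measure parameter.
    measure_ : SugenoLambdaMeasure or None
        The fitted measure (None for a single classifier).
    classes_ : ndarray
        Class labels (column index order).

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]]])
    >>> clf = SugenoFusionClassifier(density_strategy="uniform")
    >>> clf.fit(X).predict_proba(X)
    array([[0.6, 0.4]])
    """

    def __init__(
        self,
        density_strategy: str = "accuracy",
        densities: Sequence[float] | None = None,
        renormalize: bool = False,
    ) -> None:
        self.density_strategy = density_strategy
        self.densities = densities
        self.renormalize = renormalize

    def _stack(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            X = np.stack([np.asarray(x, dtype=float) for x in X], axis=1)
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                "X must have shape (n_samples, n_classifiers, n_classes); "
                f"got {X.shape}"
            )
        return np.stack([validate_confidence_matrix(X[i]) for i in range(len(X))])

    def fit(self, X, y=None) -> "SugenoFusionClassifier":
        X = self._stack(X)
        n, n_src, k = X.shape
        self.n_sources_ = n_src
        self.classes_ = (
            np.unique(np.asarray(y)) if y is not None else np.arange(k)
        )
        if y is not None and len(self.classes_) != k:
            # keep column order authoritative; y may not exercise every class
            self.classes_ = np.arange(k)
        if self.density_strategy == "user":
            self.densities_ = assign_densities("user", user_values=self.densities)
            if self.densities_.size != n_src:
                raise ValueError(
                    f"{self.densities_.size} densities for {n_src} classifiers"
                )
        elif self.density_strategy == "uniform":
            self.densities_ = assign_densities("uniform", n_sources=n_src)
        elif self.density_strategy == "accuracy":
            if y is None:
                raise ValueError("density_strategy='accuracy' requires y in fit")
            y = np.asarray(y)
            accs = [
                float(np.mean(self.classes_[np.argmax(X[:, s, :], axis=1)] == y))
                for s in range(n_src)
            ]
            if any(a <= 0.0 for a in accs):
                raise ValueError(
                    f"a classifier scored accuracy 0 on the fit data: {accs!r}"
                )
            self.densities_ = assign_densities("accuracy", accuracies=accs)
        else:
            raise ValueError(
                f"unknown density_strategy {self.density_strategy!r}"
            )
        if n_src > 1:
            self.measure_ = SugenoLambdaMeasure(self.densities_)
            self.lambda_ = self.measure_.lam
        else:
            self.measure_ = None
            self.lambda_ = 0.0
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw fused Sugeno scores, shape (n_samples, n_classes)."""
        check_is_fitted(self, "densities_")
        X = self._stack(X)
        if X.shape[1] != self.n_sources_:
            raise ValueError(
                f"X has {X.shape[1]} classifiers; fitted with {self.n_sources_}"
            )
        if self.n_sources_ == 1:
            return X[:, 0, :].copy()
        return np.column_stack(
            [
                sugeno_integral_batch(X[:, :, j], self.measure_)
                for j in range(X.shape[2])
            ]
        )

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        if self.renormalize:
            sums = scores.sum(axis=1, keepdims=True)
            sums[sums == 0.0] = 1.0
            scores = scores / sums
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
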