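"""Seeded generator of correlated multi-classifier prediction tables.

Emulates the study setting in which N trained image classifiers each emit a
softmax probability vector over K neuron-morphology classes for every test
image, without requiring any images or training: ground-truth labels are
drawn uniformly over K; whether classifier n gets sample j right is a
Bernoulli event whose rate equals the classifier's configured skill; and
the emitted probability vector is a Dirichlet draw sharply peaked (by a
concentration parameter) on the predicted class, with the argmax pinned to
that class so realized accuracy is exactly calibrated.

Error correlation between classifiers is induced through a Gaussian copula:
each sample carries a latent difficulty normal deviate shared (with weight
``error_correlation``) across classifiers, so at correlation 1 all
classifiers fail on the same hard samples while each marginal accuracy
stays at its configured skill.

:func:`complementary_scenario` instead partitions the classes among the
classifiers so each one is expert on a disjoint subset and near-chance
(with nearly flat probability vectors) elsewhere — the regime in which a
sound fusion rule beats every individual classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io import PredictionTable

__all__ = ["SimulationConfig", "simulate", "complementary_scenario"]

#: Concentration of the near-flat vectors non-experts emit in the
#: complementary scenario.
WEAK_CONCENTRATION = 1.5


@dataclass
class SimulationConfig:
    """Study conditions for one simulated ensemble run.

    Defaults mirror the reference setting: three base classifiers with
    skills equal to the three modified networks' test accuracies, four
    morphology classes, independent errors, and sharply peaked
    (concentration 8) probability vectors.
    """

    n_classes: int = 4
    n_samples: int = 5000
    skills: tuple = (0.9537, 0.9673, 0.9478)
    concentration: float = 8.0
    error_correlation: float = 0.0
    seed: int = 0
    class_labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.skills or any(not (0.0 < s < 1.0) for s in self.skills):
            raise ValueError("every skill must lie strictly in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not (0.0 <= self.error_correlation <= 1.0):
            raise ValueError("error_correlation must lie in [0, 1]")
        if not self.class_labels:
            self.class_labels = [f"class_{k}" for k in range(self.n_classes)]
        if len(self.class_labels) != self.n_classes:
            raise ValueError(
                f"{len(self.class_labels)} labels for {self.n_classes} classes"
            )

    @property
    def n_classifiers(self) -> int:
        return len(self.skills)


def _dirichlet_peaked(
    rng: np.random.Generator,
    pred: np.ndarray,
    k: int,
    concentration: float,
) -> np.ndarray:
    """Row-wise Dirichlet draws with the concentration on column pred[i].

    The largest entry is swapped into the predicted column when a draw's
    argmax strays, so argmax(vector) == pred holds by construction.
    """
    n = pred.size
    alpha = np.ones((n, k))
    alpha[np.arange(n), pred] = concentration
    g = rng.gamma(shape=alpha)
    probs = g / g.sum(axis=1, keepdims=True)
    amax = np.argmax(probs, axis=1)
    stray = amax != pred
    if np.any(stray):
        rows = np.flatnonzero(stray)
        pv = probs[rows, pred[rows]].copy()
        probs[rows, pred[rows]] = probs[rows, amax[rows]]
        probs[rows, amax[rows]] = pv
    return probs


def _wrong_class(
    rng: np.random.Generator, truth: np.ndarray, k: int
) -> np.ndarray:
    """A uniformly random class different from the true one, per sample."""
    return (truth + rng.integers(1, k, size=truth.size)) % k


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, list[PredictionTable]]:
    """Generate ground truth and one prediction table per classifier.

    Returns the truth frame (``sample_id``, ``true_label``) and N
    :class:`~neurofuse.io.PredictionTable` objects.  Identical configs
    (including seed) yield identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_classes
    rho = config.error_correlation
    truth = rng.integers(k, size=n)
    sample_ids = [f"s{idx:06d}" for idx in range(n)]
    labels = np.asarray(config.class_labels, dtype=object)
    difficulty = rng.standard_normal(n)  # shared latent difficulty

    tables = []
    for skill in config.skills:
        eps = rng.standard_normal(n)
        z = np.sqrt(rho) * difficulty + np.sqrt(1.0 - rho) * eps
        u = ndtr(z)  # marginally uniform regardless of rho
        correct = u < skill
        pred = np.where(correct, truth, _wrong_class(rng, truth, k))
        probs = _dirichlet_peaked(rng, pred, k, config.concentration)
        tables.append(
            PredictionTable(
                sample_ids=sample_ids,
                class_labels=list(labels),
                probabilities=probs,
                true_labels=list(labels[truth]),
            )
        )
    truth_frame = pd.DataFrame(
        {"sample_id": sample_ids, "true_label": labels[truth]}
    )
    return truth_frame, tables


def complementary_scenario(
    config: SimulationConfig,
    expert_assignment: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, list[PredictionTable]]:
    """Disjoint-expertise variant: classifier n is skilled only on its classes.

    Classes are partitioned round-robin among the N classifiers (or by the
    explicit ``expert_assignment``, class -> classifier, which must use
    every classifier).  On its own classes a classifier is correct with its
    configured skill and emits a peaked vector; elsewhere it predicts
    uniformly at random (chance accuracy 1/K) with a nearly flat vector.
    """
    n_clf = config.n_classifiers
    k = config.n_classes
    if k < n_clf:
        raise ValueError(
            f"{k} classes cannot give {n_clf} classifiers disjoint expertise"
        )
    if expert_assignment is None:
        assignment = np.arange(k) % n_clf
    else:
        assignment = np.asarray(list(expert_assignment), dtype=int)
        if assignment.shape != (k,) or np.any(assignment < 0) or np.any(
            assignment >= n_clf
        ):
            raise ValueError(
                f"expert_assignment must map each of {k} classes to a "
                f"classifier index < {n_clf}"
            )
        if len(set(assignment.tolist())) != n_clf:
            raise ValueError(
                "degenerate expertise: every classifier needs at least one "
                f"expert class, got assignment {assignment.tolist()!r}"
            )

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    truth = rng.integers(k, size=n)
    sample_ids = [f"s{idx:06d}" for idx in range(n)]
    labels = np.asarray(config.class_labels, dtype=object)

    tables = []
    for c, skill in enumerate(config.skills):
        expert_here = assignment[truth] == c
        u = rng.random(n)
        correct = expert_here & (u < skill)
        pred = np.where(correct, truth, _wrong_class(rng, truth, k))
        # non-experts guess uniformly over all classes
        guess = rng.integers(k, size=n)
        pred = np.where(expert_here, pred, guess)
        conc = np.where(expert_here, config.concentration, WEAK_CONCENTRATION)
        alpha = np.ones((n, k))
        alpha[np.arange(n), pred] = conc
        g = rng.gamma(shape=alpha)
        probs = g / g.sum(axis=1, keepdims=True)
        amax = np.argmax(probs, axis=1)
        stray = amax != pred
        rows = np.flatnonzero(stray)
        pv = probs[rows, pred[rows]].copy()
        probs[rows, pred[rows]] = probs[rows, amax[rows]]
        probs[rows, amax[rows]] = pv
        tables.append(
            PredictionTable(
                sample_ids=sample_ids,
                class_labels=list(labels),
                probabilities=probs,
                true_labels=list(labels[truth]),
            )
        )
    truth_frame = pd.DataFrame(
        {"sample_id": sample_ids, "true_label": labels[truth]}
    )
    return truth_frame, tables
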