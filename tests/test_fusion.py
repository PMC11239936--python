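"""Sugeno integral and fusion: oracle equivalence, invariants, estimator API."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from neurofuse.fusion import (
    SugenoFusionClassifier,
    assign_densities,
    fuse_dataset,
    fuse_sample,
    sugeno_integral,
    sugeno_integral_batch,
)
from neurofuse.io import PredictionTable
from neurofuse.measure import SugenoLambdaMeasure

from conftest import random_densities


def brute_force_integral(f, m):
    """Independent oracle: max over all nonempty subsets A of
    min(min_{i in A} f_i, measure(A))."""
    n = len(f)
    best = 0.0
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            v = min(min(f[i] for i in subset), m.measure(subset))
            best = max(best, v)
    return best


def uniform_measure(n):
    return SugenoLambdaMeasure([1.0 / n] * n)


class TestSugenoIntegral:
    def test_idempotence_constant_vector(self, rng):
        m = SugenoLambdaMeasure(random_densities(rng, 3))
        assert sugeno_integral([0.7, 0.7, 0.7], m) == 0.7

    def test_uniform_density_hand_example(self):
        m = uniform_measure(3)
        assert m.lam == 0.0
        assert sugeno_integral([0.3, 0.6, 0.9], m) == pytest.approx(0.6, abs=1e-15)

    def test_uniform_density_single_confident_source(self):
        assert sugeno_integral([0.0, 0.0, 1.0], uniform_measure(3)) == pytest.approx(
            1 / 3, abs=1e-15
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(400):
            n = int(rng.integers(2, 5))
            m = SugenoLambdaMeasure(random_densities(rng, n))
            f = rng.random(n)
            assert sugeno_integral(f, m) == pytest.approx(
                brute_force_integral(f, m), abs=1e-12
            )

    def test_monotone_in_each_confidence(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 5))
            m = SugenoLambdaMeasure(random_densities(rng, n))
            f = rng.random(n)
            base = sugeno_integral(f, m)
            i = int(rng.integers(n))
            bumped = f.copy()
            bumped[i] = min(1.0, bumped[i] + rng.random() * (1 - bumped[i]))
            assert sugeno_integral(bumped, m) >= base - 1e-15

    def test_bounded_by_confidence_span(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            m = SugenoLambdaMeasure(random_densities(rng, n))
            f = rng.random(n)
            v = sugeno_integral(f, m)
            assert f.min() - 1e-15 <= v <= f.max() + 1e-15

    def test_tied_confidences_permutation_invariant(self, rng):
        m = SugenoLambdaMeasure(random_densities(rng, 3))
        f = np.array([0.4, 0.4, 0.8])
        ref = sugeno_integral(f, m)
        for perm in itertools.permutations(range(3)):
            g = np.asarray([f[i] for i in perm])
            dens_perm = SugenoLambdaMeasure(m.densities[list(perm)])
            assert sugeno_integral(g, dens_perm) == pytest.approx(ref, abs=1e-12)

    def test_uniform_closed_form(self, rng):
        """With g_i = 1/N the chain is (N-i)/N and the integral reduces to
        max_i min(f_(i), (N - i) / N) over 0-based sorted positions."""
        for n in range(2, 6):
            m = uniform_measure(n)
            for _ in range(50):
                f = rng.random(n)
                fs = np.sort(f)
                closed = max(
                    min(fs[i], (n - i) / n) for i in range(n)
                )
                assert sugeno_integral(f, m) == pytest.approx(closed, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected 3"):
            sugeno_integral([0.1, 0.2], uniform_measure(3))

    def test_batch_path_matches_scalar_path(self, rng):
        m = SugenoLambdaMeasure(random_densities(rng, 4))
        F = rng.random((200, 4))
        batch = sugeno_integral_batch(F, m)
        scalar = np.array([sugeno_integral(row, m) for row in F])
        np.testing.assert_allclose(batch, scalar, atol=1e-14)


class TestFuseSample:
    def test_unanimous_one_hot(self):
        m = uniform_measure(3)
        res = fuse_sample(np.tile([0.0, 1.0], (3, 1)), m, ["a", "b"])
        assert res.predicted_label == "b"
        assert res.fused_scores[1] == 1.0

    def test_uniform_rows_tie_break_first_label(self):
        m = uniform_measure(3)
        res = fuse_sample(np.full((3, 4), 0.25), m, list("abcd"))
        np.testing.assert_allclose(res.fused_scores, 0.25)
        assert res.predicted_label == "a"

    def test_hand_worked_two_class_example(self):
        m = uniform_measure(3)
        rows = np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]])
        res = fuse_sample(rows, m, [0, 1])
        assert res.fused_scores[0] == pytest.approx(0.6, abs=1e-15)
        assert res.fused_scores[1] == pytest.approx(0.4, abs=1e-15)
        assert res.predicted_label == 0
        assert len(res.per_class_detail) == 2

    def test_row_count_must_match_measure(self):
        with pytest.raises(ValueError, match="sources"):
            fuse_sample(np.full((2, 3), 1 / 3), uniform_measure(3))


def make_table(ids, labels, probs, truth=None):
    return PredictionTable(
        sample_ids=ids, class_labels=labels, probabilities=np.asarray(probs),
        true_labels=truth,
    )


class TestFuseDataset:
    def test_perfect_unanimous_tables(self):
        probs = np.eye(3)[[0, 1, 2, 0]]
        t = make_table(
            [f"s{i}" for i in range(4)], list("xyz"), probs,
            truth=["x", "y", "z", "x"],
        )
        fused = fuse_dataset([t, t, t], density_strategy="accuracy")
        assert list(fused["predicted_label"]) == ["x", "y", "z", "x"]
        assert (fused["predicted_label"] == fused["true_label"]).all()

    def test_consistent_with_fuse_sample(self):
        rows = np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]])
        tables = [
            make_table(["s0"], ["a", "b"], rows[i : i + 1]) for i in range(3)
        ]
        m = uniform_measure(3)
        fused = fuse_dataset(tables, m=m)
        assert fused.loc[0, "p_a"] == pytest.approx(0.6)
        assert fused.loc[0, "p_b"] == pytest.approx(0.4)
        assert fused.loc[0, "predicted_label"] == "a"

    def test_empty_table_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fuse_dataset([])

    def test_misaligned_sample_ids_rejected(self):
        a = make_table(["s0", "s1"], ["x", "y"], np.full((2, 2), 0.5))
        b = make_table(["s0", "s2"], ["x", "y"], np.full((2, 2), 0.5))
        with pytest.raises(ValueError, match="s1"):
            fuse_dataset([a, b], density_strategy="uniform")

    def test_mismatched_class_labels_rejected(self):
        a = make_table(["s0"], ["x", "y"], [[0.5, 0.5]])
        b = make_table(["s0"], ["x", "z"], [[0.5, 0.5]])
        with pytest.raises(ValueError, match="class labels"):
            fuse_dataset([a, b], density_strategy="uniform")


class TestAssignDensities:
    def test_uniform(self):
        np.testing.assert_allclose(
            assign_densities("uniform", n_sources=3), [1 / 3] * 3
        )

    def test_accuracy_passthrough(self):
        g = assign_densities("accuracy", accuracies=[0.9537, 0.9673, 0.9478])
        np.testing.assert_allclose(g, [0.9537, 0.9673, 0.9478])

    def test_perfect_accuracy_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            g = assign_densities("accuracy", accuracies=[1.0, 0.9])
        assert g[0] == pytest.approx(1.0 - 1e-6)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_densities("accuracy")
        with pytest.raises(ValueError):
            assign_densities("user")
        with pytest.raises(ValueError):
            assign_densities("nope")


class TestEstimator:
    def make_X_y(self, rng, n=300):
        from neurofuse.synthetic import SimulationConfig, simulate

        cfg = SimulationConfig(n_samples=n, seed=11)
        truth, tables = simulate(cfg)
        X = np.stack([t.probabilities for t in tables], axis=1)
        y = truth["true_label"].to_numpy()
        return X, y

    def test_fit_sets_trailing_underscore_attributes(self, rng):
        X, y = self.make_X_y(rng)
        clf = SugenoFusionClassifier().fit(X, y)
        assert clf.densities_.shape == (3,)
        assert -1.0 < clf.lambda_ < 0.0  # skilled classifiers: sum g > 1
        assert clf.measure_ is not None
        assert len(clf.classes_) == 4

    def test_accuracy_strategy_requires_y(self, rng):
        X, _ = self.make_X_y(rng)
        with pytest.raises(ValueError, match="requires y"):
            SugenoFusionClassifier().fit(X)

    def test_predict_beats_chance_and_matches_proba_argmax(self, rng):
        X, y = self.make_X_y(rng)
        clf = SugenoFusionClassifier().fit(X, y)
        pred = clf.predict(X)
        proba = clf.predict_proba(X)
        assert (pred == clf.classes_[np.argmax(proba, axis=1)]).all()
        assert np.mean(pred == y) > 0.8

    def test_get_set_params_and_clone(self):
        clf = SugenoFusionClassifier(density_strategy="uniform", renormalize=True)
        params = clf.get_params()
        assert params["density_strategy"] == "uniform"
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_user_densities_and_renormalize(self, rng):
        X, y = self.make_X_y(rng)
        clf = SugenoFusionClassifier(
            density_strategy="user", densities=[0.9537, 0.9673, 0.9478],
            renormalize=True,
        ).fit(X)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_wrong_classifier_count_at_predict(self, rng):
        X, y = self.make_X_y(rng)
        clf = SugenoFusionClassifier(density_strategy="uniform").fit(X)
        with pytest.raises(ValueError, match="classifiers"):
            clf.predict(X[:, :2, :])
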