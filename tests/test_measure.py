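"""Sugeno lambda-measure: root finding, subset evaluation, axioms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse.measure import (
    RESIDUAL_TOL,
    SugenoLambdaMeasure,
    solve_lambda,
    validate_densities,
)

from conftest import random_densities


def fold_union(gs, lam):
    """Independent left-fold of the disjoint-union rule over given values."""
    value = gs[0]
    for g in gs[1:]:
        value = value + g + lam * value * g
    return value


class TestSolveLambda:
    def test_additive_case_returns_zero(self):
        assert solve_lambda([0.2, 0.3, 0.5]) == 0.0

    def test_equal_halves_root(self):
        # (1 + lam/2)^3 = 1 + lam reduces to 0.125 lam^2 + 0.75 lam + 0.5 = 0
        expected = (-0.75 + np.sqrt(0.75**2 - 4 * 0.125 * 0.5)) / (2 * 0.125)
        lam = solve_lambda([0.5, 0.5, 0.5])
        assert lam == pytest.approx(expected, abs=1e-10)
        assert lam == pytest.approx(-0.7639320, abs=1e-6)

    def test_single_source_has_no_root(self):
        with pytest.raises(ValueError, match="single information source"):
            solve_lambda([0.9])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.0], [-0.1, 0.5], [1.5]])
    def test_boundary_densities_rejected(self, bad):
        with pytest.raises(ValueError, match="strictly in"):
            solve_lambda(bad)

    def test_sign_rule_and_residual(self, rng):
        """lambda is negative when densities over-fill the unit mass and
        positive when they under-fill it; residual stays below 1e-10."""
        for _ in range(300):
            n = rng.integers(2, 7)
            g = random_densities(rng, n)
            total = g.sum()
            if abs(total - 1.0) <= 1e-9:
                continue
            lam = solve_lambda(g)
            assert np.sign(lam) == np.sign(1.0 - total)
            assert lam > -1.0
            residual = abs(np.prod(1.0 + lam * g) - 1.0 - lam)
            assert residual < RESIDUAL_TOL

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_equation_holds(self, gs):
        lam = solve_lambda(gs)
        assert abs(np.prod([1.0 + lam * g for g in gs]) - 1.0 - lam) < RESIDUAL_TOL


class TestMeasure:
    def test_empty_set_is_zero(self):
        m = SugenoLambdaMeasure([0.5, 0.5, 0.5])
        assert m.measure(set()) == 0.0

    def test_singletons_return_densities(self):
        m = SugenoLambdaMeasure([0.2, 0.6, 0.7])
        for i, g in enumerate([0.2, 0.6, 0.7]):
            assert m.measure({i}) == pytest.approx(g, abs=1e-15)

    def test_pair_value_equal_halves(self):
        m = SugenoLambdaMeasure([0.5, 0.5, 0.5])
        expected = 0.5 + 0.5 + m.lam * 0.25
        assert m.measure({0, 1}) == pytest.approx(expected, abs=1e-12)
        assert m.measure({0, 1}) == pytest.approx(0.8090170, abs=1e-6)

    def test_boundary_axioms_random(self, rng):
        """Empty set -> 0 and full set -> 1 (within 1e-9) across sizes."""
        for _ in range(1000):
            n = int(rng.integers(2, 7))
            m = SugenoLambdaMeasure(random_densities(rng, n))
            assert m.measure([]) == 0.0
            assert abs(m.measure(range(n)) - 1.0) < 1e-9

    def test_monotone_under_inclusion(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            m = SugenoLambdaMeasure(random_densities(rng, n))
            subsets = list(
                itertools.chain.from_iterable(
                    itertools.combinations(range(n), r) for r in range(n + 1)
                )
            )
            values = {s: m.measure(s) for s in subsets}
            for a in subsets:
                for b in subsets:
                    if set(a) <= set(b):
                        assert values[a] <= values[b] + 1e-12

    def test_fold_order_independent(self, rng):
        """All element orderings of a subset fold to the same value."""
        for n in range(2, 6):
            g = random_densities(rng, n)
            m = SugenoLambdaMeasure(g)
            for r in range(2, n + 1):
                for subset in itertools.combinations(range(n), r):
                    ref = m.measure(subset)
                    for perm in itertools.permutations(subset):
                        v = fold_union([g[i] for i in perm], m.lam)
                        assert v == pytest.approx(ref, abs=1e-12)

    def test_additive_limit_is_exact_sum(self):
        g = [0.1, 0.2, 0.3, 0.4]
        m = SugenoLambdaMeasure(g)
        assert m.lam == 0.0
        for r in range(1, 5):
            for subset in itertools.combinations(range(4), r):
                assert m.measure(subset) == pytest.approx(
                    sum(g[i] for i in subset), abs=1e-15
                )

    def test_out_of_range_index_rejected(self):
        m = SugenoLambdaMeasure([0.5, 0.5])
        with pytest.raises(IndexError):
            m.measure({0, 2})

    def test_supplied_lambda_checked_against_residual(self):
        with pytest.raises(ValueError, match="residual"):
            SugenoLambdaMeasure([0.5, 0.5, 0.5], lam=-0.5)

    def test_single_source_full_set_is_one(self):
        m = SugenoLambdaMeasure([0.9])
        assert m.measure({0}) == 1.0
        assert m.measure([]) == 0.0


class TestNestedChain:
    def test_additive_uniform_chain(self):
        m = SugenoLambdaMeasure([1 / 3] * 3)
        chain = m.nested_chain_measures()
        assert chain == pytest.approx([1.0, 2 / 3, 1 / 3], abs=1e-12)

    def test_equal_halves_chain(self):
        chain = SugenoLambdaMeasure([0.5, 0.5, 0.5]).nested_chain_measures()
        assert chain[0] == pytest.approx(1.0, abs=1e-9)
        assert chain[1] == pytest.approx(0.8090170, abs=1e-6)
        assert chain[2] == 0.5

    def test_single_source_chain(self):
        assert SugenoLambdaMeasure([0.7]).nested_chain_measures().tolist() == [1.0]

    def test_chain_matches_suffix_measures_and_decreases(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 6))
            m = SugenoLambdaMeasure(random_densities(rng, n))
            order = rng.permutation(n)
            chain = m.nested_chain_measures(order)
            assert np.all(np.diff(chain) <= 1e-12)
            for i in range(n):
                assert chain[i] == pytest.approx(
                    m.measure(order[i:]), abs=1e-9
                )

    def test_invalid_ordering_rejected(self):
        m = SugenoLambdaMeasure([0.5, 0.5])
        with pytest.raises(ValueError, match="permutation"):
            m.nested_chain_measures([0, 0])


def test_validate_densities_shapes():
    with pytest.raises(ValueError):
        validate_densities([])
    with pytest.raises(ValueError):
        validate_densities([np.nan, 0.5])
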