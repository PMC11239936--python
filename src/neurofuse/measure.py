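"""Sugeno :math:`\\lambda`-fuzzy measures over a finite set of information sources.

A fuzzy measure on sources :math:`X = \\{x_1, \\dots, x_N\\}` is a set function
:math:`g : 2^X \\to [0, 1]` with :math:`g(\\emptyset) = 0`, :math:`g(X) = 1`
and monotone under inclusion.  The Sugeno :math:`\\lambda`-measure is the
one-parameter family fixed by the singleton values ("fuzzy densities")
:math:`g_i = g(\\{x_i\\})` together with the union rule for disjoint sets

.. math:: g(A \\cup B) = g(A) + g(B) + \\lambda\\, g(A)\\, g(B),

where :math:`\\lambda \\in (-1, \\infty)` is the unique solution of the
normalization equation

.. math:: \\lambda + 1 = \\prod_{i=1}^{N} (1 + \\lambda g_i)

other than the trivial root :math:`\\lambda = 0`.  When the densities sum to
exactly 1 the measure is additive and :math:`\\lambda = 0`.  In a classifier
ensemble each source is one base classifier and its density encodes the
standalone worth of that classifier (e.g. its validation accuracy).

This module solves the normalization equation and evaluates the measure on
arbitrary subsets; :mod:`neurofuse.fusion` consumes it for the max--min
fuzzy integral.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

#: |sum(g) - 1| below this is treated as the additive case, lambda = 0.
SUM_ONE_TOL = 1e-9

#: Required residual of the normalization equation at the accepted root.
RESIDUAL_TOL = 1e-10

__all__ = [
    "SUM_ONE_TOL",
    "RESIDUAL_TOL",
    "LambdaConvergenceError",
    "validate_densities",
    "solve_lambda",
    "SugenoLambdaMeasure",
]


class LambdaConvergenceError(RuntimeError):
    """Raised when the normalization equation cannot be solved to tolerance."""


def validate_densities(densities: Iterable[float]) -> np.ndarray:
    """Validate a density vector: finite, strictly inside (0, 1), N >= 1.

    Boundary densities are rejected: g_i = 0 makes a source vacuous and
    g_i = 1 degenerates the normalization equation.
    """
    g = np.asarray(list(densities), dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("densities must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(g)):
        raise ValueError(f"densities must be finite, got {g!r}")
    if np.any(g <= 0.0) or np.any(g >= 1.0):
        raise ValueError(
            f"every density must lie strictly in (0, 1); got {g.tolist()!r}"
        )
    return g


def _deflated_poly(g: np.ndarray) -> np.ndarray:
    """Coefficients (ascending) of q with h(lam) = lam * q(lam).

    h(lam) = prod(1 + lam g_i) - 1 - lam is a polynomial whose constant term
    vanishes, so the trivial root at 0 divides out exactly.  The remaining
    coefficients are the elementary symmetric polynomials e_k(g):
    q(lam) = (e_1 - 1) + e_2 lam + ... + e_N lam^(N-1).
    """
    coeffs = np.array([1.0])
    for gi in g:
        coeffs = np.convolve(coeffs, np.array([1.0, gi]))
    q = coeffs[1:].copy()  # drop e_0; q[k] multiplies lam^k
    q[0] -= 1.0
    return q


def solve_lambda(densities: Iterable[float], tolerance: float = SUM_ONE_TOL) -> float:
    """Solve the normalization equation for the measure parameter lambda.

    Parameters
    ----------
    densities : sequence of float
        Fuzzy densities g_i, each strictly in (0, 1).
    tolerance : float
        If ``|sum(g) - 1| <= tolerance`` the measure is additive and 0.0 is
        returned without root finding.

    Returns
    -------
    float
        The unique root in (-1, 0) when ``sum(g) > 1``, in (0, inf) when
        ``sum(g) < 1``, or exactly 0.0 in the additive case.  The residual
        ``|prod(1 + lam*g) - 1 - lam|`` of the returned value is below 1e-10.

    Raises
    ------
    ValueError
        Invalid densities, non-positive tolerance, or a single source
        (N = 1 admits no nonzero root; fusion must bypass lambda).
    LambdaConvergenceError
        Root finding failed to reach the residual tolerance.
    """
    g = validate_densities(densities)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    total = float(g.sum())
    if abs(total - 1.0) <= tolerance:
        return 0.0
    if g.size == 1:
        raise ValueError(
            "a single information source admits no valid lambda "
            f"(density {g[0]!r}); fuse without a measure"
        )

    q = _deflated_poly(g)

    def qfun(lam: float) -> float:
        return float(np.polynomial.polynomial.polyval(lam, q))

    try:
        if total > 1.0:
            # q(-1) = -prod(1 - g_i) < 0, q(0) = sum(g) - 1 > 0
            lam = brentq(qfun, -1.0, 0.0, xtol=1e-12, maxiter=200)
        else:
            lo, hi = 0.0, 1.0
            for _ in range(200):
                if qfun(hi) > 0.0:
                    break
                hi *= 2.0
            else:
                raise LambdaConvergenceError(
                    f"no sign change found for densities {g.tolist()!r}"
                )
            lam = brentq(qfun, lo, hi, xtol=1e-12, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # brentq failures
        raise LambdaConvergenceError(
            f"lambda root finding failed for densities {g.tolist()!r}: {exc}"
        ) from exc

    residual = abs(float(np.prod(1.0 + lam * g)) - 1.0 - lam)
    if residual >= RESIDUAL_TOL:
        raise LambdaConvergenceError(
            f"residual {residual:.3e} exceeds {RESIDUAL_TOL:.0e} "
            f"for densities {g.tolist()!r}"
        )
    return float(lam)


class SugenoLambdaMeasure:
    """A Sugeno lambda-fuzzy measure fixed by per-source densities.

    Parameters
    ----------
    densities : sequence of float
        One density per information source, each strictly in (0, 1).
    lam : float, optional
        Pre-solved measure parameter; solved from the densities when omitted.
        A supplied value is checked against the normalization residual.
    tolerance : float
        Additive-case detection tolerance passed to :func:`solve_lambda`.

    Notes
    -----
    Sources are indexed 0..N-1.  Subset values are computed by left-folding
    the disjoint-union rule in ascending index order; the result is
    independent of fold order (the rule is associative and commutative for
    a fixed lambda), which the test suite verifies exhaustively.

    For a single source the normalization axiom overrides the singleton
    density: the full (= singleton) set has measure 1 and lambda is fixed
    at 0.
    """

    def __init__(
        self,
        densities: Iterable[float],
        lam: float | None = None,
        tolerance: float = SUM_ONE_TOL,
    ) -> None:
        self.densities = validate_densities(densities)
        if self.densities.size == 1:
            self.lam = 0.0
        elif lam is None:
            self.lam = solve_lambda(self.densities, tolerance=tolerance)
        else:
            lam = float(lam)
            if lam <= -1.0:
                raise ValueError(f"lambda must exceed -1, got {lam}")
            residual = abs(float(np.prod(1.0 + lam * self.densities)) - 1.0 - lam)
            if residual >= RESIDUAL_TOL:
                raise ValueError(
                    f"supplied lambda {lam!r} has normalization residual "
                    f"{residual:.3e} >= {RESIDUAL_TOL:.0e}"
                )
            self.lam = lam

    @property
    def n_sources(self) -> int:
        return int(self.densities.size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SugenoLambdaMeasure(densities={self.densities.tolist()}, "
            f"lam={self.lam:.6g})"
        )

    def measure(self, subset: Iterable[int]) -> float:
        """Measure of a subset of source indices (0-based).

        The empty set maps to 0, singletons to their density, the full set
        to 1 (within 1e-9); intermediate subsets fold the union rule.
        """
        indices = sorted(set(int(i) for i in subset))
        if any(i < 0 or i >= self.n_sources for i in indices):
            raise IndexError(
                f"subset {indices!r} out of range for {self.n_sources} sources"
            )
        if not indices:
            return 0.0
        if self.n_sources == 1:
            return 1.0
        value = float(self.densities[indices[0]])
        for i in indices[1:]:
            gi = float(self.densities[i])
            value = value + gi + self.lam * value * gi
        return float(min(max(value, 0.0), 1.0))

    def nested_chain_measures(
        self, ordering: Sequence[int] | None = None
    ) -> np.ndarray:
        """Measures of the nested suffix sets of an ordering of all sources.

        Element ``i`` is the measure of the sources at positions ``i..N-1``
        of ``ordering`` (default: ascending index order).  The sequence is
        non-increasing and starts at 1.
        """
        n = self.n_sources
        if ordering is None:
            order = np.arange(n)
        else:
            order = np.asarray(list(ordering), dtype=int)
            if sorted(order.tolist()) != list(range(n)):
                raise ValueError(
                    f"ordering {order.tolist()!r} is not a permutation of 0..{n - 1}"
                )
        if n == 1:
            return np.array([1.0])
        out = np.empty(n)
        value = float(self.densities[order[-1]])
        out[n - 1] = value
        for pos in range(n - 2, -1, -1):
            gi = float(self.densities[order[pos]])
            value = value + gi + self.lam * value * gi
            out[pos] = value
        return np.clip(out, 0.0, 1.0)
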