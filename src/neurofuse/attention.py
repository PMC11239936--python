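"""Array-level squeeze-and-excitation operators, global average pooling, GELU.

The squeeze-and-excitation (SE) channel-attention block acts on a C x H x W
feature map in three steps: *squeeze* reduces each channel to its spatial
mean (identical to global average pooling), *excitation* passes the C-vector
through a bottleneck of two linear maps — a rectifier inside, a logistic
sigmoid outside — producing per-channel gates in (0, 1), and *scale*
multiplies each channel by its gate.  GELU is the Gaussian error linear
unit x * Phi(x) with Phi the standard normal CDF, implemented exactly via
the error function rather than the tanh approximation.

These are pure-numpy reference implementations for verification and
parameter accounting; no training or backpropagation is involved.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

__all__ = ["squeeze", "excitation", "scale", "gelu", "make_excitation_weights"]


def _check_feature_map(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError(f"feature map must be C x H x W, got shape {fm.shape}")
    if min(fm.shape) < 1:
        raise ValueError(f"all feature-map dimensions must be >= 1: {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite entries")
    return fm


def squeeze(fm: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean z_c of a C x H x W map (global average pool)."""
    fm = _check_feature_map(fm)
    return fm.mean(axis=(1, 2))


def excitation(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Two-layer channel gate: logistic(W2 @ relu(W1 @ z)), outputs in (0, 1).

    ``w1`` has shape (C/r, C) and ``w2`` shape (C, C/r) for reduction
    ratio r.
    """
    z = np.asarray(z, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if z.ndim != 1:
        raise ValueError(f"z must be 1-D, got shape {z.shape}")
    c = z.size
    if w1.ndim != 2 or w1.shape[1] != c:
        raise ValueError(f"W1 shape {w1.shape} incompatible with C={c}")
    if w2.ndim != 2 or w2.shape != (c, w1.shape[0]):
        raise ValueError(
            f"W2 shape {w2.shape} incompatible with W1 {w1.shape} and C={c}"
        )
    return expit(w2 @ np.maximum(w1 @ z, 0.0))


def scale(fm: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Multiply channel c of a C x H x W map by gate s_c."""
    fm = _check_feature_map(fm)
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.size != fm.shape[0]:
        raise ValueError(
            f"gate vector length {s.size} != channel count {fm.shape[0]}"
        )
    return fm * s[:, None, None]


def gelu(x):
    """Gaussian error linear unit, exact form x * Phi(x), elementwise."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("gelu input must be finite")
    out = x * ndtr(x)
    return out if out.ndim else float(out)


def make_excitation_weights(
    c: int, r: int = 16, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random bottleneck weights (W1, W2) for C channels and reduction r.

    r must divide C; default r=16 is the standard SE configuration.
    """
    if c < 1 or r < 1 or c % r:
        raise ValueError(f"reduction ratio r={r} must divide C={c}")
    rng = rng or np.random.default_rng()
    hidden = c // r
    return rng.standard_normal((hidden, c)), rng.standard_normal((c, hidden))
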