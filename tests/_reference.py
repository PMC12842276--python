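"""Independent reference implementations used as test oracles.

Deliberately simple, written against the method definitions only, and
sharing no code with the package: naive neighbour-comparison extrema,
linear-interpolation envelopes with edge padding, and a fixed-iteration
sifting loop. Numerical agreement between these and the package is
evidence both follow the same construction, not a tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_extrema(x) -> tuple[list[int], list[int]]:
    """Interior extrema by exhaustive neighbour comparison (no plateaus)."""
    x = np.asarray(x, dtype=float)
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            maxima.append(i)
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            minima.append(i)
    return maxima, minima


def _linear_envelope(idx, val, n):
    # pad with the end samples so np.interp covers [0, n-1]
    t = np.arange(n)
    return np.interp(t, idx, val)


def reference_sift_c1(x, n_iters: int = 12) -> np.ndarray:
    """First IMF via fixed-count sifting with linear envelopes.

    A different extrema rule (strict neighbour comparison), a different
    interpolant (piecewise linear, edge-padded) and a different stopping
    rule (fixed iteration count) from the implementation under test.
    """
    h = np.asarray(x, dtype=float).copy()
    for _ in range(n_iters):
        maxima, minima = brute_force_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            break
        upper = _linear_envelope(maxima, h[maxima], len(h))
        lower = _linear_envelope(minima, h[minima], len(h))
        h = h - 0.5 * (upper + lower)
    return h


def brute_force_confusion(y_true, y_pred, k: int) -> np.ndarray:
    """Pairwise tally by explicit double loop over classes."""
    out = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[t, p] += 1
    return out


def hand_cross_entropy(y_true, probs) -> float:
    """Per-sample -log p(true), summed by explicit loop, then averaged."""
    total = 0.0
    for i, t in enumerate(y_true):
        total += -np.log(max(min(probs[i][t], 1.0), 1e-12))
    return total / len(y_true)
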