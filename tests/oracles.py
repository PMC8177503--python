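"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the L0 oracle
enumerates every changepoint subset and scores it by bound-constrained
least squares; the trailing-percentile oracle recomputes each window from
scratch; the van Rossum oracle integrates the kernel-difference squared
numerically.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.optimize import nnls


def l0_subset_rss(y: np.ndarray, gamma: float, subset) -> float:
    """RSS of the best feasible calcium path with jumps exactly at ``subset``.

    The path is c_t = gamma^t * c1 + sum_{s in subset, s <= t} gamma^(t-s) z_s
    with c1 free and all z_s >= 0 (upward jumps).  Profiling out c1 turns
    the problem into non-negative least squares.
    """
    T = len(y)
    a0 = gamma ** np.arange(T, dtype=float)
    if len(subset) == 0:
        c1 = (a0 @ y) / (a0 @ a0)
        r = y - a0 * c1
        return float(r @ r)
    cols = []
    for s in subset:
        col = np.zeros(T)
        col[s:] = gamma ** np.arange(T - s)
        cols.append(col)
    Az = np.column_stack(cols)
    P = np.eye(T) - np.outer(a0, a0) / (a0 @ a0)
    z, _ = nnls(P @ Az, P @ y)
    c1 = (a0 @ (y - Az @ z)) / (a0 @ a0)
    r = y - a0 * c1 - Az @ z
    return float(r @ r)


def l0_enumerate(y: np.ndarray, gamma: float, lam: float):
    """Global optimum by exhaustive enumeration (lengths up to ~14)."""
    T = len(y)
    best_obj, best_set = np.inf, ()
    for k in range(T):
        for subset in itertools.combinations(range(1, T), k):
            obj = 0.5 * l0_subset_rss(y, gamma, subset) + lam * k
            if obj < best_obj:
                best_obj, best_set = obj, subset
    return best_obj, best_set


def trailing_percentile(values: np.ndarray, window: int, pct: float) -> np.ndarray:
    """Per-index trailing-window percentile, recomputed from scratch."""
    out = np.empty(len(values))
    for t in range(len(values)):
        lo = max(0, t - window + 1)
        out[t] = np.percentile(values[lo : t + 1], pct)
    return out


def van_rossum_quadrature(u: np.ndarray, v: np.ndarray, tau: float) -> float:
    """van Rossum distance by adaptive quadrature of the defining integral."""

    def f(t, train):
        dt = t - train
        return np.sum(np.exp(-dt[dt >= 0] / tau))

    def integrand(t):
        return (f(t, u) - f(t, v)) ** 2

    t_max = max(u.max() if len(u) else 0.0, v.max() if len(v) else 0.0) + 60 * tau
    pts = np.unique(np.concatenate([u, v]))
    total = 0.0
    lo = 0.0
    for p in list(pts) + [t_max]:
        if p > lo:
            val, _ = quad(integrand, lo, p, limit=400)
            total += val
            lo = p
    return float(np.sqrt(total / tau))
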