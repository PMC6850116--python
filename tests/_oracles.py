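"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: confidence bounds come
from bisection on binomial tail probabilities (not beta quantiles), the
least-squares fit from explicit normal equations, and distances from an
explicit per-pair loop.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import binom


def cp_bounds_bisect(k, n: int, alpha: float = 0.05, iters: int = 60):
    """Clopper-Pearson bounds by bisection on the binomial tail conditions.

    lower solves P(X >= k | p) = alpha/2 (increasing in p), upper solves
    P(X <= k | p) = alpha/2 (decreasing in p).  Vectorised over ``k``.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    half = alpha / 2.0

    lo, hi = np.zeros_like(k), np.ones_like(k)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = binom.sf(k - 1, n, mid) < half  # tail too small -> root above
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    lower = np.where(k == 0, 0.0, 0.5 * (lo + hi))

    lo, hi = np.zeros_like(k), np.ones_like(k)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        above = binom.cdf(k, n, mid) > half  # tail too big -> root above
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    upper = np.where(k == n, 1.0, 0.5 * (lo + hi))
    return lower, upper


def ols_r_squared(x, y):
    """R^2, slope and intercept from the explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot, float(beta[1]), float(beta[0])


def pairwise_sqrt_euclidean(values):
    """Per-pair recomputation of sqrt-transform Euclidean distances."""
    v = np.sqrt(np.asarray(values, dtype=float))
    n = v.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((v[i] - v[j]) ** 2).sum())
    return out
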