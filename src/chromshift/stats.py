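"""Shared statistical primitives: BH adjustment, vectorized Fisher exact
tests, and the scaled inverse-chi-square moment fit used for variance
shrinkage."""

from __future__ import annotations

import numpy as np
from scipy import special, stats


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    out = np.full(n, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def fisher_exact_two_sided(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                           d: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for tables [[a, b], [c, d]].

    Uses the point-probability rule: p = sum of hypergeometric outcomes
    whose probability does not exceed that of the observed table (with a
    1 + 1e-7 relative guard, as in common implementations).
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    n = a + b + c + d
    r1 = a + b          # first row margin
    k = a + c           # first column margin
    lo = np.maximum(0, k - (n - r1))
    hi = np.minimum(k, r1)
    width = int(np.max(hi - lo)) + 1 if a.size else 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    xx = np.where(valid, x, lo[:, None])
    logpmf = (
        _lchoose(r1[:, None], xx)
        + _lchoose((n - r1)[:, None], k[:, None] - xx)
        - _lchoose(n[:, None], k[:, None])
    )
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    obs = np.exp(
        _lchoose(r1, a) + _lchoose(n - r1, c) - _lchoose(n, k)
    )
    p = np.sum(np.where(pmf <= obs[:, None] * (1 + 1e-7), pmf, 0.0), axis=1)
    return np.minimum(p, 1.0)


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def odds_ratio(a, b, c, d, haldane: bool = False) -> float:
    """Sample odds ratio (a*d)/(b*c); Haldane-Anscombe 0.5 correction on
    request when any cell is zero."""
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma, as in the
    standard moment-matching fit for the inverse-chi-square prior)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def sign_test_p(n_pos: int, n_neg: int) -> float:
    """Two-sided exact sign test (ties excluded by the caller)."""
    n = n_pos + n_neg
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_pos, n, 0.5).pvalue)
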