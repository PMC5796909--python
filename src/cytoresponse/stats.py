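"""Shared elementary statistics: BH adjustment, rank-sum tests, 2x2 tables.

These primitives back every enrichment and comparison stage, so their
conventions are fixed here once: strict one-sided enrichment tails are upper
hypergeometric tails, two-sided Fisher tests use the minimum-likelihood
convention, and the Wilcoxon rank-sum test switches to exact enumeration for
small groups (midranks for ties) and otherwise uses the normal approximation
with tie and continuity corrections.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "rank_sum_test",
    "fisher_exact_2x2",
    "hypergeom_tail",
    "odds_ratio",
]


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    p : array-like
        Raw p-values, each in (0, 1].

    Returns
    -------
    ndarray
        q-values in the input order: q_(i) = min_{j>=i} m * p_(j) / j, capped
        at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _midranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _rank_sum_exact(ranks, n_x, w_obs, alternative):
    """Exact rank-sum p by enumerating all assignments of n_x midranks."""
    n = ranks.size
    count_ge = 0
    count_le = 0
    total = 0
    for idx in combinations(range(n), n_x):
        w = sum(ranks[i] for i in idx)
        total += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
        if w <= w_obs + 1e-9:
            count_le += 1
    p_greater = count_ge / total
    p_less = count_le / total
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def rank_sum_test(x, y, alternative="two-sided", exact_max=10):
    """Wilcoxon (Mann-Whitney) rank-sum test comparing two samples.

    Uses exact enumeration over all rank assignments when
    ``min(len(x), len(y)) <= exact_max`` (handles ties via midranks),
    otherwise a normal approximation with tie and continuity corrections.

    Returns
    -------
    (W, p) : rank sum of ``x`` (midranks) and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[: x.size].sum())
    n1, n2 = x.size, y.size
    n = n1 + n2
    if min(n1, n2) <= exact_max:
        p = _rank_sum_exact(ranks, n1, w, alternative)
        return w, p
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    sd = np.sqrt(var_w)
    z_greater = (w - mean_w - 0.5) / sd
    z_less = (w - mean_w + 0.5) / sd
    p_greater = sps.norm.sf(z_greater)
    p_less = sps.norm.cdf(z_less)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return w, float(p)


def hypergeom_tail(overlap, universe, n_set, n_draw):
    """Upper hypergeometric tail P(X >= overlap).

    ``universe`` items, ``n_set`` marked, ``n_draw`` drawn without
    replacement.
    """
    if overlap < 0 or n_set > universe or n_draw > universe:
        raise ValueError("inconsistent hypergeometric parameters")
    return float(sps.hypergeom.sf(overlap - 1, universe, n_set, n_draw))


def fisher_exact_2x2(table, alternative="greater"):
    """Fisher's exact test on a 2x2 table.

    ``alternative='greater'`` tests over-representation of cell (0, 0); the
    two-sided p sums all tables with fixed margins whose probability does not
    exceed the observed one (minimum-likelihood convention).
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be a non-negative 2x2 array")
    _, p = sps.fisher_exact(table, alternative=alternative)
    return float(p)


def odds_ratio(table):
    """Sample odds ratio ad/bc of a 2x2 table; inf when bc == 0, 0/0 -> nan."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    num, den = a * d, b * c
    if den == 0:
        return np.nan if num == 0 else np.inf
    return float(num / den)
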