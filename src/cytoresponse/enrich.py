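"""Shared-signature construction and rank/set enrichment statistics.

The shared response signature is the intersection of same-direction DEG
calls across every cytokine x time condition. Rank-based overlap statistics
compare two ranked lists at increasing depth k with per-k Fisher tests and
a hypergeometric null band; set-based statistics are the upper
hypergeometric tail for over-representation and Wilcoxon rank-sum tests for
rank shifts of a gene set within a ranked signature or of fold changes
between binding-site strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, fisher_exact_2x2, hypergeom_tail, odds_ratio, \
    rank_sum_test


def shared_signature(deg_calls: dict, require_all=None):
    """Intersect per-condition DEG calls into shared up/down gene sets.

    ``deg_calls`` maps condition label -> DEG call table (gene_id index with
    a ``direction`` column). ``require_all`` lists the conditions that must
    all agree (default: every key). Returns ``(up_set, down_set)`` as sorted
    lists; the two are disjoint by construction.
    """
    conditions = list(require_all) if require_all is not None else list(deg_calls)
    missing = [c for c in conditions if c not in deg_calls]
    if missing:
        raise ValueError(f"missing condition call sets: {missing}")
    ups, downs = [], []
    for c in conditions:
        t = deg_calls[c]
        ups.append(set(t.index[t["direction"] == "up"]))
        downs.append(set(t.index[t["direction"] == "down"]))
    up = set.intersection(*ups) if ups else set()
    down = set.intersection(*downs) if downs else set()
    return sorted(up), sorted(down)


@dataclass
class OverlapCurve:
    k: np.ndarray
    overlap: np.ndarray
    p: np.ndarray             # per-k one-sided Fisher exact
    expected: np.ndarray      # hypergeometric mean k^2/N
    null_upper: np.ndarray    # hypergeometric 95th percentile

    def to_frame(self):
        return pd.DataFrame({"k": self.k, "overlap": self.overlap, "p": self.p,
                             "expected": self.expected,
                             "null_upper95": self.null_upper})


def rank_overlap_curve(list_a, list_b, k_max=500, universe_size=None,
                       compute_p=True):
    """Overlap of the top-k prefixes of two ranked gene lists.

    ``list_a`` / ``list_b`` are gene ids in rank order over the same
    universe. For each k: overlap(k) = |top-k(A) & top-k(B)|, a one-sided
    Fisher exact p on the in/out-of-top-k 2x2 table, and the hypergeometric
    null mean k^2/N and 95th percentile. ``compute_p=False`` skips the per-k
    tests (overlap and expectation only) for large simulation studies.
    """
    a = list(list_a)
    b = list(list_b)
    for name, lst in (("a", a), ("b", b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicated gene in list {name}")
    n = universe_size if universe_size is not None else len(set(a) | set(b))
    k_max = min(k_max, len(a), len(b))
    if k_max > n:
        raise ValueError("k_max exceeds universe size")
    ks = np.arange(1, k_max + 1)
    overlap = np.zeros(k_max, dtype=int)
    seen_a, seen_b = set(), set()
    ov = 0
    for k in ks:
        ga, gb = a[k - 1], b[k - 1]
        seen_a.add(ga)
        seen_b.add(gb)
        ov += int(ga in seen_b) + int(gb in seen_a) - int(ga == gb)
        overlap[k - 1] = ov
    expected = ks.astype(float) ** 2 / n
    if compute_p:
        p = np.empty(k_max)
        for i, k in enumerate(ks):
            x = overlap[i]
            table = [[x, k - x], [k - x, n - 2 * k + x]]
            p[i] = fisher_exact_2x2(table, alternative="greater")
        null_upper = sps.hypergeom.ppf(0.95, n, ks, ks)
    else:
        p = np.full(k_max, np.nan)
        null_upper = np.full(k_max, np.nan)
    return OverlapCurve(k=ks, overlap=overlap, p=p, expected=expected,
                        null_upper=null_upper)


def cumulative_overlap_gsea(signature: pd.DataFrame, gene_set,
                            alternative="two-sided"):
    """Cumulative overlap curve of a gene set along a ranked signature plus
    a Wilcoxon rank-sum p comparing member vs non-member ranks.

    ``signature`` is a ranked table (gene_id column, best rank first).
    Returns ``(curve DataFrame, p_two_sided, p_one_sided)`` where the
    one-sided test asks whether members rank higher (earlier) than
    non-members.
    """
    genes = signature["gene_id"].tolist()
    n = len(genes)
    members = set(gene_set)
    m = len(members & set(genes))
    if m == 0 or m >= n:
        raise ValueError("gene set must be a non-empty proper subset of the "
                         "signature universe")
    indicator = np.array([g in members for g in genes])
    curve = pd.DataFrame({"rank": np.arange(1, n + 1),
                          "cumulative_overlap": np.cumsum(indicator)})
    ranks = np.arange(1, n + 1, dtype=float)
    member_ranks = ranks[indicator]
    other_ranks = ranks[~indicator]
    _, p_two = rank_sum_test(member_ranks, other_ranks,
                             alternative="two-sided")
    _, p_one = rank_sum_test(member_ranks, other_ranks, alternative="less")
    return curve, float(p_two), float(p_one)


def hypergeometric_enrichment(deg_set, annotation_sets: dict, universe):
    """Over-representation of a DEG set in each annotation set.

    Every set is intersected with the universe first; p is the upper
    hypergeometric tail, the odds ratio comes from the realized 2x2 table,
    and q is BH across annotation sets. Returns a DataFrame sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_set) & universe
    rows = []
    for set_id, genes in annotation_sets.items():
        ann = set(genes) & universe
        overlap = len(deg & ann)
        n_uni = len(universe)
        p = hypergeom_tail(overlap, n_uni, len(ann), len(deg))
        table = [
            [overlap, len(deg) - overlap],
            [len(ann) - overlap, n_uni - len(deg) - len(ann) + overlap],
        ]
        rows.append({"set_id": set_id, "overlap": overlap,
                     "set_size": len(ann), "deg_size": len(deg),
                     "universe_size": n_uni,
                     "odds_ratio": odds_ratio(table), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def signature_score(profile: pd.DataFrame, gene_set, condition):
    """Mean log2 FC of the set genes present in the profile.

    Returns ``(score, n_missing)``; errors when no set gene is present.
    """
    present = [g for g in gene_set if g in profile.index]
    if not present:
        raise ValueError("no gene of the set is present in the profile")
    score = float(profile.loc[present, condition].mean())
    return score, len(set(gene_set)) - len(present)


def stratified_fc_test(profile: pd.DataFrame, site_counts: pd.Series,
                       condition, threshold=2):
    """Wilcoxon rank-sum comparison of log2 FCs between binding-site strata.

    Genes with ``site_counts >= threshold`` form the high stratum. Returns a
    dict with the two-sided p and each stratum's quartiles (the plotted
    middle-50% boxes) and size.
    """
    common = profile.index.intersection(site_counts.index)
    fc = profile.loc[common, condition].to_numpy(dtype=float)
    high = site_counts.loc[common].to_numpy() >= threshold
    if high.all() or not high.any():
        raise ValueError("both strata must be non-empty")
    _, p = rank_sum_test(fc[high], fc[~high], alternative="two-sided")
    q_hi = np.quantile(fc[high], [0.25, 0.5, 0.75])
    q_lo = np.quantile(fc[~high], [0.25, 0.5, 0.75])
    return {
        "p": float(p), "n_high": int(high.sum()), "n_low": int((~high).sum()),
        "high_quartiles": tuple(q_hi), "low_quartiles": tuple(q_lo),
    }
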