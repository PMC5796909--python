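"""PWM scanning of upstream regions and motif enrichment testing.

Motifs are position-probability matrices (PPMs). Scanning scores every
window of a promoter with the log-odds of the PPM (pseudocount 1e-3)
against the background composition and counts windows whose score reaches
``threshold_fraction`` of the attainable score range; both strands are
scanned by reverse complement, overlapping hits count individually, and
windows containing N never match. Enrichment of per-gene motif counts in
DEGs versus the remaining expressed genes is tested with a logistic
regression of DEG status on the count adjusted for promoter GC content via
a fixed cubic B-spline basis (df = 4), with a likelihood-ratio p-value for
the count coefficient and BH correction across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, hypergeom_tail

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PWM:
    """Position-probability matrix over A/C/G/T with uniform default
    background."""

    motif_id: str
    matrix: np.ndarray                      # (width, 4), columns A C G T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")

    @property
    def width(self):
        return self.matrix.shape[0]

    def log_odds(self):
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def consensus_indices(self):
        return self.matrix.argmax(axis=1)

    def consensus(self):
        return "".join(_BASES[i] for i in self.consensus_indices())

    def reverse_complement(self):
        return PWM(self.motif_id + "_rc", self.matrix[::-1, ::-1].copy(),
                   self.background.copy(), self.pseudocount)


def read_meme(path_or_handle):
    """Read motifs from a MEME (minimal) file into :class:`PWM` objects."""
    from Bio import motifs as bio_motifs

    close = False
    if isinstance(path_or_handle, (str, bytes)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        records = bio_motifs.parse(handle, "minimal")
        out = []
        for rec in records:
            mat = np.column_stack([rec.counts[b] for b in _BASES]).astype(float)
            mat = mat / mat.sum(axis=1, keepdims=True)
            out.append(PWM(rec.name or rec.base_id or f"motif{len(out)+1}", mat))
        return out
    finally:
        if close:
            handle.close()


def read_jaspar(path_or_handle):
    """Read JASPAR count matrices, row-normalized to probabilities."""
    from Bio import motifs as bio_motifs

    close = False
    if isinstance(path_or_handle, (str, bytes)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        out = []
        for rec in bio_motifs.parse(handle, "jaspar"):
            mat = np.column_stack([rec.counts[b] for b in _BASES]).astype(float)
            mat = mat / mat.sum(axis=1, keepdims=True)
            out.append(PWM(rec.matrix_id or rec.name, mat))
        return out
    finally:
        if close:
            handle.close()


def _encode(seq):
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.size, 4, dtype=np.int8)        # 4 = N / other
    for i, b in enumerate(_BASES):
        code[arr == ord(b)] = i
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        raise ValueError(
            f"invalid alphabet character {chr(arr[bad.argmax()])!r} in sequence"
        )
    return code


def _scan_one_strand(code, lo_matrix, threshold):
    w = lo_matrix.shape[0]
    L = code.size
    if L < w:
        return 0
    # score matrix with N column = -inf
    S = np.full((w, 5), -np.inf)
    S[:, :4] = lo_matrix
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    scores = S[np.arange(w)[None, :], windows].sum(axis=1)
    return int(np.sum(scores >= threshold - 1e-9))


def _scan_batch(codes, lo_matrix, threshold):
    """Hit counts for a (n_seq, L) matrix of equal-length encoded sequences.

    Window scores are built by per-base correlation of indicator tracks with
    the PWM columns; windows containing N are excluded.
    """
    from scipy.ndimage import correlate1d

    w = lo_matrix.shape[0]
    n, L = codes.shape
    if L < w:
        return np.zeros(n, dtype=int)
    scores = np.zeros((n, L), dtype=np.float64)
    for b in range(4):
        kernel = lo_matrix[:, b].astype(np.float64)
        scores += correlate1d((codes == b).astype(np.float64), kernel,
                              axis=1, mode="constant", cval=0.0,
                              origin=-(w // 2))
    has_n = correlate1d((codes == 4).astype(np.float64),
                        np.ones(w, dtype=np.float64), axis=1,
                        mode="constant", cval=0.0, origin=-(w // 2))
    valid = scores[:, : L - w + 1]
    nmask = has_n[:, : L - w + 1] > 0.5
    hits = (valid >= threshold - 1e-9) & ~nmask
    return hits.sum(axis=1).astype(int)


def scan_pwm(sequences, pwm: PWM, threshold_fraction=0.8, both_strands=True):
    """Count PWM hits per sequence.

    ``sequences`` maps gene id -> sequence (dict or Series). A window is a
    hit when its log-odds score reaches
    ``min + threshold_fraction * (max - min)`` of the attainable score
    range. The reverse strand is scanned via the reverse complement of the
    sequence; a palindromic instance therefore counts once per strand.
    Returns a Series of counts indexed by gene id.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    lo = pwm.log_odds()
    smax = lo.max(axis=1).sum()
    smin = lo.min(axis=1).sum()
    threshold = smin + threshold_fraction * (smax - smin)
    items = list(sequences.items() if hasattr(sequences, "items")
                 else sequences)
    codes = []
    for gene_id, seq in items:
        try:
            codes.append(_encode(seq))
        except ValueError as exc:
            raise ValueError(f"record {gene_id!r}: {exc}") from exc
    lengths = {c.size for c in codes}
    if len(lengths) == 1 and len(codes) > 1:
        mat = np.vstack(codes)
        n = _scan_batch(mat, lo, threshold)
        if both_strands:
            rc = (3 - mat)[:, ::-1]
            rc[mat[:, ::-1] == 4] = 4
            n = n + _scan_batch(rc, lo, threshold)
        counts = {gid: int(k) for (gid, _), k in zip(items, n)}
    else:
        counts = {}
        for (gene_id, _), code in zip(items, codes):
            k = _scan_one_strand(code, lo, threshold)
            if both_strands:
                rc = (3 - code)[::-1].copy()
                rc[code[::-1] == 4] = 4
                k += _scan_one_strand(rc, lo, threshold)
            counts[gene_id] = k
    return pd.Series(counts, name=pwm.motif_id)


def scan_motifs(sequences, pwms, threshold_fraction=0.8, both_strands=True):
    """Gene x motif hit-count matrix with scan metadata in ``attrs``.

    Sequences of one common length are encoded once and scanned as a batch.
    """
    items = list(sequences.items() if hasattr(sequences, "items")
                 else sequences)
    lengths = {len(s) for _, s in items}
    if len(lengths) == 1 and len(items) > 1:
        codes = []
        for gene_id, seq in items:
            try:
                codes.append(_encode(seq))
            except ValueError as exc:
                raise ValueError(f"record {gene_id!r}: {exc}") from exc
        mat = np.vstack(codes)
        rc = (3 - mat)[:, ::-1]
        rc[mat[:, ::-1] == 4] = 4
        index = [gid for gid, _ in items]
        cols = {}
        for p in pwms:
            lo = p.log_odds()
            smax, smin = lo.max(axis=1).sum(), lo.min(axis=1).sum()
            thr = smin + threshold_fraction * (smax - smin)
            n = _scan_batch(mat, lo, thr)
            if both_strands:
                n = n + _scan_batch(rc, lo, thr)
            cols[p.motif_id] = pd.Series(n, index=index)
    else:
        cols = {p.motif_id: scan_pwm(sequences, p, threshold_fraction,
                                     both_strands) for p in pwms}
    out = pd.DataFrame(cols)
    out.attrs["scan"] = {"threshold_fraction": threshold_fraction,
                         "both_strands": both_strands}
    return out


def _gc_spline_basis(gc, df=4):
    from statsmodels.gam.smooth_basis import BSplines

    gc = np.asarray(gc, dtype=float)
    return BSplines(gc[:, None], df=[df], degree=[3],
                    include_intercept=False).basis


def motif_logistic_enrichment(hit_counts: pd.DataFrame, deg_indicator,
                              gc=None, fdr_max=0.10, spline_df=4):
    """Per-motif logistic enrichment of hit counts in DEG promoters.

    Fits, per motif, logit P(DEG) = a + b*count + s(GC) with a fixed cubic
    B-spline basis for GC (omitted when ``gc`` is None), and reports the
    likelihood-ratio p for b = 0, the count coefficient (log-odds per extra
    site), BH q across converged motifs, and the direction (enriched when
    b > 0 and q < fdr_max, depleted when b < 0 and q < fdr_max). Degenerate
    or separated fits are flagged and excluded from BH.
    """
    import statsmodels.api as sm

    deg = pd.Series(deg_indicator).reindex(hit_counts.index).astype(float)
    if deg.isna().any():
        raise ValueError("deg_indicator must cover all genes")
    if deg.sum() == 0 or deg.sum() == len(deg):
        raise ValueError("both DEG and background groups must be non-empty")
    y = deg.to_numpy()
    n = y.size
    base_cols = [np.ones(n)]
    if gc is not None:
        gc = pd.Series(gc).reindex(hit_counts.index).to_numpy(dtype=float)
        base_cols.append(_gc_spline_basis(gc, df=spline_df))
    X0 = np.column_stack(base_cols)
    ll0 = None
    rows = []
    for motif_id in hit_counts.columns:
        c = hit_counts[motif_id].to_numpy(dtype=float)
        if np.ptp(c) == 0:
            rows.append({"motif_id": motif_id, "coef": np.nan, "p": np.nan,
                         "converged": False})
            continue
        X1 = np.column_stack([X0, c])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if ll0 is None:
                    ll0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit().llf
                fit1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit(
                    maxiter=100
                )
            coef = float(fit1.params[-1])
            if not np.isfinite(coef) or abs(coef) > 50:
                raise ValueError("separation")
            lr = max(2.0 * (fit1.llf - ll0), 0.0)
            p = float(sps.chi2.sf(lr, 1))
            rows.append({"motif_id": motif_id, "coef": coef,
                         "p": max(p, np.finfo(float).tiny), "converged": True})
        except Exception:
            rows.append({"motif_id": motif_id, "coef": np.nan, "p": np.nan,
                         "converged": False})
    out = pd.DataFrame(rows).set_index("motif_id", drop=False)
    out["q"] = np.nan
    ok = out["converged"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} motifs flagged (degenerate or non-converged)")
    out["direction"] = np.where(
        ok & (out["q"] < fdr_max),
        np.where(out["coef"] > 0, "enriched", "depleted"), "",
    )
    out.attrs["fdr_max"] = fdr_max
    out.attrs["spline_df"] = spline_df if gc is not None else 0
    return out


def summarize_enriched_motifs(rows: pd.DataFrame, family_map: dict):
    """Family-level counts and over-representation among enriched motifs.

    ``family_map`` maps motif id -> family name; unmapped motifs fall into
    "unknown". The hypergeometric test asks whether a family is
    over-represented among enriched motifs relative to all tested motifs.
    """
    tested = rows[rows["converged"]]
    fam = tested["motif_id"].map(lambda m: family_map.get(m, "unknown"))
    enriched = tested["direction"] == "enriched"
    out = []
    n_total = len(tested)
    n_enr = int(enriched.sum())
    for family in sorted(fam.unique()):
        in_fam = fam == family
        k = int((in_fam & enriched).sum())
        p = hypergeom_tail(k, n_total, int(in_fam.sum()), n_enr) \
            if n_enr else 1.0
        out.append({"family": family, "n_motifs": int(in_fam.sum()),
                    "n_enriched": k, "p": p})
    return pd.DataFrame(out).sort_values(["p", "family"]).reset_index(drop=True)
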