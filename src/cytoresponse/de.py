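"""Differential expression core.

Detection filtering, TMM normalization, Cox-Reid trended dispersion
estimation, and negative-binomial GLM likelihood-ratio testing with
covariates, in the style of count-based RNA-seq differential expression:
per-gene NB GLMs with a log link and log effective library size offset are
compared between a full model (treatment + cell line) and a reduced model
(cell line only); p-values come from the chi-square LRT and are BH-adjusted.

The central objects are :class:`DifferentialExpressionModel` (built from a
:class:`CountMatrix` and a sample design table) and the
:class:`DEResults` returned by its ``fit``, which carries the per-gene table
and DEG calling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import glm
from .stats import bh_adjust

DESIGN_COLUMNS = ("sample_id", "treatment", "time", "cell_line")

#: DEG-calling presets: (fdr_max, fc_min, fc_max) or (p_max, fc_min, fc_max)
DEG_PRESETS = {
    # FDR < 0.10 with FC > 2.00 or FC < 0.50
    "standard": {"fdr_max": 0.10, "fc_min": 2.00, "fc_max": 0.50, "on": "q"},
    # heatmap criterion: P < 0.05 with FC > 1.50 or FC < 0.67
    "heatmap": {"fdr_max": 0.05, "fc_min": 1.50, "fc_max": 0.67, "on": "p"},
}


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series = None

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(
                self.counts.columns
            )
            if self.library_sizes.isna().any():
                raise ValueError("library sizes missing for some samples")
            if (self.library_sizes <= 0).any():
                bad = self.library_sizes.index[self.library_sizes <= 0][0]
                raise ValueError(f"library size must be positive (sample {bad!r})")

    @property
    def gene_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    def subset_samples(self, sample_ids):
        return CountMatrix(
            self.counts.loc[:, list(sample_ids)],
            self.library_sizes.loc[list(sample_ids)],
        )

    def subset_genes(self, gene_ids):
        return CountMatrix(self.counts.loc[list(gene_ids)], self.library_sizes)


def validate_design(design: pd.DataFrame):
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design table")
    return design.set_index("sample_id", drop=False)


def cpm(counts: CountMatrix, norm_factors=None, log=False, prior_cpm=0.25):
    """Counts per million mapped reads; optionally TMM-normalized / log2."""
    lib = counts.library_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * pd.Series(norm_factors).reindex(counts.sample_ids).to_numpy()
    out = counts.counts.to_numpy(dtype=float) / lib * 1e6
    out = pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids)
    if log:
        out = np.log2(out + prior_cpm)
    return out


def detect_expressed(counts: CountMatrix, min_cpm=0.25, min_sample_fraction=0.25):
    """Detection filter: cpm strictly > ``min_cpm`` in at least
    ceil(min_sample_fraction * n_samples) samples.

    Returns a boolean Series over genes.
    """
    zero = counts.library_sizes[counts.library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    c = cpm(counts)
    need = math.ceil(min_sample_fraction * counts.counts.shape[1])
    kept = (c > min_cpm).sum(axis=1) >= need
    kept.name = "detected"
    return kept


def tmm_factors(counts: CountMatrix, logratio_trim=0.30, abs_expr_trim=0.05):
    """Weighted trimmed mean of M-values normalization factors.

    The reference sample is the column whose upper-quartile cpm is closest to
    the mean upper-quartile. For each sample, gene-wise log2 ratios (M) to
    the reference are doubly trimmed (by M and by average abundance A) and
    averaged with inverse-asymptotic-variance weights; factors are recentered
    to geometric mean 1. Genes with a zero count in either column are
    excluded.
    """
    y = counts.counts.to_numpy(dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)
    n_samples = y.shape[1]
    if n_samples < 2:
        raise ValueError("TMM requires at least two samples")
    with np.errstate(invalid="ignore"):
        f75 = np.array(
            [np.quantile(y[:, s] / lib[s], 0.75) for s in range(n_samples)]
        )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(n_samples)
    yr, nr = y[:, ref], lib[ref]
    for s in range(n_samples):
        if s == ref:
            continue
        ys, ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if not np.any(ok):
            raise ValueError(
                f"sample {counts.sample_ids[s]!r} shares no nonzero genes "
                "with the TMM reference"
            )
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = sps.rankdata(m)
        rank_a = sps.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if np.any(keep) and np.sum(w[keep]) > 0:
            factors[s] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def build_design_matrix(design: pd.DataFrame, terms, reference=None):
    """Treatment-coded design matrix (intercept + dropped-reference dummies).

    ``terms`` are design column names or two-way interactions written
    ``"a:b"``; the treatment factor's reference level defaults to ``"CTL"``
    when present. Returns (X, column names).
    """
    reference = dict(reference or {})
    n = len(design)
    cols = [np.ones(n)]
    names = ["intercept"]

    def main_dummies(factor):
        levels = sorted(design[factor].astype(str).unique())
        ref = reference.get(factor)
        if ref is None:
            ref = "CTL" if factor == "treatment" and "CTL" in levels else levels[0]
        out = []
        for lv in levels:
            if lv == ref:
                continue
            out.append((f"{factor}[{lv}]", (design[factor].astype(str) == lv).to_numpy(float)))
        return out

    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            for na, va in main_dummies(a):
                for nb, vb in main_dummies(b):
                    cols.append(va * vb)
                    names.append(f"{na}:{nb}")
        else:
            for nm, v in main_dummies(term):
                cols.append(v)
                names.append(nm)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix for terms {list(terms)} is rank deficient")
    return X, names


@dataclass
class DispersionFit:
    """Per-gene trended NB dispersions with the fitted abundance trend."""

    phi: pd.Series
    avg_log_cpm: pd.Series
    bins: pd.DataFrame        # bin mean avg_log_cpm, raw and smoothed phi
    span: float

    def trend(self, avg_log_cpm):
        """Evaluate the trend at arbitrary average log-CPM (flat beyond ends)."""
        x = np.asarray(avg_log_cpm, dtype=float)
        xb = self.bins["avg_log_cpm"].to_numpy()
        yb = np.log(self.bins["phi_smooth"].to_numpy())
        return np.exp(np.interp(x, xb, yb))


def average_log_cpm(counts: CountMatrix, norm_factors=None):
    c = cpm(counts, norm_factors=norm_factors)
    return pd.Series(
        np.log2(c.mean(axis=1) + 0.25), index=counts.gene_ids, name="avg_log_cpm"
    )


def estimate_trended_dispersion(
    counts: CountMatrix,
    design: pd.DataFrame,
    full_terms=("treatment", "cell_line"),
    norm_factors=None,
    n_bins=20,
    span=0.5,
):
    """Trended NB dispersion by binned Cox-Reid adjusted profile likelihood.

    Genes are split into up to ``n_bins`` equal-occupancy bins by average
    log-CPM; a common dispersion per bin maximizes the summed CR-adjusted
    profile likelihood (golden/bounded search on log phi); the binned values
    are smoothed by lowess over abundance and each gene receives the trend
    value at its abundance. All-zero genes are excluded with a warning.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    design = design.set_index("sample_id", drop=False).loc[list(counts.sample_ids)]
    X, _ = build_design_matrix(design, full_terms)
    if counts.counts.shape[1] - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom for dispersion estimation")
    y_all = counts.counts.to_numpy(dtype=float)
    nonzero = y_all.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"excluding {int((~nonzero).sum())} all-zero genes "
                      "from dispersion estimation")
    lib = counts.library_sizes.to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * pd.Series(norm_factors).reindex(counts.sample_ids).to_numpy()
    offset = np.log(lib)
    alc = average_log_cpm(counts, norm_factors=norm_factors)

    idx = np.flatnonzero(nonzero)
    order = idx[np.argsort(alc.to_numpy()[idx], kind="mergesort")]
    n_bins_eff = max(1, min(n_bins, order.size // 25 or 1))
    bins = np.array_split(order, n_bins_eff)
    rows = []
    for b in bins:
        phi_b = glm.maximize_cr_common_dispersion(y_all[b], X, offset)
        rows.append({"avg_log_cpm": float(alc.to_numpy()[b].mean()),
                     "phi_raw": phi_b, "n_genes": b.size})
    bin_df = pd.DataFrame(rows).sort_values("avg_log_cpm").reset_index(drop=True)
    if len(bin_df) >= 3:
        sm = lowess(np.log(bin_df["phi_raw"]), bin_df["avg_log_cpm"],
                    frac=max(span, 2.0 / len(bin_df)), return_sorted=False)
        bin_df["phi_smooth"] = np.exp(sm)
    else:
        bin_df["phi_smooth"] = bin_df["phi_raw"]
    fit = DispersionFit(phi=None, avg_log_cpm=alc, bins=bin_df, span=span)
    phi = fit.trend(alc.to_numpy())
    fit.phi = pd.Series(phi, index=counts.gene_ids, name="dispersion")
    return fit


class DifferentialExpressionModel:
    """NB GLM likelihood-ratio model for one contrast.

    Parameters
    ----------
    counts : CountMatrix
        Counts for the samples entering the contrast.
    design : DataFrame
        Sample design (sample_id, treatment, time, cell_line) covering every
        count column.
    full_terms, reduced_terms : sequence of str
        Model terms; the tested terms are those in full but not reduced. The
        reported log2 fold change is the coefficient of the first tested
        column (natural log scale / log 2).
    dispersion : Series or float, optional
        Per-gene NB dispersions; estimated from the data when omitted.
    norm_factors : Series, optional
        TMM factors; computed when omitted.
    """

    def __init__(self, counts, design, full_terms=("treatment", "cell_line"),
                 reduced_terms=("cell_line",), dispersion=None,
                 norm_factors=None, contrast_label=""):
        self.counts = counts
        self.design = design.set_index("sample_id", drop=False).loc[
            list(counts.sample_ids)
        ]
        self.full_terms = tuple(full_terms)
        self.reduced_terms = tuple(reduced_terms)
        self.dispersion = dispersion
        self.norm_factors = norm_factors
        self.contrast_label = contrast_label

    @classmethod
    def from_dataframe(cls, counts_df, design_df, **kwargs):
        return cls(CountMatrix(counts_df), design_df, **kwargs)

    def fit(self, max_iter=100, tol=1e-8):
        counts, design = self.counts, self.design
        if self.norm_factors is None:
            self.norm_factors = tmm_factors(counts)
        Xf, names_f = build_design_matrix(design, self.full_terms)
        Xr, names_r = (
            build_design_matrix(design, self.reduced_terms)
            if self.reduced_terms
            else (np.ones((len(design), 1)), ["intercept"])
        )
        tested = [nm for nm in names_f if nm not in names_r]
        if not tested:
            raise ValueError("full model adds no terms beyond the reduced model")
        df = len(names_f) - len(names_r)
        if self.dispersion is None:
            self.dispersion = estimate_trended_dispersion(
                counts, design.reset_index(drop=True),
                full_terms=self.full_terms, norm_factors=self.norm_factors,
            ).phi
        phi = (
            pd.Series(self.dispersion).reindex(counts.gene_ids).to_numpy()
            if not np.isscalar(self.dispersion)
            else np.full(len(counts.gene_ids), float(self.dispersion))
        )
        lib = counts.library_sizes.to_numpy(dtype=float) * pd.Series(
            self.norm_factors
        ).reindex(counts.sample_ids).to_numpy()
        offset = np.log(lib)
        y = counts.counts.to_numpy(dtype=float)
        fit_full = glm.irls_nb(y, Xf, offset, phi, max_iter=max_iter, tol=tol)
        fit_red = glm.irls_nb(y, Xr, offset, phi, max_iter=max_iter, tol=tol)
        lr = np.maximum(2.0 * (fit_full.loglik - fit_red.loglik), 0.0)
        p = sps.chi2.sf(lr, df)
        converged = fit_full.converged & fit_red.converged
        p = np.where(converged, p, np.nan)
        coef_ix = names_f.index(tested[0])
        log2fc = fit_full.beta[:, coef_ix] / np.log(2.0)
        table = pd.DataFrame(
            {
                "gene_id": counts.gene_ids,
                "log2fc": log2fc,
                "avg_log_cpm": average_log_cpm(counts, self.norm_factors).to_numpy(),
                "lr_stat": lr,
                "p": p,
                "q": np.nan,
                "converged": converged,
            }
        ).set_index("gene_id", drop=False)
        ok = table["p"].notna()
        table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
        n_bad = int((~converged).sum())
        if n_bad:
            warnings.warn(f"{n_bad} genes failed to converge; p set to missing")
        # per-treatment-level coefficients, useful for interaction sign patterns
        coefs = pd.DataFrame(fit_full.beta / np.log(2.0), index=counts.gene_ids,
                             columns=names_f)
        return DEResults(table=table, tested_terms=tested, df=df,
                         coefficients=coefs, contrast_label=self.contrast_label,
                         dispersion=pd.Series(phi, index=counts.gene_ids),
                         norm_factors=self.norm_factors)


@dataclass
class DEResults:
    """Per-gene differential expression results for one contrast."""

    table: pd.DataFrame
    tested_terms: list
    df: int
    coefficients: pd.DataFrame
    contrast_label: str = ""
    dispersion: pd.Series = None
    norm_factors: pd.Series = None
    deg_thresholds: dict = field(default_factory=dict)

    def summary(self, n=10):
        t = self.table.sort_values("p")
        lines = [
            f"NB GLM likelihood-ratio test  contrast={self.contrast_label or '-'}",
            f"genes: {len(t)}   tested terms: {self.tested_terms} (df={self.df})",
            f"non-converged: {int((~t['converged']).sum())}",
            "",
            t.head(n)[["log2fc", "avg_log_cpm", "lr_stat", "p", "q"]].to_string(),
        ]
        return "\n".join(lines)

    def call_degs(self, fdr_max=0.10, fc_min=2.00, fc_max=0.50, preset=None):
        """Call DEGs with strict thresholds (see :func:`call_degs_table`)."""
        return call_degs_table(self.table, fdr_max=fdr_max, fc_min=fc_min,
                               fc_max=fc_max, preset=preset)


def call_degs_table(table: pd.DataFrame, fdr_max=0.10, fc_min=2.00,
                    fc_max=0.50, preset=None):
    """Call DEGs from a per-gene results table with strict thresholds.

    Default rule: q < fdr_max and (FC > fc_min or FC < fc_max). The
    ``"heatmap"`` preset applies P < 0.05 with FC > 1.50 or FC < 0.67
    instead. Returns a DataFrame (gene_id, direction) indexed by gene with
    the thresholds recorded in ``attrs``.
    """
    on = "q"
    if preset is not None:
        cfg = DEG_PRESETS[preset]
        fdr_max, fc_min, fc_max, on = (
            cfg["fdr_max"], cfg["fc_min"], cfg["fc_max"], cfg["on"]
        )
    sig = table[on] < fdr_max
    fc = 2.0 ** table["log2fc"]
    up = sig & (fc > fc_min)
    down = sig & (fc < fc_max)
    out = pd.DataFrame(
        {"gene_id": table.index,
         "direction": np.where(up, "up", np.where(down, "down", ""))}
    )
    out = out[out["direction"] != ""].set_index("gene_id", drop=False)
    out.attrs["thresholds"] = {
        "fdr_max": fdr_max, "fc_min": fc_min, "fc_max": fc_max, "on": on
    }
    return out


def fit_nb_lrt(counts, design, dispersions=None,
               full_terms=("treatment", "cell_line"),
               reduced_terms=("cell_line",), norm_factors=None,
               contrast_label=""):
    """Functional wrapper: fit the NB GLM LRT and return :class:`DEResults`."""
    model = DifferentialExpressionModel(
        counts, design, full_terms=full_terms, reduced_terms=reduced_terms,
        dispersion=dispersions, norm_factors=norm_factors,
        contrast_label=contrast_label,
    )
    return model.fit()


def contrast_subset(design: pd.DataFrame, treatment, time, control="CTL"):
    """Sample ids entering the (treatment vs control at one time) contrast."""
    d = design
    keep = (d["time"].astype(str) == str(time)) & d["treatment"].isin(
        [treatment, control]
    )
    return d.loc[keep, "sample_id"].tolist()


def interaction_test(counts, design, dispersions, treatment, control="CTL",
                     norm_factors=None):
    """Treatment x time interaction LRT with sign-pattern classification.

    Fits, on the samples of one cytokine and the control at both time
    points, the model treatment + time + treatment:time + cell_line against
    the additive model, then classifies significant genes by the signs of
    the per-time treatment log2 fold changes (down_up, up_down, same_sign).
    """
    design = design.set_index("sample_id", drop=False).loc[list(counts.sample_ids)]
    sub = design[design["treatment"].isin([treatment, control])]
    times = list(dict.fromkeys(sub["time"].astype(str)))   # design order
    if len(times) < 2:
        raise ValueError(f"both time points required for {treatment!r}")
    cm = counts.subset_samples(sub["sample_id"])
    res = fit_nb_lrt(
        cm, sub,
        dispersions=dispersions,
        full_terms=("treatment", "time", "treatment:time", "cell_line"),
        reduced_terms=("treatment", "time", "cell_line"),
        norm_factors=None if norm_factors is None
        else pd.Series(norm_factors).loc[list(cm.sample_ids)],
        contrast_label=f"{treatment}xtime",
    )
    # per-time fold changes from the two simple contrasts
    fcs = {}
    for t in times:
        ids = contrast_subset(sub, treatment, t, control)
        r = fit_nb_lrt(
            cm.subset_samples(ids), sub.loc[ids],
            dispersions=dispersions,
            full_terms=("treatment", "cell_line"), reduced_terms=("cell_line",),
            norm_factors=None if norm_factors is None
            else pd.Series(norm_factors).loc[ids],
            contrast_label=f"{treatment}:{t}",
        )
        fcs[t] = r.table["log2fc"]
    tab = res.table.copy()
    t0, t1 = times[0], times[-1]
    tab["log2fc_" + t0] = fcs[t0]
    tab["log2fc_" + t1] = fcs[t1]
    pattern = np.where(
        (fcs[t0] < 0) & (fcs[t1] > 0), "down_up",
        np.where((fcs[t0] > 0) & (fcs[t1] < 0), "up_down", "same_sign"),
    )
    tab["pattern"] = pattern
    res.table = tab
    return res


def group_ttest(expression: pd.DataFrame, design: pd.DataFrame, treatment,
                time, control="CTL", pairing="cell_line"):
    """Paired two-sample t-test per gene (cytokine vs control at one time).

    Samples are paired by the ``pairing`` factor (cell line). Degenerate
    zero-variance nonzero differences report the smallest positive float
    rather than failing; fewer than two complete pairs yields missing p with
    a warning.
    """
    design = design.set_index("sample_id", drop=False)
    d = design[design["time"].astype(str) == str(time)]
    trt = d[d["treatment"] == treatment].set_index(pairing)["sample_id"]
    ctl = d[d["treatment"] == control].set_index(pairing)["sample_id"]
    pairs = trt.index.intersection(ctl.index)
    if len(pairs) < 2:
        warnings.warn("fewer than two complete pairs; p-values missing")
        return pd.DataFrame(
            {"t": np.nan, "p": np.nan, "n_pairs": len(pairs)},
            index=expression.index,
        )
    diffs = (
        expression[trt.loc[pairs].tolist()].to_numpy()
        - expression[ctl.loc[pairs].tolist()].to_numpy()
    )
    k = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(k))
    p = 2.0 * sps.t.sf(np.abs(t), k - 1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var,
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    p = np.where(zero_var, np.where(mean == 0, 1.0, np.finfo(float).tiny), p)
    return pd.DataFrame({"t": t, "p": p, "n_pairs": k}, index=expression.index)


def variance_components(expression: pd.DataFrame, design: pd.DataFrame,
                        factors=("treatment", "time", "cell_line")):
    """Per-gene one-factor R-squared for each design factor.

    For each gene and factor, the R-squared of the one-way group-mean model
    on the (log-scale) expression row; constant rows get 0 by convention.
    Returns the per-gene table plus mean/median summaries per factor.
    """
    design = design.set_index("sample_id", drop=False).loc[list(expression.columns)]
    X = expression.to_numpy(dtype=float)
    total = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    out = {}
    for f in factors:
        levels = design[f].astype(str)
        if levels.nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
        fitted = np.zeros_like(X)
        for lv in levels.unique():
            cols = np.flatnonzero((levels == lv).to_numpy())
            fitted[:, cols] = X[:, cols].mean(axis=1, keepdims=True)
        ss_between = ((fitted - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(total > 0, ss_between / total, 0.0)
        out[f] = r2
    table = pd.DataFrame(out, index=expression.index)
    summary = pd.DataFrame({"mean_r2": table.mean(), "median_r2": table.median()})
    return table, summary
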