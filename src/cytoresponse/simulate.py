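"""Synthetic data generator for the cytokine-stimulation pipeline.

Emulates the statistical structure of a multi-cytokine keratinocyte
stimulation experiment: 4 cytokines x 2 time points plus control, 2-3
replicates drawn from 3 cell lines, negative-binomial counts with a trended
dispersion phi(mu) = phi0 + a/mu, gene x cell-line log-scale offsets, and
planted response classes (shared up/down across all cytokines, an
IL-1B-specific class, and a time-flipping class whose fold changes reverse
sign between the early and late time point). Companion generators produce
ranked disease-like signatures at a target rank correlation with the truth,
promoter sequences with planted motif instances, and a SNP catalog with
SNPs planted near a chosen gene subset. Every generator is a pure function
of its configuration and seed, and returns ground-truth tables for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import CountMatrix

PLANTED_CLASSES = ("shared_up", "shared_down", "il1b_specific", "timeflip")
DEFAULT_TREATMENTS = ("CTL", "IL1B", "IL36A", "IL36B", "IL36G")
DEFAULT_TIMES = ("8h", "24h")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate_counts`.

    Defaults mirror the emulated experiment: 4 cytokines and a control at
    two time points, three replicate cell lines, planted |log2 FC| of 2
    (matching a fold-change call threshold of 2), NB dispersion trend
    phi(mu) = phi0 + a/mu with phi0 = 0.1, and gene x line offsets whose
    spread makes cell line the dominant variance factor.
    """

    n_genes: int = 2000
    n_cell_lines: int = 3
    replicates_per_group: int = 3
    treatments: tuple = DEFAULT_TREATMENTS
    times: tuple = DEFAULT_TIMES
    pi_shared_up: float = 0.05
    pi_shared_down: float = 0.02
    pi_specific: float = 0.03
    pi_timeflip: float = 0.03
    effect_log2fc: float = 2.0
    dispersion_intercept: float = 0.1    # phi0
    dispersion_slope: float = 1.0        # a in phi(mu) = phi0 + a/mu
    cellline_sd: float = 0.5             # log2-scale gene x line offsets
    baseline_logmean_range: tuple = (6.6, 11.0)   # log2 expected count
    libsize_fold_range: float = 2.0
    seed: int = 0

    def validate(self):
        pis = (self.pi_shared_up, self.pi_shared_down,
               self.pi_specific, self.pi_timeflip)
        if any(p < 0 for p in pis) or sum(pis) > 1.0:
            raise ValueError("planted class proportions must be >= 0 and sum <= 1")
        for name in ("n_genes", "n_cell_lines", "replicates_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion_intercept < 0 or self.dispersion_slope < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.cellline_sd < 0:
            raise ValueError("cellline_sd must be >= 0")
        if "CTL" not in self.treatments:
            raise ValueError("treatments must include CTL")
        return self


def _assign_classes(cfg: SimulationConfig, rng):
    g = cfg.n_genes
    counts = {
        "shared_up": int(np.floor(cfg.pi_shared_up * g)),
        "shared_down": int(np.floor(cfg.pi_shared_down * g)),
        "il1b_specific": int(np.floor(cfg.pi_specific * g)),
        "timeflip": int(np.floor(cfg.pi_timeflip * g)),
    }
    if cfg.effect_log2fc == 0:
        counts = {k: 0 for k in counts}
    labels = np.array(["null"] * g, dtype=object)
    order = rng.permutation(g)
    pos = 0
    for cls in PLANTED_CLASSES:
        k = counts[cls]
        labels[order[pos : pos + k]] = cls
        pos += k
    return labels


def true_log2fc_matrix(truth: pd.DataFrame, treatments=None, times=None):
    """Gene x condition matrix of planted log2 fold changes."""
    cols = [c for c in truth.columns if c.startswith("log2fc_")]
    mat = truth[cols].copy()
    mat.columns = [c[len("log2fc_"):] for c in cols]
    return mat


def simulate_counts(config: SimulationConfig):
    """Draw NB counts for the configured design.

    Returns ``(CountMatrix, design DataFrame, truth DataFrame)``. The truth
    table records, per gene, the planted class, the true dispersion at the
    gene's baseline abundance, and the true log2 FC for every
    (treatment, time) condition (columns ``log2fc_<treatment>:<time>``).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, g + 1)]
    labels = _assign_classes(cfg, rng)

    lo, hi = cfg.baseline_logmean_range
    base_log2 = rng.uniform(lo, hi, size=g)
    mu_base = 2.0 ** base_log2
    phi = cfg.dispersion_intercept + cfg.dispersion_slope / mu_base

    lines = [f"line{chr(65 + i)}" for i in range(cfg.n_cell_lines)]
    line_offsets = rng.normal(0.0, cfg.cellline_sd, size=(g, cfg.n_cell_lines))

    # planted per-condition effects
    e = cfg.effect_log2fc
    cytokines = [t for t in cfg.treatments if t != "CTL"]
    conditions = [(t, tm) for t in cytokines for tm in cfg.times]
    fc = {cond: np.zeros(g) for cond in conditions}
    t_early, t_late = cfg.times[0], cfg.times[-1]
    for i, cls in enumerate(labels):
        if cls == "shared_up":
            for cond in conditions:
                fc[cond][i] = e
        elif cls == "shared_down":
            for cond in conditions:
                fc[cond][i] = -e
        elif cls == "il1b_specific":
            for tm in cfg.times:
                if ("IL1B", tm) in fc:
                    fc[("IL1B", tm)][i] = e
        elif cls == "timeflip":
            for t in cytokines:
                fc[(t, t_early)][i] = e
                fc[(t, t_late)][i] = -e

    # samples: one replicate per cell line (cycled when replicates exceed lines)
    rows = []
    for trt in cfg.treatments:
        for tm in cfg.times:
            for r in range(cfg.replicates_per_group):
                line = lines[r % cfg.n_cell_lines]
                rows.append(
                    {"sample_id": f"{trt}_{tm}_r{r + 1}", "treatment": trt,
                     "time": tm, "cell_line": line}
                )
    design = pd.DataFrame(rows)
    n_samples = len(design)
    log_fold = np.log2(cfg.libsize_fold_range)
    lib_rel = 2.0 ** rng.uniform(-log_fold / 2, log_fold / 2, size=n_samples)

    counts = np.empty((g, n_samples), dtype=np.int64)
    line_index = {ln: i for i, ln in enumerate(lines)}
    for s, row in design.iterrows():
        cond = (row["treatment"], row["time"])
        eff = fc[cond] if cond in fc else np.zeros(g)
        mu = mu_base * lib_rel[s] * 2.0 ** (
            line_offsets[:, line_index[row["cell_line"]]] + eff
        )
        if cfg.dispersion_intercept == 0 and cfg.dispersion_slope == 0:
            counts[:, s] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
            counts[:, s] = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids,
                                  columns=design["sample_id"]))
    truth = pd.DataFrame({"gene_id": gene_ids, "class": labels,
                          "baseline_log2_mean": base_log2,
                          "true_dispersion": phi}).set_index("gene_id",
                                                             drop=False)
    for (t, tm), v in fc.items():
        truth[f"log2fc_{t}:{tm}"] = v
    return cm, design, truth


def simulate_signature(truth: pd.DataFrame, target_rank_corr: float, seed=0):
    """Ranked signature with a target Spearman correlation to the truth.

    The latent score is the normal score of the (tie-jittered) rank of the
    mean planted log2 FC; Gaussian noise is mixed in at the Pearson level
    2*sin(pi*rho/6) that yields Spearman correlation ``target_rank_corr``
    for bivariate normal scores. With a heavily tied truth (mostly null
    genes) the achievable Spearman against the raw truth is correspondingly
    bounded; the target is met when the truth scores are mostly distinct.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    if not 0.0 <= target_rank_corr <= 1.0:
        raise ValueError("target_rank_corr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mat = true_log2fc_matrix(truth)
    t = mat.mean(axis=1).to_numpy() if mat.shape[1] else np.zeros(len(truth))
    n = t.size
    jitter = rng.normal(0.0, 1e-9, size=n)
    ranks = sps.rankdata(t + jitter, method="ordinal")
    z = sps.norm.ppf((ranks - 0.375) / (n + 0.25))
    if target_rank_corr >= 1.0:
        scores = z
    else:
        rho_p = 2.0 * np.sin(np.pi * target_rank_corr / 6.0)
        scores = rho_p * z + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    sig = pd.DataFrame({"gene_id": truth["gene_id"].to_numpy(),
                        "score": scores})
    return sig.sort_values("score", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def simulate_promoters(truth: pd.DataFrame, motifs, enrichment_rate_deg,
                       base_rate, length=5000, gc_beta=(50.0, 50.0), seed=0):
    """Upstream sequences with planted consensus motif instances.

    Background bases are i.i.d. with a per-gene GC fraction drawn from a
    Beta distribution; for each motif, consensus-sequence instances are
    planted at Poisson(``enrichment_rate_deg``) counts for shared-signature
    genes and Poisson(``base_rate``) otherwise, at uniform non-overlapping
    positions (overlap avoidance is shared across motifs).

    Returns ``(sequences: Series gene_id -> str, promoter_truth DataFrame)``.
    """
    if enrichment_rate_deg < 0 or base_rate < 0:
        raise ValueError("planting rates must be >= 0")
    widths = [m.width for m in motifs]
    if widths and max(widths) > length:
        raise ValueError("motif wider than promoter length")
    rng = np.random.default_rng(seed)
    alphabet = np.array(["A", "C", "G", "T"])
    seqs = {}
    rows = []
    deg_classes = {"shared_up", "shared_down"}
    for gene_id, cls in zip(truth["gene_id"], truth["class"]):
        gc = float(rng.beta(*gc_beta))
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = rng.choice(4, size=length, p=probs)
        occupied = np.zeros(length, dtype=bool)
        planted = {}
        positions = {}
        for m in motifs:
            rate = enrichment_rate_deg if cls in deg_classes else base_rate
            k = int(rng.poisson(rate)) if rate > 0 else 0
            cons = m.consensus_indices()
            w = cons.size
            placed = []
            for _ in range(k):
                for _try in range(200):
                    pos = int(rng.integers(0, length - w + 1))
                    if not occupied[pos : pos + w].any():
                        seq[pos : pos + w] = cons
                        occupied[pos : pos + w] = True
                        placed.append(pos)
                        break
            planted[m.motif_id] = len(placed)
            positions[m.motif_id] = placed
        seqs[gene_id] = "".join(alphabet[seq])
        row = {"gene_id": gene_id, "class": cls, "gc_fraction": gc}
        for m in motifs:
            row[f"planted_{m.motif_id}"] = planted[m.motif_id]
            row[f"positions_{m.motif_id}"] = ",".join(map(str,
                                                          positions[m.motif_id]))
        rows.append(row)
    ptruth = pd.DataFrame(rows).set_index("gene_id", drop=False)
    return pd.Series(seqs, name="sequence"), ptruth


def make_gene_loci(gene_ids, genes_per_chrom=1000, spacing=100_000,
                   gene_length=10_000):
    """Synthetic gene loci: one chromosome per ``genes_per_chrom`` genes,
    fixed spacing, 0-based half-open spans, alternating strand."""
    rows = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // genes_per_chrom + 1}"
        start = (i % genes_per_chrom) * spacing
        rows.append({"gene_id": gid, "chrom": chrom, "start": start,
                     "end": start + gene_length,
                     "strand": "+" if i % 2 == 0 else "-"})
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


def simulate_snp_catalog(loci: pd.DataFrame, target_genes, n_background_snps,
                         n_planted, max_planted_distance, seed=0,
                         trait="IBD"):
    """SNP catalog with SNPs planted near target genes.

    Background SNPs are uniform over the synthetic genome; each planted SNP
    is placed within ``max_planted_distance`` of its target gene under the
    gene-edge distance convention (inside the span when the distance is 0).
    Returns ``(catalog DataFrame, snp_truth DataFrame)``.
    """
    if len(loci) == 0:
        raise ValueError("gene loci table is empty")
    target_genes = list(target_genes)
    missing = set(target_genes) - set(loci["gene_id"])
    if missing:
        raise ValueError(f"target genes absent from loci: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    chrom_sizes = (loci.groupby("chrom")["end"].max() + 100_000).to_dict()
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(sizes)])
    rows = []
    for i in range(n_background_snps):
        u = rng.uniform(0, cum[-1])
        ci = int(np.searchsorted(cum, u, side="right")) - 1
        rows.append({"snp_id": f"rs_bg{i + 1}", "chrom": chroms[ci],
                     "pos": int(u - cum[ci]), "trait": trait,
                     "planted_near_gene": ""})
    for i in range(n_planted):
        gid = target_genes[i % len(target_genes)] if target_genes else None
        if gid is None:
            break
        g = loci.loc[gid]
        d = int(max_planted_distance)
        lo = max(0, int(g["start"]) - d)
        hi = int(g["end"]) - 1 + d
        pos = int(rng.integers(lo, hi + 1))
        rows.append({"snp_id": f"rs_pl{i + 1}", "chrom": g["chrom"],
                     "pos": pos, "trait": trait, "planted_near_gene": gid})
    truth = pd.DataFrame(rows)
    catalog = truth[["snp_id", "chrom", "pos", "trait"]].copy()
    return catalog, truth
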