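"""End-to-end orchestration from a single config.

Stages run in dependency order (simulate -> de -> patterns -> signatures ->
gwas -> motifs); each stage derives its own random substream from the global
seed and the stage name, so toggling one stage never shifts another's
randomness. Every output TSV carries ``#`` header lines with the package
version, seed and a parameter hash, and the run manifest lists outputs with
sha256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__, de, enrich, gwas, io, motifs, patterns, simulate

log = logging.getLogger("cytoresponse")

STAGES = ("simulate", "de", "patterns", "signatures", "gwas", "motifs")

#: built-in demonstration motifs (near-consensus PPMs) for synthetic runs
def demo_motifs():
    def ppm(consensus):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        m = np.full((len(consensus), 4), 0.01)
        for i, b in enumerate(consensus):
            m[i, idx[b]] = 0.97
        return m

    return [
        motifs.PWM("NFKB_like", ppm("GGGACTTTCC")),
        motifs.PWM("ETS_like", ppm("ACAGGAAGTG")),
        motifs.PWM("AT_decoy", ppm("ATTTATAATA")),
    ]


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def default_config():
    return {
        "outdir": "cytoresponse_out",
        "seed": 0,
        "stages": {s: True for s in STAGES},
        "simulate": {"n_genes": 2000},
        "inputs": {},            # counts/design paths for non-simulated runs
        "thresholds": {
            "fdr": 0.10, "fc": 2.0, "k_max": 500,
            "scan_threshold": 0.8,
            "d_grid": list(gwas.DEFAULT_DISTANCE_GRID),
        },
        "som": {"grid": [6, 6], "epochs": 20},
        "motifs": {"enrichment_rate_deg": 2.0, "base_rate": 0.5,
                   "length": 1000},
        "gwas": {"n_background_snps": 20, "n_planted": 20,
                 "max_planted_distance": 200_000, "trait": "IBD"},
    }


def validate_config(config: dict):
    """Collect (not fail-fast) configuration errors; returns a list."""
    errors = []
    th = config.get("thresholds", {})
    fdr = th.get("fdr", 0.10)
    if not 0 < fdr <= 1:
        errors.append(f"thresholds.fdr out of range (0, 1]: {fdr}")
    fc = th.get("fc", 2.0)
    if fc <= 1:
        errors.append(f"thresholds.fc must exceed 1: {fc}")
    scan = th.get("scan_threshold", 0.8)
    if not 0 < scan <= 1:
        errors.append(f"thresholds.scan_threshold out of range (0, 1]: {scan}")
    if th.get("k_max", 500) < 1:
        errors.append("thresholds.k_max must be >= 1")
    inputs = config.get("inputs", {}) or {}
    for key, path in inputs.items():
        if path and not os.path.exists(path):
            errors.append(f"inputs.{key}: file not found: {path}")
    if not (config.get("stages", {}).get("simulate", True) or
            (inputs.get("counts") and inputs.get("design"))):
        errors.append("either enable the simulate stage or provide "
                      "inputs.counts and inputs.design")
    sim = config.get("simulate", {}) or {}
    try:
        simulate.SimulationConfig(**sim).validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"simulate: {exc}")
    return errors


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _param_hash(config):
    params = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict):
    """Run the configured stages; returns the manifest dict."""
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])
    meta = {"version": __version__, "seed": seed,
            "param_hash": _param_hash(cfg)}
    th = cfg["thresholds"]
    outputs = {}
    state = {}

    def emit(stage, name, writer, obj):
        path = os.path.join(outdir, name)
        writer(obj, path, metadata=meta) if writer in (
            io.write_counts, io.write_design, io.write_table,
            io.write_snp_bed, io.write_gene_bed, io.write_signature,
        ) else writer(obj, path)
        outputs.setdefault(stage, []).append(name)

    stages = cfg["stages"]
    # ---- simulate -------------------------------------------------------
    if stages.get("simulate", True):
        try:
            sim_cfg = simulate.SimulationConfig(
                **{**cfg["simulate"], "seed": stage_seed(seed, "simulate")}
            )
            counts, design, truth = simulate.simulate_counts(sim_cfg)
            state.update(counts=counts, design=design, truth=truth)
            emit("simulate", "counts.tsv", io.write_counts, counts)
            emit("simulate", "design.tsv", io.write_design, design)
            emit("simulate", "truth.tsv", io.write_table,
                 truth.reset_index(drop=True))
        except Exception as exc:
            raise PipelineError("simulate", exc) from exc
    elif cfg["inputs"].get("counts"):
        state["counts"] = io.read_counts(cfg["inputs"]["counts"])
        state["design"] = io.read_design(cfg["inputs"]["design"])
        state["truth"] = None

    # ---- de -------------------------------------------------------------
    if stages.get("de", True):
        try:
            counts, design = state["counts"], state["design"]
            detected = de.detect_expressed(counts)
            kept = counts.subset_genes(detected[detected].index)
            factors = de.tmm_factors(kept)
            disp = de.estimate_trended_dispersion(
                kept, design,
                full_terms=("treatment", "time", "treatment:time",
                            "cell_line"),
                norm_factors=factors,
            )
            cytokines = [t for t in design["treatment"].unique() if t != "CTL"]
            times = list(design["time"].unique())
            de_tables = {}
            calls = {}
            for trt in cytokines:
                for tm in times:
                    ids = de.contrast_subset(design.set_index("sample_id",
                                                              drop=False),
                                             trt, tm)
                    res = de.fit_nb_lrt(
                        kept.subset_samples(ids),
                        design[design["sample_id"].isin(ids)],
                        dispersions=disp.phi,
                        norm_factors=factors.loc[ids],
                        contrast_label=f"{trt}:{tm}",
                    )
                    label = f"{trt}:{tm}"
                    de_tables[label] = res.table
                    calls[label] = res.call_degs(fdr_max=th["fdr"],
                                                 fc_min=th["fc"],
                                                 fc_max=1.0 / th["fc"])
                    emit("de", f"de_{trt}_{tm}.tsv", io.write_table,
                         res.table.reset_index(drop=True))
            inter = {}
            for trt in cytokines:
                r = de.interaction_test(kept, design, disp.phi, trt,
                                        norm_factors=factors)
                inter[trt] = r.table
                emit("de", f"interaction_{trt}.tsv", io.write_table,
                     r.table.reset_index(drop=True))
            state.update(detected=detected, kept=kept, factors=factors,
                         dispersion=disp, de_tables=de_tables, calls=calls,
                         interactions=inter)
        except Exception as exc:
            raise PipelineError("de", exc) from exc

    # ---- patterns -------------------------------------------------------
    if stages.get("patterns", True):
        try:
            profile = patterns.build_response_profile(state["de_tables"])
            corr = patterns.response_correlation(profile)
            emit("patterns", "response_profile.tsv", io.write_table,
                 profile.rename_axis("gene_id").reset_index())
            emit("patterns", "condition_correlation.tsv", io.write_table,
                 corr.rename_axis("condition").reset_index())
            from .som import fit_som, summarize_som

            som_cfg = cfg["som"]
            som = fit_som(profile, grid=tuple(som_cfg["grid"]),
                          epochs=som_cfg["epochs"],
                          seed=stage_seed(seed, "som"))
            emit("patterns", "som_nodes.tsv", io.write_table,
                 summarize_som(som, profile).reset_index())
            k = min(15, max(2, len(profile) // 10))
            clusters = patterns.cluster_genes(profile, k=k)
            reps = patterns.select_representatives(profile, clusters)
            emit("patterns", "gene_clusters.tsv", io.write_table,
                 clusters.rename_axis("gene_id").reset_index())
            emit("patterns", "representatives.tsv", io.write_table,
                 reps.rename_axis("cluster").reset_index())
            state.update(profile=profile, clusters=clusters, reps=reps)
        except Exception as exc:
            raise PipelineError("patterns", exc) from exc

    # ---- signatures -----------------------------------------------------
    if stages.get("signatures", True):
        try:
            up, down = enrich.shared_signature(state["calls"])
            io.write_gmt({"shared_up": up, "shared_down": down},
                         os.path.join(outdir, "shared_signature.gmt"))
            outputs.setdefault("signatures", []).append("shared_signature.gmt")
            state.update(shared_up=up, shared_down=down)
            if state.get("truth") is not None and len(up) + len(down) > 0:
                sig = simulate.simulate_signature(
                    state["truth"], 0.7, seed=stage_seed(seed, "signature")
                )
                sig = sig[sig["gene_id"].isin(state["profile"].index)]
                emit("signatures", "lesion_signature.tsv", io.write_signature,
                     sig)
                target = up if up else down
                curve, p_two, p_one = enrich.cumulative_overlap_gsea(
                    sig, target
                )
                emit("signatures", "gsea_curve.tsv", io.write_table, curve)
                io.write_json(
                    {"wilcoxon_p_two_sided": p_two,
                     "wilcoxon_p_one_sided": p_one},
                    os.path.join(outdir, "gsea_stats.json"),
                )
                outputs["signatures"].append("gsea_stats.json")
        except Exception as exc:
            raise PipelineError("signatures", exc) from exc

    # ---- gwas -----------------------------------------------------------
    if stages.get("gwas", True):
        try:
            gw = cfg["gwas"]
            genes = list(state["counts"].gene_ids)
            loci = simulate.make_gene_loci(genes)
            target = state.get("shared_up") or genes[:20]
            catalog, snp_truth = simulate.simulate_snp_catalog(
                loci, target, gw["n_background_snps"], gw["n_planted"],
                gw["max_planted_distance"],
                seed=stage_seed(seed, "gwas"), trait=gw["trait"],
            )
            deg = state.get("shared_up") or target
            prox = gwas.proximity_enrichment(
                deg, loci, catalog, gw["trait"], d_grid=th["d_grid"]
            )
            emit("gwas", "gene_loci.bed.tsv", io.write_gene_bed, loci)
            emit("gwas", "snp_catalog.bed.tsv", io.write_snp_bed, catalog)
            emit("gwas", "proximity_enrichment.tsv", io.write_table,
                 prox.table)
            emit("gwas", "nearest_snps.tsv", io.write_table,
                 prox.nearest.reset_index(drop=True))
        except Exception as exc:
            raise PipelineError("gwas", exc) from exc

    # ---- motifs ---------------------------------------------------------
    if stages.get("motifs", True):
        try:
            if state.get("truth") is None:
                raise ValueError(
                    "the demo motif stage needs simulated promoters; run "
                    "with the simulate stage enabled (real promoter FASTA "
                    "input goes through `cytoresponse motifs`)"
                )
            mo = cfg["motifs"]
            pwms = demo_motifs()
            seqs, ptruth = simulate.simulate_promoters(
                state["truth"].loc[list(state["profile"].index)],
                pwms, mo["enrichment_rate_deg"], mo["base_rate"],
                length=mo["length"], seed=stage_seed(seed, "motifs"),
            )
            io.write_fasta(seqs, os.path.join(outdir, "promoters.fa"))
            outputs.setdefault("motifs", []).append("promoters.fa")
            hits = motifs.scan_motifs(seqs, pwms,
                                      threshold_fraction=th["scan_threshold"])
            deg_ind = pd.Series(
                [g in set(state.get("shared_up", []))
                 | set(state.get("shared_down", [])) for g in hits.index],
                index=hits.index,
            )
            result = motifs.motif_logistic_enrichment(
                hits, deg_ind, gc=ptruth["gc_fraction"], fdr_max=th["fdr"]
            )
            emit("motifs", "motif_counts.tsv", io.write_table,
                 hits.rename_axis("gene_id").reset_index())
            emit("motifs", "motif_enrichment.tsv", io.write_table,
                 result.reset_index(drop=True))
        except Exception as exc:
            raise PipelineError("motifs", exc) from exc

    manifest = {
        "version": __version__, "seed": seed, "param_hash": meta["param_hash"],
        "outputs": {
            stage: {name: _sha256(os.path.join(outdir, name))
                    for name in names}
            for stage, names in outputs.items()
        },
    }
    io.write_json(manifest, os.path.join(outdir, "manifest.json"))
    return manifest
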