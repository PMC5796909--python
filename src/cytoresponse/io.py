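"""Readers and writers for the pipeline's text formats.

Everything is plain TSV (with ``#``-prefixed metadata header lines), GMT,
BED-like SNP tables or FASTA. TSV gene tables are indexed by gene_id;
coordinate tables use 0-based half-open coordinates internally (1-based TSV
input can be converted on read).
"""

from __future__ import annotations

import json

import pandas as pd

from .de import CountMatrix


def _write_tsv(df: pd.DataFrame, path, metadata=None, index=False):
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs):
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(counts: CountMatrix, path, metadata=None):
    df = counts.counts.copy()
    df.insert(0, "gene_id", df.index)
    _write_tsv(df, path, metadata)


def read_counts(path):
    df = read_tsv(path).set_index("gene_id")
    return CountMatrix(df)


def write_design(design: pd.DataFrame, path, metadata=None):
    _write_tsv(design.reset_index(drop=True), path, metadata)


def read_design(path):
    return read_tsv(path, dtype=str)


def write_table(df: pd.DataFrame, path, metadata=None):
    _write_tsv(df.reset_index(drop=True) if df.index.name else df, path,
               metadata)


def write_fasta(sequences, path, width=80):
    """Write a mapping gene_id -> sequence as FASTA."""
    items = sequences.items() if hasattr(sequences, "items") else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Read FASTA into a Series gene_id -> sequence string."""
    from Bio import SeqIO

    return pd.Series(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")},
        name="sequence",
    )


def write_gmt(gene_sets: dict, path, description=""):
    with open(path, "w") as fh:
        for set_id, genes in gene_sets.items():
            fh.write("\t".join([set_id, description or set_id, *genes]) + "\n")


def read_gmt(path):
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out


def write_snp_bed(snps: pd.DataFrame, path, metadata=None):
    """BED-like SNP table: chrom, pos0, pos1, snp_id, trait."""
    bed = pd.DataFrame({
        "chrom": snps["chrom"], "pos0": snps["pos"],
        "pos1": snps["pos"] + 1, "snp_id": snps["snp_id"],
        "trait": snps["trait"],
    })
    _write_tsv(bed, path, metadata)


def read_snp_bed(path, one_based=False):
    df = read_tsv(path)
    pos = df["pos0"].astype(int) - (1 if one_based else 0)
    return pd.DataFrame({"snp_id": df["snp_id"], "chrom": df["chrom"],
                         "pos": pos, "trait": df["trait"]})


def write_gene_bed(loci: pd.DataFrame, path, metadata=None):
    bed = loci[["chrom", "start", "end", "gene_id", "strand"]]
    _write_tsv(bed, path, metadata)


def read_gene_bed(path, one_based=False):
    df = read_tsv(path)
    start = df["start"].astype(int) - (1 if one_based else 0)
    out = pd.DataFrame({"gene_id": df["gene_id"], "chrom": df["chrom"],
                        "start": start, "end": df["end"].astype(int),
                        "strand": df.get("strand", "+")})
    return out.set_index("gene_id", drop=False)


def write_signature(signature: pd.DataFrame, path, metadata=None):
    _write_tsv(signature[["gene_id", "score"]], path, metadata)


def read_signature(path):
    return read_tsv(path).sort_values("score", ascending=False,
                                      kind="mergesort").reset_index(drop=True)


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
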