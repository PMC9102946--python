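"""Readers/writers for the pipeline's plain-text interchange formats.

Tabular data is TSV with a header row (genes/CpGs as rows, samples as
columns); genomic intervals are BED (0-based half-open); gene sets are GMT;
the truth ledger and run report are JSON.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix", "write_matrix",
    "read_conditions", "write_conditions",
    "read_genes_bed", "write_genes_bed",
    "read_cpg_bed", "write_cpg_bed",
    "read_gmt", "write_gmt",
    "read_clinical", "write_clinical",
]


def read_matrix(path) -> pd.DataFrame:
    """Gene/CpG x sample TSV matrix with an index column first."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_conditions(path) -> pd.Series:
    """Two-column TSV sample_id<TAB>condition."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_conditions(cond: pd.Series, path) -> None:
    cond.rename("condition").to_csv(path, sep="\t", index_label="sample_id")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """BED6: chrom, start, end, gene_id, score, strand.

    The gene interval is written as the single TSS base [tss, tss+1); the
    promoter window is derived downstream, not stored.
    """
    bed = pd.DataFrame(
        {
            "chrom": genes.chrom,
            "start": genes.tss,
            "end": genes.tss + 1,
            "name": genes.gene_id,
            "score": 0,
            "strand": genes.strand,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(bed_path, info_path=None) -> pd.DataFrame:
    """Read a BED6 of TSS positions (+ optional gene-info TSV with biotype)."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    genes = pd.DataFrame(
        {
            "gene_id": bed.gene_id,
            "chrom": bed.chrom,
            "strand": bed.strand,
            "tss": bed.start.astype(int),
        }
    )
    if info_path is not None:
        info = pd.read_csv(info_path, sep="\t")
        genes = genes.merge(info, on="gene_id", how="left")
    return genes


def write_cpg_bed(cpgs: pd.DataFrame, path) -> None:
    """BED4: chrom, pos, pos+1, cpg_id (positions sorted within chromosome)."""
    bed = cpgs.sort_values(["chrom", "pos"], kind="stable")
    pd.DataFrame(
        {"chrom": bed.chrom, "start": bed.pos, "end": bed.pos + 1, "name": bed.cpg_id}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_cpg_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "cpg_id"]
    )
    return pd.DataFrame(
        {"cpg_id": bed.cpg_id, "chrom": bed.chrom, "pos": bed.start.astype(int)}
    )


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    if (df.os_time < 0).any():
        raise ValueError("negative os_time in clinical table")
    return df


def write_clinical(clin: pd.DataFrame, path) -> None:
    clin.to_csv(path, sep="\t", index_label="sample_id")
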