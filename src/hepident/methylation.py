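"""Promoter hypermethylation calling from CpG beta-value matrices.

Promoter windows are the 5000 bp strictly upstream of each gene's TSS,
strand-aware and clipped at the chromosome start; CpGs are assigned to every
promoter containing them (overlaps allowed), each CpG is tested for tumor
hypermethylation (one-sided rank test on beta-values), and a promoter is
called hypermethylated when at least one of its assayed CpGs passes both an
FDR and an effect-size (delta-beta) threshold.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .consensus import bh_adjust

__all__ = [
    "promoter_regions",
    "assign_cpgs",
    "percpg_hypermethylation_test",
    "call_hypermethylated_promoters",
]


def promoter_regions(genes: pd.DataFrame, span: int = 5000) -> pd.DataFrame:
    """Strand-aware promoter windows, 0-based half-open.

    For a + strand gene with TSS t the window is [max(0, t-span), t); the TSS
    base itself is excluded.  For a - strand gene (transcribed leftward) the
    upstream span is [t+1, t+1+span).  Windows are clipped at position 0.
    """
    if span <= 0:
        raise ValueError(f"span must be > 0, got {span}")
    bad = set(genes.strand) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand value(s): {bad}")
    plus = genes.strand == "+"
    start = np.where(plus, np.maximum(0, genes.tss - span), genes.tss + 1)
    end = np.where(plus, genes.tss, genes.tss + 1 + span)
    return pd.DataFrame(
        {
            "gene_id": genes.gene_id,
            "chrom": genes.chrom,
            "start": start.astype(int),
            "end": end.astype(int),
        }
    ).reset_index(drop=True)


def assign_cpgs(
    cpgs: pd.DataFrame,
    promoters: pd.DataFrame,
    total_cpgs: dict[str, int] | None = None,
) -> dict:
    """Map CpGs into promoter windows; report per-promoter coverage.

    A CpG is assigned to *every* promoter whose window contains its position
    (overlapping promoters share CpGs).  Returns a dict with:

    * ``assignment`` — DataFrame (cpg_id, gene_id) of all containments;
    * ``coverage`` — DataFrame per gene: n_assayed, and covered_fraction
      when ``total_cpgs`` (true promoter CpG totals) is provided.
    """
    trees: dict[str, IntervalTree] = {}
    for _, p in promoters.iterrows():
        if p.end > p.start:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.gene_id)
    pairs: list[tuple[str, str]] = []
    for _, c in cpgs.iterrows():
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        for iv in tree.at(c.pos):
            pairs.append((c.cpg_id, iv.data))
    assignment = pd.DataFrame(pairs, columns=["cpg_id", "gene_id"])
    n_assayed = (
        assignment.groupby("gene_id").size()
        .reindex(promoters.gene_id, fill_value=0)
        .rename("n_assayed")
    )
    coverage = n_assayed.to_frame()
    if total_cpgs is not None:
        tot = pd.Series(total_cpgs).reindex(coverage.index)
        coverage["covered_fraction"] = coverage.n_assayed / tot
    return {"assignment": assignment, "coverage": coverage.reset_index()}


def percpg_hypermethylation_test(
    beta: pd.DataFrame,
    normal_samples: list[str],
    tumor_samples: list[str],
    paired: bool = False,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-CpG tumor-vs-normal beta comparison.

    delta_beta = mean(tumor) - mean(normal).  p-values come from the Wilcoxon
    signed-rank test (``paired=True``; columns must be pair-aligned in the
    order given) or the Mann-Whitney U test, one-sided toward
    hypermethylation by default (``alternative='greater'``; 'two-sided'
    available).  q is Benjamini-Hochberg across all tested CpGs.  CpGs with
    identical values in every sample get p = 1 with a warning.
    """
    if paired and len(normal_samples) != len(tumor_samples):
        raise ValueError("paired test requires equal-length, aligned sample lists")
    min_n = 3
    if len(normal_samples) < min_n or len(tumor_samples) < min_n:
        raise ValueError(f"need at least {min_n} samples per condition")
    bn = beta[normal_samples].to_numpy(dtype=float)
    bt = beta[tumor_samples].to_numpy(dtype=float)
    if (bn < 0).any() or (bn > 1).any() or (bt < 0).any() or (bt > 1).any():
        raise ValueError("beta-values must lie in [0, 1]")
    delta = bt.mean(axis=1) - bn.mean(axis=1)
    p = np.ones(len(beta))
    n_constant = 0
    for i in range(len(beta)):
        if paired:
            d = bt[i] - bn[i]
            if np.all(d == 0):
                n_constant += 1
                continue
            p[i] = stats.wilcoxon(d, alternative=alternative).pvalue
        else:
            if np.all(bt[i] == bt[i][0]) and np.all(bn[i] == bt[i][0]):
                n_constant += 1
                continue
            p[i] = stats.mannwhitneyu(bt[i], bn[i], alternative=alternative).pvalue
    if n_constant:
        warnings.warn(
            f"{n_constant} CpG(s) constant across all samples; p set to 1",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"delta_beta": delta, "p": p, "q": bh_adjust(p)}, index=beta.index
    )


def call_hypermethylated_promoters(
    percpg: pd.DataFrame,
    assignment: pd.DataFrame,
    alpha: float = 0.05,
    delta_min: float = 0.1,
) -> pd.DataFrame:
    """Promoter-level hypermethylation verdicts.

    A promoter is hypermethylated iff at least one assigned CpG has
    q < ``alpha`` and delta_beta >= ``delta_min``.  ``top_cpg`` is the
    smallest-q CpG among the qualifying ones (tie -> largest delta_beta,
    then cpg_id); promoters with no assayed CpGs are excluded (they were
    never testable; see the coverage report).
    """
    rows = []
    merged = assignment.merge(
        percpg, left_on="cpg_id", right_index=True, how="inner"
    )
    for gene, sub in merged.groupby("gene_id", sort=True):
        hit = sub[(sub.q < alpha) & (sub.delta_beta >= delta_min)]
        if len(hit):
            best = hit.sort_values(
                ["q", "delta_beta", "cpg_id"], ascending=[True, False, True]
            ).iloc[0]
            rows.append((gene, len(sub), True, best.cpg_id, best.delta_beta, best.q))
        else:
            rows.append((gene, len(sub), False, None, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_cpgs", "hypermethylated", "top_cpg", "top_delta_beta", "top_q"],
    ).set_index("gene_id")
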