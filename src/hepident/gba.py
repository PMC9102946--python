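"""Guilt-by-association functional prediction for a target gene.

Patients are split into high and low quartiles of the target gene's
expression, coding genes are ranked by the log2 fold change between those
two patient groups, and the ranked list is scored against gene sets with a
preranked enrichment analysis: a weighted Kolmogorov-Smirnov-like running
sum whose null distribution comes from random permutations of set
membership over the ranked list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import bh_adjust

__all__ = ["quartile_groups", "rank_by_log2fc", "enrichment_score", "gsea_preranked"]


def quartile_groups(values: pd.Series) -> tuple[list[str], list[str]]:
    """Top- and bottom-quartile sample sets of a target gene's expression.

    Returns (high, low), each of size floor(n/4); boundary ties are resolved
    deterministically by sample id.
    """
    n = len(values)
    if n < 8:
        raise ValueError(f"need at least 8 samples, got {n}")
    if np.all(values.to_numpy() == values.iloc[0]):
        raise ValueError("target gene expression is constant; quartiles undefined")
    k = n // 4
    df = pd.DataFrame({"v": values}).assign(_id=values.index)
    hi = list(df.sort_values(["v", "_id"], ascending=[False, True]).index[:k])
    lo = list(df.sort_values(["v", "_id"], ascending=[True, True]).index[:k])
    return hi, lo


def rank_by_log2fc(
    expr: pd.DataFrame, high: list[str], low: list[str]
) -> pd.DataFrame:
    """Rank genes by mean(high) - mean(low) on the log scale, descending.

    Input rows should already be restricted to coding genes.  Ties are broken
    by gene id so the order is fully deterministic.
    """
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both groups need at least 2 samples")
    if expr.shape[0] == 0:
        raise ValueError("no genes to rank")
    metric = expr[high].mean(axis=1) - expr[low].mean(axis=1)
    out = pd.DataFrame({"metric": metric})
    out = out.assign(_gene=out.index).sort_values(
        ["metric", "_gene"], ascending=[False, True]
    )[["metric"]]
    return out


def enrichment_score(
    ranked_genes: list[str] | np.ndarray,
    metric: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> float:
    """Weighted KS-like enrichment score of one gene set on a ranked list.

    Walking the list top to bottom, hits advance the running sum by
    |metric|^weight (normalized by the in-set total) and misses retreat by
    1/(N - set size); the score is the extremum (largest absolute excursion,
    sign kept).
    """
    genes = np.asarray(ranked_genes)
    hit = np.isin(genes, list(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    n = len(genes)
    if n_hit == n:
        warnings.warn("gene set spans the entire ranked list (degenerate)", stacklevel=2)
        return 1.0
    w = np.abs(np.asarray(metric, dtype=float)) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all in-set metrics zero (possible when weight > 0)
        w_hit = hit.astype(float)
        total = float(n_hit)
    step = w_hit / total - (~hit) / (n - n_hit)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(np.clip(running[i], -1.0, 1.0))


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    size: int
    leading_edge: int


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a set-membership permutation null.

    ``ranked`` is the output of :func:`rank_by_log2fc` (gene-indexed,
    'metric' column, descending).  For each set, the null redraws the set's
    positions uniformly over the list ``n_perm`` times; p is the one-sided
    tail on the observed score's side with the +1 granularity correction,
    NES divides by the mean |null score| of the matching sign, and q is
    Benjamini-Hochberg across sets.  Sets with < 2 members in the list are
    skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = np.asarray(ranked.index)
    metric = ranked["metric"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        present = set(members) & set(genes)
        if len(present) < 2:
            warnings.warn(f"set {name!r} has <2 genes in the list; skipped", stacklevel=2)
            continue
        if len(present) >= len(genes):
            warnings.warn(
                f"set {name!r} spans the entire ranked list; skipped (degenerate)",
                stacklevel=2,
            )
            continue
        es = enrichment_score(genes, metric, present, weight)
        m = len(present)
        null = np.empty(n_perm)
        w = np.abs(metric) ** weight
        n = len(genes)
        for b in range(n_perm):
            pos = rng.choice(n, size=m, replace=False)
            hit = np.zeros(n, dtype=bool)
            hit[pos] = True
            w_hit = np.where(hit, w, 0.0)
            tot = w_hit.sum()
            if tot == 0:
                w_hit = hit.astype(float)
                tot = float(m)
            step = w_hit / tot - (~hit) / (n - m)
            run = np.cumsum(step)
            null[b] = run[np.argmax(np.abs(run))]
        if es >= 0:
            same = null[null >= 0]
            p = (1 + int((null >= es).sum())) / (n_perm + 1)
        else:
            same = null[null < 0]
            p = (1 + int((null <= es).sum())) / (n_perm + 1)
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        # leading edge: hits at or before the extremum position
        hit = np.isin(genes, list(present))
        w_hit = np.where(hit, w, 0.0)
        tot = w_hit.sum() or float(m)
        step = w_hit / tot - (~hit) / (n - m)
        run = np.cumsum(step)
        peak = int(np.argmax(np.abs(run)))
        if es >= 0:
            lead = int(hit[: peak + 1].sum())
        else:
            lead = int(hit[peak:].sum())
        rows.append((name, es, nes, p, m, lead))
    out = pd.DataFrame(
        rows, columns=["set_name", "es", "nes", "p", "size", "leading_edge"]
    ).set_index("set_name")
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out
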