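"""Tissue-preference classification across a multi-organ expression panel.

A gene is *liver-preferential* when few other tissues express it at a level
comparable to liver, and *ubiquitous* when more than ``k`` non-liver tissues
do.  "Comparable" is operationalized on the linear CPM scale as at least
``ratio`` times the liver mean and above an absolute expression floor.  The
module also quantifies fetal-vs-adult liver induction for a gene set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["tissue_means", "classify_liver_preferential", "fetal_adult_contrast"]


def tissue_means(
    expr: pd.DataFrame,
    tissue_labels: pd.Series | dict,
    pooling: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene mean expression by tissue (genes x tissues).

    ``tissue_labels`` maps sample -> tissue; ``pooling`` optionally maps raw
    labels to pooled ones (e.g. LUSC/LUAD -> lung) before averaging, so the
    pooled mean is the sample-weighted mean of its members.
    """
    labels = pd.Series(tissue_labels)
    missing = [s for s in expr.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without tissue label: {missing[:5]}")
    labels = labels.loc[list(expr.columns)]
    if pooling:
        labels = labels.map(lambda t: pooling.get(t, t))
    return expr.T.groupby(labels).mean().T


def classify_liver_preferential(
    means: pd.DataFrame,
    floor: float = 1.0,
    ratio: float = 0.5,
    k: int = 3,
    liver: str = "liver",
    exclude: tuple[str, ...] = ("fetal_liver",),
) -> pd.DataFrame:
    """Label genes liver_preferential vs ubiquitous from tissue means (CPM).

    A non-liver tissue counts as expressing a gene "at a similar level" when
    its mean is >= ``floor`` and >= ``ratio`` * liver mean.  Genes with more
    than ``k`` such tissues are ubiquitous; the rest are liver-preferential.
    Genes not expressed in liver (liver mean < floor) are labeled ubiquitous
    with a warning — liver preference is undefined for them.  Columns listed
    in ``exclude`` (developmental stages, not adult organs) are ignored.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if liver not in means.columns:
        raise ValueError(f"liver column {liver!r} not in tissue means")
    others = [t for t in means.columns if t != liver and t not in exclude]
    liv = means[liver].to_numpy(dtype=float)
    other = means[others].to_numpy(dtype=float)
    similar = (other >= floor) & (other >= ratio * liv[:, None])
    n_similar = similar.sum(axis=1)
    label = np.where(n_similar > k, "ubiquitous", "liver_preferential")
    silent = liv < floor
    if silent.any():
        warnings.warn(
            f"{int(silent.sum())} gene(s) not expressed in liver; labeled ubiquitous",
            stacklevel=2,
        )
        label = np.where(silent, "ubiquitous", label)
    return pd.DataFrame(
        {
            "liver_mean": liv,
            "n_similar_tissues": n_similar,
            "label": label,
        },
        index=means.index,
    )


def fetal_adult_contrast(
    expr: pd.DataFrame,
    fetal_samples: list[str],
    adult_samples: list[str],
    gene_set: list[str] | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Per-gene fetal/adult liver log2 ratio plus rank-sum p-value.

    ratio = log2((mean fetal CPM + prior) / (mean adult CPM + prior));
    negative values mean lower fetal expression.  p from the two-sided
    Mann-Whitney U test on the per-sample values.
    """
    if len(fetal_samples) < 2 or len(adult_samples) < 2:
        raise ValueError("need at least 2 samples per stage")
    sub = expr.loc[gene_set] if gene_set is not None else expr
    f = sub[fetal_samples].to_numpy(dtype=float)
    a = sub[adult_samples].to_numpy(dtype=float)
    ratio = np.log2((f.mean(axis=1) + prior) / (a.mean(axis=1) + prior))
    p = np.ones(len(sub))
    for i in range(len(sub)):
        if np.all(f[i] == f[i][0]) and np.all(a[i] == f[i][0]):
            continue
        p[i] = stats.mannwhitneyu(f[i], a[i], alternative="two-sided").pvalue
    return pd.DataFrame({"log2_fetal_adult": ratio, "p": p}, index=sub.index)
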