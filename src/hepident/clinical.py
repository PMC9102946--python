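"""Signature scoring, patient stratification and survival analysis.

Links a gene-set expression signature (mean normalized expression across the
set) to clinical outcome: Spearman correlation against a reference
signature, extreme-k stratification (the k highest- and k lowest-scoring
patients), categorical enrichment of clinical variables between subgroups
(Fisher / chi-squared), Kaplan-Meier estimation and the log-rank test, and a
per-gene survival screen.

Kaplan-Meier and log-rank computations are delegated to lifelines.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .consensus import bh_adjust

__all__ = [
    "signature_score",
    "spearman_corr",
    "stratify_extremes",
    "categorical_enrichment",
    "km_estimate",
    "logrank_test",
    "per_gene_survival",
]

log = logging.getLogger(__name__)


def signature_score(expr: pd.DataFrame, gene_set: list[str], name: str = "signature") -> pd.Series:
    """Per-sample mean of the set's normalized expression rows."""
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError(f"no gene of set {name!r} present in the matrix")
    if len(present) < len(gene_set):
        log.warning(
            "%d/%d genes of set %s missing from matrix",
            len(gene_set) - len(present), len(gene_set), name,
        )
    s = expr.loc[present].mean(axis=0)
    s.name = name
    return s


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n (<= 10)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(rho)
    count = 0
    total = 0
    chunk: list[tuple] = []
    # vectorized Pearson-of-ranks over permutation chunks
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) == 200_000:
            perm = np.asarray(chunk)
            r = (rx_c[perm] @ ry_c) / denom
            count += int(np.sum(np.abs(r) >= obs - 1e-12))
            total += len(chunk)
            chunk = []
    if chunk:
        perm = np.asarray(chunk)
        r = (rx_c[perm] @ ry_c) / denom
        count += int(np.sum(np.abs(r) >= obs - 1e-12))
        total += len(chunk)
    return count / total


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    For n > 10 the p-value uses the t approximation; for n <= 10 an exact
    permutation enumeration over all n! rank orders.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in input; Spearman rho undefined")
    rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    n = len(x)
    if n > 10:
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    else:
        p = _spearman_exact_p(x, y, rho)
    return rho, p


def stratify_extremes(scores: pd.Series, k: int = 45) -> pd.Series:
    """Assign the k highest scores to subgroup '#1', the k lowest to '#2'.

    Middle patients stay unassigned (NaN).  Boundary ties are broken
    deterministically by sample id (with a logged note).
    """
    n = len(scores)
    if 2 * k > n:
        raise ValueError(f"2k={2*k} exceeds cohort size {n}")
    df = pd.DataFrame({"score": scores}).assign(_id=scores.index)
    hi = df.sort_values(["score", "_id"], ascending=[False, True]).index[:k]
    lo = df.sort_values(["score", "_id"], ascending=[True, True]).index[:k]
    boundary_hi = df.loc[hi, "score"].min()
    if (df.score == boundary_hi).sum() > (df.loc[hi, "score"] == boundary_hi).sum():
        log.info("ties at the high-score boundary resolved by sample id")
    sub = pd.Series(np.nan, index=scores.index, dtype=object, name="subgroup")
    sub.loc[hi] = "#1"
    sub.loc[lo] = "#2"
    return sub


def categorical_enrichment(table: pd.DataFrame | np.ndarray) -> dict:
    """Association test on an r x c contingency table.

    Uses Fisher's exact test for 2x2 tables with any expected cell < 5,
    otherwise the chi-squared test without continuity correction.  Returns
    {'statistic', 'p', 'method'} ('statistic' is the odds ratio for Fisher).
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = np.asarray(table, dtype=float)
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise ValueError("table must hold non-negative integer counts")
        arr = arr.astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    total = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    if arr.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(arr)
        return {"statistic": float(odds), "p": float(p), "method": "fisher"}
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return {"statistic": float(chi2), "p": float(p), "method": "chi2"}


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a DataFrame with columns ``time`` and ``survival`` (the step
    function value just after each distinct time), beginning at S(0) = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {list(levels)}")
    if not events.any():
        raise ValueError("no events at all; log-rank undefined")
    m = groups == levels[0]
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


def per_gene_survival(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    split: str = "median",
    k: int = 45,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Survival screen: split patients per gene, log-rank each gene.

    ``split='median'`` compares above- vs below-median expression;
    ``split='extremes_k'`` compares the k highest vs k lowest.  Genes whose
    split is ill-defined (constant expression) are skipped with a warning.
    Returns per-gene chi2, p and BH q; ``attrs['n_significant']`` counts
    genes with p < alpha.
    """
    common = [s for s in expr.columns if s in clinical.index]
    if not common:
        raise ValueError("no samples shared between expression and clinical table")
    ex = expr[common]
    cl = clinical.loc[common]
    rows, skipped = [], 0
    for gene, vals in ex.iterrows():
        if split == "median":
            med = vals.median()
            grp = np.where(vals > med, "high", "low")
            if len(np.unique(grp)) < 2:
                skipped += 1
                continue
            sel = np.ones(len(vals), dtype=bool)
        elif split == "extremes_k":
            sub = stratify_extremes(vals, k=k)
            sel = sub.notna().to_numpy()
            grp = sub[sel].to_numpy()
        else:
            raise ValueError(f"unknown split rule {split!r}")
        try:
            chi2, p = logrank_test(
                cl.os_time.to_numpy()[sel], cl.os_event.to_numpy()[sel], grp
            )
        except ValueError:
            skipped += 1
            continue
        rows.append((gene, chi2, p))
    if skipped:
        warnings.warn(f"{skipped} gene(s) skipped (ill-defined split)", stacklevel=2)
    out = pd.DataFrame(rows, columns=["gene_id", "chi2", "p"]).set_index("gene_id")
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    out.attrs["n_significant"] = int((out["p"] < alpha).sum())
    return out
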