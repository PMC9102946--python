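"""Two-group moderated-t differential expression with subsampling consensus.

The differential-expression engine is the empirical-Bayes moderated t:
gene-wise residual variances are shrunk toward a prior variance s0^2 whose
weight is a prior degrees-of-freedom d0, both estimated by matching the
moments of log residual variances to a scaled F / log-chi-square model.
This stabilizes variance estimates when each gene has few samples.

On top of it sits the consensus procedure used to call robustly
downregulated genes in an unbalanced tumor/normal cohort: R independent
subsamples of the tumor arm (all normals kept each time) are each taken
through TMM normalization, log-CPM, moderated t and Benjamini-Hochberg
adjustment, and a gene is retained only if it is significant at the FDR
threshold, in the requested direction, in *every* iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exprnorm import log_cpm, tmm_factors

__all__ = [
    "moderated_t",
    "bh_adjust",
    "subsample_consensus",
    "select_top",
    "fit_variance_prior",
    "ConsensusResult",
]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges globally for
    x > 0 (same scheme as the classical variance-moderation literature).
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to gene variances.

    Works on e_g = log(s_g^2) - psi(df/2) + log(df/2), which under the model
    has mean log(s0^2) - psi(d0/2) + log(d0/2) + ... ; the excess variance of
    e_g over trigamma(df/2) identifies d0 via the trigamma inverse, and the
    mean identifies s0^2.

    Returns (d0, s0_squared); d0 may be inf when the observed log-variances
    are under-dispersed relative to pure chi-square noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive variance")
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    e_var = float(np.var(e, ddof=1)) * (n - 1) / n - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t(
    expr: pd.DataFrame,
    groups: pd.Series | dict,
    d0_override: float | None = None,
    s0_2_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test between two groups.

    Parameters
    ----------
    expr : DataFrame, genes x samples, normalized (log-CPM) expression.
    groups : sample -> label map with exactly two levels; the log fold change
        is mean(second level) - mean(first level), levels in sorted order
        unless ``groups`` is a pandas Categorical with explicit ordering.
    d0_override, s0_2_override : force the prior df / prior variance instead
        of estimating them (d0_override=0 recovers the ordinary t-test;
        d0_override=inf requires s0_2_override or uses the estimated s0^2).

    Returns
    -------
    DataFrame indexed by gene: logfc, s2 (pooled residual variance), t, df
    (total, d0+d_g), p, q; with attrs d0, s0_2, df_residual.
    """
    g = pd.Series(groups)
    g = g.loc[[s for s in expr.columns if s in g.index]]
    if set(g.index) != set(expr.columns):
        raise ValueError("groups must label every sample in expr")
    if isinstance(g.dtype, pd.CategoricalDtype):
        levels = [l for l in g.cat.categories if (g == l).any()]
    else:
        levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    idx1 = [s for s in expr.columns if g[s] == levels[0]]
    idx2 = [s for s in expr.columns if g[s] == levels[1]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    x1 = expr[idx1].to_numpy(dtype=float)
    x2 = expr[idx2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    logfc = m2 - m1
    df_res = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_res

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 > 0:
            s0_2 = (
                float(s0_2_override)
                if s0_2_override is not None
                else fit_variance_prior(s2, df_res)[1]
            )
        else:
            s0_2 = 0.0
    else:
        d0, s0_2 = fit_variance_prior(s2, df_res)
        if s0_2_override is not None:
            s0_2 = float(s0_2_override)

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "logfc": logfc,
            "s2": s2,
            "s2_moderated": s2_mod,
            "t": t,
            "df": df_total,
            "p": p,
            "q": bh_adjust(p),
        },
        index=expr.index,
    )
    out.attrs.update(
        d0=d0, s0_2=s0_2, df_residual=df_res, group_low=levels[0], group_high=levels[1]
    )
    return out


@dataclass
class ConsensusResult:
    """Per-gene consensus retention across subsampling iterations."""

    table: pd.DataFrame  # gene-indexed: n_significant, retained, mean_logfc
    n_iterations: int
    fdr_threshold: float
    direction: str
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.Index:
        return self.table.index[self.table["retained"]]


def subsample_consensus(
    counts: pd.DataFrame,
    condition: pd.Series | dict,
    n_tumor_draw: int = 50,
    n_iterations: int = 200,
    fdr_threshold: float = 0.01,
    direction: str = "down",
    seed: int | None = None,
    normal_label: str = "normal",
    tumor_label: str = "tumor",
    prior_count: float = 0.5,
) -> ConsensusResult:
    """Repeated-subsampling consensus differential expression.

    Each of ``n_iterations`` iterations draws ``n_tumor_draw`` tumor samples
    without replacement (a fresh draw each time), keeps every normal sample,
    and runs the full pipeline on the subsampled count matrix: TMM factors,
    log-CPM, moderated t (tumor minus normal), Benjamini-Hochberg adjustment.
    A gene counts as significant in an iteration when q < ``fdr_threshold``
    and its log fold change has the requested sign (``direction`` one of
    'down', 'up', 'both').  A gene is retained only if significant in every
    iteration.

    Normalization is deliberately recomputed inside each iteration: TMM
    factors depend on which samples are present.
    """
    if direction not in ("down", "up", "both"):
        raise ValueError(f"direction must be down/up/both, got {direction!r}")
    cond = pd.Series(condition)
    tumors = [s for s in counts.columns if cond.get(s) == tumor_label]
    normals = [s for s in counts.columns if cond.get(s) == normal_label]
    if len(normals) < 2:
        raise ValueError("need at least 2 normal samples")
    if n_tumor_draw > len(tumors):
        raise ValueError(
            f"n_tumor_draw={n_tumor_draw} exceeds available tumors ({len(tumors)})"
        )
    rng = np.random.default_rng(seed)
    n_sig = np.zeros(counts.shape[0], dtype=int)
    logfc_sum = np.zeros(counts.shape[0])
    for _ in range(n_iterations):
        draw = list(rng.choice(tumors, size=n_tumor_draw, replace=False))
        cols = normals + draw
        sub = counts[cols]
        labels = pd.Series(
            [normal_label] * len(normals) + [tumor_label] * len(draw), index=cols
        )
        labels = pd.Series(
            pd.Categorical(labels, categories=[normal_label, tumor_label]),
            index=cols,
        )
        nf = tmm_factors(sub)
        expr = log_cpm(sub, nf, prior_count=prior_count)
        de = moderated_t(expr, labels)
        sig = de["q"].to_numpy() < fdr_threshold
        if direction == "down":
            sig &= de["logfc"].to_numpy() < 0
        elif direction == "up":
            sig &= de["logfc"].to_numpy() > 0
        n_sig += sig
        logfc_sum += de["logfc"].to_numpy()
    table = pd.DataFrame(
        {
            "n_significant": n_sig,
            "retained": n_sig == n_iterations,
            "mean_logfc": logfc_sum / n_iterations,
        },
        index=counts.index,
    )
    return ConsensusResult(
        table=table,
        n_iterations=n_iterations,
        fdr_threshold=fdr_threshold,
        direction=direction,
        seed=seed,
        params={"n_tumor_draw": n_tumor_draw, "prior_count": prior_count},
    )


def select_top(
    consensus: ConsensusResult,
    de_full: pd.DataFrame,
    logfc_cut: float = -3.5,
    fdr_cut: float = 0.05,
    n_top: int = 35,
) -> list[str]:
    """Top downregulated genes among the consensus-retained set.

    Keeps retained genes with full-cohort logFC < ``logfc_cut`` and
    q < ``fdr_cut``; returns the ``n_top`` most negative by logFC, ascending
    (most downregulated first), ties broken by q then gene id.  If fewer than
    ``n_top`` genes qualify, all are returned (a warning is logged, not an
    error).
    """
    import logging

    common = consensus.table.index.intersection(de_full.index)
    if len(common) != len(consensus.table) or len(common) != len(de_full):
        raise ValueError("consensus result and DE table must cover the same genes")
    cand = de_full.loc[consensus.table.loc[common, "retained"][lambda s: s].index]
    cand = cand[(cand["logfc"] < logfc_cut) & (cand["q"] < fdr_cut)]
    if len(cand) < n_top:
        logging.getLogger(__name__).warning(
            "only %d genes meet the top-set criteria (requested %d)", len(cand), n_top
        )
    order = cand.assign(_gene=cand.index).sort_values(
        ["logfc", "q", "_gene"], ascending=[True, True, True]
    )
    return list(order.index[:n_top])
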