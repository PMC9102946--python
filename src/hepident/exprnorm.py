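"""Between-sample normalization of RNA-seq count matrices.

Implements library-size computation, trimmed-mean-of-M-values (TMM) scaling
factors, and the log2 counts-per-million transform.  TMM estimates, for each
sample against a reference, a robust weighted mean of per-gene log-ratios
(M-values) after double-trimming by M and by average abundance (A), which
corrects for composition bias: a minority of highly expressed genes in one
sample would otherwise deflate the apparent expression of everything else.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["library_sizes", "tmm_factors", "log_cpm", "choose_reference"]


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Per-sample library size (column sum of raw counts).

    Parameters
    ----------
    counts : DataFrame, genes x samples, non-negative integers.

    Raises
    ------
    ValueError if the matrix is empty, has negative entries, or any sample
    has zero total count (such a sample cannot be normalized).
    """
    if counts.size == 0:
        raise ValueError("count matrix is empty")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    return lib.astype(float)


def _uq_fraction(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """75th-percentile count over library size, per sample (reference picker)."""
    uq = np.percentile(counts, 75, axis=0)
    return uq / lib


def choose_reference(counts: pd.DataFrame) -> str:
    """Pick the reference sample for TMM: the one whose upper-quartile count
    fraction is closest to the mean of those fractions across samples."""
    lib = library_sizes(counts).to_numpy()
    f = _uq_fraction(counts.to_numpy(dtype=float), lib)
    return counts.columns[int(np.argmin(np.abs(f - f.mean())))]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Unrescaled TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded (their log-ratio is
    undefined).  Double trimming keeps genes whose M rank lies in
    [trim_m, 1-trim_m] and whose A rank lies in [trim_a, 1-trim_a]; the factor
    is 2**(weighted mean of surviving M) with inverse asymptotic-variance
    (delta-method binomial) weights.
    """
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    if len(o) < 2:
        raise ValueError("fewer than 2 genes with positive counts in both samples")
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    n = len(m)
    keep = np.ones(n, dtype=bool)
    if trim_m > 0 or trim_a > 0:
        # rank-based symmetric trimming, matching the published method
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive TMM trimming")
    w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    m_k, w_k = m[keep], w[keep]
    return float(2.0 ** (np.sum(w_k * m_k) / np.sum(w_k)))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """TMM normalization factors for every sample.

    Returns a DataFrame indexed by sample with columns ``lib_size`` and
    ``tmm_factor``; factors are rescaled to geometric mean 1 so they are pure
    relative corrections on top of library size.

    Parameters
    ----------
    ref_sample : reference sample id; default picks the sample whose
        upper-quartile count fraction is closest to the across-sample mean.
    trim_m, trim_a : symmetric trim fractions on M-values and A-values,
        in [0, 0.5); (0.30, 0.05) are the method's published defaults.
        Set both to 0 to disable trimming.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    for t, name in ((trim_m, "trim_m"), (trim_a, "trim_a")):
        if not (0 <= t < 0.5):
            raise ValueError(f"{name} must be in [0, 0.5), got {t}")
    lib = library_sizes(counts)
    if ref_sample is None:
        ref_sample = choose_reference(counts)
    elif ref_sample not in counts.columns:
        raise ValueError(f"reference sample {ref_sample!r} not in matrix")
    arr = counts.to_numpy(dtype=float)
    ref_idx = counts.columns.get_loc(ref_sample)
    ref_col = arr[:, ref_idx]
    lib_arr = lib.to_numpy()
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        try:
            factors[j] = _tmm_pair(
                arr[:, j], ref_col, lib_arr[j], lib_arr[ref_idx], trim_m, trim_a
            )
        except ValueError as err:
            raise ValueError(
                f"TMM failed for sample pair ({counts.columns[j]!r}, {ref_sample!r}): {err}"
            ) from None
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return pd.DataFrame(
        {"lib_size": lib_arr, "tmm_factor": factors}, index=counts.columns
    )


def log_cpm(
    counts: pd.DataFrame,
    norm: pd.DataFrame | None = None,
    prior_count: float = 0.5,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """log2 counts-per-million with a small prior to keep zeros finite.

    x_gs = log2( (c_gs + prior) / (L_s * f_s + 2 * prior) * 1e6 ),
    where L_s * f_s is the TMM-corrected effective library size.  With
    ``use_tmm=False`` (or ``norm=None``) raw library sizes are used.
    """
    if prior_count <= 0:
        raise ValueError(f"prior_count must be > 0, got {prior_count}")
    if norm is not None and use_tmm:
        eff = norm.loc[counts.columns, "lib_size"].to_numpy() * norm.loc[
            counts.columns, "tmm_factor"
        ].to_numpy()
    elif norm is not None:
        eff = norm.loc[counts.columns, "lib_size"].to_numpy()
    else:
        eff = library_sizes(counts).to_numpy()
    x = np.log2(
        (counts.to_numpy(dtype=float) + prior_count)
        / (eff + 2.0 * prior_count)
        * 1e6
    )
    return pd.DataFrame(x, index=counts.index, columns=counts.columns)


def cpm(counts: pd.DataFrame, norm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Linear counts-per-million (no prior), optionally TMM-corrected."""
    lib = library_sizes(counts).to_numpy()
    if norm is not None:
        lib = lib * norm.loc[counts.columns, "tmm_factor"].to_numpy()
    return counts / lib * 1e6
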