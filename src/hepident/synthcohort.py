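"""Synthetic multi-omics cohorts with planted, recorded ground truth.

Emulates the statistical structure of the cohorts used to identify
methylation-silenced liver lncRNAs in hepatocellular carcinoma, so the whole
downstream pipeline can be exercised and scored without any external data:

* gene annotation (coding + lncRNA) with TSS positions and a CpG map placed
  so every gene has array-covered promoter CpGs;
* negative-binomial bulk RNA-seq counts for an unbalanced normal/tumor
  cohort, with a chosen set of lncRNAs planted as downregulated in tumors
  and a coding liver-identity signature coupled to a per-patient latent
  differentiation factor;
* paired normal/tumor promoter CpG beta-values, hypermethylated in tumors
  exactly at the planted-silenced promoters;
* a multi-tissue expression panel (12 organs + fetal liver) with planted
  liver-preferential genes;
* a clinical table whose exponential survival times are coupled to a
  per-patient signature score through a log-hazard coefficient.

Every planted effect is recorded in a :class:`TruthLedger` emitted alongside
the fixtures, so recovery can be scored exactly.

Randomness: one master seed; each generator stage derives an independent
child stream as ``default_rng(SeedSequence(master, spawn_key=(stage_idx,)))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TruthLedger",
    "generate_annotation",
    "generate_cohort_counts",
    "generate_methylation",
    "generate_tissue_panel",
    "generate_clinical",
    "emit_gene_sets",
]

PROMOTER_SPAN = 5000  # bp strictly upstream of the TSS

# spawn keys for per-stage child streams (documented scheme)
_STREAMS = {
    "annotation": 0,
    "counts": 1,
    "methylation": 2,
    "tissue": 3,
    "clinical": 4,
    "genesets": 5,
}


def _rng(seed: int | None, stage: str) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stage],))
    )


@dataclass
class TruthLedger:
    """Record of every planted effect in a synthetic fixture set."""

    seed: int | None = None
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2FC
    hyperm_promoters: dict[str, float] = field(default_factory=dict)  # gene -> delta beta
    liver_pref_genes: list[str] = field(default_factory=list)
    liver_signature_genes: list[str] = field(default_factory=list)
    hazard_coeff: float | None = None  # log-hazard per SD of signature score
    latent_identity: dict[str, float] = field(default_factory=dict)  # sample -> z

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_annotation(
    n_coding: int,
    n_lnc: int,
    genome_size: int = 50_000_000,
    n_background_cpgs: int = 500,
    cpgs_per_promoter: tuple[int, int] = (1, 4),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene annotation plus a CpG map covering every promoter.

    Returns ``(genes, cpgs)``: genes with columns gene_id, biotype, chrom,
    strand, tss (0-based); cpgs with columns cpg_id, chrom, pos (0-based),
    sorted by position.  Every gene receives at least one CpG within the
    5000 bp strictly upstream of its TSS (strand-aware) and additional
    background CpGs are placed outside all promoter windows.
    """
    if n_coding < 1 or n_lnc < 1:
        raise ValueError("n_coding and n_lnc must both be >= 1")
    n_genes = n_coding + n_lnc
    if genome_size < 20 * PROMOTER_SPAN * 2:
        raise ValueError("genome_size too small for non-degenerate TSS placement")
    rng = _rng(seed, "annotation")
    tss = np.sort(
        rng.choice(
            np.arange(PROMOTER_SPAN + 1, genome_size - PROMOTER_SPAN),
            size=n_genes,
            replace=False,
        )
    )
    strand = rng.choice(["+", "-"], size=n_genes)
    biotype = np.array(["coding"] * n_coding + ["lncRNA"] * n_lnc)
    rng.shuffle(biotype)
    gene_ids = []
    nc = nl = 0
    for b in biotype:
        if b == "coding":
            gene_ids.append(f"PC_{nc:05d}")
            nc += 1
        else:
            gene_ids.append(f"LNC_{nl:05d}")
            nl += 1
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotype,
            "chrom": "chr1",
            "strand": strand,
            "tss": tss.astype(int),
        }
    )

    # promoter CpGs: inside [tss-span, tss) for +, (tss, tss+span] for -
    rows: list[tuple[str, int]] = []
    for _, g in genes.iterrows():
        k = int(rng.integers(cpgs_per_promoter[0], cpgs_per_promoter[1] + 1))
        if g.strand == "+":
            lo, hi = max(0, g.tss - PROMOTER_SPAN), g.tss  # [lo, hi)
        else:
            lo, hi = g.tss + 1, g.tss + 1 + PROMOTER_SPAN
        pos = rng.integers(lo, hi, size=k)
        rows.extend((g.gene_id, int(p)) for p in pos)

    # background CpGs strictly outside every promoter window
    starts = np.where(
        genes.strand == "+", np.maximum(0, genes.tss - PROMOTER_SPAN), genes.tss + 1
    )
    ends = np.where(genes.strand == "+", genes.tss, genes.tss + 1 + PROMOTER_SPAN)
    bg: list[int] = []
    while len(bg) < n_background_cpgs:
        cand = rng.integers(0, genome_size, size=n_background_cpgs)
        inside = np.zeros(len(cand), dtype=bool)
        for s, e in zip(starts, ends):
            inside |= (cand >= s) & (cand < e)
        bg.extend(int(p) for p in cand[~inside])
    bg = bg[:n_background_cpgs]

    all_pos = [p for _, p in rows] + bg
    order = np.argsort(all_pos, kind="stable")
    cpgs = pd.DataFrame(
        {
            "cpg_id": [f"cg{i:08d}" for i in range(len(all_pos))],
            "chrom": "chr1",
            "pos": np.asarray(all_pos)[order],
        }
    )
    return genes, cpgs


def generate_cohort_counts(
    genes: pd.DataFrame,
    n_normal: int = 50,
    n_tumor: int = 374,
    n_planted_down: int = 35,
    logfc_range: tuple[float, float] = (-6.0, -3.5),
    dispersion: float = 0.2,
    n_signature: int = 100,
    identity_coupling: float = 1.0,
    seed: int | None = None,
    truth: TruthLedger | None = None,
) -> tuple[pd.DataFrame, pd.Series, TruthLedger]:
    """Negative-binomial tumor/normal count matrix with planted downregulation.

    Counts are NB with gene-wise log-normal baseline means, a common
    dispersion, and per-sample log-normal library-size factors.  The
    ``n_planted_down`` most highly expressed lncRNAs are planted as
    downregulated in tumors: tumor mean = normal mean * 2**logFC with logFC
    drawn uniformly from ``logfc_range``.  A per-tumor latent liver-identity
    factor z ~ N(0,1) modulates both the planted lncRNAs and a coding
    liver-signature set by ``identity_coupling`` log2 units per SD, coupling
    the two signature scores the way differentiation grade couples them in
    real tumors.

    Returns ``(counts, condition, truth)``; condition maps sample to
    'normal'/'tumor'; the ledger gains de_genes, liver_signature_genes and
    latent_identity.
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    lnc_ids = list(genes.loc[genes.biotype == "lncRNA", "gene_id"])
    coding_ids = list(genes.loc[genes.biotype == "coding", "gene_id"])
    if n_planted_down > len(lnc_ids):
        raise ValueError("n_planted_down exceeds the number of lncRNAs")
    if not (logfc_range[0] <= logfc_range[1] <= 0):
        raise ValueError("logfc_range must be non-positive (downregulation)")
    rng = _rng(seed, "counts")
    n_genes = len(genes)
    gene_ids = list(genes.gene_id)
    idx = {g: i for i, g in enumerate(gene_ids)}

    # log-normal baselines; planted genes get liver-level (high) baselines so
    # their silencing is the dominant, detectable signal
    base = np.exp(rng.normal(3.5, 1.2, size=n_genes))
    planted = list(rng.choice(lnc_ids, size=n_planted_down, replace=False))
    for g in planted:
        base[idx[g]] = np.exp(rng.normal(6.0, 0.5))
    logfc = rng.uniform(logfc_range[0], logfc_range[1], size=n_planted_down)

    signature = list(
        rng.choice(coding_ids, size=min(n_signature, len(coding_ids)), replace=False)
    )

    samples = [f"N{i:03d}" for i in range(n_normal)] + [
        f"T{i:03d}" for i in range(n_tumor)
    ]
    condition = pd.Series(
        ["normal"] * n_normal + ["tumor"] * n_tumor, index=samples, name="condition"
    )
    z = rng.normal(size=n_tumor)  # latent liver identity of each tumor

    mu = np.tile(base[:, None], (1, n_normal + n_tumor))
    for g, lf in zip(planted, logfc):
        mu[idx[g], n_normal:] *= 2.0**lf
    if identity_coupling != 0:
        # unit-mean modulation so planted means still satisfy
        # tumor mean = normal mean * 2**logFC exactly
        mod = 2.0 ** (identity_coupling * z)
        mod /= np.exp((identity_coupling * np.log(2.0)) ** 2 / 2.0)
        for g in planted:
            mu[idx[g], n_normal:] *= mod
        for g in signature:
            mu[idx[g], n_normal:] *= mod

    size_factor = np.exp(rng.normal(0.0, 0.3, size=n_normal + n_tumor))
    mu = mu * size_factor[None, :]

    r = 1.0 / dispersion  # NB size parameter; var = mu + dispersion*mu^2
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = pd.DataFrame(counts, index=gene_ids, columns=samples)

    truth = truth or TruthLedger(seed=seed)
    truth.seed = seed if truth.seed is None else truth.seed
    truth.de_genes = {g: float(lf) for g, lf in zip(planted, logfc)}
    truth.liver_signature_genes = signature
    truth.latent_identity = {s: float(v) for s, v in zip(samples[n_normal:], z)}
    return cm, condition, truth


def generate_methylation(
    genes: pd.DataFrame,
    cpgs: pd.DataFrame,
    truth: TruthLedger,
    n_pairs: int = 50,
    base_beta: float = 0.3,
    delta_beta_range: tuple[float, float] = (0.2, 0.4),
    precision: float = 30.0,
    hyper_genes: list[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str], TruthLedger]:
    """Paired normal/tumor promoter beta-values with planted hypermethylation.

    Beta-values are drawn from a Beta distribution parameterized by mean and
    precision (mean*precision, (1-mean)*precision), which reproduces the
    spread of methylation-array beta-values.  For each planted-silenced
    lncRNA (default: every gene in ``truth.de_genes``; override with
    ``hyper_genes``) all promoter CpGs get their tumor mean shifted up by a
    planted delta-beta drawn from ``delta_beta_range``; all other CpGs share
    tumor/normal means.

    Returns ``(beta, pairing, truth)``: beta is CpG x sample with columns
    ``Pnnn_N`` / ``Pnnn_T``; pairing maps each normal column to its tumor
    column; the ledger gains ``hyperm_promoters``.
    """
    lo, hi = delta_beta_range
    if not (0 <= base_beta <= 1) or base_beta + hi > 1 or base_beta + lo < 0:
        raise ValueError("base_beta + delta_beta must stay inside [0, 1]")
    if precision <= 0:
        raise ValueError("precision must be > 0")
    rng = _rng(seed, "methylation")

    if hyper_genes is None:
        hyper_genes = sorted(truth.de_genes)
    known = set(genes.gene_id)
    missing = [g for g in hyper_genes if g not in known]
    if missing:
        raise ValueError(f"hyper_genes not in annotation: {missing}")

    from .methylation import promoter_regions, assign_cpgs

    promoters = promoter_regions(genes)
    assignment = assign_cpgs(cpgs, promoters)["assignment"]
    hyper_cpgs: set[str] = set()
    for g in hyper_genes:
        hyper_cpgs |= set(assignment.loc[assignment.gene_id == g, "cpg_id"])

    n_cpg = len(cpgs)
    # per-CpG baseline mean jitters around base_beta (clipped away from 0/1)
    mean_n = np.clip(
        base_beta + rng.normal(0.0, 0.05, size=n_cpg), 0.02, 0.98 - hi
    )
    delta = np.zeros(n_cpg)
    is_hyper = cpgs.cpg_id.isin(hyper_cpgs).to_numpy()
    delta[is_hyper] = rng.uniform(lo, hi, size=int(is_hyper.sum()))
    mean_t = np.clip(mean_n + delta, 0.01, 0.99)

    def draw(means: np.ndarray, n_cols: int) -> np.ndarray:
        a = means[:, None] * precision
        b = (1.0 - means[:, None]) * precision
        return np.clip(rng.beta(a, b, size=(len(means), n_cols)), 0.0, 1.0)

    beta_n = draw(mean_n, n_pairs)
    beta_t = draw(mean_t, n_pairs)
    cols_n = [f"P{i:03d}_N" for i in range(n_pairs)]
    cols_t = [f"P{i:03d}_T" for i in range(n_pairs)]
    beta = pd.DataFrame(
        np.hstack([beta_n, beta_t]),
        index=list(cpgs.cpg_id),
        columns=cols_n + cols_t,
    )
    pairing = dict(zip(cols_n, cols_t))

    gene_delta: dict[str, float] = {}
    for g in hyper_genes:
        cg = assignment.loc[assignment.gene_id == g, "cpg_id"]
        if len(cg):
            sel = cpgs.cpg_id.isin(cg).to_numpy()
            gene_delta[g] = float(delta[sel].mean())
    truth.hyperm_promoters = gene_delta
    return beta, pairing, truth


def generate_tissue_panel(
    genes: pd.DataFrame,
    truth: TruthLedger,
    tissues: list[str] | None = None,
    n_reps: int = 20,
    n_fetal: int = 5,
    liver_ratio: float = 8.0,
    fetal_reduction: float = 8.0,
    dispersion: float = 0.2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, TruthLedger]:
    """Multi-tissue count panel with planted liver-preferential genes.

    The panel covers ``tissues`` (must include 'liver'; default a 12-organ
    list) with ``n_reps`` replicates each, plus ``n_fetal`` fetal-liver
    columns.  Planted liver-preferential genes (default: the planted-DE
    lncRNAs) have liver mean ``liver_ratio`` times their mean elsewhere and
    are reduced ``fetal_reduction``-fold in fetal liver relative to adult
    liver.  Ubiquitous genes are expressed at comparable level in a random
    >=4-tissue subset including liver.
    """
    if tissues is None:
        tissues = [
            "liver",
            "lung",
            "breast",
            "kidney",
            "prostate",
            "stomach",
            "uterus",
            "thyroid",
            "colon",
            "head_neck",
            "pancreas",
            "bladder",
        ]
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    if "liver" not in tissues:
        raise ValueError("tissue panel must include 'liver'")
    rng = _rng(seed, "tissue")
    gene_ids = list(genes.gene_id)
    n_genes = len(gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}

    liver_pref = sorted(truth.de_genes) if truth.de_genes else []
    if not liver_pref:
        liver_pref = list(
            rng.choice(
                genes.loc[genes.biotype == "lncRNA", "gene_id"],
                size=min(10, (genes.biotype == "lncRNA").sum()),
                replace=False,
            )
        )
    truth.liver_pref_genes = liver_pref

    base = np.exp(rng.normal(3.5, 1.0, size=n_genes))
    non_liver = [t for t in tissues if t != "liver"]
    mu = np.zeros((n_genes, len(tissues)))
    t_index = {t: j for j, t in enumerate(tissues)}
    for g in gene_ids:
        i = idx[g]
        if g in liver_pref:
            mu[i, t_index["liver"]] = base[i] * liver_ratio
            mu[i, [t_index[t] for t in non_liver]] = base[i]
        else:
            # ubiquitous: liver plus a random >=4 of the other tissues
            k = int(rng.integers(4, len(non_liver) + 1))
            chosen = rng.choice(non_liver, size=k, replace=False)
            mu[i, t_index["liver"]] = base[i]
            for t in chosen:
                mu[i, t_index[t]] = base[i] * float(rng.uniform(0.7, 1.4))
            for t in non_liver:
                if t not in chosen:
                    mu[i, t_index[t]] = base[i] * 0.02  # effectively off
    fetal_mu = mu[:, t_index["liver"]].copy()
    for g in liver_pref:
        fetal_mu[idx[g]] /= fetal_reduction

    cols, labels, blocks = [], [], []
    r = 1.0 / dispersion
    for t in tissues:
        m = np.tile(mu[:, t_index[t]][:, None], (1, n_reps))
        blocks.append(rng.negative_binomial(r, r / (r + np.maximum(m, 1e-8))))
        cols += [f"{t}_{i:02d}" for i in range(n_reps)]
        labels += [t] * n_reps
    m = np.tile(fetal_mu[:, None], (1, n_fetal))
    blocks.append(rng.negative_binomial(r, r / (r + np.maximum(m, 1e-8))))
    cols += [f"fetal_liver_{i:02d}" for i in range(n_fetal)]
    labels += ["fetal_liver"] * n_fetal

    panel = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=cols)
    return panel, pd.Series(labels, index=cols, name="tissue"), truth


def generate_clinical(
    scores: pd.Series,
    gamma: float = -0.7,
    censor_rate: float = 0.3,
    baseline_hazard: float = 1.0 / 1000.0,
    grade_coupling: float = 1.0,
    seed: int | None = None,
    truth: TruthLedger | None = None,
) -> tuple[pd.DataFrame, TruthLedger | None]:
    """Clinical table with survival coupled to a signature score.

    Survival times are exponential with hazard h0 * exp(gamma * z) where z is
    the standardized score, so gamma < 0 means high score -> longer survival.
    Censoring times are uniform on (0, tau) with tau solved so the expected
    censored fraction equals ``censor_rate``.  Histological grade (G1..G4)
    and pathological stage (T1..T4) are drawn from an ordinal latent
    -grade_coupling*z + noise, making low scores enrich for high grades.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    rng = _rng(seed, "clinical")
    z = (scores - scores.mean()) / scores.std(ddof=0)
    n = len(scores)
    hazard = baseline_hazard * np.exp(gamma * z.to_numpy())
    t_event = rng.exponential(1.0 / hazard)

    if censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=bool)
    else:
        # solve E[P(C < T)] = censor_rate for C ~ U(0, tau):
        # P(censor) = mean over subjects of (1 - min(T, tau)/tau ... ) exact:
        # P(C < t) = min(t, tau)/tau
        def frac(tau: float) -> float:
            return float(np.mean(np.minimum(t_event, tau) / tau))

        lo, hi = 1e-6, float(t_event.max()) * 100
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
        c = rng.uniform(0, tau, size=n)
        event = t_event <= c
        time = np.minimum(t_event, c)

    latent = -grade_coupling * z.to_numpy() + rng.normal(size=n)
    cuts = np.quantile(latent, [0.25, 0.5, 0.85])
    grade = np.array(["G1", "G2", "G3", "G4"])[np.searchsorted(cuts, latent)]
    latent_s = -grade_coupling * z.to_numpy() + rng.normal(size=n)
    cuts_s = np.quantile(latent_s, [0.5, 0.8, 0.95])
    stage = np.array(["T1", "T2", "T3", "T4"])[np.searchsorted(cuts_s, latent_s)]

    clin = pd.DataFrame(
        {
            "sample_id": scores.index,
            "os_time": time,
            "os_event": event.astype(int),
            "grade": grade,
            "stage": stage,
        }
    ).set_index("sample_id")
    if truth is not None:
        truth.hazard_coeff = float(gamma)
    return clin, truth


def emit_gene_sets(
    truth: TruthLedger,
    genes: pd.DataFrame,
    n_random: int = 50,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Toy gene sets for enrichment tests: the planted coding liver-identity
    signature (genuinely co-regulated with the planted lncRNAs) and a random
    coding set of comparable size (a negative control)."""
    rng = _rng(seed if seed is not None else 0, "genesets")
    coding = [g for g in genes.loc[genes.biotype == "coding", "gene_id"]]
    pool = [g for g in coding if g not in set(truth.liver_signature_genes)]
    rand = list(rng.choice(pool, size=min(n_random, len(pool)), replace=False))
    return {
        "LIVER_IDENTITY_COREG": list(truth.liver_signature_genes),
        "RANDOM_CONTROL": rand,
    }
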