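"""End-to-end orchestration of the lncRNA silencing analysis.

Runs, in dependency order: cohort synthesis (or loading), TMM + log-CPM
normalization, subsampling consensus differential expression, top-set
selection, promoter methylation calling, tissue-preference classification,
clinical/survival analysis, and guilt-by-association enrichment for the
top-ranked lncRNA.  Every stage writes its outputs as plain-text files and
the run finishes with a machine-readable JSON report (parameter echo, input
hashes, stage timings, warnings) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .clinical import (
    categorical_enrichment,
    logrank_test,
    km_estimate,
    per_gene_survival,
    signature_score,
    spearman_corr,
    stratify_extremes,
)
from .consensus import moderated_t, select_top, subsample_consensus
from .exprnorm import cpm, log_cpm, tmm_factors
from .gba import gsea_preranked, quartile_groups, rank_by_log2fc
from .methylation import (
    assign_cpgs,
    call_hypermethylated_promoters,
    percpg_hypermethylation_test,
    promoter_regions,
)
from .synthcohort import (
    TruthLedger,
    emit_gene_sets,
    generate_annotation,
    generate_clinical,
    generate_cohort_counts,
    generate_methylation,
    generate_tissue_panel,
)
from .tissue import classify_liver_preferential, tissue_means

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthesis": {
        "n_coding": 1800,
        "n_lnc": 200,
        "n_normal": 50,
        "n_tumor": 374,
        "n_planted_down": 35,
        "logfc_range": [-6.0, -3.5],
        "dispersion": 0.2,
        "n_pairs": 50,
        "base_beta": 0.3,
        "delta_beta_range": [0.2, 0.4],
        "gamma": -0.7,
        "censor_rate": 0.3,
    },
    "consensus": {
        "n_tumor_draw": 50,
        "n_iterations": 200,
        "fdr_threshold": 0.01,
        "direction": "down",
    },
    "top_set": {"logfc_cut": -3.5, "fdr_cut": 0.05, "n_top": 35},
    "methylation": {"span": 5000, "paired": True, "alpha": 0.05, "delta_min": 0.1},
    "tissue": {"floor": 1.0, "ratio": 0.5, "k": 3},
    "clinical": {"k": 45},
    "gba": {"n_perm": 1000, "weight": 1.0},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def synthesize_cohort(config: dict, out_dir: Path) -> dict[str, Path]:
    """Generate the full synthetic fixture set and write it to ``out_dir``."""
    config = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = config["synthesis"]
    seed = config["seed"]
    genes, cpgs = generate_annotation(p["n_coding"], p["n_lnc"], seed=seed)
    counts, cond, truth = generate_cohort_counts(
        genes,
        n_normal=p["n_normal"],
        n_tumor=p["n_tumor"],
        n_planted_down=p["n_planted_down"],
        logfc_range=tuple(p["logfc_range"]),
        dispersion=p["dispersion"],
        seed=seed,
    )
    beta, pairing, truth = generate_methylation(
        genes, cpgs, truth,
        n_pairs=p["n_pairs"],
        base_beta=p["base_beta"],
        delta_beta_range=tuple(p["delta_beta_range"]),
        seed=seed,
    )
    panel, labels, truth = generate_tissue_panel(genes, truth, seed=seed)

    # signature score on tumor samples drives survival
    nf = tmm_factors(counts)
    expr = log_cpm(counts, nf)
    tumors = cond.index[cond == "tumor"]
    score = signature_score(expr[tumors], sorted(truth.de_genes), name="top_set")
    clin, truth = generate_clinical(
        score, gamma=p["gamma"], censor_rate=p["censor_rate"], seed=seed, truth=truth
    )
    sets = emit_gene_sets(truth, genes, seed=seed)

    paths = {
        "counts": out_dir / "counts.tsv",
        "conditions": out_dir / "conditions.tsv",
        "genes_bed": out_dir / "genes.bed",
        "gene_info": out_dir / "gene_info.tsv",
        "cpg_bed": out_dir / "cpg.bed",
        "beta": out_dir / "beta.tsv",
        "pairing": out_dir / "pairing.tsv",
        "tissue_panel": out_dir / "tissue_panel.tsv",
        "tissue_labels": out_dir / "tissue_labels.tsv",
        "clinical": out_dir / "clinical.tsv",
        "gene_sets": out_dir / "sets.gmt",
        "truth": out_dir / "truth.json",
    }
    hio.write_matrix(counts, paths["counts"])
    hio.write_conditions(cond, paths["conditions"])
    hio.write_genes_bed(genes, paths["genes_bed"])
    genes[["gene_id", "biotype"]].to_csv(paths["gene_info"], sep="\t", index=False)
    hio.write_cpg_bed(cpgs, paths["cpg_bed"])
    hio.write_matrix(beta, paths["beta"], float_format="%.6f")
    pd.Series(pairing, name="tumor").to_csv(
        paths["pairing"], sep="\t", index_label="normal"
    )
    hio.write_matrix(panel, paths["tissue_panel"])
    labels.to_csv(paths["tissue_labels"], sep="\t", index_label="sample_id")
    hio.write_clinical(clin, paths["clinical"])
    hio.write_gmt(sets, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "hepident_run",
    synthesize: bool = True,
    inputs: dict[str, Path] | None = None,
) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON).

    With ``synthesize=True`` the synthetic cohort is generated under
    ``out_dir/cohort`` first; otherwise ``inputs`` must point at existing
    fixture files (same keys as :func:`synthesize_cohort` returns).
    """
    config = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config, "stages": {}, "outputs": {}, "warnings": []}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**extra):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **extra
            }
            log.info("stage %s done (%.2fs)", name, report["stages"][name]["seconds"])

        return done

    # ---- inputs -----------------------------------------------------------
    end = stage("inputs")
    if synthesize:
        inputs = synthesize_cohort(config, out_dir / "cohort")
    if inputs is None:
        raise ValueError("synthesize=False requires explicit input paths")
    counts = hio.read_matrix(inputs["counts"]).astype(int)
    cond = hio.read_conditions(inputs["conditions"])
    genes = hio.read_genes_bed(inputs["genes_bed"], inputs.get("gene_info"))
    cpgs = hio.read_cpg_bed(inputs["cpg_bed"])
    beta = hio.read_matrix(inputs["beta"])
    pairing = pd.read_csv(inputs["pairing"], sep="\t", index_col=0)["tumor"]
    panel = hio.read_matrix(inputs["tissue_panel"]).astype(int)
    tissue_labels = pd.read_csv(inputs["tissue_labels"], sep="\t", index_col=0)["tissue"]
    clinical_path = inputs.get("clinical")
    clin = hio.read_clinical(clinical_path) if clinical_path and Path(clinical_path).exists() else None
    gene_sets = hio.read_gmt(inputs["gene_sets"]) if "gene_sets" in inputs else {}
    if set(counts.columns) != set(cond.index):
        raise ValueError("sample ids in counts and conditions do not match")
    report["inputs"] = {
        k: {"path": str(v), "sha256": _sha256(Path(v)) if Path(v).exists() else None}
        for k, v in inputs.items()
    }
    end()

    # ---- normalization ----------------------------------------------------
    end = stage("normalization")
    nf = tmm_factors(counts)
    expr = log_cpm(counts, nf)
    hio.write_matrix(nf, out_dir / "factors.tsv", float_format="%.6f")
    hio.write_matrix(expr, out_dir / "logcpm.tsv", float_format="%.4f")
    end()

    # ---- consensus DE + top set ------------------------------------------
    end = stage("consensus_de")
    cc = config["consensus"]
    cons = subsample_consensus(
        counts, cond,
        n_tumor_draw=cc["n_tumor_draw"],
        n_iterations=cc["n_iterations"],
        fdr_threshold=cc["fdr_threshold"],
        direction=cc["direction"],
        seed=config["seed"],
    )
    cond_cat = pd.Series(
        pd.Categorical(cond, categories=["normal", "tumor"]), index=cond.index
    )
    de_full = moderated_t(expr, cond_cat)
    ts = config["top_set"]
    top = select_top(cons, de_full, ts["logfc_cut"], ts["fdr_cut"], ts["n_top"])
    out = cons.table.join(de_full[["logfc", "p", "q"]])
    hio.write_matrix(out, out_dir / "consensus.tsv", float_format="%.5g")
    (out_dir / "top_set.txt").write_text("\n".join(top) + "\n")
    end(n_retained=int(cons.table.retained.sum()), n_top=len(top))

    # ---- promoter methylation --------------------------------------------
    end = stage("methylation")
    mc = config["methylation"]
    proms = promoter_regions(genes, span=mc["span"])
    asg = assign_cpgs(cpgs, proms)
    normals = list(pairing.index)
    tumors_m = list(pairing.values)
    percpg = percpg_hypermethylation_test(beta, normals, tumors_m, paired=mc["paired"])
    calls = call_hypermethylated_promoters(
        percpg, asg["assignment"], alpha=mc["alpha"], delta_min=mc["delta_min"]
    )
    top_calls = calls.loc[calls.index.intersection(top)]
    hio.write_matrix(calls, out_dir / "promoter_calls.tsv", float_format="%.5g")
    end(
        n_hypermethylated=int(calls.hypermethylated.sum()),
        n_top_hypermethylated=int(top_calls.hypermethylated.sum()),
    )

    # ---- tissue atlas -----------------------------------------------------
    end = stage("tissue")
    tc = config["tissue"]
    panel_nf = tmm_factors(panel)
    panel_cpm = cpm(panel, panel_nf)
    means = tissue_means(panel_cpm, tissue_labels)
    profile = classify_liver_preferential(
        means, floor=tc["floor"], ratio=tc["ratio"], k=tc["k"]
    )
    hio.write_matrix(profile, out_dir / "tissue_profile.tsv", float_format="%.4g")
    top_profile = profile.loc[profile.index.intersection(top)]
    end(
        n_liver_preferential=int((profile.label == "liver_preferential").sum()),
        n_top_liver_preferential=int(
            (top_profile.label == "liver_preferential").sum()
        ),
    )

    # ---- clinical ---------------------------------------------------------
    clinical_report: dict = {}
    end = stage("clinical")
    if clin is not None and len(top):
        tumors = [s for s in expr.columns if cond[s] == "tumor" and s in clin.index]
        score = signature_score(expr[tumors], top, name="top_set")
        liver_sig = gene_sets.get("LIVER_IDENTITY_COREG", [])
        if liver_sig:
            ref_score = signature_score(expr[tumors], liver_sig, name="liver_identity")
            rho, rho_p = spearman_corr(score.to_numpy(), ref_score.to_numpy())
            clinical_report["spearman_rho"] = rho
            clinical_report["spearman_p"] = rho_p
        sub = stratify_extremes(score, k=config["clinical"]["k"])
        assigned = sub.dropna()
        cl = clin.loc[assigned.index]
        chi2, p = logrank_test(cl.os_time, cl.os_event, assigned.to_numpy())
        clinical_report["logrank_chi2"] = chi2
        clinical_report["logrank_p"] = p
        km_rows = []
        for grp in ("#1", "#2"):
            ids = assigned.index[assigned == grp]
            km = km_estimate(clin.loc[ids, "os_time"], clin.loc[ids, "os_event"])
            km["group"] = grp
            km_rows.append(km)
        pd.concat(km_rows).to_csv(out_dir / "km_curves.tsv", sep="\t", index=False)
        grade_tab = pd.crosstab(
            clin.loc[assigned.index, "grade"].isin(["G3", "G4"]), assigned
        )
        clinical_report["grade_enrichment"] = categorical_enrichment(grade_tab)
        surv = per_gene_survival(expr.loc[top, tumors], clin, split="median")
        hio.write_matrix(surv, out_dir / "per_gene_survival.tsv", float_format="%.5g")
        clinical_report["n_survival_significant"] = surv.attrs["n_significant"]
        sub.to_csv(out_dir / "subgroups.tsv", sep="\t", index_label="sample_id")
        score.rename("score").to_csv(out_dir / "scores.tsv", sep="\t", index_label="sample_id")
    else:
        report["warnings"].append("clinical table absent; survival stages skipped")
    end(**{k: v for k, v in clinical_report.items() if not isinstance(v, dict)})
    report["clinical"] = clinical_report

    # ---- guilt by association --------------------------------------------
    end = stage("gba")
    gba_report: dict = {}
    if len(top) and gene_sets:
        tumors = [s for s in expr.columns if cond[s] == "tumor"]
        target = top[0]
        hi, lo = quartile_groups(expr.loc[target, tumors])
        coding = genes.loc[genes.get("biotype", "coding") == "coding", "gene_id"]
        ranked = rank_by_log2fc(expr.loc[expr.index.intersection(coding)], hi, lo)
        gsea = gsea_preranked(
            ranked, gene_sets,
            weight=config["gba"]["weight"],
            n_perm=config["gba"]["n_perm"],
            seed=config["seed"],
        )
        hio.write_matrix(gsea, out_dir / "gba.tsv", float_format="%.5g")
        gba_report = {"target": target, "sets": gsea[["es", "nes", "p", "q"]].to_dict("index")}
    end()
    report["gba"] = gba_report

    report_path = out_dir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    report["outputs"]["report"] = str(report_path)
    return report
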