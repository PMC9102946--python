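# Methods

## Scope and model

`hepident` implements the statistical chain used to identify lncRNAs
robustly silenced in hepatocellular carcinoma and to connect their
silencing to promoter DNA hypermethylation, liver identity and patient
outcome. The package treats the chain as five cooperating stages
(normalization → consensus differential expression → methylation calling →
tissue classification → clinical/enrichment analysis) plus a synthetic
cohort generator that provides every input with planted, recorded ground
truth. All coordinates are 0-based, half-open.

## Normalization

Between-sample scaling uses trimmed mean of M-values (TMM). For sample *s*
against reference *r*, over genes with positive counts in both,
M_g = log2((c_gs/L_s)/(c_gr/L_r)) and A_g = ½·log2((c_gs/L_s)(c_gr/L_r));
genes are double-trimmed by rank (30% on M, 5% on A — the method's
published defaults; the analysis names only the method, not the trims) and
the factor is 2 raised to the inverse-asymptotic-variance weighted mean of
the surviving M. The reference defaults to the sample whose upper-quartile
count fraction is closest to the across-sample mean; factors are rescaled
to geometric mean 1. Expression is log2 CPM with a prior count
(default 0.5, configurable; the source analysis does not state its
offset): x = log2((c + p)/(L·f + 2p)·10⁶). Genes with a zero count in
either member of a pair are excluded from factor estimation but still
receive expression values. A flag switches between TMM-corrected and raw
library sizes for the CPM denominator, since the original figure-level
choice is not recoverable.

## Consensus differential expression

The DE engine is the moderated *t* on log-CPM (trend-free, no observation
weights — the simplest faithful member of the cited workflow family, kept
behind a function boundary so a weighted variant could be swapped in).
Pooled per-gene variances s²_g with d_g = n₁+n₂−2 are shrunk toward a
prior: the moments of e_g = log s²_g − ψ(d_g/2) + log(d_g/2) identify the
prior degrees of freedom d₀ through the trigamma inverse (Newton
iteration) and the prior variance s₀² through the mean; then
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) and t̃_g is referred to a t
distribution on d₀+d_g df. If the observed log-variances are
under-dispersed relative to pure chi-square noise the estimator returns
d₀ = ∞ (all genes share s₀²; the statistic becomes z-like). d₀ = 0
recovers the ordinary two-sample t exactly.

Consensus retention repeats the whole chain (TMM → log-CPM → moderated t →
BH) on R = 200 subsamples: each draws 50 tumors without replacement
(fresh, independent draws) and keeps all normals. Normalization is
recomputed inside each iteration because factors depend on the samples
present. A gene is retained only when q < 0.01 with the required sign in
all R iterations — an intersection rule, so the retained set is a subset
of every iteration's significant set and non-increasing in R. The final
top set filters retained genes at full-cohort logFC < −3.5 and q < 0.05
and returns the 35 most negative (ties by q, then gene id). Both the
full-cohort and iteration-averaged fold changes are emitted, since the
original ranking's provenance between the two is unstated.

## Promoter methylation

Promoters span the 5 000 bp strictly upstream of the TSS: [t−5000, t) on
the + strand, [t+1, t+5001) on the − strand, clipped at position 0; the
TSS base itself is excluded, reading "upstream" literally. CpGs are
assigned to every promoter containing them (no unique-assignment rule is
imposed; overlapping promoters share CpGs), via an interval tree with a
brute-force overlap scan as the test oracle. Per CpG, Δβ is the tumor
minus normal mean and the p-value comes from a one-sided
(toward hypermethylation) Wilcoxon signed-rank test when samples are
paired, Mann–Whitney U otherwise; both modes exist because the original
paired-cohort analysis does not state which was used. BH adjustment runs
across all tested CpGs. A promoter is called hypermethylated when at least
one assigned CpG has q < α (default 0.05) and Δβ ≥ δ_min (default 0.1) —
conventional methylation-array practice; the source states neither test
nor threshold. Calling is monotone: lowering α or raising δ_min never adds
a call. Promoters without assayed CpGs are excluded from testing but kept
in the coverage report.

## Tissue classification

"Expressed at a similar level" is operationalized on the linear CPM scale:
non-liver tissue *t* counts when μ_gt ≥ τ (floor, default CPM 1) and
μ_gt ≥ r·μ_g,liver (default r = 0.5). A gene is ubiquitous when more than
k = 3 such tissues exist, liver-preferential otherwise; genes silent in
liver are labeled ubiquitous with a warning (preference is undefined for
them). The rule is monotone in r by construction. Tissue pooling (e.g. two
lung cohorts into "lung") is configuration, not hard-coded names. The
fetal/adult contrast reports log2((fetal mean + p)/(adult mean + p)) with
a two-sided rank-sum p per gene.

## Clinical outcome

Signature scores are arithmetic means of a gene set's normalized
expression per sample. Spearman's rho is the Pearson correlation of
mid-ranks; p is exact (full permutation enumeration, vectorized in
chunks) for n ≤ 10 and the t approximation above. Extreme-k
stratification takes the k highest (#1) and k lowest (#2) scores, ties
broken deterministically by sample id. Contingency tables use Fisher's
exact test for 2×2 tables with any expected cell < 5 and chi-squared
without continuity correction otherwise, matching the named tests with a
standard sparsity rule. Kaplan–Meier curves and the log-rank test are
computed with lifelines; hand-computed product-limit and
observed-minus-expected examples serve as test oracles. The per-gene
survival screen splits at the median by default (the rule behind the
original per-gene web analysis is unstated; extremes-k is available and
the rule is always reported); constant genes are skipped with a warning.

## Guilt-by-association enrichment

Patients split at the target lncRNA's top/bottom expression quartiles
(⌊n/4⌋ each); coding genes are ranked by the plain group-mean log2 fold
change — deliberately not a moderated statistic, following the described
procedure. The enrichment score is the signed extremum of a running sum
that advances |metric|^w (w = 1 default, normalized over the in-set total)
on hits and retreats 1/(N−m) on misses. The null permutes set membership
over list positions (the preranked convention — the ranked list, not the
phenotype, is the interface); p is one-sided on the observed sign with the
+1 granularity correction, NES divides by the mean |null| of matching
sign, and q is BH across sets. Sets absent from the list, or spanning it
entirely, are skipped with warnings. One structural caveat documented by
the tests: when a co-regulated set occupies a large fraction of a small
ranked list, disjoint "random" sets are genuinely depleted (negative ES) —
a zero-sum property of the running sum, visible only at toy scale.

## Synthetic cohorts and what they do (not) show

The generator emulates the statistical structure of the real cohorts so
the pipeline can be validated without downloads:

* **Counts** are negative-binomial with log-normal baselines
  (log-mean 3.5, sd 1.2), a shared dispersion (0.2 — typical bulk RNA-seq
  overdispersion), and log-normal per-sample library factors (sd 0.3).
  Planted silenced lncRNAs get liver-level baselines (log-mean 6) and
  tumor mean = normal mean × 2^logFC with logFC uniform on [−6, −3.5].
  A per-tumor latent liver-identity factor z ~ N(0,1) modulates planted
  lncRNAs and a 100-gene coding liver signature by 1 log2 unit per SD;
  the modulation is normalized to unit mean so planted fold changes are
  preserved exactly on the mean scale.
* **β-values** are Beta-distributed with mean/precision parameterization
  (precision 30, reproducing methylation-array spread), baseline mean 0.3;
  planted promoters' tumor means shift by Δβ ∈ [0.2, 0.4].
* **Tissue panel**: 12 organs × 20 replicates plus 5 fetal-liver columns;
  liver-preferential genes at 8× liver enrichment and 8× fetal reduction;
  ubiquitous genes expressed in liver plus ≥ 4 random other organs.
* **Survival** is exponential with hazard h₀·exp(γ·z_score), γ = −0.7 per
  SD of the signature score; censoring is uniform on (0, τ) with τ solved
  by bisection so the expected censored fraction matches the requested
  rate (0.3 default); grade and stage derive from an ordinal latent with
  slope −z.

One master seed drives everything; each stage uses an independent child
stream (`SeedSequence(master, spawn_key=(stage,))`), so fixture sets are
byte-reproducible. The dispersion, β precision and coupling strengths are
realistic stand-ins, not estimates of any real cohort: passing recovery
tests demonstrates the pipeline's correctness and operating
characteristics under the stated model, not performance on real tumors,
which add per-gene dispersion, batch structure, cell-type mixture and
annotation error that the generator deliberately omits.

## Numerical choices and problem sizes

Trigamma inversion iterates Newton from 0.5 + 1/x with closed-form tails;
degenerate variance inputs fall back to d₀ = ∞. Zero-variance genes stay
testable whenever s₀² > 0. Constant CpGs/genes get p = 1 or are skipped,
always with warnings. The test suite and the acceptance script run the
consensus stage at the full default geometry (50 + 374 samples, 2 000
genes, R = 200), FDR-control nulls at 500 datasets × 1 000 genes, the
log-rank type-I study at 500–1 000 cohorts of 120 patients, and
permutation nulls at 1 000–2 000 draws; these sizes were chosen as the
smallest that make the Monte-Carlo error visibly smaller than the margins
being checked.

## Known limitations

No voom-style observation weights or per-gene dispersion modeling; no
multi-factor or paired DE designs; no Cox regression or multivariable
adjustment; no DMR segmentation or M-value statistics; leading-edge genes
are counted, not listed. The CLI reads uncompressed TSV/BED/GMT only.
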