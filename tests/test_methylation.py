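"""Promoter windows, CpG assignment, hypermethylation testing and calling."""

import numpy as np
import pandas as pd
import pytest

from hepident.methylation import (
    assign_cpgs,
    call_hypermethylated_promoters,
    percpg_hypermethylation_test,
    promoter_regions,
)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "chrom", "strand", "tss"])


class TestPromoterRegions:
    def test_plus_strand_boundary(self):
        g = _genes([("g", "lncRNA", "chr1", "+", 10_000)])
        pr = promoter_regions(g, span=5000)
        assert (pr.start[0], pr.end[0]) == (5000, 10_000)
        # CpG at 9999 inside, at 10000 (the TSS) outside
        assert pr.start[0] <= 9999 < pr.end[0]
        assert not (pr.start[0] <= 10_000 < pr.end[0])

    def test_plus_strand_clipped_at_zero(self):
        g = _genes([("g", "lncRNA", "chr1", "+", 300)])
        pr = promoter_regions(g, span=5000)
        assert (pr.start[0], pr.end[0]) == (0, 300)

    def test_minus_strand_bruteforce_membership(self):
        g = _genes([("g", "lncRNA", "chr1", "-", 10_000)])
        pr = promoter_regions(g, span=5000)
        member = set(range(pr.start[0], pr.end[0]))
        # upstream of a leftward-transcribed gene: positions 10001..15000
        assert member == set(range(10_001, 15_001))

    def test_random_genes_match_bruteforce(self, rng):
        # strand-aware windows vs direct per-position membership on 1000 genes
        n = 1000
        g = _genes(
            [
                (f"g{i}", "coding", "chr1", s, int(t))
                for i, (s, t) in enumerate(
                    zip(rng.choice(["+", "-"], n), rng.integers(0, 30_000, n))
                )
            ]
        )
        pr = promoter_regions(g, span=5000).set_index("gene_id")
        probes = rng.integers(0, 40_000, size=200)
        for _, row in g.sample(50, random_state=1).iterrows():
            start, end = pr.loc[row.gene_id, ["start", "end"]]
            for p in probes:
                if row.strand == "+":
                    expected = max(0, row.tss - 5000) <= p < row.tss
                else:
                    expected = row.tss + 1 <= p < row.tss + 1 + 5000
                assert (start <= p < end) == expected

    def test_unknown_strand_errors(self):
        g = _genes([("g", "lncRNA", "chr1", ".", 100)])
        with pytest.raises(ValueError, match="strand"):
            promoter_regions(g)

    def test_positive_span_required(self):
        with pytest.raises(ValueError):
            promoter_regions(_genes([("g", "coding", "chr1", "+", 100)]), span=0)


class TestAssignCpgs:
    def test_outside_cpg_unassigned(self):
        g = _genes([("g", "lncRNA", "chr1", "+", 10_000)])
        cpgs = pd.DataFrame(
            {"cpg_id": ["c1", "c2"], "chrom": "chr1", "pos": [10_500, 9_000]}
        )
        out = assign_cpgs(cpgs, promoter_regions(g))
        assert list(out["assignment"].cpg_id) == ["c2"]

    def test_uncovered_promoter_in_coverage_report(self):
        g = _genes(
            [
                ("a", "lncRNA", "chr1", "+", 10_000),
                ("b", "lncRNA", "chr1", "+", 100_000),
            ]
        )
        cpgs = pd.DataFrame({"cpg_id": ["c1"], "chrom": "chr1", "pos": [9_000]})
        out = assign_cpgs(cpgs, promoter_regions(g))
        cov = out["coverage"].set_index("gene_id").n_assayed
        assert cov["a"] == 1 and cov["b"] == 0

    def test_coverage_fraction_with_totals(self):
        g = _genes([("a", "lncRNA", "chr1", "+", 10_000)])
        cpgs = pd.DataFrame({"cpg_id": ["c1"], "chrom": "chr1", "pos": [9_000]})
        out = assign_cpgs(cpgs, promoter_regions(g), total_cpgs={"a": 10})
        assert out["coverage"].covered_fraction[0] == pytest.approx(0.1)

    def test_matches_bruteforce_overlap_scan(self, rng):
        # 1000 CpGs x 50 promoters vs the naive O(n*m) scan
        n_prom = 50
        g = _genes(
            [
                (f"g{i}", "coding", "chr1", s, int(t))
                for i, (s, t) in enumerate(
                    zip(
                        rng.choice(["+", "-"], n_prom),
                        rng.integers(5000, 100_000, n_prom),
                    )
                )
            ]
        )
        proms = promoter_regions(g)
        cpgs = pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(1000)],
                "chrom": "chr1",
                "pos": rng.integers(0, 110_000, 1000),
            }
        )
        got = set(map(tuple, assign_cpgs(cpgs, proms)["assignment"].to_numpy()))
        brute = {
            (c.cpg_id, p.gene_id)
            for _, c in cpgs.iterrows()
            for _, p in proms.iterrows()
            if p.start <= c.pos < p.end
        }
        assert got == brute


class TestPerCpgTest:
    def _beta(self, n_pairs, delta, seed=0, n_cpg=5):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.2, 0.4, size=(n_cpg, n_pairs))
        normal = pd.DataFrame(
            base, columns=[f"P{i}_N" for i in range(n_pairs)]
        )
        # distinct per-pair shifts avoid rank ties (keeps the exact test exact)
        jitter = rng.uniform(0, 1e-3, size=(n_cpg, n_pairs)) if delta else 0.0
        tumor = pd.DataFrame(
            np.clip(base + delta + jitter, 0, 1),
            columns=[f"P{i}_T" for i in range(n_pairs)],
        )
        beta = pd.concat([normal, tumor], axis=1)
        beta.index = [f"cg{i}" for i in range(n_cpg)]
        return beta, list(normal.columns), list(tumor.columns)

    def test_identical_columns_null(self):
        beta, ns, ts = self._beta(10, 0.0)
        with pytest.warns(UserWarning, match="constant"):
            res = percpg_hypermethylation_test(beta, ns, ts, paired=True)
        assert (res.delta_beta == 0).all()
        assert (res.p == 1).all()

    def test_uniform_shift_matches_exact_signed_rank(self):
        # all 20 paired differences positive: one-sided exact p = 2^-20
        beta, ns, ts = self._beta(20, 0.3, seed=1, n_cpg=3)
        res = percpg_hypermethylation_test(beta, ns, ts, paired=True)
        assert np.allclose(res.p, 2.0**-20)
        assert (res.delta_beta > 0.29).all()

    def test_minimum_sample_size_enforced(self):
        beta, ns, ts = self._beta(2, 0.3)
        with pytest.raises(ValueError):
            percpg_hypermethylation_test(beta, ns, ts, paired=True)

    def test_unpaired_mode_detects_shift(self):
        beta, ns, ts = self._beta(30, 0.25, seed=2)
        res = percpg_hypermethylation_test(beta, ns, ts, paired=False)
        assert (res.q < 0.05).all()


class TestPromoterCalls:
    def _percpg(self, rows):
        return pd.DataFrame(
            rows, columns=["delta_beta", "p", "q"],
            index=[f"cg{i}" for i in range(len(rows))],
        )

    def test_null_calls_nothing(self):
        percpg = self._percpg([(0.0, 1.0, 1.0), (0.0, 0.9, 1.0)])
        asg = pd.DataFrame({"cpg_id": ["cg0", "cg1"], "gene_id": ["a", "a"]})
        calls = call_hypermethylated_promoters(percpg, asg)
        assert not calls.hypermethylated.any()

    def test_single_qualifying_cpg_called_and_top(self):
        percpg = self._percpg([(0.25, 0.001, 0.01), (0.05, 0.5, 0.6)])
        asg = pd.DataFrame({"cpg_id": ["cg0", "cg1"], "gene_id": ["a", "a"]})
        calls = call_hypermethylated_promoters(percpg, asg)
        assert calls.loc["a", "hypermethylated"]
        assert calls.loc["a", "top_cpg"] == "cg0"

    def test_delta_threshold_blocks_small_effects(self):
        percpg = self._percpg([(0.05, 0.001, 0.001)])
        asg = pd.DataFrame({"cpg_id": ["cg0"], "gene_id": ["a"]})
        calls = call_hypermethylated_promoters(percpg, asg, delta_min=0.1)
        assert not calls.loc["a", "hypermethylated"]

    def test_calling_monotone_in_alpha_and_delta(self, rng):
        percpg = self._percpg(
            [(d, p, p) for d, p in zip(rng.uniform(0, 0.4, 40), rng.uniform(0, 0.2, 40))]
        )
        asg = pd.DataFrame(
            {"cpg_id": percpg.index, "gene_id": [f"g{i % 10}" for i in range(40)]}
        )
        loose = call_hypermethylated_promoters(percpg, asg, alpha=0.1, delta_min=0.05)
        tight = call_hypermethylated_promoters(percpg, asg, alpha=0.02, delta_min=0.2)
        called_tight = set(tight.index[tight.hypermethylated])
        called_loose = set(loose.index[loose.hypermethylated])
        assert called_tight <= called_loose


def test_planted_promoters_recovered(small_methylation):
    genes, cpgs, beta, pairing, truth = small_methylation
    proms = promoter_regions(genes)
    asg = assign_cpgs(cpgs, proms)["assignment"]
    res = percpg_hypermethylation_test(
        beta, list(pairing), list(pairing.values()), paired=True
    )
    calls = call_hypermethylated_promoters(res, asg)
    called = set(calls.index[calls.hypermethylated])
    planted = set(truth.hyperm_promoters)
    assert planted <= called
    null = set(calls.index) - planted
    assert len(called - planted) <= max(1, len(null) // 100)


def test_silencing_anticorrelates_with_methylation(small_methylation, small_cohort):
    # called-hypermethylated genes are the planted-silenced ones, so their
    # tumor expression sits below their normal expression (sign test)
    from scipy import stats
    from hepident.exprnorm import log_cpm, tmm_factors

    genes, cpgs, beta, pairing, truth = small_methylation
    _, _, counts, cond, _ = small_cohort
    proms = promoter_regions(genes)
    asg = assign_cpgs(cpgs, proms)["assignment"]
    res = percpg_hypermethylation_test(
        beta, list(pairing), list(pairing.values()), paired=True
    )
    calls = call_hypermethylated_promoters(res, asg)
    called = [g for g in calls.index[calls.hypermethylated] if g in counts.index]
    expr = log_cpm(counts, tmm_factors(counts))
    diff = (
        expr.loc[called, cond == "tumor"].mean(axis=1)
        - expr.loc[called, cond == "normal"].mean(axis=1)
    )
    n_down = int((diff < 0).sum())
    p = stats.binomtest(n_down, len(diff), 0.5, alternative="greater").pvalue
    assert p < 0.01
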