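"""Signature scoring, Spearman, stratification, contingency tests, survival."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepident.clinical import (
    categorical_enrichment,
    km_estimate,
    logrank_test,
    per_gene_survival,
    signature_score,
    spearman_corr,
    stratify_extremes,
)


class TestSignatureScore:
    def test_single_gene_set_equals_row(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"g{i}" for i in range(5)])
        s = signature_score(expr, ["g2"])
        np.testing.assert_allclose(s, expr.loc["g2"])

    def test_constant_matrix(self):
        expr = pd.DataFrame(np.full((3, 4), 7.0), index=["a", "b", "c"])
        np.testing.assert_allclose(signature_score(expr, ["a", "b"]), 7.0)

    def test_matches_bruteforce_mean(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(30, 8)), index=[f"g{i}" for i in range(30)]
        )
        genes = [f"g{i}" for i in rng.choice(30, 20, replace=False)]
        s = signature_score(expr, genes)
        for j in range(8):
            assert s.iloc[j] == pytest.approx(
                sum(expr.loc[g].iloc[j] for g in genes) / len(genes)
            )

    def test_empty_or_absent_set_errors(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 2)), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            signature_score(expr, [])
        with pytest.raises(ValueError):
            signature_score(expr, ["zzz"])


class TestSpearman:
    def test_hand_rank_formula(self):
        # ranks of y=[3,1,2,4] vs x=[1,2,3,4]: d^2 = 4+1+1+0 = 6
        # rho = 1 - 6*6/(4*15) = 0.4
        rho, _ = spearman_corr([1, 2, 3, 4], [3, 1, 2, 4])
        assert rho == pytest.approx(0.4)

    def test_perfect_and_inverse(self, rng):
        x = rng.normal(size=20)
        assert spearman_corr(x, x)[0] == pytest.approx(1.0)
        assert spearman_corr(x, np.exp(-x))[0] == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, p1 = spearman_corr(x, y)
        rho2, p2 = spearman_corr(np.exp(x), y)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_exact_small_n_matches_full_enumeration(self):
        # independent enumeration over all 6! permutations
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        rho, p = spearman_corr(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx[list(perm)], ry)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        import math

        assert p == pytest.approx(count / math.factorial(6))

    def test_large_n_close_to_scipy(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p = spearman_corr(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho)
        assert p == pytest.approx(ref_p, rel=0.05)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])


class TestStratify:
    def test_all_assigned_when_n_equals_2k(self, rng):
        s = pd.Series(rng.normal(size=10), index=[f"p{i}" for i in range(10)])
        sub = stratify_extremes(s, k=5)
        assert sub.notna().all()
        assert (sub == "#1").sum() == 5 and (sub == "#2").sum() == 5

    def test_k1_is_argmax_argmin(self):
        s = pd.Series({"a": 1.0, "b": 5.0, "c": -2.0, "d": 0.0})
        sub = stratify_extremes(s, k=1)
        assert sub["b"] == "#1" and sub["c"] == "#2"
        assert sub[["a", "d"]].isna().all()

    def test_high_group_scores_dominate(self, rng):
        s = pd.Series(rng.normal(size=100), index=[f"p{i}" for i in range(100)])
        sub = stratify_extremes(s, k=20)
        assert s[sub == "#1"].min() >= s[sub.isna()].max()
        assert s[sub == "#2"].max() <= s[sub.isna()].min()

    def test_boundary_ties_deterministic_by_id(self):
        s = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 0.0})
        sub = stratify_extremes(s, k=1)
        assert sub["a"] == "#1"  # id-ordered among the tied top scores

    def test_oversized_k_errors(self):
        with pytest.raises(ValueError):
            stratify_extremes(pd.Series({"a": 1.0, "b": 2.0}), k=2)


class TestCategorical:
    def test_balanced_table_no_association(self):
        out = categorical_enrichment([[10, 10], [10, 10]])
        assert out["p"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 [[8,2],[1,9]]: two-sided Fisher p by summing hypergeometric
        # probabilities of tables as or more extreme
        table = np.array([[8, 2], [1, 9]])
        out = categorical_enrichment(table)
        assert out["method"] == "fisher"
        r1, c1, n = 10, 9, 20
        probs = {
            a: stats.hypergeom.pmf(a, n, r1, c1) for a in range(max(0, c1 - 10), min(r1, c1) + 1)
        }
        p_obs = probs[8]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert out["p"] == pytest.approx(expected, rel=1e-6)

    def test_doubling_preserves_odds_ratio(self):
        a = categorical_enrichment([[3, 1], [0, 4]])
        b = categorical_enrichment([[6, 2], [0, 8]])
        assert a["method"] == b["method"] == "fisher"
        assert a["statistic"] == pytest.approx(b["statistic"])

    def test_large_table_uses_chi2_without_correction(self):
        table = [[30, 20], [20, 30]]
        out = categorical_enrichment(table)
        assert out["method"] == "chi2"
        chi2, p, _, _ = stats.chi2_contingency(np.array(table), correction=False)
        assert out["statistic"] == pytest.approx(chi2)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError):
            categorical_enrichment([[0, 0], [5, 5]])


class TestKaplanMeier:
    def test_four_distinct_events_no_censoring(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(
            km.survival.to_numpy(), [1.0, 0.75, 0.5, 0.25, 0.0]
        )

    def test_all_censored_flat_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert (km.survival == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        # events at 2 and 4, censored at 3: risk sets {3, 1}
        # S(2+) = 2/3, S(4+) = 2/3 * 0 = 0
        km = km_estimate([2, 3, 4], [1, 0, 1]).set_index("time")
        assert km.loc[2.0, "survival"] == pytest.approx(2.0 / 3.0)
        assert km.loc[4.0, "survival"] == pytest.approx(0.0)

    def test_valid_survivor_function(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        km = km_estimate(t, e)
        assert km.survival.iloc[0] == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_accumulated_example(self):
        # group1 events {1,2}, group2 events {3,4}: O1=2, E1=0.8333,
        # V=0.4722, chi2 = (2-0.8333)^2/0.4722 = 2.882
        chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert chi2 == pytest.approx(2.882, abs=1e-3)

    def test_matches_permutation_null(self, rng):
        # chi2 reference distribution vs an empirical permutation null; n
        # large enough for the asymptotic approximation to hold
        n = 60
        t = rng.exponential(10, size=n)
        t[:30] *= 1.6
        e = np.ones(n, dtype=int)
        g = np.array(["a"] * 30 + ["b"] * 30)
        chi2, p = logrank_test(t, e, g)
        n_perm = 2000
        hits = 0
        for _ in range(n_perm):
            gp = rng.permutation(g)
            c, _ = logrank_test(t, e, gp)
            hits += c >= chi2 - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert abs(p - p_perm) < max(3 * se, 0.025)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], ["a", "b"])


class TestPerGeneSurvival:
    def _cohort(self, rng, n=80):
        idx = [f"p{i}" for i in range(n)]
        expr = pd.DataFrame(
            rng.normal(size=(3, n)), index=["g_flat", "g_risk", "g_const"], columns=idx
        )
        expr.loc["g_const"] = 1.0
        z = (expr.loc["g_risk"] - expr.loc["g_risk"].mean()) / expr.loc["g_risk"].std()
        t = rng.exponential(1.0 / (0.01 * np.exp(-1.2 * z)))
        clin = pd.DataFrame(
            {"os_time": t, "os_event": np.ones(n, dtype=int)}, index=idx
        )
        return expr, clin

    def test_constant_gene_skipped_with_warning(self, rng):
        expr, clin = self._cohort(rng)
        with pytest.warns(UserWarning, match="skipped"):
            out = per_gene_survival(expr, clin)
        assert "g_const" not in out.index

    def test_risk_gene_detected(self, rng):
        expr, clin = self._cohort(rng, n=200)
        with pytest.warns(UserWarning):
            out = per_gene_survival(expr, clin)
        assert out.loc["g_risk", "p"] < 0.05
        assert out.attrs["n_significant"] >= 1

    def test_empty_join_errors(self, rng):
        expr, clin = self._cohort(rng)
        clin.index = [f"x{i}" for i in range(len(clin))]
        with pytest.raises(ValueError):
            per_gene_survival(expr, clin)
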