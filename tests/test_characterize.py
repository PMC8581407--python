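"""Cluster-descriptive statistics: enrichment, feature screens, similarity, survival."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import inflaclust as ic
from inflaclust.characterize import chi2_stat_2x2


def enumeration_hypergeom_sf(N, Kt, n, k):
    """P(X >= k) by literally enumerating all C(N, n) cluster draws."""
    hits = total = 0
    population = [1] * Kt + [0] * (N - Kt)
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


class TestHypergeomEnrichment:
    def test_matches_exhaustive_enumeration_at_n20(self):
        # N=20, one type of 8, one cluster of 5 with overlap 4
        types = np.array(["T"] * 8 + ["U"] * 12)
        labels = np.array([1] * 4 + [2] * 4 + [1] * 1 + [2] * 11)
        recs = ic.hypergeom_enrichment(labels, types)
        rec = next(r for r in recs if r.tumor_type == "T" and r.cluster == 1)
        assert (rec.n_total, rec.n_type, rec.n_cluster, rec.overlap) == (20, 8, 5, 4)
        expected = enumeration_hypergeom_sf(20, 8, 5, 4)
        assert rec.p == pytest.approx(expected, abs=1e-9)

    def test_zero_overlap_gives_p_one(self):
        types = np.array(["A"] * 5 + ["B"] * 5)
        labels = np.array([1] * 5 + [2] * 5)
        recs = ic.hypergeom_enrichment(labels, types)
        rec = next(r for r in recs if r.tumor_type == "A" and r.cluster == 2)
        assert rec.overlap == 0 and rec.p == pytest.approx(1.0)

    def test_whole_cohort_cluster_is_degenerate(self):
        types = np.array(["A"] * 4 + ["B"] * 6)
        labels = np.ones(10, dtype=int)
        recs = ic.hypergeom_enrichment(labels, types)
        for r in recs:
            assert r.overlap == r.n_type and r.p == pytest.approx(1.0)

    def test_p_nonincreasing_in_overlap(self):
        from scipy import stats

        ps = [float(stats.hypergeom.sf(k - 1, 40, 15, 10)) for k in range(0, 11)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_bh_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(0)
        types = rng.choice(["A", "B", "C"], 60)
        labels = rng.integers(1, 4, 60)
        recs = ic.hypergeom_enrichment(labels, types)
        for r in recs:
            assert r.fdr >= r.p - 1e-15
        by_p = sorted(recs, key=lambda r: r.p)
        fdrs = [r.fdr for r in by_p]
        assert fdrs == sorted(fdrs)

    def test_single_tumor_type_warns_all_p_one(self):
        types = np.array(["A"] * 10)
        labels = np.array([1] * 5 + [2] * 5)
        with pytest.warns(UserWarning, match="single tumor type"):
            recs = ic.hypergeom_enrichment(labels, types)
        assert all(r.p == 1.0 for r in recs)


class TestChisqFeatureScreen:
    def test_statistic_matches_closed_form(self):
        # feature present in 100% of cluster A, 0% elsewhere
        labels = np.array([1] * 40 + [2] * 60)
        feats = pd.DataFrame({"f": [1] * 40 + [0] * 60})
        recs = ic.chisq_feature_screen(labels, feats)
        rec = next(r for r in recs if r.cluster == 1)
        a, b, c, d = 40, 0, 0, 60
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2_stat_2x2(a, b, c, d) == pytest.approx(expected, abs=1e-9)
        assert rec.effect == pytest.approx(1.0)
        assert rec.p < 1e-10

    def test_equal_frequencies_give_zero_statistic(self):
        assert chi2_stat_2x2(10, 30, 10, 30) == pytest.approx(0.0, abs=1e-12)

    def test_role_swap_invariance(self):
        labels = np.array([1] * 30 + [2] * 30)
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 60)
        recs1 = ic.chisq_feature_screen(labels, pd.DataFrame({"f": x}))
        recs2 = ic.chisq_feature_screen(labels, pd.DataFrame({"f": 1 - x}))
        for r1, r2 in zip(recs1, recs2):
            assert r1.p == pytest.approx(r2.p, abs=1e-12)
            assert r1.effect == pytest.approx(-r2.effect, abs=1e-12)

    def test_constant_feature_skipped(self):
        labels = np.array([1] * 5 + [2] * 5)
        recs = ic.chisq_feature_screen(labels, pd.DataFrame({"f": [0] * 10}))
        assert recs == []

    def test_sparse_table_uses_exact_fallback(self):
        labels = np.array([1] * 6 + [2] * 50)
        feats = pd.DataFrame({"f": [1, 1, 0, 0, 0, 0] + [0] * 50})
        recs = ic.chisq_feature_screen(labels, feats)
        assert any(r.note == "fisher_exact_fallback" for r in recs)


class TestDiffExpression:
    def test_lncrna_threshold_needs_logfc_above_two(self):
        # a gene at logFC ~1.5 with tiny p must not be significant for lncRNA
        rng = np.random.default_rng(0)
        n = 30
        base = rng.normal(5, 0.1, size=(2, 2 * n))
        base[0, :n] += 1.5
        expr = ic.ExpressionMatrix(
            pd.DataFrame(base, index=["lnc1", "lnc2"],
                         columns=[f"s{i}" for i in range(2 * n)])
        )
        labels = np.array([1] * n + [2] * n)
        recs = ic.diff_expression_one_vs_rest(expr, labels, "lncRNA")
        rec = next(r for r in recs if r.feature == "lnc1" and r.cluster == 1)
        assert rec.fdr < 1e-5 and abs(rec.effect) > 1
        assert not rec.significant
        coding = ic.diff_expression_one_vs_rest(expr, labels, "coding")
        rec_c = next(r for r in coding if r.feature == "lnc1" and r.cluster == 1)
        assert rec_c.significant

    def test_planted_il18_genes_up_in_cluster6(self, scheme, small_cohort):
        up_set = scheme.scores["IL18"][0].members
        labels = small_cohort.true_labels.to_numpy()
        recs = ic.diff_expression_one_vs_rest(small_cohort.expr, labels, "coding")
        hits = [
            r for r in recs
            if r.cluster == 6 and r.feature in up_set and r.significant and r.effect > 0
        ]
        assert len(hits) >= len(up_set) - 1  # delta_high=1.5 > coding threshold 1

    def test_constant_gene_gets_p_one(self):
        df = pd.DataFrame(
            {f"s{i}": [1.0, float(i)] for i in range(12)}, index=["flat", "var"]
        )
        expr = ic.ExpressionMatrix(df)
        labels = np.array([1] * 6 + [2] * 6)
        recs = ic.diff_expression_one_vs_rest(expr, labels)
        flat = [r for r in recs if r.feature == "flat"]
        assert all(r.p == 1.0 and r.effect == 0.0 for r in flat)


class TestTumorMapSimilarity:
    def test_identical_vectors_have_similarity_one(self):
        X = np.vstack([np.ones(5), np.ones(5), np.zeros(5)])
        scores = ic.ScoreMatrix(pd.DataFrame(
            X, columns=["IC", "CASP1", "GSDMD", "IL1B", "IL18"], index=["a", "b", "c"]
        ))
        S = ic.tumor_map_similarity(scores)
        assert S.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(S), 1.0)

    def test_formula_arithmetic(self):
        # distance 1 -> 0.5; distance 3 -> 0.25
        X = np.array([[0.0] * 5, [1.0, 0, 0, 0, 0], [3.0, 0, 0, 0, 0]])
        scores = ic.ScoreMatrix(pd.DataFrame(
            X, columns=["IC", "CASP1", "GSDMD", "IL1B", "IL18"], index=list("abc")
        ))
        S = ic.tumor_map_similarity(scores)
        assert S.loc["a", "b"] == pytest.approx(0.5)
        assert S.loc["a", "c"] == pytest.approx(0.25)

    def test_matches_loop_oracle_and_bounds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 2, size=(10, 5))
        scores = ic.ScoreMatrix(pd.DataFrame(
            X, columns=["IC", "CASP1", "GSDMD", "IL1B", "IL18"],
            index=[f"s{i}" for i in range(10)]
        ))
        S = ic.tumor_map_similarity(scores).to_numpy()
        for i in range(10):
            for j in range(10):
                d = math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(5)))
                assert S[i, j] == pytest.approx(1 / (1 + d), abs=1e-9)
        assert ((S > 0) & (S <= 1)).all()
        np.testing.assert_allclose(S, S.T, atol=1e-12)


def logrank_oracle(time, event, group):
    """Two-group log-rank chi-square by explicit risk-set arithmetic."""
    times = sorted({t for t, e in zip(time, event) if e == 1})
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        at_risk = [(ti, ei, gi) for ti, ei, gi in zip(time, event, group) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for ti, ei, gi in at_risk if gi == 1)
        d = sum(1 for ti, ei, gi in zip(time, event, group) if ti == t and ei == 1)
        d1 = sum(
            1 for ti, ei, gi in zip(time, event, group) if ti == t and ei == 1 and gi == 1
        )
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestSurvivalContrasts:
    def test_logrank_matches_hand_risk_set_arithmetic(self):
        # 8-subject toy with distinct times
        time = [1, 2, 3, 4, 5, 6, 7, 8]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        group = [1, 1, 1, 1, 2, 2, 2, 2]
        out = ic.survival_contrasts(np.array(group), np.array(time), np.array(event))
        expected = logrank_oracle(time, event, group)
        assert out["logrank_stat"] == pytest.approx(expected, abs=1e-9)

    def test_identical_groups_give_zero_statistic(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        group = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        out = ic.survival_contrasts(group, time, event)
        assert out["logrank_stat"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_hazards_order_hazard_ratios(self, small_cohort):
        labels = small_cohort.true_labels.to_numpy()
        out = ic.survival_contrasts(
            labels,
            small_cohort.survival["time"].to_numpy(),
            small_cohort.survival["event"].to_numpy(),
        )
        # cluster 6 has the largest planted hazard multiplier
        assert out["hazard_ratios"].loc[6, 1] > 1.0

    def test_default_cohort_survival_separates_clusters(self, default_cohort):
        out = ic.survival_contrasts(
            default_cohort.true_labels.to_numpy(),
            default_cohort.survival["time"].to_numpy(),
            default_cohort.survival["event"].to_numpy(),
        )
        assert out["logrank_p"] < 0.05
        assert out["hazard_ratios"].loc[6, 1] > 1.0

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            ic.survival_contrasts(
                np.array([1, 1, 2, 2]),
                np.array([1.0, 2, 3, 4]),
                np.array([0, 0, 0, 0]),
            )

    def test_masking_hides_nonsignificant_pairs(self, small_cohort):
        labels = small_cohort.true_labels.to_numpy()
        out = ic.survival_contrasts(
            labels,
            small_cohort.survival["time"].to_numpy(),
            small_cohort.survival["event"].to_numpy(),
        )
        masked = out["hazard_ratios_masked"]
        pmat = out["hr_pvalues"]
        for i in masked.index:
            for j in masked.columns:
                if i == j:
                    continue
                if pmat.loc[i, j] >= 0.05:
                    assert np.isnan(masked.loc[i, j])
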