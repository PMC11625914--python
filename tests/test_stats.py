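"""Cohort statistics tests: clustering, scan, FDR, ROC, summary utilities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from nvcoupling.stats import (SummaryGroup, anova_from_summary, bh_fdr,
                              chi_square_counts, cluster_progression,
                              correlate_with_scores, group_effect_scan,
                              mann_whitney_auc, monthly_rate,
                              optimal_1d_partition, pooled_mean, roc_auc,
                              tukey_hsd_from_summary)
from nvcoupling.types import DegeneracyError, NvcMatrix


class TestProgressionClustering:
    def test_well_separated_triplets_recovered_exactly(self):
        data = np.array([-41, -40, -42, -14, -13, -15, -4, -5, -3], dtype=float)
        out = cluster_progression(data, seed=0)
        assert tuple(out.sizes) == (3, 3, 3)
        assert np.allclose(sorted(out.centroids), (-41, -14, -4))
        # matches the exhaustive contiguous-partition optimum
        oracle_labels, _ = optimal_1d_partition(data, k=3)
        ours = pd.factorize(out.labels)[0]
        assert len(set(zip(ours, oracle_labels))) == 3  # same partition
        assert list(out.labels[:3]) == ["VFP"] * 3
        assert list(out.labels[-3:]) == ["SP"] * 3

    def test_all_equal_values_degenerate(self):
        with pytest.raises(DegeneracyError):
            cluster_progression(np.full(9, -10.0))

    def test_monthly_rate_conversion(self):
        assert round(monthly_rate(-13.85), 2) == -1.15
        out = cluster_progression(
            np.array([-41.0, -40, -42, -14, -13.55, -14, -4, -5, -3]), seed=0)
        assert np.allclose(out.monthly_rates, out.centroids / 12.0)

    def test_seeded_determinism(self, rng):
        data = rng.normal(-15, 10, size=40)
        a = cluster_progression(data, seed=7)
        b = cluster_progression(data, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.centroids, b.centroids)


def _toy_matrix_and_clinical(rng, n_a=20, n_b=20, shift=0.0):
    n = n_a + n_b
    idx = [f"s{i}" for i in range(n)]
    group = ["ALS"] * n_a + ["HC"] * n_b
    age = rng.normal(60, 8, n)
    sex = rng.choice(["M", "F"], n)
    data = pd.DataFrame(
        rng.standard_normal((n, 3)), index=idx, columns=["u1", "u2", "u3"])
    data.loc[[i for i, g in zip(idx, group) if g == "ALS"], "u1"] += shift
    clinical = pd.DataFrame({"group": group, "age": age, "sex": sex}, index=idx)
    matrix = NvcMatrix(metric="ALFF", granularity="network", data=data)
    return matrix, clinical


class TestGroupEffectScan:
    def test_two_group_f_equals_t_squared_from_statsmodels(self, rng):
        import statsmodels.formula.api as smf
        matrix, clinical = _toy_matrix_and_clinical(rng, shift=0.8)
        res = group_effect_scan(matrix, clinical)
        df = clinical.copy()
        df["y"] = matrix.data["u1"]
        fit = smf.ols("y ~ C(group) + age + C(sex)", data=df).fit()
        t = fit.tvalues["C(group)[T.HC]"]
        assert res.table.loc["u1", "F"] == pytest.approx(t ** 2, abs=1e-8)
        assert res.table.loc["u1", "p"] == pytest.approx(
            fit.pvalues["C(group)[T.HC]"], abs=1e-10)

    def test_constant_column_excluded_from_family(self, rng):
        matrix, clinical = _toy_matrix_and_clinical(rng)
        matrix.data["u2"] = 1.0
        res = group_effect_scan(matrix, clinical)
        assert "u2" in res.excluded
        assert np.isnan(res.table.loc["u2", "p"])
        assert np.isfinite(res.table.loc["u1", "q"])

    def test_tiny_groups_rejected(self, rng):
        matrix, clinical = _toy_matrix_and_clinical(rng)
        clinical["group"] = ["ALS"] + ["HC"] * (len(clinical) - 1)
        with pytest.raises(ValueError, match="2 subjects"):
            group_effect_scan(matrix, clinical)


class TestBhFdr:
    def test_handworked_stepup_example(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.060, 0.074])
        adj, reject = bh_fdr(p, q=0.05)
        # step-up thresholds k*q/m: only the first two survive
        assert list(np.flatnonzero(reject)) == [0, 1]
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)

    def test_all_tiny_and_single_p(self):
        _, rej = bh_fdr(np.full(7, 0.001))
        assert rej.all()
        _, rej1 = bh_fdr(np.array([0.049]), q=0.05)
        assert rej1[0]

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(40)
        adj, reject = bh_fdr(p, q=0.05)
        rej_sm, adj_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, adj_sm, atol=1e-12)
        assert np.array_equal(reject, rej_sm)

    def test_nan_preserves_indexing(self):
        p = np.array([0.01, np.nan, 0.02])
        adj, reject = bh_fdr(p)
        assert np.isnan(adj[1]) and not reject[1]
        assert reject[0] and reject[2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=12), st.data())
    def test_lowering_a_p_never_removes_rejections(self, ps, data):
        p = np.array(ps)
        _, before = bh_fdr(p)
        i = data.draw(st.integers(0, len(p) - 1))
        factor = data.draw(st.floats(0.0, 1.0))
        p2 = p.copy()
        p2[i] = p[i] * factor
        _, after = bh_fdr(p2)
        others = np.delete(np.arange(len(p)), i)
        assert np.all(after[others] >= before[others])
        assert after[i] >= before[i]


class TestCorrelations:
    def test_self_correlation_is_one(self, rng):
        x = pd.Series(rng.standard_normal(30))
        out = correlate_with_scores(x, pd.DataFrame({"same": x}))
        assert out.loc["same", "r"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["same", "p"] < 1e-20

    def test_toy_table_matches_hand_computation(self):
        x = pd.Series([1.0, 2, 3, 4, 5, 6])
        y = pd.Series([2.0, 1, 4, 3, 7, 5])
        out = correlate_with_scores(x, pd.DataFrame({"y": y}))
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std(ddof=0) * y.std(ddof=0))
        assert out.loc["y", "r"] == pytest.approx(oracle, abs=1e-12)
        t = oracle * np.sqrt(4 / (1 - oracle ** 2))
        assert out.loc["y", "p"] == pytest.approx(2 * sps.t.sf(abs(t), 4), abs=1e-12)

    def test_pairwise_complete_and_degenerate_handling(self, rng):
        x = pd.Series(rng.standard_normal(20))
        scores = pd.DataFrame({
            "partial": pd.Series(rng.standard_normal(20)).where(lambda s: s.index < 10),
            "flat": pd.Series(np.ones(20)),
        })
        out = correlate_with_scores(x, scores)
        assert out.loc["partial", "n"] == 10
        assert out.loc["flat", "reason"] == "zero variance"


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc(np.array([1, 2, 3, 10, 11, 12]),
                    np.array(["a"] * 3 + ["b"] * 3), positive="b",
                    n_boot=50, seed=0)
        assert r.auc == 1.0

    def test_pairwise_counting_oracle(self):
        # SP scores (1,2,3) vs VFP (2.5,4,5); positive = higher-scoring class
        scores = np.array([1, 2, 3, 2.5, 4, 5])
        labels = np.array(["SP", "SP", "SP", "VFP", "VFP", "VFP"])
        r = roc_auc(scores, labels, positive="VFP", n_boot=50, seed=0)
        assert r.auc == pytest.approx(8 / 9, abs=1e-12)

    def test_identical_multisets_give_half(self):
        scores = np.array([1.0, 2, 3, 1, 2, 3])
        labels = np.array(["x"] * 3 + ["y"] * 3)
        assert roc_auc(scores, labels, positive="x", n_boot=50, seed=0).auc == 0.5

    def test_trapezoid_equals_mann_whitney_with_ties(self, rng):
        scores = rng.integers(0, 5, size=60).astype(float)
        labels = rng.choice(["a", "b"], size=60)
        r = roc_auc(scores, labels, positive="a", n_boot=50, seed=0)
        assert r.trapezoid_auc == pytest.approx(r.auc, abs=1e-10)
        assert r.auc == pytest.approx(
            roc_auc_score((labels == "a").astype(int), scores), abs=1e-12)
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 1, 25)])
        labels = np.array(["n"] * 25 + ["p"] * 25)
        r1 = roc_auc(scores, labels, positive="p", n_boot=300, seed=42)
        r2 = roc_auc(scores, labels, positive="p", n_boot=300, seed=42)
        assert r1.ci == r2.ci
        assert r1.ci[0] <= r1.auc <= r1.ci[1]
        rd = roc_auc(scores, labels, positive="p", ci_method="delong")
        assert rd.ci[0] <= rd.auc <= rd.ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array(["a", "a"]))


class TestSummaryUtilities:
    def test_equal_means_give_zero_f(self):
        f, *_ = anova_from_summary([SummaryGroup(10, 5.0, 1.0),
                                    SummaryGroup(12, 5.0, 2.0)])
        assert f == 0.0

    def test_summary_anova_equals_raw_anova(self, rng):
        groups_raw = [rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9),
                      rng.normal(-0.2, 0.8, 15)]
        summaries = [SummaryGroup(len(g), g.mean(), g.std(ddof=1))
                     for g in groups_raw]
        f, df1, df2, p = anova_from_summary(summaries)
        f_raw, p_raw = sps.f_oneway(*groups_raw)
        assert f == pytest.approx(f_raw, abs=1e-8)
        assert p == pytest.approx(p_raw, abs=1e-10)
        assert (df1, df2) == (2, 33)

    def test_zero_within_variance_flagged_infinite(self):
        f, *_ , p = anova_from_summary([SummaryGroup(5, 1.0, 0.0),
                                        SummaryGroup(5, 2.0, 0.0)])
        assert np.isinf(f) and p == 0.0

    def test_pooled_mean_weighted(self):
        assert pooled_mean([SummaryGroup(1, 4.0)]) == 4.0
        got = pooled_mean([SummaryGroup(27, 36.67, 4.82),
                           SummaryGroup(13, 27.77, 5.35),
                           SummaryGroup(8, 0.0, 0.0)])
        assert got == pytest.approx((27 * 36.67 + 13 * 27.77) / 48, abs=1e-12)

    def test_chi_square_hand_example_and_oracle(self, rng):
        chi2, p = chi_square_counts([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0, abs=1e-12)
        table = rng.integers(5, 40, size=(2, 3))
        chi2b, pb = chi_square_counts(table)
        oracle = sps.chi2_contingency(table, correction=False)
        assert chi2b == pytest.approx(oracle.statistic, abs=1e-10)
        assert pb == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_chi_square_identical_distributions_zero(self):
        chi2, p = chi_square_counts([[20, 30], [40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [1, 2]])

    def test_tukey_from_summary_matches_scipy_on_raw_data(self, rng):
        groups_raw = [rng.normal(0, 1, 10), rng.normal(1, 1, 10),
                      rng.normal(2, 1, 10)]
        summaries = [SummaryGroup(len(g), g.mean(), g.std(ddof=1))
                     for g in groups_raw]
        ours = tukey_hsd_from_summary(summaries)
        oracle = sps.tukey_hsd(*groups_raw)
        for _, row in ours.iterrows():
            i, j = int(row["group_i"]), int(row["group_j"])
            assert row["p"] == pytest.approx(oracle.pvalue[i, j], abs=1e-6)
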