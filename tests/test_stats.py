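import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from feulgen import stats, synthetic
from feulgen.stats import (
    ConfusionMatrix,
    cohort_summary,
    confusion_matrix,
    describe,
    ks_test,
    multi_group_comparison,
    stepwise_lda,
    two_group_test,
)


class TestDescribe:
    def test_constant_column_sd_zero(self):
        table = pd.DataFrame({"x": [5.0] * 10, "g": ["a"] * 10})
        out = describe(table, "g")
        assert out.loc["a", ("x", "std")] == 0.0

    def test_single_row_sd_missing(self):
        table = pd.DataFrame({"x": [3.0], "g": ["a"]})
        out = describe(table, "g")
        assert np.isnan(out.loc["a", ("x", "std")])

    def test_generator_roundtrip_area_mean(self):
        table = synthetic.sample_feature_table("normal", 10_000, seed=7)
        out = describe(table, "cell_type")
        se = 94.1 / np.sqrt(10_000)
        assert abs(out.loc["normal", ("Area", "mean")] - 117.1) < 3 * se

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            describe(pd.DataFrame(), "g")


class TestTwoGroupTest:
    def test_identical_degenerate_samples(self):
        t, p, _ = two_group_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_strongly_separated(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 100), rng.normal(5, 1, 100)
        _, p, _ = two_group_test(a, b)
        assert p < 1e-15

    def test_missing_values_dropped_and_n_reported(self):
        a = np.array([1.0, 2.0, np.nan, 3.0])
        b = np.array([1.5, 2.5, 3.5])
        _, _, (na, nb) = two_group_test(a, b)
        assert (na, nb) == (3, 3)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)
        t, p, _ = two_group_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_permutation_oracle_agreement(self):
        # 5000-permutation reference on n = 50
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1, 25)
        _, p, _ = two_group_test(a, b)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        perms = rng.permuted(np.tile(pooled, (5000, 1)), axis=1)
        diffs = np.abs(perms[:, :25].mean(axis=1) - perms[:, 25:].mean(axis=1))
        assert p == pytest.approx(np.mean(diffs >= observed), abs=0.01)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(21)
        n_reps, n = 2000, 20
        a = rng.normal(0, 1, (n_reps, n))
        b = rng.normal(0, 1, (n_reps, n))
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
        # sanity: scipy batch == our scalar on first rep
        t0, p0, _ = two_group_test(a[0], b[0])
        assert p0 == pytest.approx(res.pvalue[0])
        rate = np.mean(res.pvalue < 0.05)
        assert 0.04 <= rate <= 0.06


class TestKSTest:
    def test_identical_samples(self):
        a = np.arange(10.0)
        d, p = ks_test(a, a)
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert d == 1.0

    def test_shifted_uniforms(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(0.5, 1.5, 1000)
        d, p = ks_test(a, b)
        assert d == pytest.approx(0.5, abs=0.05)
        assert p < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_test([], [1.0])


class TestMultiGroupComparison:
    @staticmethod
    def _table(shift=0.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for g, mu in zip("abc", (0.0, 0.0, shift)):
            frames.append(pd.DataFrame({"x": rng.normal(mu, 1, n), "g": g}))
        return pd.concat(frames, ignore_index=True)

    def test_shifted_group_detected(self):
        out = multi_group_comparison(self._table(shift=5.0), "g")
        assert out.loc[0, "p"] < 1e-6

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {"x": rng.normal(0, 1, 40), "g": ["a"] * 20 + ["b"] * 20}
        )
        out = multi_group_comparison(table, "g")
        t, _, _ = two_group_test(
            table.loc[table.g == "a", "x"], table.loc[table.g == "b", "x"],
            equal_var=True,
        )
        assert out.loc[0, "F"] == pytest.approx(t**2, rel=1e-9)

    def test_single_group_rejected(self):
        table = pd.DataFrame({"x": np.arange(5.0), "g": "a"})
        with pytest.raises(ValueError):
            multi_group_comparison(table, "g")

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(31)
        n_reps, n = 2000, 20
        groups = [rng.normal(0, 1, (n_reps, n)) for _ in range(3)]
        res = sps.f_oneway(*groups, axis=1)
        rate = np.mean(res.pvalue < 0.05)
        assert 0.04 <= rate <= 0.06


class TestCohortSummary:
    def test_prevalence_from_counts(self):
        out = cohort_summary({"affected": 15, "unaffected": 585})
        assert out.loc[out.category == "affected", "percent"].item() == 2.5
        assert out.loc[out.category == "total", "count"].item() == 600

    def test_zero_part(self):
        out = cohort_summary({"a": 0, "b": 50})
        assert out.loc[out.category == "a", "percent"].item() == 0.0

    def test_subgroup_totals(self):
        out = cohort_summary({"normal": 28141, "neoplastic": 92083})
        assert out.loc[out.category == "total", "count"].item() == 120224

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary({"a": 0})

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary({"a": -1, "b": 5})


class TestConfusionMatrix:
    def test_rows_sum_to_100(self):
        cm = ConfusionMatrix(classes=["a", "b"], counts=np.array([[7, 3], [2, 8]]))
        np.testing.assert_allclose(cm.percentages.sum(axis=1), 100.0, atol=0.1)

    def test_correct_rate(self):
        cm = ConfusionMatrix(classes=["a", "b"], counts=np.array([[9, 1], [1, 9]]))
        assert cm.correct_rate == pytest.approx(0.9)

    def test_builder_ordering(self):
        cm = confusion_matrix(
            np.array(["a", "a", "b"]), np.array(["a", "b", "b"]), ["a", "b"]
        )
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])


class TestStepwiseLDA:
    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(1)
        n = 200
        table = pd.DataFrame(
            {
                "x": np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)]),
                "y": rng.normal(0, 1, 2 * n),
                "cls": ["a"] * n + ["b"] * n,
            }
        )
        model, cm = stepwise_lda(table, "cls")
        assert cm.correct_rate == 1.0
        assert "x" in model.features

    def test_bayes_rate_on_1d_two_gaussians(self):
        rng = np.random.default_rng(0)
        n = 50_000
        table = pd.DataFrame(
            {
                "x": np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)]),
                "cls": ["a"] * n + ["b"] * n,
            }
        )
        _, cm = stepwise_lda(table, "cls")
        bayes = sps.norm.cdf(1.0)  # ~0.8413
        assert cm.correct_rate == pytest.approx(bayes, abs=0.005)

    def test_selection_consistency_with_noise_features(self):
        hits, few_noise = 0, 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            n = 100
            data = {"signal": np.concatenate([rng.normal(0, 1, n), rng.normal(1.5, 1, n)])}
            for k in range(10):
                data[f"noise{k}"] = rng.normal(0, 1, 2 * n)
            table = pd.DataFrame(data)
            table["cls"] = ["a"] * n + ["b"] * n
            model, _ = stepwise_lda(table, "cls")
            hits += "signal" in model.features
            few_noise += sum(f != "signal" for f in model.features) <= 2
        assert hits / n_reps > 0.9
        assert few_noise / n_reps > 0.9

    def test_confusion_rows_sum_100(self):
        table = pd.concat(
            [
                synthetic.sample_feature_table("normal", 300, seed=1),
                synthetic.sample_feature_table("neoplastic", 300, seed=2),
            ],
            ignore_index=True,
        )
        _, cm = stepwise_lda(table, "cell_type")
        np.testing.assert_allclose(cm.percentages.sum(axis=1), 100.0, atol=0.1)

    def test_cross_validated_confusion(self):
        rng = np.random.default_rng(6)
        n = 500
        table = pd.DataFrame(
            {
                "x": np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)]),
                "cls": ["a"] * n + ["b"] * n,
            }
        )
        _, cm_cv = stepwise_lda(table, "cls", cv_folds=5)
        _, cm_rs = stepwise_lda(table, "cls")
        assert cm_cv.counts.sum() == 2 * n  # every row predicted exactly once
        # held-out accuracy close to (and typically not above) resubstitution
        assert cm_cv.correct_rate == pytest.approx(cm_rs.correct_rate, abs=0.03)

    def test_single_class_rejected(self):
        table = pd.DataFrame({"x": np.arange(10.0), "cls": "a"})
        with pytest.raises(ValueError):
            stepwise_lda(table, "cls")

    def test_nonsignificant_features_have_largest_pvalues(self):
        # at study scale, the features whose published group means barely
        # differ (Compactness, ModRatio, Sphericity) should rank among the
        # least significant of the 21
        normal = synthetic.sample_feature_table("normal", 28141, seed=3)
        neo = synthetic.sample_feature_table("neoplastic", 92083, seed=4)
        table = pd.concat([normal, neo], ignore_index=True)
        comp = stats.compare_groups(table, "cell_type")
        ranked = comp.sort_values("p", ascending=False)["feature"].tolist()
        assert set(ranked[:3]) == {"Compactness", "ModRatio", "Sphericity"}


class TestStepwiseInternals:
    def test_wilks_lambda_bounds(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (100, 3))
        y = np.repeat([0, 1], 50)
        w, t = stats._sscp(x, y, 2)
        lam = stats._wilks(w, t, [0, 1, 2])
        assert 0 < lam <= 1.0 + 1e-12
        assert stats._wilks(w, t, []) == 1.0
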