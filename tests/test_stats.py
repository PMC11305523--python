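import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obesim import stats
from oracles import (
    chi2_loop,
    ols_normal_equations,
    partial_corr_recursive,
    stable_subsets,
)


def _country_frame(n, seed=0, **columns):
    rng = np.random.default_rng(seed)
    base = {
        "nation": [f"c{i}" for i in range(n)],
        "development_class": ["developing"] * n,
    }
    base.update(columns)
    return pd.DataFrame(base)


class TestLogTransform:
    def test_log_identity_and_e(self):
        table = pd.DataFrame({"v": [1.0, math.e]})
        out = stats.log_transform(table, ["v"])
        assert out["v"].tolist() == pytest.approx([0.0, 1.0])

    def test_matches_elementwise_reference(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.5, 50.0, 10)
        table = pd.DataFrame({"v": values})
        out = stats.log_transform(table, ["v"])
        assert out["v"].to_numpy() == pytest.approx(np.log(values))

    def test_floor_rule(self):
        table = pd.DataFrame({"v": [0.0, 0.4, 2.0, -1.0]})
        out = stats.log_transform(table, ["v"])
        report = out.attrs["log_transform"]["cells"]["v"]
        assert report["n_floored"] == 2
        assert report["floor_value"] == pytest.approx(0.2)
        assert out["v"].iloc[0] == pytest.approx(math.log(0.2))

    def test_missing_mode(self):
        table = pd.DataFrame({"v": [0.0, 1.0]})
        out = stats.log_transform(table, ["v"], nonpositive="missing")
        assert np.isnan(out["v"].iloc[0])
        assert out.attrs["log_transform"]["cells"]["v"]["n_set_missing"] == 1

    def test_original_untouched(self):
        table = pd.DataFrame({"v": [1.0, 2.0]})
        stats.log_transform(table, ["v"])
        assert table["v"].tolist() == [1.0, 2.0]


class TestCorrelationMatrix:
    def test_diagonal_and_perfect_pair(self):
        table = pd.DataFrame({"x": np.arange(10.0) + 1, "y": 2 * (np.arange(10.0) + 1)})
        for method in (stats.PEARSON_ON_LOGS, stats.SPEARMAN_ON_RAW):
            cm = stats.correlation_matrix(table, ["x", "y"], method)
            assert cm.r.loc["x", "x"] == 1.0
            assert cm.r.loc["x", "y"] == pytest.approx(1.0)

    def test_matches_direct_covariance_oracle(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        cm = stats.correlation_matrix(table, ["a", "b", "c"], stats.PEARSON_ON_LOGS)
        for u in "abc":
            for v in "abc":
                x, y = table[u].to_numpy(), table[v].to_numpy()
                direct = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert cm.r.loc[u, v] == pytest.approx(direct, abs=1e-12)

    def test_pairwise_complete_n(self):
        table = pd.DataFrame(
            {"a": [1.0, 2, 3, np.nan, 5], "b": [2.0, 4, np.nan, 8, 10]}
        )
        cm = stats.correlation_matrix(table, ["a", "b"], stats.PEARSON_ON_LOGS)
        assert cm.n.loc["a", "b"] == 3
        assert cm.n.loc["a", "a"] == 4

    def test_insufficient_pairs_unavailable(self):
        table = pd.DataFrame({"a": [1.0, 2, np.nan], "b": [1.0, np.nan, 3]})
        cm = stats.correlation_matrix(table, ["a", "b"], stats.PEARSON_ON_LOGS)
        assert np.isnan(cm.r.loc["a", "b"])

    def test_absent_column_marked_unavailable(self):
        table = pd.DataFrame({"a": np.arange(5.0)})
        cm = stats.correlation_matrix(table, ["a", "zz"], stats.PEARSON_ON_LOGS)
        assert np.isnan(cm.r.loc["a", "zz"])
        assert cm.n.loc["a", "zz"] == 0

    def test_pearson_on_logs_equals_spearman_for_loglinear_data(self):
        x = np.linspace(1.0, 9.0, 15)
        table = pd.DataFrame({"x": x, "y": np.exp(0.5 + 2.0 * np.log(x))})
        logs = stats.log_transform(table, ["x", "y"])
        pear = stats.correlation_matrix(logs, ["x", "y"], stats.PEARSON_ON_LOGS)
        spear = stats.correlation_matrix(table, ["x", "y"], stats.SPEARMAN_ON_RAW)
        assert pear.r.loc["x", "y"] == pytest.approx(spear.r.loc["x", "y"])
        assert pear.r.loc["x", "y"] == pytest.approx(1.0)


class TestPartialCorrelation:
    def test_no_controls_reduces_to_pearson(self, small_table):
        res = stats.partial_correlation(small_table, "x", "y")
        assert res.r == pytest.approx(np.corrcoef(small_table["x"], small_table["y"])[0, 1])

    def test_matches_recursive_formula(self, small_table):
        for controls in [["z1"], ["z2"], ["z1", "z2"]]:
            res = stats.partial_correlation(small_table, "x", "y", controls)
            oracle = partial_corr_recursive(small_table, "x", "y", controls)
            assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_independent_controls_noop_at_large_n(self):
        rng = np.random.default_rng(9)
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        table = pd.DataFrame({"x": x, "y": y, "z": z})
        plain = stats.partial_correlation(table, "x", "y")
        partial = stats.partial_correlation(table, "x", "y", ["z"])
        assert partial.r == pytest.approx(plain.r, abs=0.02)

    def test_degrees_of_freedom_and_n(self, small_table):
        res = stats.partial_correlation(small_table, "x", "y", ["z1", "z2"])
        assert res.n == 12
        assert res.df == 12 - 2 - 2

    def test_too_few_rows(self):
        table = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3], "z": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            stats.partial_correlation(table, "x", "y", ["z"])

    def test_rank_deficient_controls_rejected(self, small_table):
        table = small_table.assign(z3=small_table["z1"] * 2.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            stats.partial_correlation(table, "x", "y", ["z1", "z3"])


class TestOlsRegression:
    def test_exact_linear_function(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=(2, 20))
        table = pd.DataFrame({"y": 1.0 + 2.0 * x1 - 3.0 * x2, "x1": x1, "x2": x2})
        fit = stats.ols_regression(table, "y", ["x1", "x2"])
        assert fit.params.loc["x1", "beta"] == pytest.approx(2.0)
        assert fit.params.loc["x2", "beta"] == pytest.approx(-3.0)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_pure_noise_beta_near_zero(self):
        rng = np.random.default_rng(3)
        n = 4000
        table = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        fit = stats.ols_regression(table, "y", ["x"])
        assert abs(fit.params.loc["x", "beta"]) < 0.08

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 8
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 0.5 - 1.2 * x1 + 0.7 * x2 + rng.normal(0, 0.3, size=n)
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = stats.ols_regression(table, "y", ["x1", "x2"])
        beta, se, p = ols_normal_equations(np.column_stack([np.ones(n), x1, x2]), y)
        assert fit.params["beta"].to_numpy() == pytest.approx(beta)
        assert fit.params["std_error"].to_numpy() == pytest.approx(se)
        assert fit.params["p"].to_numpy() == pytest.approx(p)
        assert fit.df2 == n - 2 - 1

    def test_collinear_predictors_rejected(self):
        table = pd.DataFrame({"y": [1.0, 2, 3, 4, 5], "a": [1.0, 2, 3, 4, 5]})
        table["b"] = 2 * table["a"]
        with pytest.raises(ValueError, match="collinear"):
            stats.ols_regression(table, "y", ["a", "b"])


class TestStepwise:
    def _planted(self, n=40, seed=8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        y = 1.5 * X[:, 1] - 2.0 * X[:, 3] + rng.normal(0, 1.0, size=n)
        cols = [f"v{i}" for i in range(5)]
        table = pd.DataFrame(X, columns=cols)
        table["y"] = y
        return table, cols

    def test_single_strong_candidate_selected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        table = pd.DataFrame({"y": 2 * x + rng.normal(0, 0.5, 50), "x": x})
        res = stats.stepwise_ols(table, "y", ["x"])
        assert res.selected == ("x",)
        assert res.steps[0].action == "enter"

    def test_single_weak_candidate_gives_empty_model(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"y": rng.normal(size=30), "x": rng.normal(size=30)})
        # verify the premise: the candidate really is non-significant
        assert stats.ols_regression(table, "y", ["x"]).params.loc["x", "p"] > 0.2
        res = stats.stepwise_ols(table, "y", ["x"])
        assert res.selected == ()
        assert res.fit is None

    def test_recovers_planted_pair(self):
        table, cols = self._planted()
        res = stats.stepwise_ols(table, "y", cols)
        assert sorted(res.selected) == ["v1", "v3"]

    def test_agrees_with_exhaustive_search(self):
        table, cols = self._planted()
        res = stats.stepwise_ols(table, "y", cols)
        stable = stable_subsets(table, "y", cols)
        assert tuple(sorted(res.selected)) in stable

    @pytest.mark.parametrize("seed", range(6))
    def test_final_model_is_stable_across_seeds(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = 45
        X = rng.normal(size=(n, 4))
        y = 1.2 * X[:, 0] + rng.normal(0, 1.0, size=n)
        cols = [f"v{i}" for i in range(4)]
        table = pd.DataFrame(X, columns=cols)
        table["y"] = y
        res = stats.stepwise_ols(table, "y", cols)
        assert tuple(sorted(res.selected)) in stable_subsets(table, "y", cols)

    def test_deterministic(self):
        table, cols = self._planted()
        a = stats.stepwise_ols(table, "y", cols)
        b = stats.stepwise_ols(table, "y", cols)
        assert a.selected == b.selected
        assert a.steps == b.steps


class TestMedianSplit:
    def test_one_to_four(self):
        table = pd.DataFrame({"v": [1.0, 2, 3, 4]})
        below, above, med = stats.median_split(table, "v")
        assert med == pytest.approx(2.5)
        assert len(below) == 2 and len(above) == 2

    def test_ties_go_below(self):
        table = pd.DataFrame({"v": [1.0, 2, 2, 3]})
        below, above, med = stats.median_split(table, "v")
        assert med == pytest.approx(2.0)
        assert len(below) == 3 and len(above) == 1

    def test_group_ranges(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"v": rng.uniform(0.0, 1.0, 31)})
        below, above, med = stats.median_split(table, "v")
        assert above["v"].min() > med
        assert below["v"].max() <= med

    def test_missing_rows_excluded(self):
        table = pd.DataFrame({"v": [1.0, np.nan, 3.0, 4.0]})
        below, above, med = stats.median_split(table, "v")
        assert len(below) + len(above) == 3

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            stats.median_split(pd.DataFrame({"v": [1.0, np.nan]}), "v")


class TestFitExponential:
    def test_exact_exponential(self):
        x = np.linspace(0.0, 2.0, 12)
        table = pd.DataFrame({"x": x, "y": np.exp(1.0 - 2.0 * x)})
        fit = stats.fit_exponential(table, "x", "y")
        assert fit.intercept == pytest.approx(1.0)
        assert fit.rate == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.predict([0.0])[0] == pytest.approx(math.e)

    def test_flat_data(self):
        table = pd.DataFrame({"x": np.arange(10.0), "y": np.full(10, 3.0)})
        fit = stats.fit_exponential(table, "x", "y")
        assert fit.rate == pytest.approx(0.0, abs=1e-12)

    def test_matches_log_level_ols_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 3, 25)
        y = np.exp(0.4 - 1.1 * x + rng.normal(0, 0.2, 25))
        table = pd.DataFrame({"x": x, "y": y})
        fit = stats.fit_exponential(table, "x", "y")
        beta, _, _ = ols_normal_equations(np.column_stack([np.ones(25), x]), np.log(y))
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.rate == pytest.approx(beta[1])

    def test_nonpositive_rows_dropped_and_counted(self):
        table = pd.DataFrame({"x": [0.0, 1, 2, 3, 4], "y": [1.0, -2.0, 4.0, 0.0, 16.0]})
        fit = stats.fit_exponential(table, "x", "y")
        assert fit.n_used == 3
        assert fit.n_dropped == 2


class TestVarianceExplained:
    def test_paper_rounding_examples(self):
        assert stats.variance_explained(-0.336) == pytest.approx(11.2896)
        assert round(stats.variance_explained(-0.336)) == 11
        assert stats.variance_explained(-0.573) == pytest.approx(32.8329)
        assert round(stats.variance_explained(-0.573)) == 33

    def test_zero(self):
        assert stats.variance_explained(0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.variance_explained(1.2)

    @given(r=st.floats(-1.0, 1.0))
    def test_bounds(self, r):
        v = stats.variance_explained(r)
        assert 0.0 <= v <= 100.0


class TestFisherZ:
    def test_equal_correlations(self):
        res = stats.fisher_z_compare(0.4, 50, 0.4, 80)
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation(self):
        res = stats.fisher_z_compare(0.5, 1000, 0.0, 1000)
        assert res.p_value < 1e-10

    def test_paper_partial_comparison_near_003(self):
        # above-median partial r vs all-nations partial r, 4 controls each;
        # the n's follow the printed regression dfs (64 and 133 complete rows)
        res = stats.fisher_z_compare(
            -0.573, 64, -0.336, 133, sidedness="two_sided", controls1=4, controls2=4
        )
        assert res.p_value == pytest.approx(0.03, abs=0.03)
        one = stats.fisher_z_compare(
            -0.573, 64, -0.336, 133, sidedness="one_sided", controls1=4, controls2=4
        )
        assert one.p_value == pytest.approx(res.p_value / 2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_z_compare(1.0, 50, 0.3, 50)


class TestContingency:
    def test_equal_cells_zero_chi2(self):
        res = stats.contingency_from_counts([[10, 10], [10, 10]])
        assert res.chi_squared == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_printed_counts_match_loop_oracle(self):
        counts = [[58, 22], [1, 47]]
        res = stats.contingency_from_counts(counts)
        assert res.chi_squared == pytest.approx(chi2_loop(counts), abs=1e-10)
        assert res.p_value < 1e-5
        assert res.row_percentages[0, 0] == pytest.approx(72.5)

    @pytest.mark.parametrize("counts", [
        [[5, 9], [3, 14]], [[40, 2], [7, 31]], [[12, 12], [1, 30]],
    ])
    def test_loop_oracle_various_tables(self, counts):
        res = stats.contingency_from_counts(counts)
        assert res.chi_squared == pytest.approx(chi2_loop(counts), abs=1e-10)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            stats.contingency_from_counts([[0, 0], [3, 4]])

    def test_yates_correction_flag(self):
        counts = [[12, 5], [3, 14]]
        plain = stats.contingency_from_counts(counts, correction=False)
        yates = stats.contingency_from_counts(counts, correction=True)
        assert yates.chi_squared < plain.chi_squared

    def test_classify_from_table(self):
        table = _country_frame(
            6,
            mmr_1990=[100.0, 700.0, 200.0, 900.0, 50.0, 600.0],
            obesity_2016=[25.0, 5.0, 30.0, 25.0, 10.0, 2.0],
        )
        res = stats.classify_and_contingency(table)
        # low MMR: 25, 30, 10 -> two high-obesity; high MMR: 5, 25, 2 -> one
        assert res.counts.tolist() == [[2, 1], [1, 2]]
        assert res.n == 6

    def test_empty_subset_rejected(self):
        table = _country_frame(3, mmr_1990=[1.0, 2.0, 3.0], obesity_2016=[1.0, 2.0, 3.0])
        table["development_class"] = "developed"
        with pytest.raises(ValueError):
            stats.classify_and_contingency(table)


class TestRowPercentages:
    def test_printed_values(self):
        pct = stats.row_percentages([[58, 22], [1, 47]])
        assert pct[0, 0] == pytest.approx(72.5)
        assert pct[1, 0] == pytest.approx(100.0 / 48.0)  # paper rounds to 2%

    def test_degenerate_full_row(self):
        assert stats.row_percentages([[7, 0]])[0].tolist() == [100.0, 0.0]

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            stats.row_percentages([[0, 0]])

    @given(a=st.integers(0, 50), b=st.integers(0, 50))
    @settings(max_examples=30)
    def test_rows_sum_to_hundred(self, a, b):
        if a + b == 0:
            return
        assert stats.row_percentages([[a, b]])[0].sum() == pytest.approx(100.0)
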