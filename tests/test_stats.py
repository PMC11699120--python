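"""Descriptive and univariable inferential statistics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from condylokit.stats import (
    compare_groups,
    describe,
    gee_logistic,
    gee_logistic_from_counts,
    univariable_logistic,
    univariable_logistic_from_counts,
)


class TestDescribe:
    def test_basic_moments(self):
        out = describe(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        row = out.loc["x"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["median"] == pytest.approx(2.0)

    def test_iqr_linear_interpolation(self):
        """Quartiles of 1..8 by linear interpolation: [2.75, 6.25]."""
        out = describe(pd.DataFrame({"x": np.arange(1.0, 9.0)}))
        assert out.loc["x", "q1"] == pytest.approx(2.75)
        assert out.loc["x", "q3"] == pytest.approx(6.25)

    def test_constant_column_sd_zero(self):
        out = describe(pd.DataFrame({"x": [4.0, 4.0, 4.0]}))
        assert out.loc["x", "sd"] == 0.0

    def test_categorical_counts(self):
        out = describe(pd.DataFrame({"sex": ["m", "f", "f", "f"]}))
        assert out.loc["sex=f", "count"] == 3
        assert out.loc["sex=f", "pct"] == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe(pd.DataFrame())


class TestUnivariableLogistic:
    def test_balanced_table_odds_ratio_one(self):
        fit = univariable_logistic_from_counts(["a", "b"], [20, 20], [20, 20], reference="a")
        assert fit.odds_ratio("b") == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_product_oracle(self, seed):
        """Categorical ML odds ratios equal the contingency cross-products."""
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(3, 80, size=4)
        fit = univariable_logistic_from_counts(["ref", "lvl"], [int(c), int(a)], [int(d), int(b)],
                                               reference="ref")
        assert fit.odds_ratio("lvl") == pytest.approx((a * d) / (b * c), rel=1e-8)

    def test_wald_ci_from_cell_counts(self):
        """The Wald CI equals exp(log OR +/- 1.96 sqrt(sum of 1/cells))."""
        fit = univariable_logistic_from_counts(["ref", "lvl"], [6, 7], [86, 20], reference="ref")
        se = np.sqrt(1 / 7 + 1 / 20 + 1 / 6 + 1 / 86)
        lo, hi = fit.ci("lvl")
        orr = (7 * 86) / (20 * 6)
        assert lo == pytest.approx(orr * np.exp(-1.959963984540054 * se), rel=1e-6)
        assert hi == pytest.approx(orr * np.exp(+1.959963984540054 * se), rel=1e-6)

    def test_continuous_predictor_matches_statsmodels(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 * x - 2)))).astype(int)
        fit = univariable_logistic(pd.Series(y), pd.Series(x, name="x"))
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(np.exp(ref.params[1]), rel=1e-8)

    def test_separated_level_reported_not_fatal(self):
        fit = univariable_logistic_from_counts(
            ["no", "bilateral"], [15, 0], [151, 10], reference="no"
        )
        assert fit.separated_levels == ["bilateral"]
        assert fit.odds_ratio("bilateral") == 0.0
        assert fit.ci("bilateral") == (0.0, np.inf)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            univariable_logistic(pd.Series([1, 1, 1]), pd.Series([1.0, 2.0, 3.0]))


class TestGEE:
    def test_point_estimates_match_glm_under_independence(self, rng):
        """Independence-working-correlation GEE point estimates coincide
        with ordinary logistic regression on clustered data."""
        n = 80
        cluster = np.repeat(np.arange(n), 2)
        x = rng.normal(size=2 * n)
        y = (rng.random(2 * n) < 1 / (1 + np.exp(-0.7 * x))).astype(int)
        gee = gee_logistic(pd.Series(y), pd.Series(x, name="x"), cluster)
        glm = univariable_logistic(pd.Series(y), pd.Series(x, name="x"))
        assert gee.table.loc["x", "odds_ratio"] == pytest.approx(
            glm.table.loc["x", "odds_ratio"], rel=1e-6
        )

    def test_singleton_clusters_reduce_to_robust_glm(self, rng):
        x = rng.normal(size=150)
        y = (rng.random(150) < 1 / (1 + np.exp(-x))).astype(int)
        gee = gee_logistic(pd.Series(y), pd.Series(x, name="x"), np.arange(150))
        hc0 = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit(cov_type="HC0")
        assert gee.table.loc["x", "odds_ratio"] == pytest.approx(np.exp(hc0.params[1]), rel=1e-8)
        assert gee.table.loc["x", "se_log"] == pytest.approx(hc0.bse[1], rel=1e-8)

    def test_duplicated_clusters_leave_or_and_robust_se_unchanged(self, rng):
        """Duplicating every row within its cluster leaves both the point
        estimate and the sandwich SE unchanged (bread doubles, meat
        quadruples)."""
        n = 60
        cluster = np.repeat(np.arange(n), 2)
        x = rng.normal(size=2 * n)
        y = (rng.random(2 * n) < 1 / (1 + np.exp(-0.6 * x))).astype(int)
        base = gee_logistic(pd.Series(y), pd.Series(x, name="x"), cluster)
        dup = gee_logistic(
            pd.Series(np.concatenate([y, y])),
            pd.Series(np.concatenate([x, x]), name="x"),
            np.concatenate([cluster, cluster]),
        )
        assert dup.table.loc["x", "odds_ratio"] == pytest.approx(
            base.table.loc["x", "odds_ratio"], rel=1e-6
        )
        assert dup.table.loc["x", "se_log"] == pytest.approx(
            base.table.loc["x", "se_log"], rel=1e-6
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            gee_logistic(pd.Series([0, 1]), pd.Series([1.0, 2.0]), np.zeros(2))

    def test_counts_interface_cross_product(self):
        fit = gee_logistic_from_counts(["ref", "lvl"], [7, 10], [177, 44], reference="ref")
        assert fit.odds_ratio("lvl") == pytest.approx((10 * 177) / (44 * 7), rel=1e-6)


class TestCompareGroups:
    def test_normal_samples_gate_to_anova(self):
        rng = np.random.default_rng(0)
        chosen = []
        for _ in range(40):
            v = np.concatenate([rng.normal(size=50), rng.normal(size=50)])
            g = np.repeat([0, 1], 50)
            chosen.append(compare_groups(v, g).test_used == "anova")
        assert np.mean(chosen) >= 0.8  # ~0.90 expected with a 5% gate per group

    def test_skewed_samples_gate_to_kruskal(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.lognormal(0, 1.0, 60), rng.lognormal(0, 1.0, 60)])
        g = np.repeat([0, 1], 60)
        assert compare_groups(v, g).test_used == "kruskal_wallis"

    def test_identical_groups_never_significant(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            base = rng.normal(size=30)
            v = np.concatenate([base, base])
            g = np.repeat([0, 1], 30)
            out = compare_groups(v, g)
            assert out.p_value > 0.05

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0] * 5 + [1.0, 2, 3, 4, 5]), np.repeat([0, 1], 5))
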