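"""Weighted ATE estimation, bootstrap, two-step selection, correlation, WLS."""

import numpy as np
import pandas as pd
import pytest

from sitmir.datasets import SCREENING_SELECTED, SCREENING_TOP10
from sitmir.effects import (
    bootstrap_ate_table,
    interaction_wls,
    pearson_correlation,
    rank_and_select,
    validate_significance,
    weighted_ate,
    weighted_ate_bootstrap,
)
from sitmir.synthetic import generate_confounded_trial


class TestWeightedAte:
    def test_unit_weights_give_simple_mean_difference(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        t = np.repeat([1.0, 0.0], 15)
        assert weighted_ate(y, t, np.ones(30)) == pytest.approx(
            y[:15].mean() - y[15:].mean()
        )

    def test_hand_computed_weighted_means(self):
        y = np.array([2.0, 4.0, 6.0, 1.0, 3.0, 5.0])
        t = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        w = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 1.0])
        treated = (2 + 8 + 6) / 4
        control = (3 + 3 + 5) / 5
        assert weighted_ate(y, t, w) == pytest.approx(treated - control)

    def test_tiny_arm_is_inestimable(self):
        y = np.array([1.0, 2.0, 3.0])
        assert np.isnan(weighted_ate(y, [1, 0, 0], np.ones(3)))


class TestBootstrapAte:
    def _trial(self, n=90, seed=0):
        X, t, y, _ = generate_confounded_trial(n, effect=1.0, confounding=0.6, seed=seed)
        return X, t, y

    def test_boot_sd_stabilizes_with_more_resamples(self):
        X, t, y = self._trial()
        a = weighted_ate_bootstrap(y, X, t, B=300, seed=4)
        b = weighted_ate_bootstrap(y, X, t, B=600, seed=4)
        assert abs(b.boot_sd - a.boot_sd) / a.boot_sd < 0.05

    def test_scale_equivariance(self):
        X, t, y = self._trial()
        a = weighted_ate_bootstrap(y, X, t, B=100, seed=9)
        b = weighted_ate_bootstrap(3.0 * y, X, t, B=100, seed=9)
        assert b.ate == pytest.approx(3.0 * a.ate)
        assert b.boot_sd == pytest.approx(3.0 * a.boot_sd, rel=1e-9)

    def test_matrix_and_single_row_agree(self):
        X, t, y = self._trial(n=60, seed=3)
        expr = pd.DataFrame([y, 2 * y], index=["m1", "m2"])
        table = bootstrap_ate_table(expr, X, t, B=80, seed=5)
        single = weighted_ate_bootstrap(y, X, t, B=80, seed=5, mir="m1")
        assert table.loc["m1", "ate"] == pytest.approx(single.ate)
        assert table.loc["m1", "boot_sd"] == pytest.approx(single.boot_sd)

    def test_percentile_ci_available(self):
        X, t, y = self._trial(n=60, seed=3)
        rec = weighted_ate_bootstrap(y, X, t, B=200, seed=5, ci_method="percentile")
        assert rec.ci_low < rec.ate < rec.ci_high


class TestRankAndSelect:
    def test_reported_screening_rows_recover_starred_set(self):
        sel = rank_and_select(SCREENING_TOP10)
        assert set(sel.selected) == set(SCREENING_SELECTED)
        assert sel.ranked.loc["miR-133b", "std_ate_rank"] == 7

    def test_degenerate_small_table_keeps_everything(self):
        table = SCREENING_TOP10.iloc[:4]
        sel = rank_and_select(table)
        assert set(sel.top10) == set(table.index)
        assert set(sel.selected) == set(table.index)

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "ate": rng.normal(size=84),
                "std_ate": rng.normal(size=84),
                "unweighted_sd": rng.uniform(0.1, 5, 84),
            },
            index=[f"miR-x{i}" for i in range(84)],
        )
        sel = rank_and_select(table)
        order = sorted(
            table.index, key=lambda m: (-abs(table.loc[m, "std_ate"]), -abs(table.loc[m, "ate"]), m)
        )
        top10 = order[:10]
        expected = sorted(top10, key=lambda m: -table.loc[m, "unweighted_sd"])[:5]
        assert sel.top10 == top10
        assert set(sel.selected) == set(expected)

    def test_inestimable_rows_are_dropped(self):
        table = SCREENING_TOP10.copy()
        table.loc["miR-broken"] = [np.nan, np.nan, np.nan]
        sel = rank_and_select(table)
        assert "miR-broken" not in sel.ranked.index


class TestSignificance:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.108, 0.228, True),  # excludes zero from above
            (-0.026, 0.138, False),  # straddles zero
            (0.000, 0.0206, False),  # zero on the boundary is not exclusion
            (-0.5, -0.1, True),  # excludes zero from below
        ],
    )
    def test_zero_exclusion_rule(self, lo, hi, expected):
        table = pd.DataFrame({"ci_low": [lo], "ci_high": [hi]}, index=["m"])
        assert bool(validate_significance(table).iloc[0]) is expected

    def test_null_effect_never_significant(self):
        table = pd.DataFrame({"ci_low": [0.0], "ci_high": [0.0]}, index=["m"])
        assert not validate_significance(table).any()


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.linspace(0, 1, 20)
        assert pearson_correlation(x, x)["combined"] == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 3)["combined"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=50), rng.normal(size=50)
        expected = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert pearson_correlation(x, y)["combined"] == pytest.approx(expected)

    def test_stratified_output(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.3, size=40)
        groups = np.repeat(["IS+", "SS+"], 20)
        out = pearson_correlation(x, y, groups)
        assert set(out) == {"combined", "IS+", "SS+"}
        assert all(np.isfinite(v) for v in out.values())

    def test_zero_variance_is_undefined(self):
        out = pearson_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(out["combined"])


class TestInteractionWls:
    def _design(self, n=200, interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = (rng.random(n) < 0.5).astype(float)
        h = (rng.random(n) < 0.4).astype(float)
        y = 1.0 + 0.5 * t + 0.2 * h + interaction * t * h + rng.normal(0, 1, n)
        return y, t, h

    def test_unit_weights_match_ols(self):
        import statsmodels.api as sm

        y, t, h = self._design(seed=2)
        out = interaction_wls(y, t, h, np.ones_like(y))
        X = np.column_stack([np.ones_like(t), t, h, t * h])
        ols = sm.OLS(y, X).fit()
        assert out["coef"].to_numpy() == pytest.approx(ols.params)

    def test_interaction_recovery_within_three_se(self):
        y, t, h = self._design(n=400, interaction=1.0, seed=3)
        out = interaction_wls(y, t, h, np.ones_like(y))
        est, se = out.loc["group:hispanic", ["coef", "se"]]
        assert abs(est - 1.0) < 3 * se

    def test_type_one_error_near_nominal(self):
        rejections = 0
        reps = 400
        for r in range(reps):
            y, t, h = self._design(n=200, interaction=0.0, seed=1000 + r)
            out = interaction_wls(y, t, h, np.ones_like(y))
            rejections += out.loc["group:hispanic", "p"] < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_empty_cell_rejected(self):
        y, t, h = self._design(seed=4)
        h[t == 1] = 0.0
        with pytest.raises(ValueError, match="cell"):
            interaction_wls(y, t, h, np.ones_like(y))
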