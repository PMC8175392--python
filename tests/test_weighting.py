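"""CBPS propensity fits, stabilized weights, imputation, balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sitmir.synthetic import generate_confounded_trial
from sitmir.weighting import (
    FitError,
    PropensityFit,
    balance_report,
    cbps_fit,
    impute_pmm,
    stabilized_weights,
    weighted_ks,
)


def _logit(p):
    return np.log(p / (1 - p))


class TestCbpsFit:
    def test_exact_first_moment_balance(self):
        X, t, _, _ = generate_confounded_trial(200, confounding=0.8, seed=2)
        fit = cbps_fit(X, t)
        w = stabilized_weights(fit, t)
        for col in X.columns:
            v = X[col].to_numpy()
            diff = np.average(v[t == 1], weights=w[t == 1]) - np.average(
                v[t == 0], weights=w[t == 0]
            )
            assert abs(diff) < 1e-6

    def test_no_confounding_limit_gives_flat_propensity(self):
        X, t, _, _ = generate_confounded_trial(4000, confounding=0.0, seed=3)
        fit = cbps_fit(X, t)
        assert np.std(fit.propensities) < 0.05
        assert np.abs(fit.propensities - t.mean()).max() < 0.2

    def test_binary_covariate_matches_closed_form(self):
        # with one binary covariate the moment equations decouple per level:
        # pi(x) equals the within-level treated fraction, so
        # b0 = logit(p(x=0)), b1 = logit(p(x=1)) - logit(p(x=0))
        x = np.array([0] * 40 + [1] * 40, dtype=float)
        t = np.concatenate([np.repeat([1, 0], [10, 30]), np.repeat([1, 0], [25, 15])])
        fit = cbps_fit(x[:, None], t.astype(float))
        b0_expected = _logit(10 / 40)
        b1_expected = _logit(25 / 40) - _logit(10 / 40)
        assert fit.beta[0] == pytest.approx(b0_expected, abs=1e-6)
        assert fit.beta[1] == pytest.approx(b1_expected, abs=1e-6)

    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        t = np.tile([0.0, 1.0], 10)
        with pytest.raises(ValueError, match="a"):
            cbps_fit(X, t)

    def test_single_arm_rejected(self):
        with pytest.raises(FitError):
            cbps_fit(np.arange(10.0)[:, None], np.ones(10))

    def test_infeasible_balance_errors_by_default(self):
        # 2 controls cannot span the treated mean of 2 covariates in general
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        X[:2] += 10.0  # controls far outside the treated cloud
        t = np.array([0.0, 0.0] + [1.0] * 10)
        with pytest.raises(FitError):
            cbps_fit(X, t)
        fit = cbps_fit(X, t, on_infeasible="best")
        assert not fit.converged
        assert fit.residual_norm > 0


class TestStabilizedWeights:
    def test_flat_propensity_gives_unit_weights(self):
        t = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        fit = PropensityFit(
            beta=np.zeros(1),
            propensities=np.full(5, 0.4),
            residual_norm=0.0,
            converged=True,
            n_iter=0,
        )
        assert stabilized_weights(fit, t) == pytest.approx(np.ones(5))

    def test_arm_means_are_one(self):
        X, t, _, _ = generate_confounded_trial(150, confounding=0.9, seed=5)
        w = stabilized_weights(cbps_fit(X, t), t)
        assert np.mean(w[t == 1]) == pytest.approx(1.0)
        assert np.mean(w[t == 0]) == pytest.approx(1.0)

    def test_covariate_scaling_invariance(self):
        X, t, _, _ = generate_confounded_trial(150, confounding=0.9, seed=6)
        w1 = stabilized_weights(cbps_fit(X, t), t)
        X2 = X.copy()
        X2["bmi"] = X2["bmi"] * 10
        w2 = stabilized_weights(cbps_fit(X2, t), t)
        assert w1 == pytest.approx(w2, abs=1e-5)


class TestImputePmm:
    def _table(self, n=80, missing=0.15, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "a": x + rng.normal(0, 0.5, n),
                "b": 2 * x + rng.normal(0, 0.5, n),
                "c": rng.normal(5, 1, n),
            }
        )
        complete = df.copy()
        df.loc[rng.random(n) < missing, "a"] = np.nan
        return df, complete

    def test_complete_table_unchanged(self):
        df, _ = self._table(missing=0.0)
        pd.testing.assert_frame_equal(impute_pmm(df, seed=1), df)

    def test_imputed_values_come_from_observed_support(self):
        df, _ = self._table()
        out = impute_pmm(df, seed=1)
        observed = set(df["a"].dropna())
        imputed = out.loc[df["a"].isna(), "a"]
        assert imputed.notna().all()
        assert all(v in observed for v in imputed)

    def test_mcar_mean_recovered_over_replicates(self):
        errs = []
        for r in range(60):
            df, complete = self._table(n=100, missing=0.1, seed=100 + r)
            out = impute_pmm(df, seed=r)
            errs.append(out["a"].mean() - complete["a"].mean())
        se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 3 * se + 0.02

    def test_entirely_missing_variable_rejected(self):
        df, _ = self._table()
        df["a"] = np.nan
        with pytest.raises(ValueError, match="a"):
            impute_pmm(df, seed=1)

    def test_seeded_determinism(self):
        df, _ = self._table()
        pd.testing.assert_frame_equal(impute_pmm(df, seed=7), impute_pmm(df, seed=7))


class TestBalanceReport:
    def _data(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = (rng.random(n) < 0.5).astype(float)
        return X, t

    def test_identical_arms_have_zero_imbalance(self):
        X, _ = self._data()
        X2 = pd.concat([X, X], ignore_index=True)
        t = np.concatenate([np.zeros(len(X)), np.ones(len(X))])
        rep = balance_report(X2, t, np.ones(len(X2)))
        assert np.allclose(rep["std_diff_weighted"], 0)
        assert np.allclose(rep.loc[rep["kind"] == "covariate", "ks_weighted"], 0)

    def test_unit_weights_reduce_to_classical_formula(self):
        X, t = self._data(seed=3)
        rep = balance_report(X, t, np.ones(len(X)), include_interactions=False)
        for col in ("a", "b"):
            v = X[col].to_numpy()
            pooled = np.sqrt((v[t == 1].std(ddof=1) ** 2 + v[t == 0].std(ddof=1) ** 2) / 2)
            expected = (v[t == 1].mean() - v[t == 0].mean()) / pooled
            assert rep.loc[col, "std_diff_weighted"] == pytest.approx(expected)
            assert rep.loc[col, "std_diff_unweighted"] == pytest.approx(expected)

    def test_post_cbps_first_moments_balance(self):
        X, t, _, _ = generate_confounded_trial(180, confounding=0.8, seed=8)
        w = stabilized_weights(cbps_fit(X, t), t)
        rep = balance_report(X, t, w)
        raw = rep[rep["kind"] == "covariate"]
        assert raw["std_diff_weighted"].abs().max() < 1e-6

    def test_weighting_reduces_imbalance_on_confounded_data(self):
        pre, post = [], []
        for r in range(30):
            X, t, _, _ = generate_confounded_trial(150, confounding=0.9, seed=300 + r)
            w = stabilized_weights(cbps_fit(X, t, on_infeasible="best"), t)
            rep = balance_report(X, t, w)
            raw = rep[rep["kind"] == "covariate"]
            pre.append(raw["std_diff_unweighted"].abs().mean())
            post.append(raw["std_diff_weighted"].abs().mean())
        assert np.mean(post) < np.mean(pre)

    def test_weighted_ks_with_unit_weights_matches_scipy(self):
        rng = np.random.default_rng(4)
        x1, x0 = rng.normal(0, 1, 60), rng.normal(0.5, 1.2, 45)
        ks = weighted_ks(x1, x0, np.ones(60), np.ones(45))
        assert ks == pytest.approx(stats.ks_2samp(x1, x0).statistic)
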