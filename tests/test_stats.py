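"""Correlation screen, logit transform, influence diagnostics and the
conflict regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from statsmodels.stats.outliers_influence import OLSInfluence

from vectsick import stats
from vectsick.stats import (
    SCREEN_PREDICTORS,
    fit_conflict_model,
    influence_diagnostics,
    influence_exclusion,
    inverse_logit_outcome,
    logit_outcome,
    spearman_screen,
    standardize_coefficients,
)


def cohort_frame(n=20, seed=0, **overrides):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"id": [f"p{i}" for i in range(n)]})
    df["mssq"] = rng.gamma(2.2, 7.5, n)
    df["conflict_pb"] = rng.uniform(0, 1, n)
    for col in SCREEN_PREDICTORS[2:]:
        df[col] = rng.normal(size=n)
    eta = -1.64 + 0.02 * df["mssq"] + 2.15 * df["conflict_pb"]
    eta = eta + rng.normal(0, 0.4, n)
    df["ssq_ts"] = inverse_logit_outcome(eta)
    df["sick"] = df["ssq_ts"] > 80
    for col, val in overrides.items():
        df[col] = val
    return df


class TestSpearmanScreen:
    def test_perfect_and_inverse_correlation(self):
        df = cohort_frame(15, seed=1)
        df["conflict_pb"] = df["ssq_ts"] / df["ssq_ts"].max()
        df["mssq"] = -df["ssq_ts"]
        out = spearman_screen(df).table
        assert out.loc["conflict_pb", "rho"] == pytest.approx(1.0)
        assert out.loc["mssq", "rho"] == pytest.approx(-1.0)

    def test_bonferroni_over_ten_predictors(self):
        out = spearman_screen(cohort_frame(19, seed=2))
        assert out.m_tests == 10
        t = out.table
        assert np.allclose(
            t["p_adjusted"], np.minimum(1.0, 10 * t["p"]), equal_nan=True
        )

    def test_constant_predictor_flagged(self):
        out = spearman_screen(cohort_frame(12, seed=3, n_hm=4)).table
        assert out.loc["n_hm", "degenerate"]
        assert np.isnan(out.loc["n_hm", "rho"])

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_screen(cohort_frame(2))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        """Spearman rho is unchanged by strictly monotone transforms."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        df = cohort_frame(12, seed=4, mssq=x, ssq_ts=100 + 10 * np.tanh(y))
        rho_raw = spearman_screen(df).table.loc["mssq", "rho"]
        df2 = df.assign(mssq=np.exp(x), ssq_ts=df["ssq_ts"] ** 3)
        rho_tr = spearman_screen(df2).table.loc["mssq", "rho"]
        assert rho_tr == pytest.approx(rho_raw)


class TestLogit:
    def test_midpoint_is_zero(self):
        assert logit_outcome(235.62 / 2) == pytest.approx(0.0)

    def test_known_value(self):
        # ssq_ts 79 -> p = 0.3353 -> ln(0.3353/0.6647)
        assert logit_outcome(79.0) == pytest.approx(-0.684, abs=0.001)

    @given(st.floats(0.5, 235.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_round_trip(self, ts):
        assert inverse_logit_outcome(logit_outcome(ts)) == pytest.approx(ts)

    @pytest.mark.parametrize("bad", [0.0, -3.0, 235.62, 300.0])
    def test_bounds_rejected(self, bad):
        with pytest.raises(ValueError, match="strictly inside"):
            logit_outcome(bad)


class TestInfluence:
    @pytest.mark.parametrize("n,p_extra,seed", [(8, 1, 0), (15, 2, 1), (25, 3, 2)])
    def test_matches_brute_force_leave_one_out(self, n, p_extra, seed):
        """Closed-form diagnostics equal explicit refit-without-case-i values."""
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p_extra))])
        y = X @ rng.normal(size=X.shape[1]) + rng.normal(size=n)
        fit = sm.OLS(y, X).fit()
        diag = influence_diagnostics(fit)
        p = X.shape[1]
        for i in range(n):
            mask = np.arange(n) != i
            loo = sm.OLS(y[mask], X[mask]).fit()
            resid_i = y[i] - X[i] @ loo.params
            # prediction variance at x_i from the leave-one-out fit
            var_i = loo.mse_resid * (1 + X[i] @ loo.normalized_cov_params @ X[i])
            t_brute = resid_i / np.sqrt(var_i)
            assert diag["studentized_external"][i] == pytest.approx(
                t_brute, abs=1e-8
            )
            yhat_full = X[i] @ fit.params
            yhat_loo = X[i] @ loo.params
            h_i = X[i] @ np.linalg.inv(X.T @ X) @ X[i]
            dffits_brute = (yhat_full - yhat_loo) / np.sqrt(loo.mse_resid * h_i)
            assert diag["dffits"][i] == pytest.approx(dffits_brute, abs=1e-8)

    def test_matches_statsmodels_olsinfluence(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = X @ [1.0, 0.5, -2.0] + rng.normal(size=20)
        fit = sm.OLS(y, X).fit()
        diag = influence_diagnostics(fit)
        infl = OLSInfluence(fit)
        assert np.allclose(diag["studentized_external"], infl.resid_studentized_external)
        assert np.allclose(diag["dffits"], infl.dffits[0])

    def test_noiseless_data_excludes_nothing(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = X @ [2.0, 3.0]
        keep, excl = influence_exclusion(y, X, np.arange(15))
        assert keep.all() and excl == []

    def test_gross_outlier_is_excluded(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(19), rng.normal(size=19)])
        y = X @ [1.0, 2.0] + rng.normal(0, 0.5, 19)
        y[7] += 10 * 0.5  # 10 residual SDs
        keep, excl = influence_exclusion(y, X, np.arange(19))
        assert 7 in excl
        assert not keep[7]

    def test_exclusion_floor_raises(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        y = rng.normal(size=5) * 100
        with pytest.raises(ValueError, match="too few cases"):
            influence_exclusion(y, X, np.arange(5), iterate=True)


class TestConflictModel:
    def test_noiseless_recovery_is_exact(self):
        df = cohort_frame(25, seed=11)
        eta = -1.64 + 0.02 * df["mssq"] + 2.15 * df["conflict_pb"]
        df["ssq_ts"] = inverse_logit_outcome(eta)
        res = fit_conflict_model(df)
        assert res.coefficients["estimate"].to_numpy() == pytest.approx(
            [-1.64, 0.02, 2.15], abs=1e-9
        )
        assert res.r_squared_retained == pytest.approx(100.0)
        assert res.excluded_ids == ()

    def test_nested_f_equals_squared_t(self):
        """Adding one predictor: the F-test p equals the added coefficient's
        t-test p and F = t^2."""
        df = cohort_frame(19, seed=12)
        res = fit_conflict_model(df)
        keep = ~df["id"].isin(res.excluded_ids)
        y = logit_outcome(df.loc[keep, "ssq_ts"].to_numpy())
        X = sm.add_constant(df.loc[keep, ["mssq", "conflict_pb"]].to_numpy())
        fit = sm.OLS(y, X).fit()
        t_conf = fit.tvalues[2]
        assert res.nested_f["F"] == pytest.approx(t_conf**2, rel=1e-10)
        assert res.nested_f["p"] == pytest.approx(fit.pvalues[2], rel=1e-10)
        assert res.nested_f["df2"] == res.n_retained - 3

    def test_standardized_estimates_match_zscore_refit(self):
        df = cohort_frame(21, seed=13)
        res = fit_conflict_model(df)
        keep = ~df["id"].isin(res.excluded_ids)
        y = logit_outcome(df.loc[keep, "ssq_ts"].to_numpy())
        Z = df.loc[keep, ["mssq", "conflict_pb"]].to_numpy()
        Zs = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        zfit = sm.OLS(ys, sm.add_constant(Zs)).fit()
        assert res.coefficients["standardized"].to_numpy()[1:] == pytest.approx(
            zfit.params[1:], rel=1e-9
        )

    def test_r2_never_drops_when_predictor_added(self):
        for seed in range(5):
            res = fit_conflict_model(cohort_frame(19, seed=seed))
            assert res.r_squared_retained >= res.r_squared_mssq_only

    def test_standardize_rejects_constant_predictor(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(10), np.full(10, 2.0)])
        y = rng.normal(size=10)
        fit = sm.OLS(y, X).fit()
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_coefficients(fit, X, y)

    def test_overall_r2_scores_model_on_all_cases(self):
        df = cohort_frame(19, seed=14)
        res = fit_conflict_model(df)
        y = logit_outcome(df["ssq_ts"].to_numpy())
        X = sm.add_constant(df[["mssq", "conflict_pb"]].to_numpy())
        pred = X @ res.coefficients["estimate"].to_numpy()
        assert res.r_squared_overall == pytest.approx(
            100 * np.corrcoef(y, pred)[0, 1] ** 2
        )
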