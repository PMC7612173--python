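"""Concrete estimating functions, nuisance fits and CSV schemas."""

import numpy as np
import pandas as pd
import pytest

from betel.exceptions import ValidationError
from betel.io import validate_design_frame, validate_obs_frame, load_design_csv
from betel.mestimation import solve_m_estimator
from betel.moments import (
    aipw,
    design_matrix,
    design_moment,
    dr_moment,
    fit_logistic,
    fit_wls,
    logistic_score,
    ols_score,
    sequential_dr_fit,
    stacked_dr_model,
    weighted_linreg_moment,
)
from betel.simulation import gen_design_data, gen_ks_data, DESIGN_TRUTH


class TestDesignMoment:
    def test_unselected_records_contribute_exact_zero(self, design_toy):
        model = design_moment(
            lambda df, th: df["Y"].to_numpy(float) - th[0], dim=1
        )
        # NaN-masked Y must not leak: rows with R=0 are exactly 0
        with np.errstate(invalid="ignore"):
            G = model.moments(design_toy.assign(Y=design_toy.Y.fillna(np.nan)), [0.3])
        assert G[2, 0] == 0.0

    def test_single_record_arithmetic(self):
        df = pd.DataFrame({"R": [1], "Y": [1.0], "pi": [0.5]})
        model = design_moment(lambda d, th: d["Y"].to_numpy(float) - th[0], dim=1)
        assert model.moments(df, [0.0])[0, 0] == pytest.approx(2.0)

    def test_linear_regression_moment_matches_weighted_normal_equations(self):
        # u(Z, theta) = X'(Y - X theta) on 3 selected records
        df = pd.DataFrame(
            {
                "R": [1, 1, 1],
                "Y": [1.0, 2.0, 2.5],
                "pi": [0.5, 1.0, 0.25],
                "X1": [0.0, 1.0, 2.0],
            }
        )

        def u(d, th):
            X = design_matrix(d, ["X1"])
            return (d["Y"].to_numpy(float) - X @ th)[:, None] * X

        model = design_moment(u, dim=2)
        est = solve_m_estimator(model, df, np.zeros(2), tol=1e-12)
        # weighted normal equations with weights 1/pi
        X = design_matrix(df, ["X1"])
        w = 1.0 / df["pi"].to_numpy(float)
        ref = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * df["Y"].to_numpy()))
        np.testing.assert_allclose(est.theta_hat, ref, atol=1e-9)


class TestScores:
    def test_score_averages_vanish_at_reference_fits(self, ks_df):
        sm = pytest.importorskip("statsmodels.api")
        cols = ["W1", "W2", "W3", "W4"]
        X = design_matrix(ks_df, cols)
        r = ks_df["R"].to_numpy(float)
        y = np.where(r == 1, ks_df["Y"].to_numpy(float), 0.0)

        alpha = fit_logistic(X, r)
        alpha_ref = sm.GLM(r, X, family=sm.families.Binomial()).fit().params
        np.testing.assert_allclose(alpha, alpha_ref, atol=1e-6)
        assert np.max(np.abs(logistic_score(X, r, alpha).mean(axis=0))) < 1e-9

        sel = r == 1
        beta = fit_wls(X[sel], y[sel])
        beta_ref = sm.OLS(y[sel], X[sel]).fit().params
        np.testing.assert_allclose(beta, beta_ref, atol=1e-6)
        assert np.max(np.abs(ols_score(X, y, r, beta).mean(axis=0))) < 1e-9

    def test_ols_score_zero_for_unselected(self, ks_df):
        cols = ["W1", "W2", "W3", "W4"]
        X = design_matrix(ks_df, cols)
        r = ks_df["R"].to_numpy(float)
        y = np.where(r == 1, ks_df["Y"].to_numpy(float), 0.0)
        S = ols_score(X, y, r, np.zeros(5))
        assert np.all(S[r == 0] == 0.0)

    def test_weighted_logistic_matches_statsmodels(self, ks_df):
        sm = pytest.importorskip("statsmodels.api")
        cols = ["W1", "W2", "W3", "W4"]
        X = design_matrix(ks_df, cols)
        r = ks_df["R"].to_numpy(float)
        w = np.random.default_rng(3).dirichlet(np.ones(len(ks_df)))
        alpha = fit_logistic(X, r, w)
        ref = (
            sm.GLM(r, X, family=sm.families.Binomial(), var_weights=w)
            .fit()
            .params
        )
        np.testing.assert_allclose(alpha, ref, atol=1e-6)


class TestDoublyRobustMoment:
    def test_reduces_to_plain_mean_without_selection(self):
        n = 6
        r = np.ones(n)
        y = np.arange(1.0, n + 1)
        X = np.column_stack([np.ones(n), np.zeros(n)])
        # alpha huge -> propensity ~ 1
        alpha = np.array([40.0, 0.0])
        beta = np.array([2.0, 0.0])
        h = dr_moment(r, y, X, X, alpha, beta, gamma=y.mean())
        assert h.mean() == pytest.approx(0.0, abs=1e-10)

    def test_constant_outcome_model_gives_augmented_ipw(self):
        # phi = c - gamma constant: averaged h = 0 has the closed form
        # gamma = mean[R Y / pi - c (R/pi - 1)]
        r = np.array([1.0, 1.0, 0.0, 1.0])
        y = np.array([2.0, 1.0, 0.0, 3.0])
        X_ps = np.column_stack([np.ones(4), np.array([0.0, 1.0, 2.0, 0.5])])
        alpha = np.array([0.3, -0.4])
        c = 1.7
        X_or = np.column_stack([np.ones(4), np.zeros(4)])
        beta = np.array([c, 0.0])
        from scipy.special import expit

        pi = expit(X_ps @ alpha)
        inv = np.where(r == 1, 1 / pi, 0.0)
        gamma_hand = np.mean(r * y * inv - c * (r * inv - 1.0))
        h = dr_moment(r, y, X_ps, X_or, alpha, beta, gamma_hand)
        assert h.mean() == pytest.approx(0.0, abs=1e-12)

    def test_aipw_toys(self):
        # all selected, unit propensity -> sample mean
        df = pd.DataFrame(
            {"R": [1, 1, 1], "Y": [1.0, 2.0, 6.0], "W1": [0.0, 0.0, 0.0]}
        )
        mu = aipw(df, ["W1"], ["W1"], alpha=[40.0, 0.0], beta=[0.0, 0.0])
        assert mu == pytest.approx(3.0)

    def test_aipw_hand_computed_four_records(self):
        # pi_hat = (0.5, 0.5, 0.25, 1), m_hat = (1, 2, 0, 1),
        # R = (1,1,0,1), Y = (2,1,-,3):
        # terms 4-1=3, 2-2=0, 0, 3-0=3 -> mean 1.5
        r = np.array([1.0, 1.0, 0.0, 1.0])
        y = np.array([2.0, 1.0, 0.0, 3.0])
        pi_hat = np.array([0.5, 0.5, 0.25, 1.0])
        m_hat = np.array([1.0, 2.0, 0.0, 1.0])
        inv = np.where(r == 1, 1 / pi_hat, 0.0)
        val = np.mean(r * y * inv - m_hat * (r * inv - 1.0))
        assert val == pytest.approx(1.5)

    def test_stacked_root_equals_aipw_at_nuisance_fits(self, ks_df):
        cols = ["W1", "W2", "W3", "W4"]
        alpha, beta, gamma = sequential_dr_fit(ks_df, cols, cols)
        assert gamma == pytest.approx(aipw(ks_df, cols, cols, alpha, beta), abs=1e-12)
        model = stacked_dr_model(cols, cols)
        est = solve_m_estimator(model, ks_df, model.default_init(ks_df))
        assert est.theta_hat[-1] == pytest.approx(gamma, abs=1e-8)


class TestWeightedLinreg:
    def _frame(self):
        rng = np.random.default_rng(4)
        n = 5
        return pd.DataFrame(
            {
                "R": np.ones(n, dtype=int),
                "Y": rng.normal(size=n),
                "X1": rng.normal(size=n),
                "X2": rng.normal(size=n),
                "weight": np.array([1.0, 2.0, 0.5, 1.5, 3.0]),
            }
        )

    def test_five_record_toy_matches_normal_equations(self):
        df = self._frame()
        model = weighted_linreg_moment(["X1", "X2"])
        est = solve_m_estimator(model, df, np.zeros(3), tol=1e-12)
        X = design_matrix(df, ["X1", "X2"])
        w = df["weight"].to_numpy()
        ref = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * df["Y"].to_numpy()))
        np.testing.assert_allclose(est.theta_hat, ref, atol=1e-8)

    def test_equal_weights_give_ols(self):
        df = self._frame().assign(weight=1.0)
        model = weighted_linreg_moment(["X1", "X2"])
        est = solve_m_estimator(model, df, np.zeros(3), tol=1e-12)
        X = design_matrix(df, ["X1", "X2"])
        ref, *_ = np.linalg.lstsq(X, df["Y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(est.theta_hat, ref, atol=1e-8)

    def test_weight_rescaling_invariance(self):
        df = self._frame()
        model = weighted_linreg_moment(["X1", "X2"])
        a = solve_m_estimator(model, df, np.zeros(3), tol=1e-12).theta_hat
        df2 = df.assign(weight=df["weight"] * 7.3)
        b = solve_m_estimator(model, df2, np.zeros(3), tol=1e-12).theta_hat
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestSchemas:
    def test_design_round_trip(self, tmp_path, design_df_small):
        path = tmp_path / "d.csv"
        design_df_small.to_csv(path, index=False)
        df = load_design_csv(path)
        assert (df["R"] == design_df_small["R"]).all()
        # unobserved rows stay masked
        assert df.loc[df.R == 0, "Y"].isna().all()

    def test_blank_versus_zero_enforced(self):
        bad = pd.DataFrame({"R": [1, 0], "Y": [1.0, 0.0], "pi": [0.5, np.nan]})
        with pytest.raises(ValidationError):
            validate_design_frame(bad)

    def test_pi_range_enforced(self):
        bad = pd.DataFrame({"R": [1], "Y": [1.0], "pi": [1.5]})
        with pytest.raises(ValidationError):
            validate_design_frame(bad)
        bad = pd.DataFrame({"R": [1], "Y": [1.0], "pi": [0.0]})
        with pytest.raises(ValidationError):
            validate_design_frame(bad)

    def test_missing_observed_outcome_rejected(self):
        bad = pd.DataFrame({"R": [1], "Y": [np.nan], "pi": [0.5]})
        with pytest.raises(ValidationError):
            validate_design_frame(bad)

    def test_obs_frame_requires_complete_covariates(self):
        bad = pd.DataFrame({"R": [1, 0], "Y": [1.0, np.nan], "W1": [0.1, np.nan]})
        with pytest.raises(ValidationError):
            validate_obs_frame(bad)


class TestUnbiasednessTransfer:
    def test_design_moment_is_unbiased_at_truth(self):
        """Monte-Carlo mean of g(D, theta_0) vanishes within 3 SEs."""
        df = gen_design_data(1_000_000, seed=99)
        from betel.moments import design_mean_model

        G = design_mean_model().moments(df, np.array([DESIGN_TRUTH]))
        se = G.std(ddof=1) / np.sqrt(G.shape[0])
        assert abs(G.mean()) < 3 * se


class TestDoubleRobustnessBias:
    @pytest.mark.parametrize("ps_correct,or_correct", [(True, False), (False, True)])
    def test_one_correct_model_keeps_estimator_unbiased(self, ps_correct, or_correct):
        from betel.simulation import ks_columns, KS_TRUTH

        reps, n = 500, 200
        est = np.empty(reps)
        for r in range(reps):
            df = gen_ks_data(n, seed=50_000 + r)
            _, _, est[r] = sequential_dr_fit(
                df, ks_columns(ps_correct), ks_columns(or_correct)
            )
        bias = est.mean() - KS_TRUTH
        esd = est.std(ddof=1)
        assert abs(bias) < 3 * esd / np.sqrt(reps)
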