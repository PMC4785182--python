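"""Vieira-Morf estimation, stability, whiteness battery, order selection."""

import numpy as np
import pytest

from stepnet.mvar import (MVARWindowModel, box_pierce, check_stability,
                          fit_mvar_vieira_morf, ljung_box, mcleod_li,
                          mvar_residuals, select_model_order)
from stepnet.mvar import test_whiteness as whiteness_battery


def _simulate_var(A_list, n, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    m = A_list[0].shape[0]
    p = len(A_list)
    X = np.zeros((m, n))
    for t in range(p, n):
        X[:, t] = sum(A @ X[:, t - k - 1] for k, A in enumerate(A_list))
        X[:, t] += sd * rng.standard_normal(m)
    return X


class TestVieiraMorf:
    def test_scalar_ar1_recovered(self):
        X = _simulate_var([np.array([[0.5]])], 10_000, seed=0)
        model = fit_mvar_vieira_morf(X, 1)
        assert model.A[0, 0, 0] == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_least_squares_on_long_data(self):
        """VM and OLS coincide asymptotically; statsmodels VAR is the
        independent least-squares oracle."""
        import statsmodels.tsa.api as tsa

        A1 = np.array([[0.5, 0.3], [0.0, 0.4]])
        X = _simulate_var([A1], 10_000, seed=1)
        model = fit_mvar_vieira_morf(X, 1)
        ols = tsa.VAR(X.T).fit(1, trend="n")
        assert np.abs(model.A[0] - ols.coefs[0]).max() < 1e-2
        assert np.abs(model.sigma - ols.sigma_u_mle).max() < 0.05

    def test_order_zero_returns_sample_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 5000))
        model = fit_mvar_vieira_morf(X, 0)
        Xc = X - X.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(model.sigma, Xc @ Xc.T / 5000, atol=1e-9)
        assert model.order == 0 and model.A.shape == (0, 3, 3)

    def test_multi_trial_pooling_matches_long_fit_statistically(self):
        A1 = np.array([[0.6, 0.2], [-0.1, 0.5]])
        trials = np.stack([_simulate_var([A1], 200, seed=10 + i)
                           for i in range(100)])
        model = fit_mvar_vieira_morf(trials, 1)
        assert np.abs(model.A[0] - A1).max() < 0.05
        assert model.n_trials == 100

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_mvar_vieira_morf(np.zeros((5, 8)), 3)


class TestStability:
    @pytest.mark.parametrize("a, stable, radius", [
        (0.5, True, 0.5),
        (1.1, False, 1.1),
    ])
    def test_scalar_cases(self, a, stable, radius):
        m = MVARWindowModel(order=1, A=np.array([[[a]]]),
                            sigma=np.eye(1), n_eff=100)
        got_stable, got_radius = check_stability(m)
        assert got_stable is stable
        assert got_radius == pytest.approx(radius)

    def test_triangular_matrix_radius_from_diagonal(self):
        m = MVARWindowModel(order=1,
                            A=np.array([[[0.5, 0.3], [0.0, 0.4]]]),
                            sigma=np.eye(2), n_eff=100)
        _, radius = check_stability(m)
        assert radius == pytest.approx(0.5)


class TestWhitenessBattery:
    def test_statistics_match_direct_formula_and_statsmodels(self):
        """Q statistics agree with statsmodels' acorr_ljungbox to 1e-9."""
        from statsmodels.stats.diagnostic import acorr_ljungbox

        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        h = 10
        ref = acorr_ljungbox(x - x.mean(), lags=h, boxpierce=True)
        q_lb, _ = ljung_box(x, h)
        q_bp, _ = box_pierce(x, h)
        assert q_lb == pytest.approx(ref["lb_stat"].iloc[-1], abs=1e-9)
        assert q_bp == pytest.approx(ref["bp_stat"].iloc[-1], abs=1e-9)
        # McLeod-Li is Ljung-Box on the squared series
        q_ml, _ = mcleod_li(x, h)
        assert q_ml == pytest.approx(ljung_box(x ** 2, h)[0], abs=1e-9)

    def test_type_one_error_near_alpha_on_iid_series(self):
        rng = np.random.default_rng(4)
        n_runs, rejections = 300, {"lb": 0, "bp": 0, "ml": 0}
        for _ in range(n_runs):
            x = rng.standard_normal(1000)
            rejections["lb"] += ljung_box(x, 20)[1] < 0.05
            rejections["bp"] += box_pierce(x, 20)[1] < 0.05
            rejections["ml"] += mcleod_li(x, 20)[1] < 0.05
        for name, r in rejections.items():
            assert 0.02 < r / n_runs < 0.09, name

    def test_detects_ar1_residual_correlation(self):
        rng = np.random.default_rng(5)
        rejected = 0
        for i in range(50):
            x = _simulate_var([np.array([[0.8]])], 1000, seed=100 + i)[0]
            rejected += ljung_box(x, 20)[1] < 0.05
        assert rejected >= 50 * 0.99

    def test_battery_passes_on_white_and_fails_on_correlated(self):
        rng = np.random.default_rng(6)
        white = rng.standard_normal((40, 3, 50))
        rep = whiteness_battery(white, h=8, alpha=0.05, p=0)
        assert rep.passed
        ar = np.stack([_simulate_var([0.7 * np.eye(3)], 50, seed=i)
                       for i in range(40)])
        rep2 = whiteness_battery(ar, h=8, alpha=0.05, p=0)
        assert not rep2.passed

    def test_degenerate_lag_arguments_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            whiteness_battery(np.zeros((2, 100)), h=3, p=3)
        with pytest.raises(ValueError, match="must exceed h"):
            whiteness_battery(np.zeros((2, 5)), h=8)


class TestOrderSelection:
    def test_strong_var2_selected_in_most_runs(self):
        """Order selection on data simulated from a strong VAR(2)."""
        A = [np.array([[0.6, 0.2], [0.1, 0.4]]),
             np.array([[-0.5, 0.0], [0.1, -0.4]])]
        hits = 0
        n_runs = 20
        for i in range(n_runs):
            X = _simulate_var(A, 3000, seed=200 + i)
            sel = select_model_order([X[None]], range(1, 6), h=10)
            hits += sel.order == 2 and sel.passed
        assert hits >= int(0.9 * n_runs)

    def test_white_noise_selects_smallest_candidate(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((3, 4000))
        sel = select_model_order([X[None]], range(1, 6), h=10)
        assert sel.order == 1 and sel.passed

    def test_criteria_table_matches_direct_formula(self):
        """AIC/SBC/HQ rows recomputed from the stored fit's covariance."""
        A1 = np.array([[0.5, 0.2], [0.0, 0.4]])
        X = _simulate_var([A1], 2000, seed=8)
        sel = select_model_order([X[None]], [2], h=10)
        model = fit_mvar_vieira_morf(X[None], 2)
        n_eff, m, p = model.n_eff, 2, 2
        logdet = np.linalg.slogdet(model.sigma)[1]
        row = sel.table.iloc[0]
        assert row["AIC"] == pytest.approx(logdet + 2 * p * m * m / n_eff,
                                           abs=1e-9)
        assert row["SBC"] == pytest.approx(
            logdet + p * m * m * np.log(n_eff) / n_eff, abs=1e-9)
        assert row["HQ"] == pytest.approx(
            logdet + 2 * p * m * m * np.log(np.log(n_eff)) / n_eff, abs=1e-9)

    def test_no_passing_candidate_returns_flagged_best_effort(self):
        """An MA(1) series is no finite-order AR: every candidate fails the
        battery and the diagnostic flag is set."""
        rng = np.random.default_rng(9)
        e = rng.standard_normal(3001)
        x = (e[1:] + 0.9 * e[:-1])[None, :]
        sel = select_model_order([x[None]], [1], h=10)
        assert not sel.passed
        assert sel.order == 1

    def test_residuals_shrink_with_order(self):
        A = [np.array([[0.6]]), np.array([[-0.5]])]
        X = _simulate_var(A, 3000, seed=10)
        m1 = fit_mvar_vieira_morf(X, 1)
        m2 = fit_mvar_vieira_morf(X, 2)
        r1 = mvar_residuals(m1, X).var()
        r2 = mvar_residuals(m2, X).var()
        assert r2 < r1
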