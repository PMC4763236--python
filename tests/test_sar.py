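import dataclasses

import numpy as np
import pandas as pd
import pytest

from richdet import synthetic as syn
from richdet.sar import (
    compare_full_model,
    fit_sar_err,
    pseudo_r2,
    sar_err_loglik,
    select_lag,
)
from richdet.weights import build_distance_band_weights


def _lattice_weights(side):
    xs, ys = np.meshgrid(np.arange(side) * 60.0, np.arange(side) * 60.0)
    cents = np.column_stack([xs.ravel(), ys.ravel()])
    return cents, build_distance_band_weights(cents, 61.0)  # rook adjacency


def dense_loglik(lam, y, X, W_dense):
    """Brute-force SAR-error profile log-likelihood: dense det and solve."""
    n = len(y)
    A = np.eye(n) - lam * W_dense
    Ay, AX = A @ y, A @ X
    beta = np.linalg.solve(AX.T @ AX, AX.T @ Ay)
    e = y - X @ beta
    Ae = A @ e
    sigma2 = (Ae @ Ae) / n
    sign, logdet = np.linalg.slogdet(A)
    assert sign > 0
    return -(n / 2) * (np.log(2 * np.pi) + np.log(sigma2) + 1) + logdet


class TestLogLik:
    def test_lambda_zero_equals_ols_profile(self):
        rng = np.random.default_rng(0)
        _, w = _lattice_weights(5)
        n = w.n
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        ll = sar_err_loglik(0.0, y, X, w)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = float(((y - X @ beta) ** 2).mean())
        expected = -(n / 2) * (np.log(2 * np.pi) + np.log(s2) + 1)
        assert ll == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("side", [5, 7])
    def test_matches_dense_oracle(self, side):
        rng = np.random.default_rng(side)
        _, w = _lattice_weights(side)
        n = w.n
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        W_dense = w.w.toarray()
        for lam in (-0.6, -0.2, 0.0, 0.3, 0.5, 0.9):
            assert sar_err_loglik(lam, y, X, w) == pytest.approx(
                dense_loglik(lam, y, X, W_dense), abs=1e-8
            )

    def test_eigen_logdet_real_over_admissible_range(self):
        _, w = _lattice_weights(6)
        eigs = w.eigenvalues()
        assert np.isrealobj(eigs)
        for lam in np.linspace(-0.9, 0.99, 25):
            ld = np.sum(np.log(1 - lam * eigs))
            assert np.isfinite(ld)

    def test_out_of_interval_lambda_rejected(self):
        rng = np.random.default_rng(1)
        _, w = _lattice_weights(4)
        X = np.ones((w.n, 1))
        with pytest.raises(ValueError):
            sar_err_loglik(1.5, rng.normal(size=w.n), X, w)


class TestFitSarErr:
    def test_ols_limit_when_lambda_zero(self):
        # beta path: GLS at lambda = 0 is exactly OLS
        rng = np.random.default_rng(2)
        cents = rng.uniform(0, 2000, (300, 2))
        w = build_distance_band_weights(cents, 150.0)
        M = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        y = M @ np.array([1.0, 0.5, 0.0]) + rng.normal(0, 0.3, 300)
        from richdet.sar import profile_beta

        ols, *_ = np.linalg.lstsq(M, y, rcond=None)
        np.testing.assert_allclose(profile_beta(0.0, y, M, w), ols, atol=1e-6)
        # lambda path: on independent-noise data lambda-hat averages to ~0
        lams = []
        for seed in range(8):
            r2 = np.random.default_rng(100 + seed)
            cents = r2.uniform(0, [4000, 3000], (600, 2))
            w = build_distance_band_weights(cents, 100.0)
            X = pd.DataFrame(r2.normal(size=(600, 2)), columns=["a", "b"])
            yy = 1.0 + 0.5 * X["a"].to_numpy() + r2.normal(0, 0.3, 600)
            fit = fit_sar_err(yy, X, w)
            lams.append(fit.lam)
            ols = np.linalg.lstsq(
                np.column_stack([np.ones(600), X.to_numpy()]), yy, rcond=None
            )[0]
            np.testing.assert_allclose(
                [fit.beta["const"], fit.beta["a"], fit.beta["b"]], ols, atol=0.02
            )
        assert abs(np.mean(lams)) < 0.03

    def test_beta_matches_ols_exactly_at_lambda_zero(self):
        # direct check of the lambda=0 internals (no optimization noise)
        rng = np.random.default_rng(3)
        _, w = _lattice_weights(6)
        n = w.n
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        ll0 = sar_err_loglik(0.0, y, X, w)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        s2 = float(((y - X @ beta) ** 2).mean())
        assert ll0 == pytest.approx(
            -(n / 2) * (np.log(2 * np.pi) + np.log(s2) + 1), abs=1e-9
        )

    def test_aic_and_z_identities(self, small_landscape):
        cfg, counties, w, env, richness = small_landscape
        from richdet.screening import log_transform, residualize_on_area

        x, _ = log_transform(env)
        y = residualize_on_area(
            np.log10(richness), np.log10(counties["area_km2"].to_numpy())
        )
        fit = fit_sar_err(y, x[["elevational_range", "net_primary_productivity"]], w)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (fit.p_count + 2))
        for v in fit.variables:
            assert fit.z[v] == pytest.approx(fit.beta[v] / fit.se[v])
        assert 0.0 <= fit.pseudo_r2 <= 1.0

    def test_gls_and_hessian_se_agree(self):
        rng = np.random.default_rng(4)
        cents = rng.uniform(0, 1500, (200, 2))
        w = build_distance_band_weights(cents, 200.0)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        u = np.linalg.solve(np.eye(200) - 0.5 * w.w.toarray(), rng.normal(0, 0.3, 200))
        y = 1.0 + 0.5 * X["a"].to_numpy() + u
        f_gls = fit_sar_err(y, X, w, se_method="gls")
        f_hes = fit_sar_err(y, X, w, se_method="hessian")
        for v in ("a", "b"):
            assert f_hes.se[v] == pytest.approx(f_gls.se[v], rel=0.15)

    def test_null_coefficient_z_coverage(self):
        rng = np.random.default_rng(5)
        cover = 0
        reps = 60
        for _ in range(reps):
            cents = rng.uniform(0, 1500, (150, 2))
            w = build_distance_band_weights(cents, 250.0)
            X = pd.DataFrame({"a": rng.normal(size=150), "null": rng.normal(size=150)})
            u = np.linalg.solve(
                np.eye(150) - 0.4 * w.w.toarray(), rng.normal(0, 0.3, 150)
            )
            y = 0.5 * X["a"].to_numpy() + u
            fit = fit_sar_err(y, X, w)
            cover += abs(fit.z["null"]) < 1.96
        assert cover / reps > 0.85


class TestPseudoR2:
    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(6)
        cents = rng.uniform(0, 1000, (60, 2))
        w = build_distance_band_weights(cents, 300.0)
        X = pd.DataFrame({"a": rng.normal(size=60)})
        y = 2.0 + 3.0 * X["a"].to_numpy()
        fit = fit_sar_err(y + rng.normal(0, 1e-8, 60), X, w)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-6)

    def test_trend_only_equals_ols_r2_at_zero_lambda(self):
        rng = np.random.default_rng(7)
        cents = rng.uniform(0, 1000, (120, 2))
        w = build_distance_band_weights(cents, 300.0)
        X = pd.DataFrame({"a": rng.normal(size=120)})
        y = 1.0 + X["a"].to_numpy() + rng.normal(0, 0.5, 120)
        fit = fit_sar_err(y, X, w)
        r2_trend = pseudo_r2(fit, y, X, w, trend_only=True)
        M = np.column_stack([np.ones(120), X.to_numpy()])
        yhat = M @ np.linalg.solve(M.T @ M, M.T @ y)
        r2_ols = np.corrcoef(yhat, y)[0, 1] ** 2
        # lambda-hat is near zero here, so the trend r2 nearly equals OLS r2
        assert r2_trend == pytest.approx(r2_ols, abs=0.02)


class TestLagSelectionAndComparison:
    def test_single_candidate_trivial(self, small_landscape):
        cfg, counties, w, env, richness = small_landscape
        from richdet.screening import log_transform, residualize_on_area

        x, _ = log_transform(env)
        y = residualize_on_area(
            np.log10(richness), np.log10(counties["area_km2"].to_numpy())
        )
        best, table, fits = select_lag(
            y, x[["elevational_range"]], counties[["x_km", "y_km"]].to_numpy(),
            candidate_lags=(200.0,),
        )
        assert best == 200.0
        assert len(table) == 1

    def test_default_candidates_are_the_seven_lags(self):
        from richdet.weights import CANDIDATE_LAGS_KM

        assert select_lag.__defaults__[0] == CANDIDATE_LAGS_KM

    def test_identical_columns_delta_r2_zero(self, small_landscape):
        cfg, counties, w, env, richness = small_landscape
        from richdet.screening import log_transform, residualize_on_area

        x, _ = log_transform(env)
        y = residualize_on_area(
            np.log10(richness), np.log10(counties["area_km2"].to_numpy())
        )
        X = x[["elevational_range", "net_primary_productivity"]]
        cmp = compare_full_model(y, X, X, w)
        assert cmp["delta_r2"] == pytest.approx(0.0, abs=1e-12)

    def test_superset_columns_rejected(self, small_landscape):
        cfg, counties, w, env, richness = small_landscape
        from richdet.screening import log_transform

        x, _ = log_transform(env)
        with pytest.raises(ValueError):
            compare_full_model(
                np.log10(richness),
                x[["elevational_range", "ndvi"]],
                x[["elevational_range"]],
                w,
            )


class TestAreaEffect:
    def test_dominant_predictor_stable_across_methods(self, small_landscape):
        cfg, counties, w, env, richness = small_landscape
        from richdet.sar import area_effect_check
        from richdet.screening import log_transform

        x, _ = log_transform(env)
        X = x[["elevational_range", "net_primary_productivity", "ndvi"]]
        res = area_effect_check(
            np.log10(richness), X, np.log10(counties["area_km2"].to_numpy()), w
        )
        assert res["top_predictor_agrees"]
        assert res["ranking_residualized"][0] == "elevational_range"

    def test_constant_area_rejected(self, small_landscape):
        cfg, counties, w, env, richness = small_landscape
        from richdet.sar import area_effect_check
        from richdet.screening import log_transform

        x, _ = log_transform(env)
        with pytest.raises(Exception):
            area_effect_check(
                np.log10(richness),
                x[["elevational_range"]],
                np.zeros(len(richness)),
                w,
            )
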