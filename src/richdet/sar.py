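"""Step 3: maximum-likelihood simultaneous autoregressive (SAR) error model.

The model is y = Xβ + u with u = λWu + ε, ε ~ N(0, σ²I), W the
row-standardized distance-band weights.  Writing A = I − λW, the
concentrated (profile) log-likelihood over λ is

    ℓ(λ) = −(n/2)(ln 2π + ln σ̂²(λ) + 1) + ln|A|,

with β̂(λ) the GLS fit of Ay on AX, σ̂²(λ) = ‖A(y − Xβ̂)‖²/n, and
ln|A| = Σ_i ln(1 − λ e_i) computed once from the eigenvalues e_i of W
(real by similarity to a symmetric matrix for row-standardized
distance-band weights).  λ̂ maximizes ℓ by bounded 1-D optimization;
coefficient SEs come from the GLS covariance σ̂²(X'A'AX)⁻¹ (a
numerical-Hessian route is available for cross-checks), giving normal
z = β̂/SE and two-sided p.  Model fit is summarized by AIC
(−2ℓ + 2(p + 2): coefficients plus λ and σ²), a pseudo-r² (squared
Pearson correlation of predicted and observed, prediction including
the spatial signal λ̂W(y − Xβ̂)), and Moran's I of the innovation
residuals A(y − Xβ̂).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .weights import CANDIDATE_LAGS_KM, SpatialWeights, build_distance_band_weights, morans_i

_LAMBDA_MARGIN = 1e-6


def _admissible_interval(weights: SpatialWeights) -> tuple[float, float]:
    eigs = weights.eigenvalues()
    emin = float(eigs.min())
    lo = 1.0 / emin if emin < 0 else -1.0 + _LAMBDA_MARGIN
    emax = float(eigs.max())
    hi = 1.0 / emax if emax > 0 else 1.0 - _LAMBDA_MARGIN
    return lo + _LAMBDA_MARGIN, hi - _LAMBDA_MARGIN


def sar_err_loglik(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    weights: SpatialWeights,
) -> float:
    """Concentrated SAR-error log-likelihood at spatial coefficient lam."""
    lo, hi = _admissible_interval(weights)
    if not lo - _LAMBDA_MARGIN <= lam <= hi + _LAMBDA_MARGIN:
        raise ValueError(f"lambda={lam} outside admissible interval ({lo:.4f}, {hi:.4f})")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    W = weights.w
    Ay = y - lam * (W @ y)
    AX = X - lam * (W @ X)
    beta, _, rank, _ = np.linalg.lstsq(AX, Ay, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("X'A'AX is singular at this lambda")
    e = y - X @ beta
    Ae = e - lam * (W @ e)
    sigma2 = float(Ae @ Ae) / n
    logdet = float(np.sum(np.log(1.0 - lam * weights.eigenvalues())))
    return -(n / 2.0) * (np.log(2.0 * np.pi) + np.log(sigma2) + 1.0) + logdet


def profile_beta(
    lam: float, y: np.ndarray, X: np.ndarray, weights: SpatialWeights
) -> np.ndarray:
    """GLS coefficients β̂(λ) at a fixed spatial coefficient.

    At λ = 0 this reduces exactly to the OLS fit of y on X.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    W = weights.w
    Ay = y - lam * (W @ y)
    AX = X - lam * (W @ X)
    beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
    return beta


@dataclass
class SarFit:
    """Fitted SAR-error model, laid out for a z / AIC / r² report table."""

    lam: float
    beta: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    sigma2: float
    loglik: float
    aic: float
    pseudo_r2: float
    resid_moran: float
    lag_km: float
    n: int
    p_count: int
    se_method: str = "gls"
    variables: list[str] = field(default_factory=list)

    def stars(self, var: str) -> str:
        pv = self.p[var]
        if pv < 0.001:
            return "***"
        if pv < 0.01:
            return "**"
        if pv < 0.05:
            return "*"
        return ""

    def ranked_predictors(self) -> list[str]:
        """Non-intercept predictors by decreasing |z| (importance order)."""
        names = [v for v in self.variables if v != "const"]
        return sorted(names, key=lambda v: (-abs(self.z[v]), v))

    def to_table(self) -> dict:
        """JSON-ready summary mirroring a per-predictor z-table."""
        return {
            "predictors": {
                v: {"z": self.z[v], "beta": self.beta[v], "stars": self.stars(v)}
                for v in self.variables
                if v != "const"
            },
            "lambda": self.lam,
            "AIC": self.aic,
            "fitted_r2": self.pseudo_r2,
            "morans_i": self.resid_moran,
            "lag_km": self.lag_km,
            "n": self.n,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_table(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(M.shape[1])]
    if "const" not in names:
        M = np.column_stack([np.ones(M.shape[0]), M])
        names = ["const"] + names
    return M, names


def fit_sar_err(
    y: np.ndarray,
    X,
    weights: SpatialWeights,
    se_method: str = "gls",
    xatol: float = 1e-8,
    moran_permutations: int = 0,
) -> SarFit:
    """Maximum-likelihood SAR-error fit with bounded 1-D search over λ.

    X may be a DataFrame (named columns) or array; an intercept column
    is added when absent.  Isolate units contribute OLS-like rows.
    """
    y = np.asarray(y, dtype=float)
    M, names = _as_design(X)
    if len(y) != M.shape[0]:
        raise ValueError("y and X disagree in length")
    lo, hi = _admissible_interval(weights)

    trace: list[tuple[float, float]] = []

    def neg(lam: float) -> float:
        ll = sar_err_loglik(lam, y, M, weights)
        trace.append((lam, ll))
        return -ll

    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    if not res.success:
        raise RuntimeError(f"lambda optimization failed: {res.message}; trace={trace[-5:]}")
    lam = float(res.x)

    W = weights.w
    Ay = y - lam * (W @ y)
    AX = M - lam * (W @ M)
    xtx = AX.T @ AX
    beta = np.linalg.solve(xtx, AX.T @ Ay)
    e = y - M @ beta
    Ae = e - lam * (W @ e)
    n = len(y)
    sigma2 = float(Ae @ Ae) / n
    loglik = float(-res.fun)

    if se_method == "gls":
        cov = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov))
    elif se_method == "hessian":
        se = _hessian_se(lam, beta, sigma2, y, M, weights)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    with np.errstate(divide="ignore"):
        zvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))

    p_count = M.shape[1]
    aic = -2.0 * loglik + 2.0 * (p_count + 2)

    yhat = M @ beta + lam * (W @ e)
    r2 = _pseudo_r2_values(yhat, y)
    if moran_permutations > 0:
        mi, _ = morans_i(Ae, weights, permutations=moran_permutations, seed=0)
    else:
        mi, _ = morans_i(Ae, weights, permutations=0)

    return SarFit(
        lam=lam,
        beta=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        z=dict(zip(names, map(float, zvals))),
        p=dict(zip(names, map(float, pvals))),
        sigma2=sigma2,
        loglik=loglik,
        aic=float(aic),
        pseudo_r2=r2,
        resid_moran=float(mi),
        lag_km=weights.lag_km,
        n=n,
        p_count=p_count,
        se_method=se_method,
        variables=names,
    )


def _hessian_se(lam, beta, sigma2, y, M, weights) -> np.ndarray:
    """SEs for β from the inverse numerical Hessian over (λ, β, ln σ²)."""
    W = weights.w
    eigs = weights.eigenvalues()
    n = len(y)

    def nll(theta: np.ndarray) -> float:
        la, bs, ls2 = theta[0], theta[1:-1], np.exp(theta[-1])
        e = y - M @ bs
        Ae = e - la * (W @ e)
        logdet = float(np.sum(np.log(1.0 - la * eigs)))
        return (n / 2.0) * np.log(2 * np.pi * ls2) + float(Ae @ Ae) / (2 * ls2) - logdet

    theta0 = np.concatenate([[lam], beta, [np.log(sigma2)]])
    h = 1e-5 * np.maximum(np.abs(theta0), 1.0)
    k = len(theta0)
    H = np.zeros((k, k))
    f0 = nll(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(theta0 + ei + ej) - nll(theta0 + ei) - nll(theta0 + ej) + f0
            ) / (h[i] * h[j])
    cov = np.linalg.inv(H)
    return np.sqrt(np.maximum(np.diag(cov)[1:-1], 0.0))


def _pseudo_r2_values(yhat: np.ndarray, y: np.ndarray) -> float:
    if np.std(yhat) == 0:
        raise ValueError("constant predictions: pseudo-r² undefined")
    r = np.corrcoef(yhat, y)[0, 1]
    return float(r * r)


def pseudo_r2(fit: SarFit, y: np.ndarray, X, weights: SpatialWeights,
              trend_only: bool = False) -> float:
    """Squared Pearson correlation of predicted and observed responses.

    Prediction is Xβ̂ + λ̂W(y − Xβ̂) by default; ``trend_only`` drops
    the spatial signal term.
    """
    y = np.asarray(y, dtype=float)
    M, names = _as_design(X)
    beta = np.array([fit.beta[nm] for nm in names])
    trend = M @ beta
    if trend_only:
        yhat = trend
    else:
        e = y - trend
        yhat = trend + fit.lam * (weights.w @ e)
    return _pseudo_r2_values(yhat, y)


def select_lag(
    y: np.ndarray,
    X,
    centroids: np.ndarray,
    candidate_lags: tuple[float, ...] = CANDIDATE_LAGS_KM,
    ids: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame, dict[float, SarFit]]:
    """Fit the SAR-error model at every candidate band radius.

    Returns the argmin-AIC lag, a per-lag diagnostic table (AIC,
    log-likelihood, λ̂, pseudo-r², residual Moran's I, isolate
    fraction) and the fitted models.
    """
    if len(candidate_lags) == 0:
        raise ValueError("need at least one candidate lag")
    rows = []
    fits: dict[float, SarFit] = {}
    errors: dict[float, str] = {}
    for lag in candidate_lags:
        try:
            w = build_distance_band_weights(centroids, lag, ids=ids)
            fit = fit_sar_err(y, X, w)
            fits[lag] = fit
            rows.append(
                {
                    "lag_km": lag,
                    "aic": fit.aic,
                    "loglik": fit.loglik,
                    "lambda": fit.lam,
                    "pseudo_r2": fit.pseudo_r2,
                    "resid_moran": fit.resid_moran,
                    "isolate_fraction": w.n_isolates / w.n,
                }
            )
        except Exception as exc:  # collected; full failure raises below
            errors[lag] = str(exc)
    if not fits:
        raise RuntimeError(f"every candidate lag failed: {errors}")
    table = pd.DataFrame(rows).sort_values("lag_km").reset_index(drop=True)
    best = float(table.loc[table["aic"].idxmin(), "lag_km"])
    return best, table, fits


def compare_full_model(
    y: np.ndarray,
    X_top: pd.DataFrame,
    X_all: pd.DataFrame,
    weights: SpatialWeights,
) -> dict:
    """Δr² and AICs between the top-k model and the all-variable model.

    Both models are fitted at the same lag; the top-k columns must be a
    subset of the full design.
    """
    missing = set(X_top.columns) - set(X_all.columns)
    if missing:
        raise ValueError(f"top-model columns not in the full design: {sorted(missing)}")
    fit_top = fit_sar_err(y, X_top, weights)
    fit_all = fit_sar_err(y, X_all, weights)
    return {
        "delta_r2": fit_all.pseudo_r2 - fit_top.pseudo_r2,
        "r2_top": fit_top.pseudo_r2,
        "r2_all": fit_all.pseudo_r2,
        "aic_top": fit_top.aic,
        "aic_all": fit_all.aic,
    }


def area_effect_check(
    raw_log_richness: np.ndarray,
    X: pd.DataFrame,
    log_area: np.ndarray,
    weights: SpatialWeights,
) -> dict:
    """Compare residualized-response and area-as-covariate SAR fits.

    Fits (a) the SAR model of the area-residualized response on X and
    (b) the SAR model of the raw log richness on X plus a log-area
    column, and reports both importance rankings plus an agreement
    flag for the top-ranked environmental predictor.
    """
    from .screening import residualize_on_area

    y_resid = residualize_on_area(raw_log_richness, log_area)
    fit_resid = fit_sar_err(y_resid, X, weights)
    X_area = X.copy()
    X_area["log10_area"] = np.asarray(log_area, dtype=float)
    from .selection import _check_rank

    _check_rank(
        np.column_stack([np.ones(len(X_area)), X_area.to_numpy(float)]),
        ["const"] + list(X_area.columns),
    )
    fit_area = fit_sar_err(raw_log_richness, X_area, weights)
    rank_resid = fit_resid.ranked_predictors()
    rank_area = [v for v in fit_area.ranked_predictors() if v != "log10_area"]
    return {
        "ranking_residualized": rank_resid,
        "ranking_area_covariate": rank_area,
        "top_predictor_agrees": rank_resid[0] == rank_area[0],
        "fit_residualized": fit_resid,
        "fit_area_covariate": fit_area,
    }
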