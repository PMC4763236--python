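"""Step 2: bootstrap significance counting and top-k predictor selection.

A Gaussian-identity GLM (equivalently OLS) of the area-residualized
log10 richness on the screened covariates is refitted on 1000 (default)
case resamples drawn with replacement; each replicate increments a
variable's count when its two-sided coefficient p-value falls below
alpha = 0.05.  The top six variables by count form the predictor set
for the spatial model stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class GlmFit:
    """Single Gaussian GLM fit: coefficients with t-based inference."""

    params: pd.Series  # includes 'const'
    bse: pd.Series
    pvalues: pd.Series
    tvalues: pd.Series
    deviance: float  # residual sum of squares (Gaussian deviance)
    df_resid: int


def _design(X: pd.DataFrame) -> pd.DataFrame:
    return sm.add_constant(X, has_constant="add")


def _check_rank(M: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the columns involved in the deficiency via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(M, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(M.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def fit_glm(y_resid: np.ndarray, X: pd.DataFrame) -> GlmFit:
    """Gaussian-identity GLM (= OLS) with t-distribution p-values."""
    y = np.asarray(y_resid, dtype=float)
    Xd = _design(X)
    if len(y) <= Xd.shape[1]:
        raise ValueError("need n > p + 1 observations")
    _check_rank(Xd.to_numpy(float), list(Xd.columns))
    res = sm.OLS(y, Xd).fit()
    return GlmFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        tvalues=res.tvalues,
        deviance=float(res.ssr),
        df_resid=int(res.df_resid),
    )


def _ols_pvalues(Xd: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fast OLS two-sided t p-values and t statistics (columns of Xd)."""
    n, p = Xd.shape
    xtx = Xd.T @ Xd
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise
    beta = xtx_inv @ (Xd.T @ y)
    resid = y - Xd @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pvals


@dataclass
class SelectionReport:
    """Per-variable bootstrap significance counts and the top-k set."""

    variables: list[str]
    counts: dict[str, int]
    mean_abs_t: dict[str, float]
    reps: int
    alpha: float
    seed: int | None = None
    selected: list[str] = field(default_factory=list)
    tie_log: list[str] = field(default_factory=list)
    redraws: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "variables": self.variables,
                "counts": self.counts,
                "mean_abs_t": self.mean_abs_t,
                "reps": self.reps,
                "alpha": self.alpha,
                "seed": self.seed,
                "selected": self.selected,
                "tie_log": self.tie_log,
                "redraws": self.redraws,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def counts_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variable": self.variables,
                "count": [self.counts[v] for v in self.variables],
                "mean_abs_t": [self.mean_abs_t[v] for v in self.variables],
            }
        )
        return df.sort_values(
            ["count", "mean_abs_t", "variable"], ascending=[False, False, True]
        ).reset_index(drop=True)


def bootstrap_significance(
    y_resid: np.ndarray,
    X: pd.DataFrame,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> SelectionReport:
    """Count, per variable, replicates in which its coefficient has p < alpha.

    Each replicate draws n units with replacement and refits the
    Gaussian GLM.  Rank-deficient resamples are redrawn (logged), with
    a hard cap of 10x reps redraws.
    """
    y = np.asarray(y_resid, dtype=float)
    Xd_frame = _design(X)
    names = [c for c in Xd_frame.columns if c != "const"]
    Xd = Xd_frame.to_numpy(float)
    _check_rank(Xd, list(Xd_frame.columns))
    n = len(y)
    if n <= Xd.shape[1]:
        raise ValueError("need n > p + 1 observations")

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(names), dtype=int)
    abs_t_sum = np.zeros(len(names))
    redraws = 0
    done = 0
    var_cols = [list(Xd_frame.columns).index(v) for v in names]
    while done < reps:
        idx = rng.integers(0, n, n)
        try:
            t, p = _ols_pvalues(Xd[idx], y[idx])
        except np.linalg.LinAlgError:
            redraws += 1
            if redraws > 10 * reps:
                raise RuntimeError(
                    "exceeded redraw budget: too many rank-deficient resamples"
                )
            continue
        counts += (p[var_cols] < alpha).astype(int)
        abs_t_sum += np.abs(t[var_cols])
        done += 1

    return SelectionReport(
        variables=names,
        counts={v: int(c) for v, c in zip(names, counts)},
        mean_abs_t={v: float(s / reps) for v, s in zip(names, abs_t_sum)},
        reps=reps,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else None,
        redraws=redraws,
    )


def select_top_k(report: SelectionReport, k: int = 6) -> list[str]:
    """Top-k variables by significance count.

    Ties at the boundary break by larger mean |t| across replicates,
    then lexicographic name; tie decisions are logged on the report.
    """
    import warnings

    if k > len(report.variables):
        warnings.warn(
            f"k={k} exceeds the {len(report.variables)} available variables; returning all"
        )
        k = len(report.variables)
    order = sorted(
        report.variables,
        key=lambda v: (-report.counts[v], -report.mean_abs_t[v], v),
    )
    selected = order[:k]
    if k < len(order):
        boundary = report.counts[order[k - 1]]
        tied = [v for v in report.variables if report.counts[v] == boundary]
        if len(tied) > 1 and report.counts[order[k]] == boundary:
            report.tie_log.append(
                f"count tie at {boundary} among {sorted(tied)}; "
                "broken by mean |t| then name"
            )
    report.selected = selected
    return selected
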