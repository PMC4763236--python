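"""Step 1: multicollinearity screening within hypothesis categories.

Richness and county area enter on the log10 scale; richness is
residualized on area by OLS, and within each hypothesis category any
pair of covariates with |Spearman ρ| above the threshold (default 0.7)
is resolved by dropping the member that explains less deviance in a
univariate Gaussian regression of the residual response.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import EnvMatrix, analysis_scale


def log_transform(env: EnvMatrix) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply the per-variable scale transform (log10 or pass-through).

    Returns the analysis-scale frame and a record of the decision made
    for each variable ('log10' / 'untransformed').  Raises, naming the
    variable and unit, if a positive-flagged variable is non-positive.
    """
    return analysis_scale(env)


def log10_vector(values: np.ndarray, name: str = "values") -> np.ndarray:
    """log10 of a strictly positive vector (richness or area)."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError(f"{name} must be strictly positive for log10")
    return np.log10(v)


def residualize_on_area(log_richness: np.ndarray, log_area: np.ndarray) -> np.ndarray:
    """OLS residuals of log richness on intercept + log area."""
    y = np.asarray(log_richness, dtype=float)
    x = np.asarray(log_area, dtype=float)
    if y.shape != x.shape:
        raise ValueError("log_richness and log_area must have equal length")
    if x.std() == 0:
        raise ValueError("county area is constant; cannot residualize")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def spearman_matrix(env: EnvMatrix, category: str | None = None) -> pd.DataFrame:
    """Pairwise two-sided Spearman ρ for the variables of one category.

    Ties get average ranks; a constant variable yields NaN for its
    pairs (reported, not raised).
    """
    names = [
        v
        for v in env.variables
        if category is None or env.categories.get(v) == category
    ]
    if len(names) < 2:
        raise ValueError(f"need at least 2 variables in category {category!r}")
    X = env.data[names].to_numpy(float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations for Spearman correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if np.isscalar(rho):  # two-variable case returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)


def univariate_deviance(y_resid: np.ndarray, x: np.ndarray) -> float:
    """Proportion of deviance explained by a single Gaussian predictor.

    For the Gaussian-identity model this is the r² of the simple OLS of
    y_resid on x; a constant predictor explains nothing (warned).
    """
    y = np.asarray(y_resid, dtype=float)
    xv = np.asarray(x, dtype=float)
    if y.shape != xv.shape:
        raise ValueError("y_resid and x must have equal length")
    if xv.std() == 0:
        warnings.warn("constant predictor: deviance explained set to 0")
        return 0.0
    if y.std() == 0:
        return 0.0
    r = np.corrcoef(y, xv)[0, 1]
    return float(r * r)


@dataclass
class ScreeningResult:
    """Retained variables per category plus a log of every drop."""

    retained: dict[str, list[str]]
    dropped: list[dict] = field(default_factory=list)
    threshold: float = 0.7

    @property
    def retained_names(self) -> list[str]:
        out: list[str] = []
        for cat in sorted(self.retained):
            out.extend(self.retained[cat])
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"threshold": self.threshold, "retained": self.retained, "dropped": self.dropped},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def screen_variables(
    env: EnvMatrix,
    y_resid: np.ndarray,
    threshold: float = 0.7,
) -> ScreeningResult:
    """Greedy within-category pruning of strongly intercorrelated variables.

    Works on analysis-scale values.  Within each category, while any
    pair exceeds |ρ| > threshold, the worst offender pair (largest |ρ|)
    is resolved by dropping the member with the lower univariate
    deviance explained on the residual response (ties: lexicographic
    name).  Cross-category correlations are never pruned.
    """
    x_scaled, _ = log_transform(env)
    categories = sorted(set(env.categories[v] for v in env.variables))
    retained: dict[str, list[str]] = {}
    drop_log: list[dict] = []

    dev = {
        v: univariate_deviance(y_resid, x_scaled[v].to_numpy(float))
        for v in env.variables
    }

    for cat in categories:
        names = sorted(v for v in env.variables if env.categories[v] == cat)
        if len(names) < 2:
            retained[cat] = names
            continue
        rho = spearman_matrix(env, cat)
        alive = list(names)
        while True:
            worst = None
            for i, a in enumerate(alive):
                for b in alive[i + 1 :]:
                    r = rho.loc[a, b]
                    if np.isnan(r) or abs(r) <= threshold:
                        continue
                    if worst is None or abs(r) > abs(worst[2]):
                        worst = (a, b, r)
            if worst is None:
                break
            a, b, r = worst
            if dev[a] != dev[b]:
                drop, keep = (a, b) if dev[a] < dev[b] else (b, a)
            else:
                drop, keep = (max(a, b), min(a, b))
            alive.remove(drop)
            drop_log.append(
                {
                    "category": cat,
                    "dropped": drop,
                    "kept": keep,
                    "spearman_rho": float(r),
                    "deviance_dropped": dev[drop],
                    "deviance_kept": dev[keep],
                }
            )
        retained[cat] = alive
    return ScreeningResult(retained=retained, dropped=drop_log, threshold=threshold)
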