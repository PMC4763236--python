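"""Sampling-bias robustness test and inventory-completeness audits.

The robustness test re-runs the bootstrap significance-counting
procedure on stratified subsamples at fractions 60–90% of the units
(drawn without replacement within each stratum, each replicate afresh)
and asks whether the resulting top-k predictor sets match the full-data
set.  The completeness audit compares one inventory against a
reference restricted to "under-sampled" units (incompleteness score
above a cutoff, default 0.05) and summarizes the richness differences;
a nested-reserve comparison reports the Pearson correlation between
paired county and reserve richness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selection import SelectionReport, _check_rank, _design, _ols_pvalues, bootstrap_significance, select_top_k

DEFAULT_FRACTIONS = (0.6, 0.7, 0.8, 0.9)


def stratified_sample(
    units: pd.DataFrame,
    fraction: float,
    seed: int | np.random.Generator = 0,
    stratum_col: str = "stratum",
) -> np.ndarray:
    """Row positions of a without-replacement stratified subsample.

    Within each stratum, floor(fraction * n_s) units (at least one)
    are drawn; fraction 1.0 returns every unit.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if stratum_col not in units.columns:
        raise ValueError(f"units table lacks a {stratum_col!r} column")
    rng = np.random.default_rng(seed)
    picked: list[np.ndarray] = []
    for label, grp in units.groupby(stratum_col, sort=True):
        pos = units.index.get_indexer(grp.index)
        n_s = len(pos)
        if n_s == 0:
            raise ValueError(f"stratum {label!r} is empty")
        m = n_s if fraction == 1.0 else max(1, int(np.floor(fraction * n_s)))
        picked.append(rng.choice(pos, size=m, replace=False))
    return np.sort(np.concatenate(picked))


@dataclass
class RobustnessReport:
    fractions: tuple[float, ...]
    counts: dict[float, dict[str, int]]
    top_k: dict[float, list[str]]
    full_top_k: list[str]
    consistent: bool
    k: int
    reps: int
    alpha: float
    seed: int | None

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "fractions": list(self.fractions),
                "counts": {str(f): c for f, c in self.counts.items()},
                "top_k": {str(f): t for f, t in self.top_k.items()},
                "full_top_k": self.full_top_k,
                "consistent": self.consistent,
                "k": self.k,
                "reps": self.reps,
                "alpha": self.alpha,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _subsample_significance(
    y: np.ndarray,
    Xd: np.ndarray,
    names: list[str],
    var_cols: list[int],
    units: pd.DataFrame,
    fraction: float,
    reps: int,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.zeros(len(names), dtype=int)
    abs_t_sum = np.zeros(len(names))
    done = 0
    redraws = 0
    while done < reps:
        idx = stratified_sample(units, fraction, seed=rng)
        try:
            t, p = _ols_pvalues(Xd[idx], y[idx])
        except np.linalg.LinAlgError:
            redraws += 1
            if redraws > 10 * reps:
                raise RuntimeError("exceeded redraw budget in robustness test")
            continue
        counts += (p[var_cols] < alpha).astype(int)
        abs_t_sum += np.abs(t[var_cols])
        done += 1
    return counts, abs_t_sum


def robustness_test(
    y_resid: np.ndarray,
    X: pd.DataFrame,
    units: pd.DataFrame,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    reps: int = 1000,
    alpha: float = 0.05,
    k: int = 6,
    seed: int | None = 0,
) -> RobustnessReport:
    """Stratified-subsample significance counting across sample fractions.

    The full-data (fraction 1.0) reference is the case-resampling
    bootstrap itself, so a fraction of exactly 1.0 reproduces
    ``bootstrap_significance`` counts for the same seed.
    """
    y = np.asarray(y_resid, dtype=float)
    Xd_frame = _design(X)
    names = [c for c in Xd_frame.columns if c != "const"]
    Xd = Xd_frame.to_numpy(float)
    _check_rank(Xd, list(Xd_frame.columns))
    var_cols = [list(Xd_frame.columns).index(v) for v in names]

    full_report = bootstrap_significance(y, X, reps=reps, alpha=alpha, seed=seed)
    full_top = select_top_k(full_report, k=k)

    counts_by_frac: dict[float, dict[str, int]] = {}
    top_by_frac: dict[float, list[str]] = {}
    for frac in fractions:
        if frac == 1.0:
            rep = bootstrap_significance(y, X, reps=reps, alpha=alpha, seed=seed)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([0 if seed is None else seed, int(frac * 1000)])
            )
            counts, abs_t = _subsample_significance(
                y, Xd, names, var_cols, units, frac, reps, alpha, rng
            )
            rep = SelectionReport(
                variables=names,
                counts={v: int(c) for v, c in zip(names, counts)},
                mean_abs_t={v: float(s / reps) for v, s in zip(names, abs_t)},
                reps=reps,
                alpha=alpha,
                seed=seed,
            )
        counts_by_frac[frac] = rep.counts
        top_by_frac[frac] = select_top_k(rep, k=k)

    consistent = all(set(top_by_frac[f]) == set(full_top) for f in fractions)
    return RobustnessReport(
        fractions=tuple(fractions),
        counts=counts_by_frac,
        top_k=top_by_frac,
        full_top_k=full_top,
        consistent=consistent,
        k=k,
        reps=reps,
        alpha=alpha,
        seed=seed,
    )


@dataclass
class CompletenessReport:
    n_undersampled: int
    mean_diff: float
    sd_diff: float
    n_higher: int
    n_identical: int
    n_lower: int
    cutoff: float

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def compare_inventories(
    ours: pd.Series,
    reference: pd.Series,
    incompleteness: pd.Series,
    cutoff: float = 0.05,
) -> CompletenessReport:
    """Richness difference (ours − reference) over under-sampled units.

    Restricts to shared units with incompleteness > cutoff and reports
    the mean and SD of the difference plus higher/identical/lower
    counts.
    """
    shared = ours.index.intersection(reference.index).intersection(incompleteness.index)
    if len(shared) == 0:
        raise ValueError("inventories share no unit ids")
    mask = incompleteness.loc[shared] > cutoff
    under = shared[mask.to_numpy()]
    diff = (ours.loc[under] - reference.loc[under]).to_numpy(float)
    if len(diff) == 0:
        return CompletenessReport(0, float("nan"), float("nan"), 0, 0, 0, cutoff)
    return CompletenessReport(
        n_undersampled=len(diff),
        mean_diff=float(diff.mean()),
        sd_diff=float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        n_higher=int((diff > 0).sum()),
        n_identical=int((diff == 0).sum()),
        n_lower=int((diff < 0).sum()),
        cutoff=cutoff,
    )


def nested_reserve_correlation(
    county_richness: np.ndarray, reserve_richness: np.ndarray
) -> tuple[float, float]:
    """Pearson r (two-sided p) between paired county and reserve richness."""
    a = np.asarray(county_richness, dtype=float)
    b = np.asarray(reserve_richness, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
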