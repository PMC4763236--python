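"""Split-line (two-segment breakpoint) regression.

The response is regressed on the predictor separately on each side of a
candidate breakpoint (independent fits; a discontinuity is allowed),
and the candidate minimizing total residual sum of squares wins.  Units
with predictor values above a cap (default 6000 m, the exclusion used
for extreme elevational ranges) are dropped first.  Points exactly at
the breakpoint belong to the lower segment.  Per-segment R², slope F
and p mirror the usual two-regime report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_X_CAP = 6000.0
DEFAULT_GRID_STEP = 50.0
_MIN_SIDE = 4  # admissible breakpoints need at least this many points per side


@dataclass
class SegmentFit:
    slope: float
    intercept: float
    r2: float
    f: float
    p: float
    n: int
    rss: float


@dataclass
class SplitLineFit:
    breakpoint: float
    pre: SegmentFit
    post: SegmentFit
    total_rss: float
    grid: np.ndarray = field(repr=False)
    n_excluded: int = 0
    x_cap: float = DEFAULT_X_CAP

    @property
    def n_pre(self) -> int:
        return self.pre.n

    @property
    def n_post(self) -> int:
        return self.post.n

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "breakpoint": self.breakpoint,
                "x_cap": self.x_cap,
                "n_excluded": self.n_excluded,
                "total_rss": self.total_rss,
                "pre": {
                    "slope": self.pre.slope, "intercept": self.pre.intercept,
                    "r2": self.pre.r2, "F": self.pre.f, "p": self.pre.p, "n": self.pre.n,
                },
                "post": {
                    "slope": self.post.slope, "intercept": self.post.intercept,
                    "r2": self.post.r2, "F": self.post.f, "p": self.post.p, "n": self.post.n,
                },
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def plot_split_line(fit: SplitLineFit, x: np.ndarray, y: np.ndarray, path) -> None:
    """Two-panel scatter + fitted-line figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = x <= fit.x_cap
    x, y = x[keep], y[keep]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, seg, mask, label in (
        (axes[0], fit.pre, x <= fit.breakpoint, "below"),
        (axes[1], fit.post, x > fit.breakpoint, "above"),
    ):
        ax.scatter(x[mask], y[mask], s=6, alpha=0.4)
        xs = np.linspace(x[mask].min(), x[mask].max(), 10)
        ax.plot(xs, seg.intercept + seg.slope * xs, "r-")
        ax.set_title(f"{label} {fit.breakpoint:.0f}: R²={seg.r2:.3f}, F={seg.f:.1f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _segment_fit(x: np.ndarray, y: np.ndarray) -> SegmentFit:
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        # vertical stack of points: flat line through the mean
        rss = float(((y - ym) ** 2).sum())
        return SegmentFit(0.0, ym, 0.0, 0.0, 1.0, n, rss)
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    tss = float(((y - ym) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    df = n - 2
    if df <= 0 or rss == 0:
        f = np.inf if (r2 > 0 and rss == 0) else 0.0
        p = 0.0 if rss == 0 and r2 > 0 else 1.0
    else:
        f = r2 / (1.0 - r2) * df if r2 < 1 else np.inf
        p = float(stats.f.sf(f, 1, df))
    return SegmentFit(slope, intercept, r2, f, p, n, rss)


def default_grid(x: np.ndarray, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Candidate breakpoints every ``step`` from the 5th to 95th percentile."""
    lo, hi = np.percentile(x, [5, 95])
    start = np.ceil(lo / step) * step
    return np.arange(start, hi + step / 2, step)


def fit_split_line(
    x: np.ndarray,
    y: np.ndarray,
    x_cap: float = DEFAULT_X_CAP,
    grid: np.ndarray | None = None,
) -> SplitLineFit:
    """Grid-search two-segment regression of y on x.

    Candidates leaving fewer than four points on either side are
    inadmissible; among admissible candidates the total RSS of the two
    independent OLS lines is minimized (ties: smaller breakpoint).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = x <= x_cap
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 2 * _MIN_SIDE:
        raise ValueError("too few points after applying the x-cap")
    if grid is None:
        grid = default_grid(x)
    grid = np.asarray(grid, dtype=float)

    best = None
    for b in grid:
        left = x <= b
        n_l = int(left.sum())
        n_r = len(x) - n_l
        if n_l < _MIN_SIDE or n_r < _MIN_SIDE:
            continue
        fit_l = _segment_fit(x[left], y[left])
        fit_r = _segment_fit(x[~left], y[~left])
        rss = fit_l.rss + fit_r.rss
        if best is None or rss < best[0] - 1e-15:
            best = (rss, b, fit_l, fit_r)
    if best is None:
        raise ValueError("no admissible breakpoint: a segment is empty at every candidate")
    rss, b, fit_l, fit_r = best
    return SplitLineFit(
        breakpoint=float(b),
        pre=fit_l,
        post=fit_r,
        total_rss=float(rss),
        grid=grid,
        n_excluded=n_excluded,
        x_cap=x_cap,
    )
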