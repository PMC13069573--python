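"""Normalized expression variability (NEV).

For each gene at each timepoint the squared coefficient of variation
CV² = var / mean² is computed across individuals.  Because CV² is
strongly coupled to mean expression (for overdispersed counts CV²
falls roughly as 1/mean before flattening at a biological floor), a
mean–variance trend is fitted in (log2 mean, log2 CV²) space and each
gene's variability is expressed relative to it:

    NEV = log2(CV²) − log2(CV²̂(μ))

so NEV > 0 means more variable than genes of similar mean expression
and NEV < 0 less.  A gene's summarized NEV is the median of its
per-timepoint NEVs.

The trend smoother is locally weighted regression (lowess) of
log2(CV²) on log2(mean), span 0.3, with one robustness iteration,
fitted per timepoint by default.  Evaluation outside the fitted mean
range clamps to the boundary fitted value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ExpressionPanel

__all__ = [
    "TrendFit",
    "TrendFitError",
    "compute_stats",
    "fit_trend",
    "compute_nev",
    "nev_pipeline",
    "DEFAULT_SPAN",
    "MIN_TREND_POINTS",
]

DEFAULT_SPAN = 0.3
DEFAULT_ROBUST_ITER = 1
MIN_TREND_POINTS = 50
MIN_MEAN = 1.0  # expression-unit filter before the log-space fit


class TrendFitError(RuntimeError):
    pass


def compute_stats(panel: ExpressionPanel, timepoint: str | None = None,
                  min_individuals: int = 2) -> pd.DataFrame:
    """Per-(gene, timepoint) mean, unbiased variance, CV² and n_used.

    The mean is the arithmetic mean over non-missing individuals and the
    variance the (n−1) sample variance.  Genes with fewer than
    ``min_individuals`` non-missing values, or zero mean, get NaN CV²
    (flagged missing, never dropped silently).
    """
    timepoints = [timepoint] if timepoint is not None else panel.timepoints
    frames = []
    for tp in timepoints:
        mat = panel.timepoint_matrix(tp)
        n_used = np.sum(~np.isnan(mat), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # dof<=0 rows
            mean = np.nanmean(np.where(np.isnan(mat), np.nan, mat), axis=1)
            var = np.nanvar(mat, axis=1, ddof=1)
            cv2 = var / mean**2
        ok = (n_used >= min_individuals) & (mean > 0)
        mean = np.where(n_used >= 1, mean, np.nan)
        cv2 = np.where(ok, cv2, np.nan)
        frames.append(pd.DataFrame({
            "gene": panel.genes,
            "timepoint": tp,
            "mean": mean,
            "cv2": cv2,
            "n_used": n_used,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class TrendFit:
    """Evaluable mapping from log2(mean) to expected log2(CV²)."""

    x: np.ndarray  # sorted, unique log2 mean of the fit points
    y: np.ndarray  # fitted log2 CV² at those points
    method: str = "lowess"
    span: float = DEFAULT_SPAN
    n_points: int = 0

    def __call__(self, log2_mean) -> np.ndarray:
        # flat extrapolation beyond the fitted range
        return np.interp(np.asarray(log2_mean, dtype=float), self.x, self.y)

    def grid(self, n: int = 100) -> pd.DataFrame:
        """Diagnostic grid of mean vs fitted CV² over the fitted range."""
        gx = np.linspace(self.x[0], self.x[-1], n)
        return pd.DataFrame({"mean": 2.0**gx, "fitted_cv2": 2.0 ** self(gx)})


def fit_trend(stats: pd.DataFrame, span: float = DEFAULT_SPAN,
              robust_iter: int = DEFAULT_ROBUST_ITER,
              min_mean: float = MIN_MEAN,
              min_points: int = MIN_TREND_POINTS) -> TrendFit:
    """Fit the mean–variance trend on (gene, timepoint) points.

    Points with mean < ``min_mean`` or CV² ≤ 0 are excluded (the fit is
    in log space).  Raises :class:`TrendFitError` when fewer than
    ``min_points`` remain.
    """
    ok = (stats["mean"] >= min_mean) & (stats["cv2"] > 0)
    pts = stats.loc[ok]
    if len(pts) < min_points:
        raise TrendFitError(
            f"only {len(pts)} usable (gene, timepoint) points "
            f"(need ≥ {min_points}); lower the expression filter or pool timepoints"
        )
    lx = np.log2(pts["mean"].to_numpy())
    ly = np.log2(pts["cv2"].to_numpy())
    fitted = lowess(ly, lx, frac=span, it=robust_iter, return_sorted=True)
    # collapse duplicate x to the mean fitted value so interp is well defined
    fx, inv = np.unique(fitted[:, 0], return_inverse=True)
    fy = np.bincount(inv, weights=fitted[:, 1]) / np.bincount(inv)
    return TrendFit(x=fx, y=fy, span=span, n_points=len(pts))


def compute_nev(stats: pd.DataFrame, trends: dict[str, TrendFit] | TrendFit,
                min_timepoints: int | None = None) -> pd.DataFrame:
    """NEV per gene per timepoint plus the median-summarized NEV.

    ``trends`` maps timepoint → TrendFit (per-timepoint normalization) or
    is a single pooled fit.  CV² = 0 or undefined gives a missing NEV at
    that timepoint, never −inf.  The summarized NEV is the median over
    defined timepoints, reported only when at least ``min_timepoints``
    (default ceil(T/2)) are defined.
    """
    stats = stats.copy()
    timepoints = list(pd.unique(stats["timepoint"]))
    if min_timepoints is None:
        min_timepoints = math.ceil(len(timepoints) / 2)

    def trend_for(tp: str) -> TrendFit:
        if isinstance(trends, TrendFit):
            return trends
        return trends[tp]

    nev = np.full(len(stats), np.nan)
    ok = (stats["cv2"] > 0) & (stats["mean"] > 0)
    for tp in timepoints:
        sel = (stats["timepoint"] == tp) & ok
        if not sel.any():
            continue
        m = stats.loc[sel, "mean"].to_numpy()
        c = stats.loc[sel, "cv2"].to_numpy()
        nev[sel.to_numpy()] = np.log2(c) - trend_for(tp)(np.log2(m))
    stats["nev"] = nev

    wide = stats.pivot(index="gene", columns="timepoint", values="nev")
    wide = wide.reindex(columns=timepoints)
    n_def = wide.notna().sum(axis=1)
    summary = wide.median(axis=1, skipna=True)
    summary[n_def < min_timepoints] = np.nan
    out = wide.copy()
    out.columns = [f"nev__{tp}" for tp in timepoints]
    out["nev_median"] = summary
    out["n_timepoints_used"] = n_def
    # preserve panel gene order
    order = pd.unique(stats["gene"])
    return out.reindex(order)


def nev_pipeline(panel: ExpressionPanel, span: float = DEFAULT_SPAN,
                 robust_iter: int = DEFAULT_ROBUST_ITER,
                 min_individuals: int = 2, min_mean: float = MIN_MEAN,
                 min_timepoints: int | None = None,
                 pool_timepoints: bool = False
                 ) -> tuple[pd.DataFrame, dict[str, TrendFit]]:
    """Panel → (NEV table, fitted trends): stats, trend fit, normalization.

    The trend is fitted per timepoint by default; ``pool_timepoints``
    fits one trend on all (gene, timepoint) points instead.
    """
    stats = compute_stats(panel, min_individuals=min_individuals)
    if pool_timepoints:
        pooled = fit_trend(stats, span=span, robust_iter=robust_iter,
                           min_mean=min_mean)
        trends: dict[str, TrendFit] = {tp: pooled for tp in panel.timepoints}
    else:
        trends = {
            tp: fit_trend(stats[stats["timepoint"] == tp], span=span,
                          robust_iter=robust_iter, min_mean=min_mean)
            for tp in panel.timepoints
        }
    table = compute_nev(stats, trends, min_timepoints=min_timepoints)
    return table, trends
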