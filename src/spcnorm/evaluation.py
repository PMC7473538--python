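"""Method-quality metrics for normalized spectral counts.

Covers the three diagnostics used to rank normalization methods:
technical-replicate regression (slope/intercept/R^2), per-protein
coefficient of variation across runs, and observed-vs-theoretical
fold-change linearity for spike-in standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizedMatrix

__all__ = [
    "RegressionFit",
    "CVReport",
    "replicate_regression",
    "median_slope",
    "protein_cv",
    "linearity_vs_theoretical",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class CVReport:
    """Per-protein CV (%) over a set of runs, with summary quartiles.

    Proteins whose mean over the selected runs is zero have no defined
    CV; they are excluded from ``cv`` and counted in ``n_excluded``.
    For log2-odds (Rsc) matrices the values are shifted back to odds
    space (2**value) before the CV is taken, since a CV of signed log
    values is not meaningful.
    """

    cv: pd.Series
    n_excluded: int
    median: float
    q1: float
    q3: float


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    if x.size < 3:
        raise ValueError("regression needs >= 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance on the x axis")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
    )


def replicate_regression(
    norm: NormalizedMatrix, run_a: str, run_b: str
) -> RegressionFit:
    """OLS of run_b abundances on run_a abundances over all proteins.

    Perfect technical reproducibility gives slope 1, intercept 0 and
    R^2 = 1; departures measure the method's replicate scatter.
    """
    for run in (run_a, run_b):
        if run not in norm.values.columns:
            raise KeyError(f"run {run!r} not in matrix")
    x = norm.values[run_a].to_numpy(dtype=float)
    y = norm.values[run_b].to_numpy(dtype=float)
    return _ols(x, y)


def median_slope(fits: list[RegressionFit]) -> float:
    """Median best-fit slope over a set of replicate-pair regressions."""
    if not fits:
        raise ValueError("no fits")
    return float(np.median([f.slope for f in fits]))


def protein_cv(norm: NormalizedMatrix, runs: list[str] | None = None) -> CVReport:
    """Per-protein coefficient of variation (%) across runs.

    CV = 100 * sd / mean with the n-1 sample standard deviation, over
    the selected runs (all runs by default).
    """
    values = norm.values if runs is None else norm.values[list(runs)]
    if values.shape[1] < 2:
        raise ValueError("CV needs >= 2 runs")
    if norm.scale == "log2_odds":
        values = np.power(2.0, values)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    defined = mean != 0
    cv = 100.0 * sd[defined] / mean[defined]
    cv.name = "cv_percent"
    q1, med, q3 = np.percentile(cv, [25, 50, 75]) if len(cv) else (np.nan,) * 3
    return CVReport(
        cv=cv,
        n_excluded=int((~defined).sum()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def linearity_vs_theoretical(
    fc_observed: np.ndarray | pd.Series,
    fc_theoretical: np.ndarray | pd.Series,
) -> RegressionFit:
    """OLS of observed on theoretical log2 fold changes for a standard.

    Both inputs are linear-scale fold changes over the same mixture
    pairs; non-positive observations cannot be log-transformed and are
    dropped with a warning.  A method that recovers the spike ratios
    perfectly gives slope 1 and R^2 = 1.
    """
    obs = np.asarray(fc_observed, dtype=float)
    theo = np.asarray(fc_theoretical, dtype=float)
    if obs.shape != theo.shape:
        raise ValueError("observed and theoretical FC vectors differ in length")
    ok = (obs > 0) & (theo > 0) & np.isfinite(obs)
    if (~ok).any():
        warnings.warn(
            f"excluding {(~ok).sum()} non-positive/undefined FC pairs", stacklevel=2
        )
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable FC pairs")
    return _ols(np.log2(theo[ok]), np.log2(obs[ok]))
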