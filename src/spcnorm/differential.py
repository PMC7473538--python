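"""Two-condition differential analysis of normalized spectral counts.

The pipeline follows the standard spectral-count workflow: fold change
of condition means, unpaired Student's t-test per protein, Benjamini-
Hochberg correction, and method-specific fold-change fences estimated
from the unchanged (non-significant) proteins via the Tukey rule
Q1 - 1.5*IQR / Q3 + 1.5*IQR.  A protein is called differentially
expressed only when both the q-value and the fold-change fence agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizedMatrix

__all__ = [
    "CutoffBounds",
    "fold_changes",
    "t_test_bh",
    "estimate_fc_cutoffs",
    "empirical_fdr",
    "differential_table",
]

#: floor for a lower fence that the Tukey rule pushes below zero
CUTOFF_FLOOR = 1e-6


@dataclass(frozen=True)
class CutoffBounds:
    """Fold-change fences with their quartile diagnostics."""

    lower: float
    upper: float
    q1: float
    q3: float
    iqr: float


def _split_runs(
    norm: NormalizedMatrix, conditions: Sequence[str], design: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    a, b = conditions
    runs_a = [r for r in norm.run_ids if design[r] == a]
    runs_b = [r for r in norm.run_ids if design[r] == b]
    if not runs_a or not runs_b:
        raise ValueError(f"conditions {conditions} not both present in the design")
    return runs_a, runs_b


def fold_changes(
    norm: NormalizedMatrix,
    design: Mapping[str, str],
    conditions: Sequence[str],
) -> pd.DataFrame:
    """Per-protein fold change of condition means (condition2/condition1).

    Linear-scale methods ratio the group means; log2-odds methods (Rsc)
    difference them and exponentiate, so the fold change is always on a
    linear scale.  Under NSAF a zero mean yields 0 or +inf, recorded as
    such and flagged ``degenerate`` rather than clamped.
    """
    runs_a, runs_b = _split_runs(norm, conditions, design)
    mean_a = norm.values[runs_a].mean(axis=1)
    mean_b = norm.values[runs_b].mean(axis=1)
    if norm.scale == "log2_odds":
        log2fc = mean_b - mean_a
        fc = np.power(2.0, log2fc)
        degenerate = pd.Series(False, index=fc.index)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = mean_b / mean_a
            fc = fc.where(~((mean_a == 0) & (mean_b == 0)), np.nan)
            log2fc = np.log2(fc)
        degenerate = (mean_a == 0) | (mean_b == 0)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "log2fc": log2fc,
            "degenerate": degenerate,
        }
    )
    out.index.name = "protein_id"
    return out


def t_test_bh(
    norm: NormalizedMatrix,
    design: Mapping[str, str],
    conditions: Sequence[str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Unpaired two-sided t-test per protein with BH step-up correction.

    The default is the pooled equal-variance Student's t; Welch is
    available via ``equal_var=False``.  Degenerate rows (zero variance
    in both groups) get p = 1 when the means agree and p = 0 when they
    differ, flagged in the ``degenerate_variance`` column.
    """
    runs_a, runs_b = _split_runs(norm, conditions, design)
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("t-test needs >= 2 replicates per condition")
    x = norm.values[runs_a].to_numpy()
    y = norm.values[runs_b].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    zero_var = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    equal_means = np.isclose(x.mean(axis=1), y.mean(axis=1))
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(zero_var & ~equal_means, 0.0, p)
    if np.isnan(p).any():
        p = np.where(np.isnan(p), 1.0, p)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    out = pd.DataFrame(
        {
            "p_value": p,
            "q_value": q,
            "bh_reject": reject,
            "degenerate_variance": zero_var & ~equal_means,
        },
        index=norm.values.index,
    )
    out.index.name = "protein_id"
    return out


def estimate_fc_cutoffs(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    quartile_method: str = "linear",
) -> CutoffBounds:
    """Fold-change fences from the unchanged-protein FC dispersion.

    The mask is raw p >= ``p_threshold`` (uncorrected): proteins the
    t-test cannot distinguish define the null fold-change spread, and
    the fences are Q1 - 1.5*IQR and Q3 + 1.5*IQR over their linear
    fold changes.  ``quartile_method`` is passed to ``numpy.quantile``
    (default linear interpolation between order statistics).
    """
    fcs = table.loc[
        (table["p_value"] >= p_threshold) & np.isfinite(table["fc"]), "fc"
    ].to_numpy()
    if fcs.size == 0:
        raise ValueError("no unchanged proteins to estimate cutoffs from")
    if fcs.size < 8:
        raise ValueError(
            f"only {fcs.size} unchanged proteins; quartile fences need >= 8"
        )
    q1, q3 = np.quantile(fcs, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("degenerate FC distribution: IQR is 0", stacklevel=2)
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    if lower <= 0:
        warnings.warn(
            f"lower fence {lower:.3g} <= 0 clamped to {CUTOFF_FLOOR}", stacklevel=2
        )
        lower = CUTOFF_FLOOR
    return CutoffBounds(lower=float(lower), upper=float(upper),
                        q1=float(q1), q3=float(q3), iqr=float(iqr))


def empirical_fdr(
    table: pd.DataFrame,
    null_proteins: Iterable[str],
    significant: pd.Series | None = None,
) -> float:
    """Percentage of significance calls among known-unchanged proteins.

    Computed as 100 * |significant AND null| / |all proteins in the
    table| — the spike-in benchmark convention where every background
    protein is truly unchanged.  By default the table's ``significant``
    column is used; pass ``significant`` explicitly to score another
    criterion (e.g. the raw-p rule ``table["p_value"] < 0.05``).
    """
    null_set = set(null_proteins)
    if significant is None:
        if "significant" not in table.columns:
            raise ValueError("table lacks a 'significant' column; run the full pipeline")
        significant = table["significant"]
    false_pos = sum(
        1 for pid, sig in significant.items() if sig and pid in null_set
    )
    return 100.0 * false_pos / len(table)


def differential_table(
    norm: NormalizedMatrix,
    design: Mapping[str, str],
    conditions: Sequence[str],
    alpha: float = 0.05,
    cutoffs: CutoffBounds | tuple[float, float] | str = "auto",
    equal_var: bool = True,
) -> tuple[pd.DataFrame, CutoffBounds]:
    """Full fold-change table: FC, p, q, fences, significance, direction.

    ``cutoffs="auto"`` estimates the fences from this comparison's own
    unchanged proteins; pass a :class:`CutoffBounds` or ``(low, high)``
    to reuse fences calibrated elsewhere (e.g. on a null comparison).
    Significance requires both q < ``alpha`` and FC outside the fences.
    """
    fc = fold_changes(norm, design, conditions)
    tests = t_test_bh(norm, design, conditions, alpha=alpha, equal_var=equal_var)
    table = fc.join(tests)
    if cutoffs == "auto":
        bounds = estimate_fc_cutoffs(table)
    elif isinstance(cutoffs, CutoffBounds):
        bounds = cutoffs
    else:
        low, high = cutoffs
        bounds = CutoffBounds(lower=float(low), upper=float(high),
                              q1=float("nan"), q3=float("nan"), iqr=float("nan"))
    outside = (table["fc"] < bounds.lower) | (table["fc"] > bounds.upper)
    table["significant"] = (table["q_value"] < alpha) & outside
    table["direction"] = np.select(
        [table["significant"] & (table["fc"] > 1.0),
         table["significant"] & (table["fc"] < 1.0)],
        ["up", "down"],
        default="unchanged",
    )
    return table, bounds
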