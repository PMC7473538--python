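"""Spectral-count normalization: CBN(P), CBN(S), NSAF and Rsc.

All four methods turn raw per-run spectral counts S_{x,M} into
abundances comparable across runs M.  The complexity-based methods add
a pseudo-count f tied to the experiment's complexity:

    CBN_{x,M} = (S_{x,M} + f) / (t_M + f)       f = 1/P  (CBN(P))
                                                f = 1/t  (CBN(S))

where t_M is the total count of run M, P the number of identified
proteins and t the grand total over all runs.  NSAF length-normalizes
and scales each run to unit sum; Rsc is a log2 count-odds with a fixed
pseudo-count of 0.5:

    NSAF_{x,M} = (S_{x,M}/L_x) / sum_i (S_{i,M}/L_i)
    Rsc_{x,M}  = log2( (S_{x,M} + 0.5) / (t_M - S_{x,M} + 0.5) )

Because f enters the CBN and Rsc numerators, absent proteins map to a
small positive abundance instead of zero, which keeps fold changes
finite.  NSAF has no adjustment factor, so zero counts stay zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import RunTotals, SpectralCountMatrix, run_totals

__all__ = [
    "METHODS",
    "AdjustmentFactor",
    "NormalizedMatrix",
    "adjustment_factor",
    "normalize_cbn",
    "normalize_nsaf",
    "normalize_rsc",
    "normalize",
]

#: public method tags, in the order the reports use
METHODS = ("cbn_p", "cbn_s", "nsaf", "rsc")

RSC_F = 0.5


@dataclass(frozen=True)
class AdjustmentFactor:
    """Pseudo-count f with its provenance (the P / t it derives from)."""

    method: str
    value: float
    n_proteins: int | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("adjustment factor must be positive")


@dataclass
class NormalizedMatrix:
    """Per-protein, per-run normalized abundances under one method.

    ``scale`` is ``"linear"`` for CBN/NSAF and ``"log2_odds"`` for Rsc;
    downstream fold-change code dispatches on it.
    """

    values: pd.DataFrame
    method: str
    scale: str
    f: float | None = None

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)


def adjustment_factor(totals: RunTotals, method: str) -> AdjustmentFactor:
    """Complexity-based adjustment factor for a given experiment.

    f = 1/P for ``cbn_p``, f = 1/t for ``cbn_s`` and the fixed 0.5 for
    ``rsc``.  P and t always come from :class:`RunTotals`, i.e. they are
    recomputed over the whole matrix (all runs), never per run.
    """
    if method == "cbn_p":
        if totals.n_proteins < 1:
            raise ValueError("empty experiment: no proteins")
        return AdjustmentFactor("cbn_p", 1.0 / totals.n_proteins,
                                n_proteins=totals.n_proteins, t=totals.t)
    if method == "cbn_s":
        if totals.t <= 0:
            raise ValueError("empty experiment: total spectral counts is 0")
        return AdjustmentFactor("cbn_s", 1.0 / totals.t,
                                n_proteins=totals.n_proteins, t=totals.t)
    if method == "rsc":
        return AdjustmentFactor("rsc", RSC_F,
                                n_proteins=totals.n_proteins, t=totals.t)
    raise ValueError(f"unknown method {method!r}")


def normalize_cbn(
    m: SpectralCountMatrix,
    f: AdjustmentFactor,
    variant: str = "shift_both",
) -> NormalizedMatrix:
    """Complexity-based normalization with pseudo-count ``f``.

    ``variant`` selects how the pseudo-count enters the ratio:
    ``"shift_both"`` (default) computes (S + f)/(t_M + f);
    ``"shift_denominator"`` computes S/(t_M + f); ``"shift_numerator"``
    computes (S + f)/t_M.  The default keeps every output strictly
    positive, which is what makes fold changes of absent proteins
    well defined.
    """
    if f.method not in ("cbn_p", "cbn_s"):
        raise ValueError(f"normalize_cbn needs a CBN adjustment factor, got {f.method!r}")
    totals = run_totals(m)
    t_m = totals.per_run
    s = m.counts
    if variant == "shift_both":
        values = (s + f.value).div(t_m + f.value, axis=1)
    elif variant == "shift_denominator":
        values = s.div(t_m + f.value, axis=1)
    elif variant == "shift_numerator":
        if (t_m == 0).any():
            raise ValueError("run with zero total counts: shift_numerator undefined")
        values = (s + f.value).div(t_m, axis=1)
    else:
        raise ValueError(f"unknown CBN variant {variant!r}")
    return NormalizedMatrix(values=values, method=f.method, scale="linear", f=f.value)


def normalize_nsaf(m: SpectralCountMatrix) -> NormalizedMatrix:
    """Normalized Spectral Abundance Factor.

    Counts are divided by protein length and each run column is scaled
    to unit sum.  Requires lengths for every protein; a run with no
    counts at all has an undefined NSAF and is a hard error.
    """
    if m.lengths is None:
        raise ValueError("NSAF requires protein lengths (FASTA or length column)")
    saf = m.counts.div(m.lengths, axis=0)
    denom = saf.sum(axis=0)
    zero_runs = denom.index[denom == 0]
    if len(zero_runs):
        raise ValueError(f"run {zero_runs[0]!r} has no spectral counts; NSAF undefined")
    values = saf.div(denom, axis=1)
    return NormalizedMatrix(values=values, method="nsaf", scale="linear", f=None)


def normalize_rsc(m: SpectralCountMatrix, f: AdjustmentFactor | None = None) -> NormalizedMatrix:
    """Log2 spectral-count odds with fixed pseudo-count 0.5.

    Values are kept in log2-odds space (``scale="log2_odds"``); the
    differential module converts group differences back to linear fold
    changes.
    """
    if f is None:
        f = AdjustmentFactor("rsc", RSC_F)
    if f.method != "rsc" or f.value != RSC_F:
        raise ValueError("Rsc uses the fixed adjustment factor 0.5")
    totals = run_totals(m)
    t_m = totals.per_run
    s = m.counts
    if (s.gt(t_m, axis=1)).any().any():
        raise ValueError("cell exceeds its run total: corrupt counts")
    odds = (s + f.value).div(s.rsub(t_m, axis=1) + f.value)
    values = np.log2(odds)
    return NormalizedMatrix(values=values, method="rsc", scale="log2_odds", f=f.value)


def normalize(m: SpectralCountMatrix, method: str, cbn_variant: str = "shift_both") -> NormalizedMatrix:
    """Dispatch to one of the four methods by tag."""
    if method in ("cbn_p", "cbn_s"):
        return normalize_cbn(m, adjustment_factor(run_totals(m), method), variant=cbn_variant)
    if method == "nsaf":
        return normalize_nsaf(m)
    if method == "rsc":
        return normalize_rsc(m)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
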