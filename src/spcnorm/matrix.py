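"""Core containers for spectral-count experiments.

A spectral-count experiment is a proteins x runs table of MS/MS counts
plus per-run metadata (condition, technical-replicate pairing) and,
optionally, protein lengths in amino-acid residues (required for NSAF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCountMatrix",
    "RunTotals",
    "run_totals",
    "average_technical_replicates",
]

#: run-metadata columns every matrix carries
META_COLUMNS = ("condition", "replicate", "pair")


@dataclass
class SpectralCountMatrix:
    """Proteins x runs spectral-count table.

    Parameters
    ----------
    counts
        DataFrame indexed by protein accession with one column per run.
        Cells are non-negative; integers for raw data, reals after
        technical-replicate averaging.  An absent protein in a run is a
        structural zero, never a missing value.
    run_meta
        DataFrame indexed by run id with columns ``condition``,
        ``replicate`` and ``pair`` (technical-pair id).
    lengths
        Optional Series of amino-acid lengths (>= 1) indexed like
        ``counts``; needed only for NSAF.
    """

    counts: pd.DataFrame
    run_meta: pd.DataFrame
    lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate run id: {dup!r}")
        if self.counts.isna().any().any():
            raise ValueError("counts contain missing cells; encode absence as 0")
        if (self.counts.to_numpy() < 0).any():
            r, c = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at protein {self.counts.index[r]!r}, "
                f"run {self.counts.columns[c]!r}"
            )
        missing_meta = self.counts.columns.difference(self.run_meta.index)
        if len(missing_meta):
            raise ValueError(f"runs without metadata: {list(missing_meta)}")
        self.run_meta = self.run_meta.loc[self.counts.columns]
        for col in META_COLUMNS:
            if col not in self.run_meta.columns:
                raise ValueError(f"run_meta lacks required column {col!r}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()][0]
                raise ValueError(f"no length for protein {missing!r}")
            if (self.lengths < 1).any():
                bad = self.lengths.index[self.lengths < 1][0]
                raise ValueError(f"length < 1 for protein {bad!r}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_runs(self) -> int:
        return self.counts.shape[1]

    def conditions(self) -> pd.Series:
        """Condition label per run, aligned to the count columns."""
        return self.run_meta["condition"]


@dataclass(frozen=True)
class RunTotals:
    """Per-run and experiment-wide spectral-count totals.

    ``t`` is the sum of all counts over all runs, ``n_proteins`` (P) the
    number of table rows; both are recomputed from the matrix, never
    trusted from input files.
    """

    per_run: pd.Series
    t: float
    n_proteins: int


def run_totals(m: SpectralCountMatrix) -> RunTotals:
    """Compute per-run totals t_M, the grand total t and protein count P."""
    if m.n_proteins == 0 or m.n_runs == 0:
        raise ValueError("empty spectral-count matrix")
    per_run = m.counts.sum(axis=0)
    for run, tot in per_run.items():
        if tot == 0:
            warnings.warn(
                f"run {run!r} has zero total spectral counts; "
                "normalization of this run is degenerate",
                stacklevel=2,
            )
    return RunTotals(per_run=per_run, t=float(per_run.sum()), n_proteins=m.n_proteins)


def average_technical_replicates(m: SpectralCountMatrix) -> SpectralCountMatrix:
    """Collapse technical replicates to one column per pair id.

    Each pair's cells are averaged with the arithmetic mean, so the
    result may hold non-integer counts.  Pairs usually have two members
    (duplicate injections) but any k >= 1 is accepted.  Members of a
    pair must share a condition label.
    """
    if m.run_meta["pair"].isna().any():
        bad = m.run_meta.index[m.run_meta["pair"].isna()][0]
        raise ValueError(f"run {bad!r} has no technical-pair id")
    pairs = m.run_meta["pair"]
    cols: dict[str, pd.Series] = {}
    meta_rows = []
    for pair_id in pairs.unique():
        members = pairs.index[pairs == pair_id]
        conds = m.run_meta.loc[members, "condition"].unique()
        if len(conds) > 1:
            raise ValueError(
                f"technical pair {pair_id!r} mixes conditions {sorted(conds)}"
            )
        cols[pair_id] = m.counts[members].mean(axis=1)
        meta_rows.append(
            {"run_id": pair_id, "condition": conds[0], "replicate": 1, "pair": pair_id}
        )
    averaged = pd.DataFrame(cols)
    meta = pd.DataFrame(meta_rows).set_index("run_id")
    return SpectralCountMatrix(counts=averaged, run_meta=meta, lengths=m.lengths)
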