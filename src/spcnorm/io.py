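"""Readers and writers for spectral-count tables.

Two dialects are supported: a generic TSV (first column protein id,
remaining columns runs, optional ``length`` column) and MaxQuant's
``proteinGroups.txt`` keyed on the "MS/MS count <run>" column family.
Protein lengths can also come from a FASTA database.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path
from typing import Mapping

import pandas as pd
from pyteomics import fasta as _fasta

from .matrix import META_COLUMNS, SpectralCountMatrix

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_run_metadata",
    "lengths_from_fasta",
]

MAXQUANT_ID_COLUMN = "Majority protein IDs"
MAXQUANT_COUNT_PREFIX = "MS/MS count "
MAXQUANT_LENGTH_COLUMN = "Sequence length"
MAXQUANT_FLAG_COLUMNS = ("Reverse", "Potential contaminant")


def read_run_metadata(source: str | PathLike | Mapping | pd.DataFrame) -> pd.DataFrame:
    """Load run metadata as a DataFrame indexed by run id.

    Accepts a TSV path with columns ``run_id, condition, replicate,
    pair``, an equivalent DataFrame, or a mapping
    ``run_id -> {"condition": ..., "replicate": ..., "pair": ...}``.
    A missing ``pair`` column defaults to one pair per run (no
    technical replication).
    """
    if isinstance(source, pd.DataFrame):
        meta = source.copy()
        if "run_id" in meta.columns:
            meta = meta.set_index("run_id")
    elif isinstance(source, Mapping):
        meta = pd.DataFrame.from_dict(source, orient="index")
        meta.index.name = "run_id"
    else:
        meta = pd.read_csv(source, sep="\t", dtype={"run_id": str}).set_index("run_id")
    if "condition" not in meta.columns:
        raise ValueError("run metadata needs a 'condition' column")
    if "replicate" not in meta.columns:
        meta["replicate"] = 1
    if "pair" not in meta.columns:
        meta["pair"] = meta.index
    return meta[list(META_COLUMNS)]


def _parse_cells(raw: pd.DataFrame) -> pd.DataFrame:
    """Coerce count cells to numbers; blanks become 0, garbage is fatal."""
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    for col in raw.columns:
        col_blank = raw[col].isna() | raw[col].astype(str).str.strip().eq("")
        bad = parsed[col].isna() & ~col_blank
        if bad.any():
            row = parsed.index[bad][0]
            raise ValueError(
                f"non-numeric count at protein {row!r}, run {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        neg = parsed[col] < 0
        if neg.any():
            row = parsed.index[neg][0]
            raise ValueError(f"negative count at protein {row!r}, run {col!r}")
    return parsed.fillna(0.0)


def _read_generic(path: Path) -> tuple[pd.DataFrame, pd.Series | None]:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    id_col = table.columns[0]
    table = table.set_index(id_col)
    table.index.name = "protein_id"
    lengths = None
    if "length" in table.columns:
        lengths = pd.to_numeric(table.pop("length"))
    return _parse_cells(table), lengths


def _read_maxquant(
    path: Path, column_map: Mapping[str, str] | None
) -> tuple[pd.DataFrame, pd.Series | None]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if MAXQUANT_ID_COLUMN not in table.columns:
        raise ValueError(
            f"not a proteinGroups table: missing {MAXQUANT_ID_COLUMN!r} column"
        )
    # rows flagged "+" in Reverse / Potential contaminant are decoys/junk
    keep = pd.Series(True, index=table.index)
    for flag in MAXQUANT_FLAG_COLUMNS:
        if flag in table.columns:
            keep &= table[flag].fillna("") != "+"
    table = table[keep]
    # protein identity = leading accession of the majority group
    ids = table[MAXQUANT_ID_COLUMN].str.split(";").str[0]
    if column_map is None:
        count_cols = [c for c in table.columns if c.startswith(MAXQUANT_COUNT_PREFIX)]
        # bare total "MS/MS count" (no run suffix) is not a run column
        column_map = {c: c[len(MAXQUANT_COUNT_PREFIX):] for c in count_cols}
    if not column_map:
        raise ValueError(
            f"no per-run {MAXQUANT_COUNT_PREFIX!r}* columns found; "
            "pass column_map to name the run columns explicitly"
        )
    counts = table[list(column_map)].rename(columns=dict(column_map))
    counts.index = ids
    counts.index.name = "protein_id"
    lengths = None
    if MAXQUANT_LENGTH_COLUMN in table.columns:
        lengths = pd.to_numeric(
            table[MAXQUANT_LENGTH_COLUMN].str.split(";").str[0]
        )
        lengths.index = ids
    return _parse_cells(counts), lengths


def read_count_table(
    path: str | PathLike,
    dialect: str = "generic_tsv",
    metadata: str | PathLike | Mapping | pd.DataFrame | None = None,
    column_map: Mapping[str, str] | None = None,
    lengths: pd.Series | None = None,
) -> SpectralCountMatrix:
    """Read a spectral-count table into a :class:`SpectralCountMatrix`.

    Parameters
    ----------
    path
        TSV file.
    dialect
        ``"generic_tsv"`` or ``"maxquant_proteingroups"``.  The MaxQuant
        dialect drops reverse-decoy and contaminant rows and, because
        column naming varies between MaxQuant versions, accepts an
        explicit ``column_map`` of {table column -> run id}.
    metadata
        Run metadata (path, mapping or DataFrame); when omitted, every
        run becomes its own condition/pair, which is enough for
        normalization but not for group comparison.
    lengths
        Overrides any length column found in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "generic_tsv":
        counts, file_lengths = _read_generic(path)
    elif dialect == "maxquant_proteingroups":
        counts, file_lengths = _read_maxquant(path, column_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if metadata is None:
        meta = read_run_metadata(
            {r: {"condition": r, "replicate": 1, "pair": r} for r in counts.columns}
        )
    else:
        meta = read_run_metadata(metadata)
        missing = counts.columns.difference(meta.index)
        if len(missing):
            raise ValueError(f"no metadata for run {missing[0]!r}")
    if lengths is None:
        lengths = file_lengths
    return SpectralCountMatrix(counts=counts, run_meta=meta, lengths=lengths)


def write_count_table(m: SpectralCountMatrix, path: str | PathLike, header_comment: str | None = None) -> None:
    """Write the generic TSV dialect (round-trips bit-exactly)."""
    out = m.counts.copy()
    if m.lengths is not None:
        out.insert(0, "length", m.lengths)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.index.name = "protein_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


def write_run_metadata(m: SpectralCountMatrix, path: str | PathLike) -> None:
    meta = m.run_meta.copy()
    meta.index.name = "run_id"
    meta.to_csv(path, sep="\t", lineterminator="\n")


def _accession(header: str) -> str:
    """UniProt-style ``sp|ACC|NAME`` (or tr|) headers -> ACC; else first token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def lengths_from_fasta(path: str | PathLike) -> pd.Series:
    """Protein lengths (residues) keyed by accession from a FASTA database."""
    lengths: dict[str, int] = {}
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            lengths[_accession(header)] = len(sequence)
    return pd.Series(lengths, name="length")
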