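"""Synthetic spectral-count experiments with known ground truth.

Two benchmark designs are generated:

* a spike-in series — a constant background proteome (the "matrix",
  emulating a whole-organism tryptic digest) plus six spiked standard
  proteins, four held at a fixed amount and two varied over a known
  ratio ladder across mixtures, each mixture injected in technical
  duplicate;
* a two-group comparison — n-vs-n biological design with technical
  duplicates and a stated fraction of truly changed proteins.

Counts are drawn per cell from a Poisson or (default) negative-binomial
model around configured expectations; the truth tables record the exact
expected ratios so parameter-recovery and false-positive-rate tests can
score any downstream method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import SpectralCountMatrix

__all__ = [
    "StandardSpec",
    "SpikeInConfig",
    "TwoGroupConfig",
    "default_standards",
    "simulate_spikein",
    "simulate_two_group",
]

MIXTURE_NAMES = "ABCDEFGHIJ"

#: spike ratio ladder spanning 1/25x to 5x, one entry per mixture
RATIO_LADDER = (1 / 25, 1 / 5, 1.0, 2.5, 5.0)


@dataclass(frozen=True)
class StandardSpec:
    """One spiked standard: name, residue length, expected counts per run
    at ratio 1 (``base_counts``) and its per-mixture ratio vector."""

    name: str
    length: int
    base_counts: float
    ratios: tuple[float, ...]


def default_standards(n_mixtures: int = 5, base_counts: float = 90.0) -> list[StandardSpec]:
    """Six standards mirroring the classic spike-in panel.

    HBA/HBB/BSA/PYG are held constant (ratio 1 everywhere); ENO climbs
    the 1/25–5x ladder across mixtures and ADH descends it.  Lengths are
    the UniProt sequence lengths of the real standards.  ``base_counts``
    (expected counts per run at ratio 1) defaults to ~6.5% of the
    background's per-run total, the mass fraction at which such
    standards are typically spiked (a few ng/uL against a ~67 ng/uL
    whole-proteome digest).
    """
    ones = tuple(1.0 for _ in range(n_mixtures))
    ladder = RATIO_LADDER[:n_mixtures]
    if len(ladder) < n_mixtures:
        raise ValueError("ratio ladder defined for at most 5 mixtures")
    return [
        StandardSpec("HBA", 142, base_counts, ones),
        StandardSpec("HBB", 145, base_counts, ones),
        StandardSpec("BSA", 607, base_counts, ones),
        StandardSpec("PYG", 843, base_counts, ones),
        StandardSpec("ENO", 436, base_counts, ladder),
        StandardSpec("ADH", 348, base_counts, tuple(reversed(ladder))),
    ]


@dataclass
class SpikeInConfig:
    """Study conditions for the spike-in benchmark.

    ``background_mean_log``/``background_sd_log`` parameterize the
    log-normal from which each background protein's expected TOTAL
    spectral counts over the whole experiment is drawn (the per-run
    expectation is that total divided by the number of runs); the
    defaults give ~400 proteins and ~13-18k total counts per
    experiment, the scale of a single-organism digest on a linear ion
    trap.  ``dispersion`` is the negative-binomial over-dispersion
    (var = mu + dispersion * mu^2); 0 or ``noise="poisson"`` gives
    Poisson counts.
    """

    n_background: int = 400
    background_mean_log: float = math.log(20.0)
    background_sd_log: float = 1.0
    length_mean_log: float = math.log(300.0)
    length_sd_log: float = 0.35
    noise: str = "negative_binomial"
    dispersion: float = 0.05
    n_mixtures: int = 5
    n_technical_reps: int = 2
    standards: list[StandardSpec] = field(default_factory=default_standards)
    seed: int = 0


@dataclass
class TwoGroupConfig:
    """Study conditions for the two-group (e.g. mutant vs wild-type)
    design: ``n_per_group`` biological replicates per condition, each
    injected ``n_technical_reps`` times, with ``fraction_changed`` of
    the proteins shifted in group 2 by a log2 effect drawn uniformly
    from [``effect_low``, ``effect_high``] with random sign."""

    n_proteins: int = 2860
    n_per_group: int = 3
    n_technical_reps: int = 2
    fraction_changed: float = 0.05
    effect_low: float = 0.3
    effect_high: float = 2.0
    mean_log: float = math.log(20.0)
    sd_log: float = 1.0
    length_mean_log: float = math.log(300.0)
    length_sd_log: float = 0.35
    noise: str = "negative_binomial"
    dispersion: float = 0.05
    conditions: tuple[str, str] = ("WT", "MUT")
    seed: int = 0


def draw_counts(
    rng: np.random.Generator,
    mean: np.ndarray,
    noise: str = "negative_binomial",
    dispersion: float = 0.05,
) -> np.ndarray:
    """Draw integer counts with the configured noise model.

    Negative binomial is parameterized by mean mu and over-dispersion
    alpha with variance mu + alpha*mu^2 (size = 1/alpha); alpha -> 0
    recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("negative expected count")
    if noise == "poisson" or dispersion == 0:
        return rng.poisson(mean)
    if noise != "negative_binomial":
        raise ValueError(f"unknown noise model {noise!r}")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _lengths(rng: np.random.Generator, n: int, mean_log: float, sd_log: float) -> np.ndarray:
    return np.maximum(50, np.round(rng.lognormal(mean_log, sd_log, n))).astype(int)


def simulate_spikein(cfg: SpikeInConfig) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Generate the spike-in benchmark with its ground-truth ratios.

    Returns the count matrix (background + standards, one column per
    mixture x technical replicate) and a truth table with ``is_null``
    and the true relative amount of each protein in every mixture
    (background proteins are 1 everywhere).
    """
    rng = np.random.default_rng(cfg.seed)
    mixtures = list(MIXTURE_NAMES[: cfg.n_mixtures])
    n_runs = cfg.n_mixtures * cfg.n_technical_reps
    for std in cfg.standards:
        if len(std.ratios) != cfg.n_mixtures:
            raise ValueError(f"standard {std.name}: ratio vector length != n_mixtures")
        if any(r <= 0 for r in std.ratios):
            raise ValueError(f"standard {std.name}: ratios must be positive")

    bg_ids = [f"ECOLI_{i:04d}" for i in range(cfg.n_background)]
    bg_total = rng.lognormal(cfg.background_mean_log, cfg.background_sd_log, cfg.n_background)
    bg_per_run = bg_total / n_runs
    bg_lengths = _lengths(rng, cfg.n_background, cfg.length_mean_log, cfg.length_sd_log)

    protein_ids = bg_ids + [s.name for s in cfg.standards]
    lengths = pd.Series(
        np.concatenate([bg_lengths, [s.length for s in cfg.standards]]),
        index=protein_ids, name="length",
    )

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for mi, mix in enumerate(mixtures):
        expectations = np.concatenate(
            [bg_per_run, [s.base_counts * s.ratios[mi] for s in cfg.standards]]
        )
        for rep in range(1, cfg.n_technical_reps + 1):
            run_id = f"{mix}{rep}"
            columns[run_id] = draw_counts(rng, expectations, cfg.noise, cfg.dispersion)
            meta_rows.append(
                {"run_id": run_id, "condition": mix, "replicate": rep, "pair": mix}
            )

    counts = pd.DataFrame(columns, index=protein_ids)
    counts.index.name = "protein_id"
    meta = pd.DataFrame(meta_rows).set_index("run_id")
    matrix = SpectralCountMatrix(counts=counts, run_meta=meta, lengths=lengths)

    truth = pd.DataFrame(
        {f"ratio_{mix}": [1.0] * cfg.n_background
         + [s.ratios[mi] for s in cfg.standards]
         for mi, mix in enumerate(mixtures)},
        index=protein_ids,
    )
    truth.insert(0, "is_null", [True] * cfg.n_background
                 + [all(r == s.ratios[0] for r in s.ratios) for s in cfg.standards])
    truth.index.name = "protein_id"
    return matrix, truth


def simulate_two_group(cfg: TwoGroupConfig) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Generate a two-group comparison with recorded true log2 effects.

    Group-2 expectations of changed proteins are scaled by 2**log2fc;
    the truth table records ``is_null`` and ``log2fc`` (0 for null
    proteins) so recall and false-positive rates can be scored exactly.
    """
    if not 0 <= cfg.fraction_changed < 1:
        raise ValueError("fraction_changed must lie in [0, 1)")
    rng = np.random.default_rng(cfg.seed)
    n_runs = 2 * cfg.n_per_group * cfg.n_technical_reps
    ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    total = rng.lognormal(cfg.mean_log, cfg.sd_log, cfg.n_proteins)
    per_run = total / n_runs
    lengths = pd.Series(
        _lengths(rng, cfg.n_proteins, cfg.length_mean_log, cfg.length_sd_log),
        index=ids, name="length",
    )

    n_changed = int(round(cfg.fraction_changed * cfg.n_proteins))
    changed_idx = rng.choice(cfg.n_proteins, size=n_changed, replace=False)
    log2fc = np.zeros(cfg.n_proteins)
    if n_changed:
        magnitude = rng.uniform(cfg.effect_low, cfg.effect_high, n_changed)
        sign = rng.choice([-1.0, 1.0], n_changed)
        log2fc[changed_idx] = magnitude * sign

    cond_a, cond_b = cfg.conditions
    mu = {cond_a: per_run, cond_b: per_run * np.power(2.0, log2fc)}
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in (cond_a, cond_b):
        for bio in range(1, cfg.n_per_group + 1):
            pair = f"{cond}{bio}"
            for rep in range(1, cfg.n_technical_reps + 1):
                run_id = f"{pair}_r{rep}"
                columns[run_id] = draw_counts(rng, mu[cond], cfg.noise, cfg.dispersion)
                meta_rows.append(
                    {"run_id": run_id, "condition": cond, "replicate": rep, "pair": pair}
                )

    counts = pd.DataFrame(columns, index=ids)
    counts.index.name = "protein_id"
    meta = pd.DataFrame(meta_rows).set_index("run_id")
    matrix = SpectralCountMatrix(counts=counts, run_meta=meta, lengths=lengths)

    truth = pd.DataFrame({"is_null": log2fc == 0, "log2fc": log2fc}, index=ids)
    truth.index.name = "protein_id"
    return matrix, truth
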