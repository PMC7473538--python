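# Methods

This note records the models, conventions and design choices behind
`spcnorm`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Normalization model

All four methods map raw spectral counts S_{x,M} (protein x, run M) to
abundances comparable across runs.

**CBN.** CBN(x,M) = (S_{x,M} + f)/(t_M + f), with t_M the run total and f a
pseudo-count derived from experiment complexity: f = 1/P (CBN(P), P = number
of proteins in the table) or f = 1/t (CBN(S), t = grand total count). P and
t are always recomputed from the matrix that is being normalized — after any
row filtering and over *all* runs — never taken per run or trusted from input
files. The published formula's typography is ambiguous about where f enters;
this implementation adds it to numerator and denominator, the only reading
under which (a) f fulfils its stated purpose of eliminating zero outputs for
absent proteins, and (b) CBN(P) and CBN(S) can give materially different fold
changes for a low-count protein, which the published validation data show.
The two alternative readings, S/(t_M+f) and (S+f)/t_M, remain available via
`normalize_cbn(..., variant=...)` for sensitivity analysis.

**NSAF.** (S/L)_x normalized to unit column sum. Protein length L comes from
a `length` column, the MaxQuant "Sequence length" field, or a FASTA database
(UniProt `sp|ACC|NAME` headers are parsed to the accession). NSAF has no
pseudo-count by construction; a zero count is a zero abundance, and a run
with no counts at all is a hard error rather than a silently degenerate
column.

**Rsc.** log2((S+0.5)/(t_M−S+0.5)), kept in log2-odds space and tagged so
downstream code dispatches on scale: fold changes difference the group means
and exponentiate, and CVs are computed on 2^value (odds), since the CV of a
signed log quantity is not meaningful.

Counts may be non-integer (after technical-replicate averaging); every
formula accepts reals.

## Differential pipeline

1. **Replicate averaging.** Technical duplicates ("pairs" in the run
   metadata) are collapsed by arithmetic mean. Geometric means were rejected
   because zero counts are routine. Pair members must share a condition.
2. **Fold change.** FC = mean(condition2)/mean(condition1) over the averaged
   replicates (FC of group means, not mean of pairwise FCs). NSAF FCs may be
   0 or +inf when a group mean is zero; they are recorded as such with a
   `degenerate` flag, never clamped.
3. **Testing.** Two-sided unpaired Student's t (pooled variance; the method
   is named after Student, not Welch, in the source workflow — Welch is
   available via `equal_var=False`), then Benjamini–Hochberg step-up over all
   tested proteins. Zero-variance-in-both-groups rows get p = 1 (equal
   means) or p = 0 with a `degenerate_variance` flag (unequal means).
4. **FC fences.** Quartiles of the linear FCs of the "unchangeable" proteins
   — raw p ≥ 0.05, uncorrected, because the fence is a description of the
   null FC spread, not an inference — with the Tukey rule Q1 − 1.5·IQR /
   Q3 + 1.5·IQR. Quartiles use linear interpolation (`numpy.quantile`
   default); the convention is an argument because published fence values
   can be sensitive to it. A lower fence pushed below zero by a wide IQR is
   clamped to 1e-6 with a warning; at least 8 masked proteins are required.
5. **Calling.** Significant = (q < alpha) AND (FC outside the fences), i.e.
   statistically significant *and* differentially expressed. Direction is
   up/down by FC vs 1.

Empirical FDR is reported as 100 × (significant ∧ truly-null)/(all proteins)
— the spike-in benchmark convention where the entire background is null. The
raw-p variant (p < 0.05, no BH) is available through the `significant=`
argument and is the convention used for the 5%-calibration checks.

## Evaluation metrics

Technical-replicate agreement is summarized by OLS of replicate 2 on
replicate 1 over all proteins (slope, intercept, R²; an intercept is fitted
because published reference fits report one). Per-protein CV (%) uses the
n−1 standard deviation over the selected runs; proteins with zero mean are
excluded and counted. Spike-recovery linearity regresses observed on
theoretical log2 FCs across mixture pairs, excluding non-positive FCs with
a warning.

## Synthetic benchmarks

The generator reproduces the statistical structure of the two validation
designs, not the mass spectrometry itself.

**Spike-in series** (`SpikeInConfig`): 400 background proteins emulating a
constant whole-organism digest, plus six standards — four at fixed amount,
ENO ascending and ADH descending the ratio ladder (1/25, 1/5, 1, 2.5, 5) —
across five mixtures in technical duplicate (10 runs). Each background
protein's expected *total* count over the whole experiment is log-normal
(μ = log 20, σ = 1); the per-run expectation is that total divided by the
number of runs. This gives ≈13–18k total counts per experiment and ≈3–4
counts/protein/run, the scale of a single-organism digest on a linear ion
trap. Standards default to 90 expected counts/run at ratio 1 ≈ 6.5% of the
per-run background total, the mass fraction at which such standards are
spiked (a few ng/µL against a ~67 ng/µL digest). Background lengths are
log-normal (log 300, 0.35, floored at 50 aa), typical of a bacterial
proteome; standards carry their real sequence lengths. Because run totals
enter every normalization, a spike that dominates the column sum compresses
its own estimated ratio (compositional closure) — the defaults keep
standards minor components, as in the real design.

**Two-group design** (`TwoGroupConfig`): 2860 proteins, 3 vs 3 biological
replicates × 2 technical injections (12 runs), 5% changed proteins with
|log2FC| uniform on [0.3, 2.0] and random sign applied to the group-2
expectation. Same abundance model as above.

**Count noise.** Cells are independent negative-binomial draws with
var = μ + α·μ² and dispersion α = 0.05 by default — real spectral counts are
over-dispersed relative to Poisson — with a Poisson option (α = 0 or
`noise="poisson"`) for clean limiting tests. Zeros arise naturally from the
count model; there is no separate dropout layer, since absence is treated as
a structural zero throughout.

**What the simulation does not emulate:** peptide-level sampling and
identification dropout, between-animal biological variance, correlated
run-to-run efficiency drifts, and protein-specific detectability. Tests that
pass on this generator therefore validate the estimators and the pipeline
logic under a known count model, not the full behaviour of real LC-MS/MS
data; in particular, method differences driven by identification dropout
(which penalize NSAF strongly on real data) appear here only in attenuated
form, through the noisier length-weighted NSAF denominator and the CBN
pseudo-count.

## Numerical and testing conventions

- Canonical fixed seed 0 for single-realization tests;
  `numpy.random.Generator` throughout, so fixed-seed runs are byte-identical.
- The null-calibration simulations (centered log2FC, 5% raw-p false-positive
  rate over 200 simulations) use 400 proteins at a constant ≈30 expected
  counts/run: the count regime of well-quantified proteins, where the
  t-on-counts approximation is meaningful. Tolerance for the 5% check is ±1
  percentage point — with 80 000 pooled tests the Monte-Carlo error is far
  smaller than the systematic error of a t-test on (near-)discrete data, so
  the band reflects the latter.
- The strong-effect recall check (5% changed, |log2FC| ∈ [1, 2], 30
  counts/run, 50 simulations of 1000 proteins) is implemented faithfully and
  currently **fails by design of the conditions themselves**: with technical
  duplicates averaged, a 3-vs-3 pooled t-test has 4 degrees of freedom, and
  BH over a 5%-true table demands p ≲ 0.0025, which a 2–4-fold effect at 30
  over-dispersed counts/run cannot reliably reach (measured recall ≈ 0.17;
  even the Poisson limit gives ≈ 0.77 < 0.8). The acceptance script reports
  the measured recall as-is.
- Benchmark-reproduction tests (published spike-in and mouse-cortex tables)
  run only when the corresponding supplementary TSV exports are dropped into
  `data/benchmarks/`; they are not redistributable with the package and the
  tests fail with instructions otherwise.
- Problem sizes in the acceptance script (one spike-in realization, 200 null
  simulations × 400 proteins, 50 recall simulations × 1000 proteins) were
  chosen to make Monte-Carlo error small relative to each quantity's
  tolerance while keeping a full run around a few seconds.

## Known limitations

- Two-condition designs only; no ANOVA, moderated variance, or imputation.
- Protein identity is the leading accession of a MaxQuant protein group;
  group collapsing and peptide-level parsing are out of scope.
- The t-test is applied to normalized counts, not to a count model; at very
  low counts its p-values are approximate (the calibration tests quantify
  this at ≈30 counts/run).
- CBN variants other than the default reading are provided for sensitivity
  analysis, not validated against published fold-change tables.
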