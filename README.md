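# spcnorm

Normalization and differential analysis for **spectral-count label-free
proteomics**, centred on **Complexity Based Normalization (CBN)** with the
established NSAF and Rsc methods alongside for comparison.

Spectral counting quantifies a protein by the number of MS/MS fragmentation
events assigned to its peptides in an LC-MS/MS run. Raw counts are not
comparable across runs — they drift with injection amount and instrument
state — so a normalization step precedes any fold-change (FC) calculation.
`spcnorm` is for proteomics analysts who have a proteins × runs count table
(e.g. MaxQuant `proteinGroups.txt`) and want normalized abundances,
two-condition differential calls with empirical FC cutoffs, and quality
metrics for choosing among normalization methods.

## The methods

For protein *x* in run *M*, with spectral counts S<sub>x,M</sub>, run total
t<sub>M</sub>, protein length L<sub>x</sub>, experiment-wide protein count
*P* and grand total *t*:

- **CBN** — counts over run totals with a *complexity-based* pseudo-count
  *f*:

      CBN(x,M) = (S(x,M) + f) / (t(M) + f)

  with **f = 1/P** (CBN(P)) or **f = 1/t** (CBN(S)). The pseudo-count is
  tied to sample complexity rather than chosen by the operator, and keeps
  every abundance strictly positive so fold changes stay finite when a
  protein drops out of a run.

- **NSAF** — length-normalized counts scaled to unit column sum:
  NSAF(x,M) = (S/L)<sub>x</sub> / Σ<sub>i</sub>(S/L)<sub>i,M</sub>. No
  pseudo-count: zeros stay zeros.

- **Rsc** — log2 count odds with the fixed pseudo-count 0.5:
  Rsc(x,M) = log2((S + 0.5)/(t<sub>M</sub> − S + 0.5)).

The differential pipeline averages technical-duplicate injections, computes
FC of condition means (difference of means in log-odds space for Rsc), runs
an unpaired two-sided Student's t-test per protein with Benjamini–Hochberg
correction, estimates method-specific FC fences from the unchanged proteins
(Tukey rule: Q1 − 1.5·IQR, Q3 + 1.5·IQR of the null FC spread), and calls a
protein significant only when **both** q < 0.05 and its FC lies outside the
fences.

A simulation module generates the two benchmark designs used to validate
all of this with known ground truth: a spike-in series (six standards over
a constant ~400-protein background, mixtures A–E in technical duplicate,
two standards spanning 1/25×–5×) and a two-group 3-vs-3 study with a stated
fraction of truly changed proteins.

## Worked example

`examples/02_spikein_benchmark.py` simulates the spike-in design and ranks
the methods:

```
simulated 406 proteins, 19671 total counts over 10 runs

method   median slope  median CV %
cbn_p           1.060         73.1
cbn_s           1.060         73.2
nsaf            1.058         73.5
rsc             0.685         56.1

ENO ladder (1/25x ... 5x), observed vs theoretical log2 FC:
  slope 0.974, R^2 0.991 over 10 mixture pairs
```

Reading: the replicate-regression slope should be 1 for a perfectly
reproducible method — Rsc's fixed pseudo-count drags it far below 1 — and
the per-protein CV over the constant background should be small; CBN(P)
edges out CBN(S) and NSAF. The ladder fit shows CBN(P) recovers known spike
ratios proportionally (slope ≈ 1) across a ~125-fold range.

`examples/03_two_group_differential.py` runs the full pipeline on a
simulated mutant-vs-WT study with 5% truly changed proteins (4–8×):

```
FC fences from unchanged proteins: [0.60, 1.24]
significant proteins: 34 (19 up, 15 down)
recall on truly changed proteins: 0.82
false calls among null proteins: 0.12% of the table
```

The other examples cover the four normalization formulas on a toy table
and MaxQuant/FASTA input handling. A thin CLI wraps the same library:

```sh
spcnorm simulate spikein --seed 0 --out counts.tsv --meta-out meta.tsv
spcnorm normalize --method cbn-p --counts counts.tsv --meta meta.tsv --out norm.tsv
spcnorm compare --norm norm.tsv --meta meta.tsv --conditions A,E --out results.tsv
spcnorm evaluate --norm norm.tsv --meta meta.tsv --report report.tsv
```

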