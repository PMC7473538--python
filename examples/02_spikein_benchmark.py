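"""Simulated spike-in benchmark: reproducibility and spike recovery.

Generates the default spike-in series (400-protein constant background,
six standards, mixtures A-E in technical duplicate), then compares the
four normalization methods on replicate regression and per-protein CV,
and checks how linearly CBN(P) recovers the ENO spike ratio ladder.
"""

import itertools

import numpy as np

import spcnorm as sp

m, truth = sp.simulate_spikein(sp.SpikeInConfig(seed=0))
totals = sp.run_totals(m)
print(f"simulated {totals.n_proteins} proteins, {totals.t:.0f} total counts "
      f"over {m.n_runs} runs\n")

background = [p for p in m.protein_ids if p.startswith("ECOLI_")]
print(f"{'method':7s} {'median slope':>13s} {'median CV %':>12s}")
for method in sp.METHODS:
    nm = sp.normalize(m, method)
    fits = [sp.replicate_regression(nm, f"{mix}1", f"{mix}2") for mix in "ABCDE"]
    cv = sp.protein_cv(nm)
    med_cv = np.median(cv.cv.loc[cv.cv.index.intersection(background)])
    print(f"{method:7s} {sp.median_slope(fits):13.3f} {med_cv:12.1f}")

avg = sp.average_technical_replicates(m)
nm = sp.normalize(avg, "cbn_p")
design = avg.run_meta["condition"].to_dict()
obs, theo = [], []
for a, b in itertools.combinations("ABCDE", 2):
    fc = sp.fold_changes(nm, design, (a, b))
    obs.append(fc.loc["ENO", "fc"])
    theo.append(truth.loc["ENO", f"ratio_{b}"] / truth.loc["ENO", f"ratio_{a}"])
fit = sp.linearity_vs_theoretical(np.array(obs), np.array(theo))
print(f"\nENO ladder (1/25x ... 5x), observed vs theoretical log2 FC:")
print(f"  slope {fit.slope:.3f}, R^2 {fit.r_squared:.3f} over {fit.n_points} mixture pairs")
print("A slope near 1 with high R^2 means the method reads out spiked\n"
      "amount ratios proportionally across a ~125-fold range; the CV table\n"
      "above shows which methods quantify the constant background most\n"
      "reproducibly (lower is better; a median replicate slope near 1 is better).")
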