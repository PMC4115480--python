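# frapkit

Quantification and group comparison of **fluorescence recovery after
photobleaching (FRAP)** assays for chromatin-binding proteins, with a
seeded synthetic-data generator for validation.

In a FRAP experiment a small circular region of a GFP-positive nucleus
is bleached with a laser pulse after a handful of prescans, and a
time-lapse series records unbleached molecules exchanging back into
the region. The half-time of recovery, t½, reports how tightly the
tagged protein binds chromatin: binding-dead bromodomain mutants and
displacing inhibitors both shorten t½. Because group means of t½ are
the assay readout, the whole chain from raw region intensities to
multiple-comparison statistics has to be reproducible — that chain is
what this package implements.

## The quantification chain

For each cell, three region-mean intensity traces are measured: the
bleached region F(t)ROI, the whole nucleus F(t)total, and a background
region F(t)BG.

1. **Normalization with acquisition-photobleach correction** (double
   normalization in the style of Phair):

   F(t)norm = [(F(t)ROI − F(t)BG) / (F(t)total − F(t)BG)] ×
              [(F(i)total − F(i)BG) / (F(i)ROI − F(i)BG)]

   where F(i) denotes a channel's mean over the prebleach scans. Any
   per-frame fluorophore loss caused by the imaging laser is common to
   ROI and nucleus and cancels in the ratio; the prebleach level maps
   to 1.

2. **Double-exponential association fit** of the post-bleach curve:

   y(x) = y0 + A1·(1 − e^(−x/t1)) + A2·(1 − e^(−x/t2)),

   with A1, A2 ≥ 0 and t1, t2 > 0, reported with t1 ≤ t2. The fitted
   plateau y0 + A1 + A2 below 1 measures the immobile fraction.

3. **Half-recovery time** by bracketing bisection: t½ solves
   y(t½) = y0 + (A1 + A2)/2, to 1e-6 s.

4. **QC filter**: cells with plateau > 1.1 (focal drift) or adjusted
   R² < 0.95 (irregular recovery) are removed as imaging artefacts;
   boundary values pass.

5. **Group statistics**: per-group Grubbs outlier elimination
   (two-sided, iterative, α = 0.05), then arithmetic mean ± SEM,
   one-way ANOVA with Tukey–Kramer all-pairs comparisons
   (studentized-range distribution, Kramer form for unequal n), and a
   percent-of-control selectivity profile.

The synthetic generator (`frapkit.simulate`, `frapkit.imaging`)
produces ground-truth-annotated traces and single-channel TIFF stacks
with the same structure — prescans, instantaneous bleach, geometric
acquisition bleaching, additive noise — so every stage can be checked
against known kinetics.

## Worked example

```python
from frapkit import (SimulationSpec, calibrate_kinetics_for_thalf,
                     simulate_group, quantify_cell)

kin = calibrate_kinetics_for_thalf(6.3)     # truth t1/2 = 6.3 s
spec = SimulationSpec(kinetics=kin, n_cells=5, cell_cv=0.0, seed=1,
                      duration_s=100.0)     # acquire well past the plateau
for trace in simulate_group(spec)[0]:
    r = quantify_cell(trace)
    print(f"{trace.cell_id}: t1/2 = {r.t_half_s:.2f} s, "
          f"plateau = {r.fit.plateau:.3f}, qc = {r.qc_pass}")
```

prints

```
cell000: t1/2 = 6.22 s, plateau = 0.938, qc = True
cell001: t1/2 = 6.47 s, plateau = 0.958, qc = True
cell002: t1/2 = 6.74 s, plateau = 0.957, qc = True
cell003: t1/2 = 6.19 s, plateau = 0.938, qc = True
cell004: t1/2 = 6.27 s, plateau = 0.946, qc = True
```

— five cells simulated at 2% noise with a calibrated 6.3 s half-time
and a 5% immobile fraction, each quantified back to within a few
percent of the truth. The 100 s series matters: the slow association
component (t2 ≈ 27 s here) must approach its plateau within the
acquisition window for the fit to pin t½ tightly.

The numbered scripts under `analysis/` run complete study designs on
simulated cohorts — a bromodomain mutant panel with an inhibitor arm,
a SAHA-widened assay window, and an inhibitor selectivity profile —
and print group means, Tukey-adjusted p-values and percent-of-control
tables; outputs land under `results/`. The same designs run from a
single YAML config through the CLI:

```sh
frapkit all --config design.yaml --seed 7
frapkit report --config design.yaml   # adds the summary figure
```

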