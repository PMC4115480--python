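# Methods

## Quantification model

The measured quantity for each cell is a triplet of region-mean
intensity time series — bleached ROI, whole nucleus, background —
sampled at a fixed frame interval, with a block of prebleach scans
before an instantaneous bleach event.

**Normalization.** The relative fluorescence at frame *t* is the
background-subtracted ROI/nucleus ratio, rescaled by the inverse
prebleach ratio (means over the prebleach scans). This double
normalization has three properties the pipeline's tests pin down at
machine precision: invariance to a common gain, invariance to a common
additive offset across all three channels, and — at zero background —
invariance to any common per-frame multiplicative loss on ROI and
nucleus. The last is the acquisition-photobleach correction: imaging
illumination bleaches the whole field, so the loss factor is shared
and cancels. The normalization is undefined when the
background-subtracted nucleus signal is non-positive at any frame;
that raises an error naming the frame rather than producing a silent
infinity.

A consequence worth stating: since the nucleus loses fluorophore at
the bleach event, normalized recovery to 1 means equilibration with
the *remaining* pool, not with the prebleach state. Ground-truth
kinetics in the simulators are defined in this double-normalized
space, which is what makes truth curves exactly recoverable.

**Recovery model.** Post-bleach curves are fitted with a
double-exponential association,
y(x) = y0 + A1(1 − e^(−x/t1)) + A2(1 − e^(−x/t2)).
Prebleach frames are excluded from the fit (their normalized values
are kept as a diagnostic; their mean is 1 by construction). The two
components absorb the mixture of fast diffusive exchange and slower
binding-limited exchange without committing to a mechanistic
reaction–diffusion model; no such model is fitted here.

Constraints: A1, A2 ≥ 0 and t1, t2 > 0 guarantee a monotone model,
which the half-recovery bisection assumes. The constrained fit also
uses finite caps (y0 ∈ [−1, 2], amplitudes ≤ 3, time constants ≤ 1e5 s)
because unbounded fits on noisy traces occasionally diverge into
"slow drift" solutions with extrapolated plateaus of 10² or more;
capped divergent fits still land above the plateau QC threshold and
are removed. An unconstrained fit is available behind a flag for
sensitivity checks. Initialization: y0 from the first post-bleach
value, plateau from the mean of the final 10% of frames, time
constants at one tenth and one half of the observed span; up to five
jittered restarts on failure, and a failed fit is reported as
`converged=False`, never silently replaced. Parameters are reported
with t1 ≤ t2; when t2/t1 < 1.05 or one amplitude is below 1e-3 of the
total, a near-single-exponential diagnostic is set (the split between
components is then not identifiable; t½ is unaffected). Adjusted R²
uses p = 5 free parameters.

**Half-recovery time.** t½ solves y(t½) = y0 + (A1 + A2)/2. The
bracket [0, hint] doubles its upper end until the model exceeds the
target, then bisection converges to 1e-6 s absolute. t½ is
independent of y0 and of a common scaling of the amplitudes, and
non-decreasing in each time constant — all property-tested, with a
1e-4 s dense-grid search as the independent oracle.

**Quality control.** A fitted cell is excluded iff the fit failed,
the plateau strictly exceeds 1.1, or the adjusted R² is strictly
below 0.95; boundary values pass. Plateaus above 1 cannot arise from
the model's own normalization and indicate focal drift; low R²
indicates irregular recovery (cell movement, passing debris).

## Group statistics

Within each group, outliers among the QC-passed t½ values are
eliminated by the two-sided Grubbs test, iterated one removal per
pass at α = 0.05, with the critical value from the t-quantile formula
G_crit = ((N−1)/√N)·√(t²/(N−2+t²)), t = t_{α/(2N), N−2}. Nothing is
removed below N = 3 or at zero spread. The group summary is the
arithmetic mean with SEM = sample SD/√n.

Groups are compared by one-way ANOVA with Tukey–Kramer all-pairs
comparisons: pooled within-group MSE on N−k degrees of freedom,
pairwise statistic q = |x̄ᵢ − x̄ⱼ|/√((MSE/2)(1/nᵢ + 1/nⱼ)), adjusted p
from the studentized-range distribution with parameters (k, N−k)
(scipy's implementation; validated against statsmodels and R's
ptukey to 1e-6). The Kramer standard error handles unequal group
sizes. Degenerate zero-MSE designs are reported with a flag rather
than NaNs. Selectivity profiles divide each group's post-outlier mean
by the control mean (×100); error bars scale the group's own SEM by
the same factor, treating the control mean as a constant — a
variance-propagating alternative is available behind a flag.

**A measured property, not a defect of the implementation:** with
outlier elimination applied before the ANOVA — the analysis order
this chain deliberately reproduces — the familywise type-I error
under a four-group null of lognormal half-times (median 6 s, CV 20%,
n = 10) is ≈ 0.077 rather than the nominal 0.05; Tukey–Kramer without
the preceding Grubbs step controls the same rate at ≈ 0.045–0.048,
and under a normal-distribution null the full chain measures ≈ 0.062.
Trimming extremes shrinks the pooled MSE and shifts trimmed group
means, a known cost of outlier removal before hypothesis testing.
The acceptance suite reports this rate as computed.

## Synthetic data

The curve-level generator emulates the acquisition the pipeline
expects: 5 prescans, 0.25 s frame interval, an instantaneous bleach
between the last prescan and the first post-bleach frame (no
mid-bleach frame is emitted), double-exponential recovery in
normalized space, and three corruptions — geometric per-frame
acquisition bleaching applied to the fluorophore signal of ROI and
nucleus (not to the non-fluorophore background), an additive
background level, and additive Gaussian per-frame noise.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| n_prebleach | 5 | the emulated protocol's prescan count |
| frame_interval_s | 0.25 s | the emulated acquisition rate |
| duration_s | 60 s | covers plateaus for t½ up to ~10 s; scale with t½ (≈ 8×) for slower targets |
| kinetics | y0 0.1, plateau 0.9, t1 2 s, t2 12 s | mid-range assay: t½ ≈ 4.7 s, 10% immobile |
| cell_cv | 0.2 | lognormal CV on each cell's t1, t2; amplitudes fixed so group truth stays unimodal and calibratable |
| noise_sd | 4 (= 2% of the ROI scale 200) | plausible region-mean noise; no measured reference exists |
| total/bg noise factors | 1/3 | nucleus and background regions are ~an order of magnitude larger than the ROI, so their means are ~3× less noisy |
| acq_bleach_rate | 5e-4/frame | ~11% loss over a 240-frame series, consistent with an attenuated imaging laser |
| bleach_fraction_of_total | 0.06 | a ~6% disc-to-nucleus area ratio |

`calibrate_kinetics_for_thalf` inverts the model for simulation
design: given a target t½, an amplitude split A1/(A1+A2), a t2/t1
ratio and a plateau, it returns kinetics whose analytic t½ matches
the target within 1e-4 s (t½ scales linearly in time at fixed shape,
so the inversion is closed-form up to one bisection of the unit
shape). t½ does not depend on y0 or the amplitude scale, so y0
(default 0.1) only shapes the curve.

The image-level generator renders the same kinetics onto a pixel
grid: elliptical nucleus of uniform density, circular bleach disc
built from exactly the N pixels nearest the center (so disc pixel
count × pixel area matches the requested bleach area within one
pixel), background box outside the cell, Poisson photon noise at a
configurable gain. After the bleach event, total nuclear fluorophore
is conserved — the disc's recovery is donated by the rest of the
nucleus — and the immediate post-bleach disc level is defined
self-consistently with the truth y0 so that the extracted,
double-normalized disc trace equals the truth curve exactly in the
noise-free limit. The tests verify that the two generators agree to
1e-9 without noise and within the region-mean noise scale with noise.

What the generators do **not** emulate: reaction–diffusion transport
(no spatial recovery gradient inside the disc), optics (no
point-spread function, no axial dimension), detector specifics (no
gain nonlinearity, no saturation), cell movement or focal drift
(QC-failure modes are constructed in tests by corrupting channels
directly), and prebleach drift. Passing tests therefore show that the
*analysis chain* is correct and well-calibrated on data satisfying
its model assumptions, not that the double-exponential model is the
right description of any particular protein's recovery.

## Numerical choices

- Bisection: absolute time tolerance 1e-6 s; bracket doubling from a
  caller-supplied hint; the dense-grid test oracle uses 1e-4 s steps.
- Least squares: scipy trf with xtol=ftol=gtol=1e-12.
- Adjusted R² on flat data (zero total variance) is defined as 1 for
  a perfect fit, 0 otherwise, to keep QC total.
- Trace tables round-trip at full precision (17 significant digits,
  round-trip float parsing).
- Per-group random streams derive from the master seed and the group
  label (CRC32), so adding a group to a design never perturbs the
  draws of existing groups; per-cell streams spawn from the group
  seed and cell index.
- Duplicate (cell_id, time) rows in input are an error, never
  averaged; rows may arrive interleaved or shuffled.

## Known limitations

- Estimates of t½ for a given cell depend on the acquisition window:
  when the slow component's time constant approaches or exceeds the
  post-bleach span, the plateau — and hence t½ — is weakly
  identified, inflating per-cell scatter and occasionally producing
  capped runaway fits that the plateau QC then removes. Acquire (or
  simulate) to ≈ 8× the expected t½.
- Under severe acquisition bleaching (≥ 1%/frame over hundreds of
  frames) late-frame normalized noise grows as the inverse of the
  surviving signal; fits remain unbiased in the typical case but the
  extrapolated plateau becomes heavy-tailed across cells.
- The Grubbs-before-ANOVA ordering mildly inflates familywise error
  (measured above); treat marginal significance calls near α
  accordingly.
- The studentized-range SF is numerically integrated by scipy and is
  the slowest step of large null simulations (~0.1 s per 4-group
  replicate).
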