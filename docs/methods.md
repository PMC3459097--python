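# Methods

`neohrf` characterizes the developmental trajectory of the BOLD
hemodynamic response function (HRF) in preterm infants, term-equivalent
infants and adults, and quantifies the consequences of the HRF's
maturation for fMRI analysis. Because the underlying clinical MRI data are
not public, the package pairs every analysis component with a synthetic
data generator whose defaults encode the study conditions; this note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not establish.

## The double-gamma HRF model

The impulse response is the difference of two gamma densities,

    h(t) = A * [ g(t; a1, b1) - w * g(t; a2, b2) ] / max_t [ ... ],

with `g` the gamma probability density (shape `a`, rate `b` in 1/s), `w`
the undershoot weight and `A` the amplitude in % BOLD signal change. The
bracketed difference is normalized to unit maximum, so `A` is exactly the
positive-peak amplitude — the morphology targets can then be read directly
as parameters. The three morphology read-outs are always *measured from
the curve* on a dense grid (default dt = 0.01 s, horizon 40 s):

- **time-to-peak (TTP)** — grid argmax, seconds after stimulus onset;
- **peak amplitude** — the maximum, % signal change;
- **undershoot ratio** — |post-peak minimum| / maximum, clipped to 0 when
  the curve never goes negative after the peak.

The 40 s horizon reflects the event design's 40.5 s inter-stimulus
interval (ISI), chosen in the original experiment so that the response
fully recovers within each epoch.

### Age-group presets and calibration

Presets for the three groups are calibrated so their measured morphology
equals the published group medians:

| group   | TTP (s) | amplitude (%) | undershoot ratio |
|---------|--------:|--------------:|-----------------:|
| preterm |   11.25 |          0.52 |             0.15 |
| term    |    7.0  |          0.54 |             0.49 |
| adult   |    5.38 |          1.63 |             0.23 |

Calibration pins three of the five shape parameters and solves for the
remaining two by nested deterministic bisection (the peak rate matches
TTP at fixed weight; the weight matches the undershoot ratio):

- the undershoot gamma is fixed on an **absolute clock** (shape 40, rate
  2.2/s; trough near 17.7 s, fully recovered by ~30 s). Tying the
  undershoot timing to the peak rate — natural for a pure dilation model —
  would place the slow preterm group's undershoot past 30 s, contradicting
  the within-epoch recovery the 40.5 s ISI is built around;
- the peak gamma shape is fixed at 8. A broader peak (shape ~6) leaves a
  preterm late tail of ~0.2% of peak at the epoch boundary, which leaks
  into the next epoch's pre-stimulus baseline and biases the measured
  undershoot ratio by more than 1%.

Once the curve is normalized to unit peak, the amplitude constraint is
absorbed by `A`, so two free parameters against two remaining constraints
give a unique, deterministic solution. A zero-undershoot target returns
`w = 0` in closed form. Within this family the reachable TTP range is
roughly 1–12.5 s (the peak cannot move past the fixed undershoot trough),
which covers all three group medians.

## Synthetic acquisitions

**Event design.** TR 0.5 s, 1000 volumes, 1 s stimulus, 40.5 s ISI: 12
complete epochs, onsets aligned to volume starts, stimulation first (the
original report does not state whether the first epoch began with
stimulation; stimulation-first is assumed and flagged here). Because a 1 s
stimulus at TR 0.5 s samples the impulse response directly, stimuli no
longer than two volumes are modelled as unit-area impulses — the active
time course then equals the HRF curve on the volume grid, and a boxcar's
systematic half-stimulus peak shift never enters the morphology estimates.
Sustained blocks (24 s on / 24 s off) use the boxcar convolution integral.

**Volumes.** Default geometry 32x32x6 voxels of 3.125x3.125x4 mm (the
acquisition matrix scale); a spherical active cluster (default radius 2
voxels) carries `baseline * (1 + s(t)/100)` with baseline fixed at 1000
arbitrary units. Noise components are individually configurable and off by
default except white Gaussian noise: Legendre polynomial drift, sinusoids
with random voxel phase (aliased cardiac/respiratory stand-ins), and
contiguous corrupted volume spans with large global intensity jumps
(motion stand-in; no geometric motion is simulated — corrupted spans are
handled by censoring, not realignment). All randomness flows through one
integer seed.

**Vessel flow.** Per-vessel pulsatile velocity waveforms (left/right
internal carotid, basilar; flow split 0.4/0.4/0.2; lumen areas 5/5/4 mm²;
20 cardiac phases) are synthesized by inverting the CBF computation: the
cosine pulse is de-meaned exactly, so the flow chain reproduces the target
CBF to rounding error. The conversion cm/s x mm² -> ml/min uses the factor
0.6 (10 mm³/s = 0.6 ml/min), fixed by dimensional analysis and unit-tested.

## Preprocessing

- **Highpass (cutoff 50 s):** regression against a discrete-cosine
  subspace containing all components with period > cutoff, mean restored.
  Deterministic, idempotent, and faithful to the cutoff semantics without
  replicating a vendor filter.
- **Smoothing (FWHM 5 mm):** per-axis Gaussian sigma in mm over
  anisotropic voxels, reflect boundary (conserves the image sum).
- **Intensity normalization:** one multiplicative factor takes the 4D
  global mean to 10000.
- **Censoring:** an epoch is dropped if any volume of its peristimulus
  window — from 2 s before onset to the epoch end minus 2 s, so that
  consecutive windows tile the run — intersects a corrupted span. The run
  is rejected when the retained fraction of the acquisition is <= 40%
  (strict: exactly 40% rejects); with 12 epochs of 41.5 s in a 500 s run,
  5 retained epochs (fraction 0.415) is the minimum that survives.

## GLM and cluster inference

Task regressors are unit-peak normalized, so with the intercept estimating
the voxel baseline the effect size `100 * beta / baseline` reads in %
signal change. Nuisance columns: intercept plus mean-centred Legendre
drift. Fitting is voxel-wise least squares with AR(1) prewhitening
(coefficient from OLS residual lag-1 autocorrelation, per voxel by
default, optionally pooled spatially); t and F statistics are mapped to z
through the standard-normal quantile of their tail probability (upper
tail for F — a one-sided convention, documented since the original
equivalent is unstated), capped at |z| = 8.2 and flagged.

Cluster inference thresholds z > 2.3 and assigns family-wise-corrected p
values from a permutation null of the maximum cluster statistic over
face-connected (6-connectivity) components:

- **within-run GLM maps:** sign-flipping of whitened *full-model*
  residuals per time point (the same flips at every voxel, preserving
  spatial correlation), added back to the reduced-model fit — the ter
  Braak scheme. Using reduced-model residuals instead leaves task signal
  in the permuted series and badly over-conserves the null at realistic
  effect sizes. The null statistic is maximum cluster extent. Calibration:
  the measured family-wise error over 500 smoothed null runs is ~0.04–0.05
  at nominal 0.05.
- **across-subject maps** (fixed-effects group means; paired contrasts):
  exhaustive subject sign-flipping (all 2^n - 1 non-identity patterns for
  n <= 12). Here the null statistic is maximum cluster *mass* (sum of
  z - 2.3): with only 63 patterns at n = 6, extent saturates — a strong
  homogeneous effect keeps the same suprathreshold set under single flips,
  capping significance at p >= 7/64 no matter how overwhelming the
  activation — whereas mass still orders the patterns.

Fixed-effects group maps are inverse-variance-weighted means (no
between-subject variance term; z grows as sqrt(n) on homogeneous cohorts).
Paired contrasts are voxel-wise one-sample t tests on effect differences.

## Peristimulus characterization

The ROI is the set of voxels strictly above the 90th centile
(linear-interpolation percentile) of the statistic inside the winning
cluster; ranking uses the uncapped F statistic (monotone with z) so cap
ties cannot dilute the selection, with a peak-voxel fallback and a
degenerate-tie flag. Epochs are converted to % change against the mean of
the 4 samples in [-2 s, 0) and averaged; the first epoch, which has no
pre-stimulus window, is skipped, leaving 11 of 12 epochs in a full run
(at least 5 are required, matching the censoring rule).

The average is fitted over t >= 0 by bounded trust-region least squares in
the same pinned double-gamma family (free: peak shape, peak rate,
undershoot weight, amplitude), best of five deterministic starts with TTP
in {4, 6, 8, 11, 14} s. The loss is soft-L1 with scale set to the
baseline-window standard error — a robust fit without committing to a
specific M-estimator; when the average is essentially noise-free the fit
falls back to plain least squares (a vanishing robust scale would freeze
the optimizer). Morphology metrics always come from the fitted curve.

Group comparisons use the exact Mann-Whitney-Wilcoxon test (exact
enumeration for combined n <= 20 without ties, tie-corrected normal
approximation otherwise) or the exact Wilcoxon signed-rank test for paired
data, with Holm-Bonferroni correction across the pairwise comparisons
within each metric. The TTP-against-age trend is summarized by
`ttp = a * exp(-b (age - age_min)) + c` with non-negative parameters — the
three-parameter decay is an assumption, as the original trend is given
only graphically; a flat series returns `b ~ 0`, flagged degenerate.

## Block-design re-analysis

Each subject's block run is fitted with a single-regressor GLM under the
age-matched and the adult HRF; subject effect/variance maps feed the
fixed-effects group map and the paired contrast. Model fit quality
(Pearson r and SSE between the cohort-mean ROI % change series and the
least-squares-scaled model prediction) quantifies the benefit of the
age-appropriate model.

A structural limitation is worth stating plainly. With double-gamma
responses calibrated to the group medians, the adult-HRF regressor still
correlates c = 0.61 with the preterm 24 s/24 s block response (a ~6 s lag
is only ~45 degrees of the 48 s cycle). Detection signal-to-noise then
scales as: matched z, adult-model 0.61 z, paired contrast
sqrt((1-c)/2) z = 0.44 z. Since 0.61 > 0.44, any valid test detects the
attenuated adult-model activation more readily than the paired
difference: the combination "significant paired contrast AND no
significant positive cluster under the adult model" cannot be reproduced
at any noise level in this family. The published data evidently contained
stronger mismatch (their exemplar correlations imply c ~ 0.42). The
synthetic experiments therefore reproduce the matched-model cluster, the
significant preterm paired contrast, the term-group null contrast and the
directional fit-quality ordering — and the adult-model analysis of the
preterm cohort is expected to (and does) find an attenuated but real
positive cluster. Notably, the adult-model correlation measured on the
synthetic preterm cohort (~0.35) closely matches the published exemplar.

## Problem sizes and study conditions

Cohort experiments use scaled volumes chosen to keep the full suite
desk-runnable while preserving every statistical property: event
characterization cohorts of 10 subjects per group on 16x16x5 grids
(active radius 2.5 voxels, white noise sd 1% of baseline, 119
permutations per subject); block cohorts of 6 subjects on 14x14x4 grids
with noise sd 3% of baseline — chosen so single-subject block detection
matches the robust subject-level activation reported for the source
cohorts; 500 null runs of 10x10x4 x 150 volumes for the family-wise error
calibration. The characterization cohort reproduces the group medians to
within a few percent and detects all pairwise TTP orderings at
Holm-adjusted p < 0.001, with the preterm-term amplitude comparison
non-significant — the same pattern as the original cohort.

## Known limitations

- Synthetic runs carry no geometric motion, no slice-timing offsets, no
  spatially varying coil profile and no anatomical structure; passing
  tests show the *analysis chain* is correct and calibrated, not that it
  is robust to artifacts the generator does not model.
- Subjects within a synthetic cohort share one true HRF; between-subject
  morphology variance in the metric tables is measurement noise only.
- The preset family pins the undershoot clock; HRFs whose undershoot
  timing scales with their peak latency are outside it.
- Fixed-effects group inference is intentional (it mirrors the original
  analysis) and does not generalize beyond the cohort analyzed.
- CBF inputs are per-phase mean lumen velocities; vessel segmentation on
  velocity maps is out of scope, and lumen areas are treated as constant
  over the cardiac cycle (per-phase areas are averaged if supplied).
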