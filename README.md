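# neohrf

**Developmental BOLD hemodynamic response characterization.**

The brain's hemodynamic response function (HRF) — the BOLD fMRI signal
change following a brief stimulus — matures dramatically across the last
trimester of gestation: preterm infants respond slowly and weakly, term
infants faster with a deep post-stimulus undershoot, and adults fastest
and strongest. Using the canonical adult HRF to analyze infant fMRI can
therefore miss real activation. `neohrf` is a toolkit for researchers
studying this maturation: it simulates event-related and block-design
BOLD acquisitions with age-specific HRFs, recovers HRF morphology from
peristimulus averages, compares age groups, re-analyzes block designs
with age-specific versus canonical HRFs, and quantifies global cerebral
blood flow (CBF) from phase-contrast vessel measurements.

## The model

The HRF is a difference of two gamma densities, normalized to unit peak:

    h(t) = A · [ g(t; a₁, b₁) − w · g(t; a₂, b₂) ] / max_t [·]

so `A` is the positive-peak amplitude in % signal change. Three morphology
read-outs are measured from the curve: time-to-peak (TTP, s), peak
amplitude (%), and the undershoot:peak ratio. Age-group presets are
calibrated so their measured morphology matches the published group
medians — preterm (11.25 s, 0.52 %, 0.15), term (7.0 s, 0.54 %, 0.49),
adult (5.38 s, 1.63 %, 0.23).

The analysis chain mirrors the original study: spatial smoothing (FWHM
5 mm), global intensity normalization, highpass filtering (cutoff 50 s),
motion-block censoring (> 40 % of the run must survive), a GLM with an
FLOBS-style 3-function HRF basis set and AR(1) prewhitening, F-test z
maps thresholded at z > 2.3 with permutation cluster correction at
p < 0.05, top-decile ROI extraction, peristimulus averaging in % signal
change against the 2 s pre-stimulus baseline, and a robust trust-region
double-gamma fit. Global CBF is summed internal-carotid + basilar flow
divided by brain mass (volume × 1.05 g/ml), in ml/100 g/min.

## Worked example

Simulate three cohorts (10 subjects per age group) with the study's
event-related design — TR 0.5 s, 1 s stimulus, 40.5 s inter-stimulus
interval, 12 epochs in 1000 volumes — and run the full characterization
chain:

```python
from neohrf.config import PipelineConfig
from neohrf.pipeline import run_characterization_cohort
from neohrf.peristimulus import compare_all_groups

cfg = PipelineConfig(
    shape=(16, 16, 5), active_radius=2.5,
    groups=("adult", "term", "preterm"), n_subjects=10,
    noise_sd=10.0, n_permutations=119, seed=11,
)
table = run_characterization_cohort(cfg)
print(table.groupby("group")[
    ["time_to_peak", "peak_amplitude", "undershoot_ratio"]
].median())
```

```
         time_to_peak  peak_amplitude  undershoot_ratio
group
adult            5.38        1.580722          0.230931
preterm         11.30        0.529373          0.142316
term             7.03        0.528265          0.534383
```

The recovered group medians sit within a few percent of the generating
morphology (adult TTP 5.38 s and amplitude ~1.6 %; preterm TTP 11.3 s;
infant amplitudes ~0.53 %), and
`compare_all_groups({g: s for g, s in table.groupby("group")})` detects
every pairwise TTP ordering at Holm-adjusted p ≈ 0.0005 while the
preterm-vs-term amplitude comparison stays non-significant — the same
pattern as the clinical cohorts.

The same chain is exposed as a CLI with staged artifacts:

```bash
neohrf --seed 11 --out-dir out report    # simulate → … → group-stats → cbf
```

Re-analyzing a synthetic preterm block cohort (24 s on / 24 s off, 6
subjects) with the age-matched versus the canonical adult HRF:

```python
from neohrf.pipeline import run_block_application
res = run_block_application(PipelineConfig(shape=(14, 14, 4), seed=1),
                            group="preterm")
print(res["matched"]["fit_correlation"], res["adult"]["fit_correlation"])
# 0.6929...  0.4298...
```

The age-matched model fits the region's signal markedly better
(r = 0.69, SSE 6.0 versus r = 0.43, SSE 9.5), and the paired t contrast
between the two analyses is cluster-significant — while for a term cohort
the two models perform near-identically and the paired contrast is null.

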