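# Methods

## The assay and its data

A light-dark transition (LDT) recording is 60 minutes of three alternating
10-minute light/dark cycles starting in light, giving three light→dark and
two dark→light transitions. Quantization-style video tracking reports, per
larva and per minute, 13 parameters: time, distance and average speed in
each of three activity classes — inactive ("freezing", speed < 1 mm/s),
small activity (1–10 mm/s) and large activity (> 10 mm/s) — plus total
distance (`dist`), total active time (`dur`) and burst aggregates
(`distb`, `durb`). Within one minute-bin the three class durations sum to
60 s, class distances sum to `dist`, and each class speed equals class
distance over class duration.

The analysis deliberately avoids per-phase averaging: each larva's 13 × 60
matrix is flattened to a vector of length 780 (parameter-major:
`inadur@min01 … inadur@min60, inadist@min01, …`), with no normalization or
scaling, so that within-phase dynamics (transition spikes, habituation)
remain visible to the classifiers. Minutes are 1-based in files and
feature names.

## Synthetic cohort generator

Raw LDT datasets are rarely released, so the generator is a first-class,
tested component, not a fixture. It emulates the assay from a small set of
latent per-minute drivers:

- **active seconds** `A(t)`: a light-phase baseline (6 s/min) or, in dark,
  a baseline (16 s/min) plus a transition spike (18 s) that decays within
  the phase as `(1 − habituation_rate)^t` (default rate 0.25/min);
- **large-activity fraction**: 0.15 in light, 0.45 in dark;
- **class-typical speeds**: 0.3 mm/s (inactive micro-movement), 4 mm/s
  (small), 16 mm/s (large) — each sitting strictly inside its class's
  speed band (thresholds 1 and 10 mm/s).

All 13 parameters are *derived* from these drivers, so every consistency
invariant holds exactly, for exposed and noisy records alike. The burst
aggregates are set equal to the large-activity class: the tracking
vocabulary never defines them independently, and this choice preserves
`distb ≤ dist`, `durb ≤ dur`.

**Exposure effects** scale the latent drivers, not the output cells:
duration-type parameters in `affected_params` scale `A(t)`,
distance/speed-type parameters scale the corresponding class speed(s), in
the affected phase(s) from `onset_min` onward. Scaling a final matrix cell
directly would break the sum-to-60 and additivity invariants; acting on
the drivers keeps exposed records internally consistent while producing
exactly the intended pre-noise mean change. The default effect is a
multiplier of 1.2 on dark-phase `dur` and `dist` — a 20% increase in dark
activity, the canonical benchmark-dose effect size for this assay.

**Noise** has two levels, both multiplicative log-normal with unit mean:
a per-larva activity scale with coefficient of variation
`between_larva_cv` (default 0.25) and per-minute factors on active time
and class speeds with log-scale SD `within_larva_noise_sd` (default 0.30).
Active time is clipped to [0, 60] s after noise. Defaults were chosen once
to produce visibly overlapping but separable groups at the default effect
size; with both set to 0 a record equals the generator's mean profile
exactly, which is what the phase-contrast and effect-arithmetic tests
assert on.

Cohorts default to 36 control + 36 exposed larvae. Each larva draws from
its own counter-derived RNG stream (`default_rng([seed, index])`), so a
cohort is bit-reproducible regardless of generation order.

The **uniform null generator** produces datasets of the same shape as a
two-group comparison filled with i.i.d. uniform values on [0, 1), with
balanced labels and no scaling to locomotor units — classification
behavior under the default preprocessing is scale-equivariant, so raw
uniform values are an adequate noise model for accuracy calibration.

What the generator does *not* emulate: well-position and plate effects,
mortality or malformation, temporal autocorrelation beyond the
deterministic spike/habituation profile, heavy-tailed burst episodes, and
cross-parameter noise correlation beyond what the shared drivers induce.
Passing tests therefore demonstrate the statistical machinery is
calibrated and leak-free, not that real assay data will reach any
particular accuracy.

## Univariate screen

Each feature is tested with a two-sided Mann–Whitney U test: exact
enumeration when the combined sample is ≤ 12 with no ties, otherwise the
normal approximation with midrank tie correction and continuity
correction (per-minute duration data contain ties, e.g. zeros). Constant
features get p = 1 by convention rather than an error. Bonferroni
adjustment uses m = the full feature count (780), not the number of
informative features. Exhaustive enumeration at n = 6 + 6 shows the
corrected normal approximation stays within 0.016 of the exact p
everywhere, with the worst case at mid-range p-values where the
continuity correction is largest; at the screen's operating point
(n ≈ 36/36, p ≪ 0.05/780) the approximation is conservative, and the
measured family-wise false-positive rate on pure-noise matrices is ~0.5%.

## Classification harness

- **Folds**: stratified fivefold partition (every class needs ≥ 5
  members), deterministic under a seed, shared across families and coding
  runs within one comparison so that between-family contrasts are not
  confounded by fold-sampling noise.
- **Dual coding**: every comparison runs twice, once with the first class
  coded 1 / second coded 2 and once reversed; predictions are mapped back
  to label space and the 2N predictions pooled into one confusion table
  (equivalent to averaging the two runs' accuracies). Class decisions
  threshold the predicted probability of code 2 at 0.5, with ties broken
  toward the class coded 1 — a bias the coding swap cancels by
  construction.
- **Families** (fixed explicit defaults, overridable per run): `glm` =
  logistic regression with L2 ridge (C = 1.0) on standardized features;
  `rf` = 50 trees, √p features per split, depth cap 20; `gbm` = 50 trees,
  depth 5, learning rate 0.1; `dl` = two hidden layers of 200 ReLU units,
  10 training epochs, standardized features. Standardization is fit on
  training folds only. Every estimator gets a deterministic per-fold seed
  derived from the fold seed and coding, so whole runs reproduce exactly.
- **Metrics**: exposed is the positive class; ratios with zero
  denominators are reported as missing (NaN), never as zero. The accuracy
  interval is a Wald binomial 95% CI on the pooled prediction count,
  emitted for plotting parity and labelled as such.

Leakage is guarded by construction (per-fold pipelines) and by test: a
memorizing stub classifier substituted into the harness scores exactly
chance on out-of-fold noise data, and would score 1.0 if any test row
reached training.

## Null calibration and significance

Two null distributions per family: (a) *random data* — fresh uniform
matrices of the comparison's shape, new folds per replicate; (b) *label
permutation* — uniform shuffles of the label vector (identity permutation
not excluded) with features untouched, replicate-specific fold seeds.
Label permutation preserves the feature distribution and its correlation
structure, so its accuracy spread is at least as large as fully random
data's; it is the recommended basis for thresholds.

The "upper 95% limit" is mean + 1.96 × SD of the null accuracies — a
normal-approximation band chosen because it reproduces the standard
printed summaries exactly (49.7% + 1.96 × 5.0% = 59.5%); an
empirical-quantile threshold (97.5th percentile) is available via
`is_significant(..., method="quantile")`. Pooling across families
averages the means and takes the square root of the average variance.
Default replicate count is 100, configurable upward; per-family counts
can be reduced for slow families.

With this package's GLM (C = 1.0 ridge), the random-data null has mean
≈ 49% and SD ≈ 8.6% at 36/36 × 780 — correctly centered, but with a
spread that depends on the regularization strength: toolkits whose GLM
defaults search for a heavier penalty produce more stable null
predictions and hence tighter bands. Thresholds should
therefore always be calibrated with the same family configuration used
for the observed comparison, which is what the workflow functions do.

## Problem sizes and numerical choices

The acceptance script runs 100 uniform-random datasets (GLM) and label
permutations with 100 replicates for GLM/RF/DL and 40 for GBM — sizes
chosen so a full calibration completes in a few minutes on one CPU while
keeping the standard error of each reported mean below one percentage
point. The test suite uses the same design at modestly reduced replicate
counts. CSV output uses `%.17g` floats and round-trip parsing, so cohorts
survive write/read bit-exactly. Seeds below 2³¹ are derived from a single
user seed via `numpy.random.SeedSequence` throughout.

## Known limitations

- The four families are fixed-default stand-ins for a reference
  implementation's behavior; absolute null SDs (hence thresholds) depend
  on the regularization strength and will differ between toolkits.
- The Wald CI on accuracy ignores the correlation between the two pooled
  coding runs and between samples sharing a fold model; it is a plotting
  aid, not an inferential interval — the permutation band is.
- No exclusion filter for dead or immobile larvae is applied before
  vectorization; records must be complete (missing cells are rejected,
  not imputed).
- `dl` determinism holds for the single-threaded default configuration;
  changing the backend's threading may perturb results within tolerance.
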