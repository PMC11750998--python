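# Methods

This note documents the models and procedures `nirscreen` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Measurement model and preprocessing

A continuous-wave fNIRS channel measures light intensity at two wavelengths
(780 and 850 nm) across a 3.0 cm source–detector separation, sampled at
8.138 Hz for 5 minutes (2441 samples). Intensity is converted to optical
density, OD(t) = −ln I(t)/⟨I⟩_t, which is linear in chromophore
concentration changes under the modified Beer–Lambert law (MBLL):

ΔOD_λ = (ε_HbO,λ·ΔHbO + ε_HbR,λ·ΔHbR) · d · ppf

with d = 3.0 cm and ppf = 6 the partial pathlength factor (the combined
pathlength multiplier applied to the geometric distance, the conventional
semantics of the conversion's ppf argument). The 2×2 extinction system is
inverted per sample; HbT = HbO + HbR by definition. Extinction
coefficients are shipped as a named table (`prahl2002`, the standard
compiled hemoglobin spectrum): at 780 nm ε_HbO = 7.10·10⁻⁴,
ε_HbR = 1.07544·10⁻³; at 850 nm ε_HbO = 1.058·10⁻³,
ε_HbR = 6.9132·10⁻⁴ µM⁻¹·cm⁻¹. Results are therefore bit-reproducible
against a declared table; swapping tables rescales concentrations but, by
construction, the synthetic forward model and the inversion always share
one table.

Stage order and parameters (all exposed in `PreprocessConfig`):

- **Channel pruning.** SNR_dB = 20·log₁₀(mean I / sd I) per channel and
  wavelength; a channel is dropped when SNR < 25 dB at either wavelength.
  The dB criterion needs a definition the acquisition software does not
  publish; the raw-intensity mean/sd ratio is the standard CW quality
  metric. A constant channel has infinite SNR and is kept. A subject with
  all 48 channels pruned is excluded, not errored.
- **Motion detection** (per channel, union over wavelengths): within every
  sliding window of 2 s, the peak-to-peak excursion is compared against
  50× the channel's baseline OD SD and against 5 OD units absolute; hits
  are dilated by 4 s each side. The baseline SD is estimated in two
  passes — first robustly (1.4826·MAD) so that the artifacts being sought
  do not inflate it, then as an ordinary SD over the samples the first
  pass left clean. A plain single-pass SD provably misses large spikes
  (a 60·σ spike lasting 1 s inflates the full-record SD ~3.6×, lifting the
  50·σ bar above the spike itself), which is why the robust first pass is
  used.
- **Spline correction.** Within each flagged segment a smoothing spline is
  fitted (csaps-convention p = 0.99, mapped to the
  `scipy.interpolate.make_smoothing_spline` penalty as λ = (1−p)/p) and
  subtracted; segments shorter than 4 samples are linearly detrended
  instead. Segments are then re-anchored by level shifts computed from
  short-window (~0.33 s) means at each boundary so the series stays
  continuous; clean stretches keep their shape but may be shifted as a
  whole — that is precisely what removes baseline-shift artifacts, and it
  is harmless downstream because the band-pass removes constant offsets.
- **Band-pass.** 3rd-order Butterworth, 0.01–0.1 Hz, applied
  forward–backward (zero phase). Measured response: 0.14% amplitude loss
  at 0.05 Hz, ~53 dB attenuation at 0.25 Hz (respiration), ~128 dB at
  1 Hz (cardiac). The half-power point sits at the nominal edges, so Mayer
  waves at exactly 0.1 Hz are only half-attenuated — a genuine confound of
  this band choice that the synthetic generator reproduces.
- **PCA cleanup.** Per wavelength, the leading principal component of the
  channels-over-time OD matrix (pruned channels excluded) is projected
  out (default `pca_remove=1`, configurable, 0 disables). This targets
  superficial/global physiology common to many channels. It runs once,
  after filtering and before MBLL inversion, matching the documented stage
  order; whether it should act on OD or on concentrations is
  operationally irrelevant because the MBLL inversion is linear and
  channel-wise, but the OD placement is kept for fidelity.

Invariants validated by the suite: intensity scale invariance of the whole
chain; exact HbT conservation; zero-phase filtering; MBLL
forward∘inverse = identity to 1e-9; the PCA stage changes the signal only
within the removed (rank-`pca_remove`) subspace.

## ROI connectivity

The fixed montage partitions the 48 channels into 10 ROIs with counts
(6,6,6,6,3,3,5,5,4,4). ROI series are unweighted means over unpruned
member channels; an ROI with no surviving channel is invalid and its pairs
are recorded as missing.

- **COH**: Welch magnitude-squared coherence (Hann window, 120 s segments,
  50% overlap), averaged over frequency bins in 0.01–0.1 Hz and clipped to
  [0, 1]. The underlying coherence method's exact estimator is not
  published; Welch band-averaging is the reproducible standard choice, and
  the segment length is config-exposed. The segment length is capped at
  half the record so at least ~3 segments are always averaged — with a
  single segment, coherence is identically 1 regardless of input, a
  degenerate estimator. At the default operating point (300 s record,
  120 s segments) the independent-noise floor of the band-averaged
  estimator is ≈ 0.32 (mean over 100 simulated pairs), which the suite
  asserts stays below 0.35.
- **PLV**: both series are zero-phase band-limited to 0.01–0.1 Hz (the one
  analysis band; no second narrower band is defined), instantaneous phases
  are taken from the analytic (Hilbert) signal, and
  PLV = |mean exp(iΔφ)| after discarding 5% of samples at each end
  (analytic-signal edge transients). Independent-noise floor ≈ 0.16 at the
  default length (asserted < 0.3).

Both estimators are symmetric, bounded in [0, 1], and exactly 1 for a
series against itself. 45 ROI pairs × 3 chromophores × 2 estimators give
the 270 FC features, in fixed column order
`{coh,plv}_{hbo,hbr,hbt}_ROIi_ROIj` (i < j).

## Group statistics

`GroupDifferenceModel.fit()` runs per connection: pairwise-complete
removal of missing subjects, a Shapiro–Wilk normality check (α = 0.05)
gating a z-score transform, one-way fixed-effects ANOVA
(F = MS_between/MS_within, df = (k−1, N−k)), Benjamini–Hochberg FDR over
the 45 connections of each (estimator, chromophore) family (pooled
correction available via config), and — where the corrected p < 0.05 —
Fisher LSD-t contrasts for the three group pairs using the omnibus MSW,
df = N−k. Two caveats are deliberate fidelity choices rather than
statistical recommendations: a z-transform is location-scale only and
cannot normalize a non-normal distribution (and leaves the ANOVA F
unchanged); and per-family FDR mirrors how results are reported per
estimator/chromophore rather than a global error-rate argument. The suite
checks both statistics against brute-force plain-Python oracles on 1,000
random small instances and cross-checks ANOVA against
`scipy.stats.f_oneway`; permutation simulations confirm the
ANOVA+FDR gate's type-I rate stays at or below nominal.

## Classifier screening

Feature sets: `fc_only` (270 columns) and `fc_plus_neuro` (+ MMSE, TMT-A,
TMT-B, BNT, HVLT, CDT). Tasks: SCD vs NC, MCI vs NC, MCI vs SCD, the
impaired group being the positive class. Stratified 5-fold and 10-fold CV
are both run and reported side by side (they were "adopted successively"
without a stated pooling rule, so neither is privileged).

Per training fold: (1) variance filter, (2) z-score with training
statistics, (3) PCA retaining 95% of variance (config-exposed), (4)
classifier. All statistics are frozen before touching test rows; the suite
asserts transforms are a function of the training fold only.

The printed reduction rule — drop features with variance ≤ 1 — is kept as
the default threshold, but it interacts badly with FC features, whose
values live in [0, 1] and whose variances are therefore ≪ 1: applied
literally it deletes all 270 FC columns (and applied after z-scoring it
deletes *every* column, since z-scored training variance is exactly 1).
The filter therefore evaluates raw (pre-normalization) training variances,
and its empty-result behavior is a policy: `on_empty="raise"` for strict
use, `on_empty="keep_all"` (warn and skip the filter) in the end-to-end
screen so FC-only models remain runnable. A `strict_paper_order` audit
mode (z-score first, strictly-less-than rule) exists for comparison. In
practice the threshold only ever bites the TMT score columns' large
variances' complement — i.e., with mixed features it keeps the scores and
drops the FC block, which is another reason the keep-all fallback is the
end-to-end default.

Metrics are computed on the pooled out-of-fold predictions (one confusion
matrix and one AUC per model, matching a single-number-per-model report):
ACC, specificity/sensitivity w.r.t. the positive class, rank-based AUC
(validated against an exhaustive pairwise-comparison oracle) with a DeLong
95% CI. **EACC** is the mean pooled accuracy of the identical CV pipeline
over `n_perm` random label permutations (default 200), computed per model;
ACC − EACC is a model's margin over its own chance behavior, which for
imbalanced tasks sits at the majority-class prevalence rather than 0.5.

Classifiers use library-typical defaults (no hyperparameter search):
sklearn LDA/LR/GNB/SVC(rbf)/KNN/RF(100)/GBDT, `xgboost.XGBClassifier`
(100 trees), and an in-package RUSBoost — AdaBoost.M1 over decision stumps
with the majority class randomly undersampled to the minority size before
each boosting round, the defining structure of that algorithm. No other
resampling is applied anywhere.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the study conditions
(group sizes 48/65/90 for NC/SCD/MCI, 300 s at 8.138 Hz, 48 channels, six
score scales) with known ground truth.

- **Coupling model.** Latent ROI HbO signals are unit-variance band-limited
  (0.01–0.1 Hz) Gaussian processes mixed as x = L·s with L·Lᵀ equal to the
  configured 10×10 coupling matrix (eigenvalue-clipped to the nearest PSD
  matrix, rows renormalized), so the target correlation of ROI pair (i, j)
  equals coupling[i, j]. For a single pair this is exactly the
  shared-source + independent-residual construction; both COH and PLV
  respond monotonically to the injected coupling, which the suite verifies
  over couplings {0, 0.3, 0.6, 0.9} × 20 seeds through the full pipeline.
- **Default group structure.** Baseline coupling 0.3 on all pairs;
  connections ROI1–ROI3, ROI2–ROI7 and ROI4–ROI7 are raised to 0.5 (SCD)
  and 0.7 (MCI) — the compensatory-hyperconnectivity direction with
  MCI > SCD > NC. No effect sizes are published for the group contrasts,
  so these deltas are free parameters chosen once to be resolvable at
  cohort scale, not calibrated to any dataset.
- **Chromophores.** ΔHbR = −0.3·ΔHbO + independent narrowband noise
  (ratio and residual configurable); ΔHbT follows by summation. The
  anticorrelated-copy model is the simplest physiologically signed choice;
  no generative HbR model is published.
- **Forward measurement.** Concentrations map through the same MBLL (same
  extinction table, d, ppf) the preprocessing inverts; nuisance is added in
  OD: shared sinusoidal oscillators at 1 Hz (cardiac), 0.25 Hz
  (respiratory) and 0.1 Hz (Mayer) with ±20% per-channel gain jitter and
  amplitudes expressed relative to the neural OD SD (defaults 0.8, 0.4,
  0.4), linear per-channel drift (default 1.0 relative), probe-wide motion
  events at 0.5/min (Poisson), each a spike (5–20× signal SD, 0.5–2 s) or
  a baseline step with channel-specific signed amplitude, white OD noise
  (SD 0.005), and finally I = I₀·exp(−OD) with I₀ = 1000, guaranteeing
  strictly positive intensities. Event times are recorded per channel as
  ground truth.
- **Scores.** Normal draws with the configured group mean/SD — defaults
  are the published cohort table (e.g. MCI MMSE 25.49 ± 2.56) — clipped to
  instrument bounds (MMSE 0–30, BNT 0–30, HVLT 0–36, CDT 0–10, TMT ≥ 0 s)
  and rounded for the integer-valued scales. Clipping at the MCI MMSE
  upper bound biases the mean by only ≈ −0.04 points, so the generator
  recovers the configured mean within ±0.1 at n = 10,000.
- **Reproducibility.** One root seed; each subject draws from an
  independent spawned child stream, so cohorts are bit-identical across
  runs and stable under group-size changes.

What passing on synthetic data does **not** show: the generator has no
photon-transport forward model, no layered scalp/skull optics, no
heterogeneous per-subject coupling, no realistic score–connectivity
correlation structure beyond group membership, and its separations are
deliberately clean. Classifier metrics on synthetic cohorts therefore
bound the pipeline's correctness, not its clinical performance; published
cohort-level accuracies are not reproducible without the subject data and
are not a target of this package.

## Problem sizes and runtime choices

The test suite and example runs use deliberately small problems — 2-minute
recordings, cohorts of 9–36 subjects, n_perm of 1–10 for smoke tests and
200 only where the EACC's own convergence is the property under test —
sizes chosen so the full validation runs on a laptop-class single core in
a few minutes while keeping every statistical check at adequate power.
The acceptance script's two quantities use the full 2441-sample recording
length and n = 10,000 score draws.

## Known limitations

- The SNR definition, COH estimator details, PCA component count and
  normality test are reconstructions of under-specified steps; all are
  config-exposed and their defaults documented above.
- Spline re-anchoring can leave small level errors when genuine slow
  signal falls inside a flagged segment (inherent to segment-wise motion
  correction); the band-pass removes the resulting offsets.
- DeLong CIs assume independent observations; pooled out-of-fold scores
  mildly violate this (shared training folds), a standard approximation.
- With three groups, per-family BH-FDR across 45 connections controls the
  FDR within family only; no across-family statement is made.
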