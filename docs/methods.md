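# Methods

## The problem

Resting-state EEG functional connectivity between internet-addiction (IA)
and healthy-control (HC) groups, quantified by phase synchronization
metrics that are robust to volume conduction, and used as features for
cross-validated group classification. The participant EEG of the emulated
study is not publicly deposited, so the package is driven end-to-end by a
synthetic cohort generator with planted ground truth: every claim a test
makes is a claim about a known generative model, not about real brains.

## Phase-lag metrics

For band-limited, mean-removed channels *x_a*, *x_b*, the analytic signals
*z(t) = x(t) + i·x̂(t)* (Hilbert transform via the one-sided frequency-domain
construction) give instantaneous phases φ(t) and the phase difference
Δφ = φ_a − φ_b. The two metrics:

* **PLI** = | ⟨ sign(sin Δφ(t)) ⟩ | — the imbalance between lead and lag
  samples. `sign(0)` contributes 0 (a tie is neither lead nor lag); this is
  what makes zero-lag (volume-conducted) dependence invisible.
* **WPLI** = | ⟨ Im{z_a z̄_b} ⟩ | / ⟨ |Im{z_a z̄_b}| ⟩ — each sample
  weighted by the magnitude of the imaginary cross-component, down-weighting
  near-zero-lag samples whose PLI signs are noise-driven. When the
  denominator is exactly zero (a pure zero-lag pair), WPLI is reported as 0
  with a warning: no detectable lagged coupling.

Both metrics lie in [0, 1], are symmetric in the channel order, and are
invariant to rescaling either channel. PLI satisfies the exact identity
PLI = |p⁺ − p⁻| with p± the lead/lag sample proportions (ties counted in N).

### Null behaviour and effective sample size

For *independent phase samples*, the signed-lag mean is asymptotically
N(0, 1/N), so null PLI follows a folded normal with mean √(2/(πN)) — the
closed form the test suite checks with phase-iid (circular white) inputs.
Real filtered signals violate the iid assumption: the analytic signal's
one-sided spectrum autocorrelates consecutive phase samples, inflating null
PLI by roughly √(N/N_eff) with N_eff ≈ N·(bandwidth/Nyquist). Measured at
N = 10,000: white noise through the Hilbert transform gives mean null PLI
≈ 0.0099 against the iid value 0.0080; narrow bands (delta at 250 Hz) sit
several times higher. Tests of "filtering creates no spurious phase lags"
therefore use the broadband (1–60 Hz) filter, where the inflation is small,
and narrowband null levels are treated as what they are — a smaller
effective N, not a bias toward any lag direction.

## Preprocessing

* **Filters.** Windowed-sinc (Hamming) linear-phase FIRs, transition width
  25% of the lower band edge (floored at 1 Hz), tap count 3.3·fs/Δf forced
  odd, applied forward–backward (zero net phase; the applied magnitude
  response is squared). Forward–backward application is mandatory here:
  the product of this pipeline is phase, and a causal filter's group delay
  would register as connectivity. Implementation: single FFT convolution
  with the taps' autocorrelation on an odd-reflection-padded series —
  identical to `filtfilt` output but O(N log N), which matters at
  8 bands × 32 channels × cohort scale.
* **Broadband stage.** 1–60 Hz band-pass, then 49–51 Hz band-stop
  (> 40 dB at 50 Hz) against line interference.
* **Bands.** delta 1–4, theta 4–8, alpha 8–12, beta1 12–21, beta2 21–30,
  gamma1 30–40, gamma2 40–50, gamma3 50–60 Hz; each band-limited copy is
  produced by the same zero-phase FIR machinery on the continuous
  (unexcised) series, so excision gaps never pass through a filter.
* **Artifact rejection stand-in.** The emulated workflow removed artifact
  segments by manual inspection plus ICA; as a deterministic, testable
  stand-in, samples where any channel exceeds ±100 µV are excised
  synchronously across channels with a ±200 ms guard window. Surviving runs
  shorter than 10 s are dropped; a subject with no surviving run is
  excluded (the 10-s exclusion rule). Intervals are 0-based half-open.
  Synthetic cohorts are artifact-free by construction, and strongly planted
  sources legitimately exceed a fixed µV threshold, so cohort-level
  experiments disable the stand-in (threshold ∞); it is exercised by
  dedicated tests with planted spikes.
* **Edge trimming.** After the per-segment Hilbert transform, 1 s is
  discarded at each segment end to kill filter/transform transients.
  Per-segment metric values are combined as a duration-weighted mean
  (for gap-free synthetic data this reduces to the single-pass value).

## Synthetic cohort generator

Each subject is 32 channels (10-20 montage) of unit-SD 1/f pink noise
scaled to `noise_sd` (default 10 µV), plus planted couplings, then a
zero-lag mixing matrix:

* **Sources.** Band-pass-filtered Gaussian noise, not sinusoids, so the
  instantaneous phase is nondegenerate. A source occupies the central 60%
  of its band (edges pulled in by 20% of the bandwidth per side): with
  edge-to-edge sources, filter transitions bleed lagged energy into
  adjacent analysis bands, which blurs the planted ground truth across
  bands. Source bandwidth is a testability choice — the emulated study
  does not characterize its participants' spectra.
* **Couplings.** A coupling adds the source to both channels of a pair,
  the second delayed by `phase_lag/(2π f_center)` seconds — a
  frequency-consistent phase offset within the narrow band — and scaled by
  the group's strength (a multiple of `noise_sd`). Lags must avoid 0 and
  ±π, where the metrics are blind by design. The default study-style
  pattern (`study_couplings`) plants frontal delta pairs and
  occipital-weighted gamma pairs, stronger in the IA group.
* **Volume conduction.** A symmetric matrix I + K with K a Gaussian kernel
  of inter-electrode distance (length scale 0.4 head radii), scaled so the
  largest off-diagonal row sum equals `mixing_spread` (default 0.3);
  every channel's own signal stays dominant. Mixing is applied last and is
  strictly zero-lag, so it must raise amplitude correlations but not
  PLI/WPLI.
* **Seeding.** One master seed; per-subject generators derive from
  `SeedSequence([master, subject_index])`, so cohorts are exactly
  reproducible and any subject can be regenerated alone.

What the generator does **not** emulate: realistic forward head modelling,
eye-blink/EMG artifact morphology, heterogeneous per-subject spectra,
nonstationarity. Passing tests therefore demonstrate that the pipeline
recovers the structure this model plants and stays calibrated under this
model's null — not that the same accuracies would be obtained on clinical
recordings.

A caveat discovered while validating recovery: with mixing enabled, the
*delayed* copy of a planted source leaks to neighbouring electrodes, so
"halo" pairs carry genuine lagged, group-different coupling and can outrank
planted pairs in the t-statistic ordering. Exact top-k recovery is
therefore evaluated at `mixing_spread = 0`, where the planted set is the
unambiguous ground truth; under default mixing the planted connections are
still required to be significant, IA-stronger, and in the top 1%.

## Feature selection and classification

* **Screening.** Per-connection two-sample t-test (Student's
  pooled-variance; Welch behind a flag), two-sided, p < 0.05, deliberately
  uncorrected for the 3,968 comparisons — reproducing the screening of the
  emulated pipeline. Constant connections are skipped with a log entry.
  Direction is the sign of t with IA first.
* **Standardization + PCA.** z-score per feature, then PCA retaining the
  smallest component count whose cumulative explained variance ≥ 99%
  (capped at rank; `var_target = 1.0` keeps everything).
* **Leakage modes.** `paper_faithful` fits selection, scaler and PCA on
  all subjects before cross-validation — the literal ordering of the
  reproduced pipeline — and logs a warning; `leak_free` refits all three
  inside each training fold. Both are first-class: the difference between
  them on null data *is* a result (measured here: leak-free ≈ 0.5,
  paper-faithful ≈ 1.0 on 22-subject null cohorts — full-cohort selection
  among 3,968 candidates can separate any labelling of a small sample).
* **Models.** SVM (RBF kernel, C = 1, `gamma='scale'`), random forest
  (100 trees, unlimited depth), kNN (k = 5, Euclidean). The emulated study
  names the model families but no hyperparameters; these are the
  conventional defaults, all exposed on `ModelSpec`.
* **Evaluation.** Stratified shuffled 5-fold CV (fold sizes within one
  subject, class counts within one of proportional), IA as positive class;
  accuracy, sensitivity and specificity from per-fold confusion counts,
  reported as mean ± sd over folds. A zero denominator yields an explicit
  `None` marker. A fold with an empty feature mask predicts the training
  majority and flags the run.

## Demographic statistics

2×2 tables are compared by Pearson chi-square *with* Yates continuity
correction: on the published gender and handedness tables the corrected
statistic reproduces the printed values (0.03, 0.112) and the uncorrected
one does not, so the correction is the default (uncorrected behind a
flag). Age uses a pooled t from the published summary statistics
(means ± SDs; raw ages unavailable), which gives |t| = 0.47 against a
printed 0.48 — attributable to rounding of the printed summaries.

## Problem sizes and numerical choices

Cohort experiments run at 250 Hz × 30 s (desk-scale renderings of the
emulated 1000 Hz × 5 min protocol; both parameters are config-overridable
and the defaults in `SyntheticConfig` are 250 Hz × 60 s). Standard
experiment sizes: null calibration 20+20 subjects (3,968 simultaneous
tests), planted recovery 20 replicate cohorts of 10+10 at strength ratio 3,
null-classification calibration 20 fresh cohorts of 10+12, separable-cohort
classification at the full study size (42 IA + 50 HC, strength ratio 4).
Analytic signals require ≥ 64 samples; filters require series longer than
3× the tap count; PCA ties are irrelevant (components are used, not
interpreted); all randomness flows from explicit seeds and every
experiment is deterministic given its seed.

## Known limitations

* The headline accuracies of the emulated study depend on undeposited
  recordings and unstated hyperparameters; this package checks the
  pipeline's statistical behaviour (calibration, recovery, leakage
  optimism, separability), not those numbers.
* The artifact stand-in is an amplitude threshold, far cruder than manual
  inspection + ICA; it exists to make the exclusion logic testable.
* EDF export is not provided (no EDF writer in the dependency set);
  recordings persist as CSV matrices with a JSON sidecar.
* Single-pass (non-epoched) metric computation is assumed; the
  duration-weighted segment aggregation is this package's generalization
  for gap-containing data, not a documented property of the emulated
  pipeline.
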