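# eegsync

Resting-state EEG phase-synchronization connectivity and cross-validated
group classification, built for studying internet-addiction (IA) versus
healthy-control (HC) cohorts — and for anyone who needs a tested,
ground-truth-calibrated implementation of PLI/WPLI connectivity pipelines.

## The problem and the approach

Coherence-style EEG connectivity measures are confounded by volume
conduction: one cortical source seen by two electrodes produces spurious
zero-lag "synchrony". The phase lag index and its weighted variant discount
zero-lag dependence by construction. With analytic signals
*z(t) = x(t) + i·x̂(t)* (Hilbert transform) and phase difference
Δφ = φ_a − φ_b for a channel pair:

```
PLI  = | ⟨ sign(sin Δφ(t)) ⟩_t |
WPLI = | ⟨ Im{z_a z̄_b} ⟩_t | / ⟨ |Im{z_a z̄_b}| ⟩_t
```

Both lie in [0, 1]; WPLI down-weights near-zero-lag samples whose PLI signs
are noise-driven. The pipeline: zero-phase FIR filtering (1–60 Hz broadband,
49–51 Hz notch, eight analysis bands from delta 1–4 Hz to gamma3 50–60 Hz),
amplitude-threshold artifact excision with a 10-s exclusion rule, per-band
PLI/WPLI over all 496 pairs of a 32-channel montage (3,968 connections per
subject and metric), two-sample-t screening at p < 0.05 (uncorrected),
z-score + PCA (99% cumulative explained variance), and stratified 5-fold
SVM-RBF / random-forest / kNN classification with accuracy, sensitivity and
specificity (IA positive).

Because no participant EEG is publicly available for the emulated study, the
package ships a synthetic cohort generator that plants known phase-lag
couplings (frontal delta, occipital gamma, stronger in IA) under pink noise
and zero-lag volume-conduction mixing — so calibration, recovery and
leakage behaviour are all checkable against ground truth. Two preprocessing
modes are first-class: `paper_faithful` (selection/z-score/PCA fitted on
all subjects before cross-validation, as the reproduced pipeline orders it)
and `leak_free` (fitted per training fold). Their gap on null data is
itself a result: full-cohort selection among 3,968 candidates reaches 100%
apparent accuracy on label-free noise.

## Worked example

```python
import numpy as np
from eegsync import (SyntheticConfig, study_couplings, generate_cohort,
                     connectivity_tensor, select_features, ModelSpec,
                     train_eval)

config = SyntheticConfig(fs=250.0, duration=30.0, seed=20260927,
                         couplings=study_couplings(strength_hc=1.0, ratio=2.0))
recordings, manifest = generate_cohort(config)      # 42 IA + 50 HC
tensors = connectivity_tensor(recordings, metric=("pli", "wpli"),
                              amp_threshold=np.inf)  # synthetic data: no artifacts
labels = np.array([r.group for r in recordings])

mask = select_features(tensors["wpli"], labels, alpha=0.05)
print(len(mask))                                     # 268 of 3968 selected
summary = train_eval(tensors["wpli"], labels, ModelSpec("svm_rbf"),
                     mode="leak_free", seed=7)
print(f"{summary.mean('accuracy'):.3f}")             # 1.000
```

Run as a full analysis (scripts are numbered; each prints its findings and
writes tables under `results/`):

```
python analysis/01_simulate_cohort.py      # cohort + ground-truth manifest
python analysis/02_connectivity_tensors.py # PLI/WPLI tensors, group means
python analysis/03_feature_selection.py    # t-test masks, engagement maps
python analysis/04_classification.py       # 3 models x 2 metrics x 2 modes
python analysis/05_null_calibration.py     # type-I error, leakage optimism
python analysis/06_cohort_stats.py         # demographic group comparisons
```

With the planted frontal-delta / occipital-gamma contrast (IA strength 2×
HC), script 03 reports the selected connections concentrating exactly
there — for WPLI, 268 of 3,968 connections significant, with delta (45) and
gamma1/gamma3 (47/59) dominating and occipital/parietal electrodes (P3, O1,
Oz, POz) the most engaged — and script 04 reports cross-validated
accuracies at or near 1.000 for all three models. Script 05 shows the
screen is calibrated (type-I fraction 0.0499 for PLI at α = 0.05 over 3,968
null connections) and quantifies leakage optimism on null cohorts:

```
null-cohort CV accuracy over 20 replicate cohorts (440 predictions per mode):
  leak_free      : 0.532 (chance band 0.5 ± 0.047)
  paper_faithful : 1.000 <- optimism from selection/z-score/PCA fitted before CV
```

Script 06 recomputes the demographic comparisons from the published counts:
gender χ² = 0.03 (p = 0.863), handedness χ² = 0.112 (p = 0.738), age
|t| = 0.47 (p = 0.642) — none significant, the groups are matched.

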