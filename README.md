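# prestim

Decoding high- vs low-arousal **anticipatory EEG activity** — the brain
state in the second *before* an emotional stimulus arrives — with classical
machine learning, both for whole epochs (static decoding) and as a function
of time inside the epoch (sliding-window, time-resolved decoding).

The package is written for EEG/BCI researchers who want a tested, seeded,
end-to-end reference implementation of this analysis: feature extraction,
discriminability-based feature reduction, cross-validated classification
against a random benchmark, and benchmark statistics — plus a synthetic EEG
generator so the entire pipeline runs and is testable without any recorded
data.

## The analysis

Input is a set of epoched multichannel recordings (epochs × channels ×
samples; reference configuration 128 channels, 250 Hz, 1000 ms epochs) with
a binary arousal label per epoch.

**Features.** Two families, each computed per channel and concatenated:

* *Spectral*: from a Welch periodogram (250-sample Hamming window, 50%
  overlap), log-transformed power is summed in θ = [4, 6) Hz,
  α = [6, 13) Hz and β = [13, 30) Hz, and each channel contributes the pair
  (β/α, θ/β) — 2 × 128 = 256 features. β/α indexes emotional arousal, θ/β
  cognitive arousal.
* *Temporal*: each channel is band-passed to 0.05–10 Hz (zero-phase
  2nd-order Butterworth), decimated to 20 Hz and z-scored over time within
  the epoch, capturing slow anticipatory (CNV-like) deflections —
  20 × 128 = 2560 features.

For time-resolved decoding the epoch is cut into 125 sliding 500 ms
windows shifted by one sample (4 ms), and the same features are extracted
per window (spectral: 16-sample Hamming Welch window zero-padded to 250,
giving 256 features; temporal: 10 points × 128 channels = 1280 features).

**Selection.** Each feature is scored by the squared point-biserial
correlation r² with the class label; features are kept best-first until
they account for 90% of the total score. Per-channel mean r², normalised to
percentages, gives scalp discriminability maps.

**Classification.** LDA (pseudo-inverse covariance), soft-margin RBF SVM
(C = 1), and 1-nearest-neighbour, against a uniform random benchmark —
evaluated by stratified 10-fold cross-validation repeated 10 times, with
selection recomputed inside every training fold (no leakage). The result is
a 10 × 4 matrix of repeat-level mean accuracies, or one accuracy sequence
per classifier over the 125 windows.

**Statistics.** Each classifier's repeat accuracies are compared to the
benchmark's with a right-tailed pooled two-sample t-test (df = 18 for
10 + 10 repeats). Per-segment p-value sequences are Bonferroni–Holm
corrected, and the *best accuracy point* is the left edge of the window
with the highest corrected-significant accuracy.

## Worked example

```python
import numpy as np
from prestim import (GeneratorConfig, TemporalEffect, RunConfig,
                     generate_epochs, run_pipeline)

# 16-channel synthetic set: a -2 z-unit anticipatory ramp from 400 ms
# onward on channels 4-7 of the high-arousal class
cfg = GeneratorConfig(
    n_epochs_per_class=100, n_channels=16, seed=21,
    temporal_effect=TemporalEffect(channels=[4, 5, 6, 7], amplitude=-2.0,
                                   onset_ms=400.0))
epochs = generate_epochs(cfg)

bundle = run_pipeline(RunConfig(mode="static", feature_kind="temporal", seed=21),
                      epochs)

cv = bundle["cv"]
for kind, acc in zip(cv.classifier_kinds, cv.mean_accuracy.mean(axis=0)):
    print(f"{kind:6s} mean accuracy {acc:.3f}")
for kind, t in bundle["tests"].items():
    print(f"{kind:6s} vs RANDOM: t({t.df})={t.t_stat:.2f}, p={t.p_raw:.2e}")
pct = bundle["selection"].channel_percent
print("top channels by r2 percent:", np.argsort(pct)[::-1][:4])
```

Output:

```
LDA    mean accuracy 0.937
SVM    mean accuracy 0.983
KNN    mean accuracy 0.893
RANDOM mean accuracy 0.485
LDA    vs RANDOM: t(18)=42.75, p=7.43e-20
SVM    vs RANDOM: t(18)=47.82, p=1.01e-20
KNN    vs RANDOM: t(18)=38.50, p=4.81e-19
top channels by r2 percent: [7 5 4 6]
```

All three classifiers decode the injected slow deflection far above the
benchmark's 0.485, the t-tests against the benchmark are overwhelming, and
the scalp-score ranking recovers exactly the four channels carrying the
effect.

The same flow is available from a shell:

```bash
prestim generate --n-per-class 100 --n-channels 16 --seed 21 epochs.csv
prestim classify --feature temporal --seed 21 --out-dir run/ epochs.csv
prestim dynamic  --feature temporal --stride 8 --seed 21 --out-dir dynrun/ epochs.csv
prestim report run/
```

Epoch CSVs use one row per epoch-channel (`epoch_id,channel_id,label,s0..`)
preceded by a `# fs=<Hz>` comment line.

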