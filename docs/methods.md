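# Methods

This note records the model assumptions, the defaults that matter, and the
numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pipeline model and assumptions

The analysis treats each labelled epoch as an independent instance of a
binary classification problem (high vs low arousal) and asks two
questions: *is the pre-stimulus EEG decodable at all* (static decoding of
whole 1000 ms epochs), and *when inside the epoch does the information
live* (sliding-window decoding over 125 windows of 500 ms shifted by one
sample). Classes are assumed approximately balanced (the generator enforces
an imbalance within [0.4, 0.6]), which is what justifies plain accuracy as
the evaluation metric.

Cross-validation repeats are treated as independent samples in the
benchmark t-test (pooled variance, df = n₁ + n₂ − 2 = 18 for 10 + 10
repeats). Repeats share the underlying data, so this is an optimistic
assumption; it is the convention of the comparison design this package
implements, and it is documented rather than corrected.

## Feature extraction

* **Band edges.** θ = [4, 6), α = [6, 13), β = [13, 30) Hz, half-open so
  the shared edges at 6 and 13 Hz are counted once. A `closed` convention
  is available as a switch; with 1 Hz resolution it double-counts the
  boundary bins.
* **Log transform.** Natural log of the Welch PSD before band summation,
  compensating the right skew of power. Ratio features divide *sums of
  logs*, so the log base is a genuine convention; it is fixed to `e` and
  recorded here. Note the direction of ratio shifts under a power change
  depends on the sign of the log-power totals — on microvolt-scale EEG they
  are positive (see the generator's amplitude scale below).
* **θ/β orientation.** The second per-channel ratio is θ/β (an inverse
  cognitive-arousal index); `invert_theta_beta=True` yields β/θ. The
  default follows the feature-vector definition this pipeline reproduces.
* **Welch scaling.** One-sided density scaling with Hamming-window power
  correction (division by `fs·Σw²`), no detrending. Any global scaling
  constant cancels in the band ratios; the choice matters only for
  consistency and for the positivity of log totals.
* **Temporal family.** 0.05–10 Hz zero-phase 2nd-order Butterworth, then
  decimation to 20 Hz, then per-epoch, per-channel z-scoring (sample SD,
  ddof = 1). Order of operations: filter at 250 Hz → decimate → z-score.
* **Sliding windows.** Window starts at samples 0…124; the 126th possible
  start (ending exactly at the epoch edge) is dropped so a 1000 ms epoch
  yields exactly 125 windows. Each window is assigned the time of its left
  extreme, (i − 1)/250 s.
* **Dynamic temporal filtering is per-window.** The 0.05 Hz high-pass has
  a time constant (~3 s) far longer than the epoch; filtering the whole
  epoch with a non-causal filter smears a late slow deflection across every
  window (measured: a −3 ramp confined to 750–1000 ms produces values
  ≈ +2 at t = 0 after whole-epoch forward-backward filtering), which would
  defeat the temporal localisation the sliding-window analysis exists for.
  Each 500 ms window is therefore filtered independently.

## Numerical choices

* **Zero-phase filtering** uses Gustafsson's minimum-transient initial
  conditions (`filtfilt(..., method="gust")`). Padding-based
  initialisation is unreliable here: with the 0.05 Hz corner the filter's
  impulse response dwarfs any affordable pad, and measured interior
  artefacts reached half the signal amplitude. With the Gustafsson method
  the measured response matches the closed-form squared Butterworth
  magnitude (e.g. 0.0029 vs 0.0027 at 40 Hz). Note an order-2 band-pass
  with a 10 Hz corner passes 5 Hz at 0.94 after two passes — "passband
  identity" holds only below ~2.7 Hz at the 1% level.
* **Decimation** is rational-ratio polyphase FIR resampling
  (`resample_poly`, Kaiser-windowed anti-alias, `padtype="line"` so
  constants and slow trends survive the short-signal edges). 250 → 20 Hz
  is the ratio 25/2, so integer-factor decimation is not applicable; the
  resampled duration must contain an integer number of output samples.
* **Selection ties.** Features sort by descending r² with stable order
  (ascending original index on ties); the selected prefix is minimal. In
  the CV harness, features that are constant within a training fold score
  r² = 0 rather than raising, since a fold can flatten a feature by chance.
* **Classifier details.** LDA uses the SVD solver (the pseudo-inverse
  route for singular shared covariance) with empirical class priors. The
  SVM bandwidth is the `scale` heuristic γ = 1/(d·Var) — no value is
  prescribed by the design, so the only defensible default is recorded
  here and configurable. kNN uses brute-force search; equidistant
  neighbours resolve to the lowest training index. The random benchmark
  draws uniform labels *inside* the same CV harness so its accuracy
  distribution has the same sampling structure as the real classifiers.
* **Folds.** Stratified, shuffled with a per-repeat seed derived from the
  master seed; everything downstream of one seed is bit-reproducible.
* **Degenerate t-tests.** Zero pooled variance: equal means give p = 0.5,
  unequal means give p ∈ {0, 1} by the sign of the difference.
* **Holm correction** is applied per classifier over its own segment
  sequence; no correction across classifiers or feature families.
* **Best accuracy point** ties resolve to the earliest window.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, not
the biophysics of EEG:

* 1/f^a coloured noise (default a = 1) via spectral shaping of white
  noise, normalised so the background has unit variance before scaling;
* narrow-band oscillations (default: 10 Hz alpha, amplitude 1 background
  SD) with independent uniform phase per epoch and channel;
* a final scale to `rms_amplitude_uv` (default 30 µV background RMS, a
  realistic pre-stimulus EEG magnitude). The scale matters for spectral
  features: with microvolt-scale data the log-power band totals are
  positive, as on recorded EEG, so boosting β power raises the β/α ratio.
  On unit-variance data the totals are negative and the shift direction
  inverts — a property of the ratio-of-log-sums feature itself.
* class effects: a **spectral effect** multiplies the β-band noise
  amplitude of high-arousal epochs on target channels; a **temporal
  effect** adds a linear ramp (CNV-like when negative) from a configurable
  onset to the epoch end, with its peak expressed in background-SD units.
  Channel topography is abstract — "central-parietal" is just an index
  subset, since the analysis uses geometry only for plotting.

What the generator does *not* model: volume conduction and realistic
inter-channel correlation, non-stationary rhythms, artefacts (blinks,
muscle), electrode geometry. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not expected accuracy
levels on recorded EEG — decodability of real anticipatory activity is far
weaker than the injected effects used in the tests.

Defaults follow the reference recording configuration: 128 channels,
250 Hz, 1000 ms epochs, approximately balanced classes. The noise spectrum
of the real recordings is uncharacterised, so the 1/f + alpha background is
a convention chosen once, not an estimate.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale study conditions:

* feature-geometry constants: one 128-channel epoch pair (the reference
  configuration, where the dimensionalities 256 / 2560 / 1280 / 256 and the
  125-window count arise);
* null calibration: five independent effect-free datasets of 400 epochs ×
  8 channels, each under the full 10 × 10-fold protocol; the five-dataset
  mean estimates the expected null accuracy (a single 400-epoch dataset's
  CV mean fluctuates with SD ≈ 0.02, so replication is what makes a ±0.03
  comparison a ≈3σ statement);
* t-test calibration: 10 000 null replicates of 10 + 10 samples;
* effect recovery: 10 channels all carrying a −3 SD ramp, 200 epochs per
  class; localisation: 8 channels (4 targeted, onset 750 ms), 50 epochs per
  class, every 8th of the 125 windows, 5 CV repeats;
* scalp-score contrast: 20 seeds at 8 channels (3 targeted), 30 epochs per
  class;
* leakage check: 40 epochs × 640 features of effect-free data, comparing
  in-fold selection against deliberate full-data selection.

## Known limitations

* The 16-sample dynamic Welch window has a ~15.6 Hz main lobe — wider than
  the θ and α bands — so dynamic spectral features are heavily smoothed
  versions of their static counterparts (measured cross-channel agreement
  r ≈ 0.85, not 1).
* Repeat accuracies are not independent (see above); reported p-values
  against the benchmark are anti-conservative in absolute terms.
* The FIR preprocessing path (0.1–45 Hz windowed sinc for continuous
  recordings) is provided but unused by the synthetic pipeline, which
  starts from already-epoched data; visual artefact rejection, ICA and
  bad-channel reconstruction are manual, data-dependent steps on real
  recordings and are out of scope.
* Only binary classification and the accuracy metric are implemented.
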