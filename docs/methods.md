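# Methods

This note documents the models, numerical choices and limitations behind
`eegfsel`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline

Trials (trials × channels × samples, µV) flow through four stages:
conditioning → feature extraction → feature selection → classification.
Every stage is a pure function of its inputs plus an explicit seed; a single
global seed is fanned out to per-stage child seeds via SHA-256, so whole-run
outputs are bitwise reproducible.

## Synthetic trials

The generator is spectral: each trial is complex-Gaussian noise in the
frequency domain with amplitude ∝ f^(−α/2) (α default 1.0, the canonical
resting-EEG 1/f slope), inverse-transformed to the time domain. Class
effects multiply the spectral *power* inside a band [low, high) on a chosen
channel subset by a factor c, so the expected between-class band-power ratio
on those channels is exactly c — this is what makes the planted-effect
recovery tests sharp (±15 % at 20 trials/class, ±10 % at 50, dominated by
estimator variance alone).

Defaults mirror the reference acquisition conditions the package targets:
60-second trials, 128 Hz, a 32-channel 10–20 montage (a 30-channel online
layout and arbitrary channel counts are equally supported), valence/arousal
ratings on the 1–9 scale drawn uniformly from the half-interval consistent
with each trial's class (threshold 5, boundary on the High side).

Blink artifacts are sums of ~300 ms Gaussian pulses at random times
(≈0.25 s⁻¹), mixed into frontal channels with per-channel coefficients in
[0.4, 0.9] and appended as an explicit `VEOG` channel; the coefficients are
recorded so ocular regression can be verified in closed form.

What the generator does **not** model: event-related potentials,
non-stationarity, inter-channel correlation structure beyond the planted
effects, volume conduction, or realistic artifact zoology. Passing tests
therefore demonstrate algorithmic correctness and statistical behaviour
under a known ground truth — not performance on recorded EEG.

## Conditioning

* **Notch**: second-order IIR notch at 50 Hz, Q = 30, applied zero-phase
  (forward–backward), so the designed magnitude response is squared. The
  design is exported (`notch_coefficients`) for verification.
* **Band-pass**: FIR, default 10th order, 0.1–70 Hz, minimum phase
  (a linear-phase prototype at twice the order is converted
  homomorphically, returning order+1 taps). A 10-tap filter cannot realize
  a 0.1 Hz transition at EEG rates; the default is kept for fidelity to
  common practice, the achieved response is whatever the exported taps say,
  and the order is configurable for users who need a real high-pass.
  Applied causally so that an impulse reproduces the exported taps exactly.
* **Ocular regression**: per trial, every EEG channel is regressed on the
  flagged EOG channels by least squares and the fitted component
  subtracted; residuals are exactly orthogonal to the EOG regressors, and
  an all-zero EOG channel yields zero coefficients (minimum-norm solution).
  Per-trial fitting is the conservative choice — coefficients are allowed
  to drift between trials.
* **Resampling**: polyphase with the rational factor of the rate ratio,
  output truncated to floor(N·target/fs).
* **Normalization**: per-column z-score. Statistics are computed on
  training folds and applied frozen to test folds; zero-variance columns
  map to 0.

## Feature bank

Column order is family-major (`stat | psd | de | rasm | wavelet`), then
channel-major, then band-minor, and is fixed so selected-feature masks are
portable. With C EEG channels and P asymmetry pairs:
F = 6C + 4C + 4C + 4P + 10C = 24C + 4P (796 at C=32, 748 at C=30, P=7).

* Statistics use the population (1/N) standard deviation; the normalized
  difference features are defined as 0 when σ = 0.
* Band power: Welch, Hann window, segment min(256, N), 50 % overlap,
  rectangular bin integration over half-open bands — so band powers over a
  partition of [0, fs/2) sum to the total power.
* Differential entropy: the band is isolated with a 4th-order zero-phase
  Butterworth filter, and h = ½ ln(2πeσ²) evaluated with the natural log
  on the 1/N variance. σ² = 0 reports a −∞ sentinel. The Gaussian closed
  form agrees with numerical integration of −∫p ln p to <1e−3 (tested).
* RASM: ratio of per-band differential entropies for the seven standard
  left/right pairs. The ratio can be negative (a band entropy is negative
  whenever σ² < 1/(2πe)) or undefined at a zero denominator, which reports
  the sentinel; masks may exclude such columns downstream.
* Wavelet: 5-level db4 decomposition with periodized boundaries; inputs
  are zero-padded to a multiple of 2⁵ so the transform is orthogonal and
  detail + approximation energies equal the signal energy to 1e−6 relative
  (property-tested). Entropy is the log-energy form −Σ d² ln d² on
  unnormalized squared coefficients, 0·ln 0 := 0. Detail-level frequency
  edges are derived from the actual sampling rate (at 128 Hz, D1 covers
  32–64 Hz) and embedded in the column names.

## Swarm selector

Positions are initialized uniform in [0, 1], velocities uniform in ±0.1;
velocities are clamped to ±0.4, positions unclamped — selection requires
positions to drift above θ = 0.8, and unclamped positions make large masks
reachable. Decoding is strictly `position > θ`; an all-below particle
degenerates to its argmax feature so fitness is always defined. Fitness is
the stratified inner 3-fold cross-validated error of a linear SVM (C=1) on
the masked columns — cross-validated rather than training error, to avoid
selecting overfit masks. The inner fold assignment is frozen from the seed,
so fitness is a deterministic function of the mask (cached by mask), which
also guarantees the global-best error is monotone non-increasing.

The random stream is consumed in a documented order (init positions, init
velocities, then per iteration and particle R1 and R2), making runs exactly
replayable; an independent straight-line re-implementation of the update
equations reproduces the swarm state to machine precision (tested at F=4,
K=2).

Swarm size defaults to 20 (commonly used; the method is insensitive within
10–50) and the iteration budget to 50, both configurable. Personal/global
bests update on strict improvement only; ties keep the incumbent, for
reproducibility over arbitrary preference. The multi-stage schedule
parameters (w_m, t₁, t₂) of strategies w1–w6 assume t₂ < tmax; shrinking
tmax below t₂ is rejected by validation rather than silently rescaled.

The Relief baseline is the classic all-instances variant: range-normalized
features, one nearest hit and one nearest miss per instance (nearest miss
over all other classes in the multiclass case), per-feature weight
|x − miss| − |x − hit| averaged over instances; top floor(keep·F) features
kept, ties broken by ascending index. No installed library provides classic
Relief, so it is implemented here and cross-checked in the tests against a
brute-force restatement of the definition.

## Evaluation protocol

Stratified k-fold (default 5). Within each outer fold: normalization
statistics fitted on train; selector run on normalized train only (its seed
derived from the outer seed and fold index); linear SVM (C=1, one-vs-one
for the 4-quadrant case) fitted on the masked train; held-out fold scored
with frozen statistics and mask. Leak-freedom is asserted in tests by
corrupting a test fold's rows and checking its mask is unchanged.

The strategy-comparison harness runs one selection per fold at
tmax = max(budgets) and snapshots the global-best mask at each budget, so
budget columns share identical random streams and differences reflect only
the extra iterations.

Quadrant labels: 1=HAHV, 2=HALV, 3=LAHV, 4=LALV, thresholding arousal and
valence at 5 with ≥ on the High side; binary labels are ±1 on valence.

## Problem sizes in the shipped tests

The planted-recovery suite uses 60 trials × 100 columns with 5 informative
columns at a unit mean shift, 10 seeds for the mask-recall sign test and 3
seeds for the selection-vs-no-selection comparison; generator-oracle tests
use 4–50 trials/class at 1–10 s per trial. These sizes were chosen so each
statistical check has clear resolution while the whole suite stays fast to
iterate on.

## Known limitations

* EDF export is a deliberately minimal 16-bit writer (one data record per
  trial, single physical range across channels); reading uses `mne` and
  accepts arbitrary EDF.
* The fraction of features a swarm selects at θ = 0.8 depends on the
  position-domain conventions above; with optimization pressure the final
  masks here are often much sparser than half the bank.
* Accuracy figures on synthetic data say nothing about recorded-EEG
  accuracy; they are ordering checks (selection ≥ no selection, informative
  recall ≫ chance) under a known ground truth.
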