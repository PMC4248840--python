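# Methods

## Problem and scope

The package studies binary operator-workload classification from free-running
scalp EEG in a passive brain–computer-interface setting, with emphasis on
*temporal* performance: how quickly a classifier trained on little data
degrades as the gap between training and use grows, and whether test-time
noise injection (a stochastic-resonance probe) changes that. Real competition
recordings are not assumed obtainable, so every experiment runs on a synthetic
study whose structure mirrors the target design: 8 subjects, 5 days, 3
sessions/day, 15-minute sessions at 256 Hz on 19 EEG + 2 EOG channels, with
5 minutes per workload state separated by ≥ 1-minute transitions.

## Signal model

Each channel is a sum of

1. **Background**: Gaussian noise with power spectral density ∝ 1/f^k
   (default k = 1), shaped in the frequency domain and normalised to a target
   RMS (default 31 μV). A one-pole high-pass with 0.5 Hz corner
   (`background_highpass_hz`) models the AC coupling of EEG amplifiers.
   This corner matters beyond realism: without it roughly half of the 1/f
   power lies below 0.5 Hz in a handful of realisation-specific Fourier
   modes, the 0–4 Hz band-power feature acquires a large per-session random
   offset, and sessions stop being exchangeable — "zero-drift" studies would
   then degrade across sessions for reasons unrelated to drift.
2. **Oscillatory components**: unit-RMS band-limited Gaussian noise
   (4th-order zero-phase Butterworth band-pass), one shared time series per
   component mixed into channels by a topography weight matrix. Defaults:
   theta (4–7 Hz, 6 μV, frontally weighted) with workload gain 1.6 and alpha
   (7–12 Hz, 10 μV, posteriorly weighted) with gain 0.7 — theta rises and
   alpha falls under high load, the classic vigilance signature. Gains
   multiply the component RMS inside high blocks, are 1 in low blocks, and
   ramp linearly across transitions (transition epochs are discarded
   downstream anyway).
3. **Blinks** (optional, default rate 0.05 Hz, 75 μV): smooth ~0.5 s
   transients carried at weight 1 on EOG channels and 0.1 on EEG channels.

Amplitudes are calibrated by whole-session sample RMS, so stated RMS values
are exact per realisation. The background default of 31 μV places the
correlation study in the regime where 15 μVrms of added noise gives
r = 1/√(1 + 15²/31²) ≈ 0.90, the wet-vs-dry electrode territory the noise
levels are compared against.

### Temporal drift

Component amplitudes follow a per-subject multiplicative log-normal random
walk: one step per new session (sd 0.08), a larger step per new day (sd 0.2),
plus a linear within-session RMS trend (fraction 0.05). All-zero drift
reproduces a stationary study. The step sizes were calibrated once so the
degradation is *graded*: with much larger steps cross-session accuracy
collapses to chance at every scale and the scales become indistinguishable,
which misrepresents the phenomenon the mechanism exists to emulate
(stabilisation over the time frame of hours). Measured over 10 single-subject
replicate studies the pooled accuracies are approximately 0.93 (same-session),
0.91 (minutes), 0.88 (hours), 0.80 (days) with drift, and flat (≈ 0.95 at
every scale) without.

## Features

Within each contiguous high/low block, 30 s epochs advance every 5 s (no
epoch straddles a block boundary). Per epoch and channel the spectrum is the
average of the magnitude-squared 1024-point FFTs of the seven consecutive
non-overlapping segments (rectangular window, no detrending; remainder
samples discarded), summed over the seven bands with half-open [low, high)
edges and the Nyquist bin assigned to the last band — so band powers exactly
partition the mean power (Parseval) and carry μV² units. Features are
absolute band powers; z-normalization (fitted on training rows only, never on
test data) absorbs scale. 21 channels × 7 bands = 147 features; EOG channels
are deliberately included as feature channels, which is what the count 147
forces.

## Classifier

A feedforward network with five hidden layers ("five hidden layers" is taken
literally; widths default to 10 and are configurable, so the "five hidden
units" reading is also expressible), tanh activations and a 2-way softmax
trained on cross-entropy by scaled conjugate gradient (Møller 1993),
implemented in-package since no installed library provides SCG. Training
uses a class-stratified random 50/50 split of the training vectors into
update and validation sets, early stopping after 8 validation evaluations
without improvement (max 300 iterations), and 10 random restarts with the
best validation loss winning. Everything is deterministic given the seed.
Prediction is the argmax of the two outputs; exact ties go to *high*,
consistent with the ensemble tie rule. Training rejects single-class inputs
and classes with fewer than 10 vectors.

## Noise ensemble

Test-time noise is zero-mean white Gaussian, independent per channel and
sample, specified by its RMS in μV (bandwidth = Nyquist, 128 Hz at 256 Hz
sampling); it is added to all 21 channels, EOG included, since EOG feeds the
feature vector. The ensemble repeats classification over 10 independent
noise realisations of the *raw* recording (training is always noise-free)
and takes a per-epoch majority vote, ties to high. Member seeds derive from
the ensemble master seed plus the session identity, so different sessions
get independent noise while runs remain reproducible. With 0 μVrms the
ensemble is exactly the single network.

The correlation study adds one noise realisation to a designated channel
(default the first), partitions the recording into consecutive
non-overlapping sections per requested length, and reports min/median/max
Pearson correlation between the clean and corrupted trace. Short sections
systematically underestimate the long-run correlation and inflate its spread.

## Protocols and statistics

* **Same-session**: the first 20 epochs (125 s) of each class's block train
  the network; 11-epoch (80 s) windows sliding by 1 epoch over the remaining
  epochs of each class stream are scored and indexed by the gap between the
  window centre and the end of that class's training data; class streams are
  pooled per gap. Window accuracies are summarised as mean and mean absolute
  deviation.
* **Cross-session**: the same per-session networks are reused prospectively —
  first → second session of a day (minutes), first → last session of a day
  (hours), very first session → every later session (days). All epochs of
  the test session are test data; causality (positive time gap) is asserted
  structurally. Session starts are spaced 30 minutes apart within a day and
  days 24 h apart.
* **Leave-one-out**: per subject, train on all sessions but one (all their
  epochs), test on the held-out session.
* **Pooling**: per-session accuracies are averaged within subject first,
  then across subjects.
* **Chance level**: the classifier output is replaced by a fair coin
  (p = 0.5 regardless of class balance) and analysed identically, 1000 runs;
  the mean converges to 50.0% with standard error 0.5/√(runs × epochs).
* **Noise-run statistics**: the probability that all n independent noise
  runs beat the no-noise baseline under Binomial(n, 0.5) is p^n
  (9.766 × 10⁻⁴ for n = 10); the exact Clopper–Pearson two-sided lower bound
  for k successes in n trials is the α/2 beta quantile, equal to
  (α/2)^(1/n) at k = n (0.69 for 10/10 at 95%).

## Numerical and design choices

* How the 1024-point FFT applies to 7680-sample epochs is decided as
  averaged non-overlapping segment periodograms with a rectangular window —
  the simplest consistent reading; the choice lives in `EpochingConfig` and
  run metadata.
* Label intervals are half-open [start, end); all times are seconds from
  session start, all amplitudes μV.
* The chance resampler, drift walk, per-subject seeds, restart seeds and
  ensemble member seeds all derive from explicit seeds via
  `numpy.random.SeedSequence`; identical inputs give bit-identical outputs.
* EDF I/O is a minimal continuous 16-bit implementation (1 s records, no
  annotations, physical dimensions restricted to the volt family); round
  trips are exact to the 16-bit quantisation step and are cross-checked
  against an independent reader in the tests. The internal `.npz` container
  is lossless.
* The test-window step defaults to 1 epoch (5 s), the finest choice; the
  sliding-window pooling convention (per class stream, pooled by gap) is a
  config option.

## What the synthetic data does and does not show

The generator reproduces the *structure* that the analysis depends on —
band-power contrasts with a known ground truth, session/day nonstationarity,
ocular artifacts in the right channels, exact determinism — so passing tests
demonstrate that the pipeline measures what it claims (epoch arithmetic,
attenuation laws, chance level, degradation ordering). It does not model
cortical sources, volume conduction, realistic artifact taxonomies, electrode
impedance changes, or the feature correlations of real EEG; absolute accuracy
figures on synthetic studies therefore say nothing about accuracies on real
recordings, and the real-data headline numbers of the motivating experiment
are out of scope by design. Problem sizes in the test suite (single-subject
replicate studies, 10 replicates per property, reduced 2 × 2 × 3 smoke study)
are the package's choice of desk-scale defaults; the full 8-subject default
is exercised structurally (plans, chance level) rather than by brute
simulation.

## Known limitations

* The stochastic-resonance *benefit* is not guaranteed on synthetic studies:
  added noise shifts every band power upward, and with aggressive drift the
  ensemble can lose accuracy rather than gain it. The machinery (ensemble,
  run comparison, binomial bounds) is fully testable either way.
* "Five hidden layers" of 10 units on 40 training vectors is heavily
  over-parameterised; early stopping and restarts keep it trainable, but
  the architecture is honoured rather than recommended.
* EDF export requires whole-second recordings and integer sampling rates.
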