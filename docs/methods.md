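# Methods

This note documents the models, parameters and numerical choices behind
`apnea_acoustics`, and what the shipped synthetic experiments do and do not
demonstrate.

## Epoch labeling

A recording is divided into half-open 30-second epochs `[30k, 30(k+1))`; a
trailing partial segment is dropped. Only obstructive apneas and hypopneas
count; central and mixed apneas and unrecognized types are excluded before
labeling. Per epoch, overlap seconds are accumulated per event type (multiple
events of one type are summed) and the label is the type with the larger
*within-epoch* overlap; an exact tie goes to apnea, the more severe class.
A config switch (`compare="total_duration"`) instead compares the total
durations of the overlapping events, for the reading in which "longer event"
refers to whole-event duration. Wake periods are not excluded — the epoch
grid covers the entire recording.

The labeler is verified against a brute-force oracle that rasterizes time at
0.01 s and sums per-type occupancy per epoch; agreement is exact on randomly
generated layouts whose onsets/durations lie on the 0.01-s lattice.

## Audio features

Audio is mono float at a configurable rate (16 kHz default; the shipped
experiments use 8 kHz, which comfortably covers the synthetic breathing band).
Each epoch becomes a log-Mel spectrogram: Hann window (50 ms default, 64 ms
in the experiment configs), hop half the window, power spectrum, triangular
Mel filterbank between `fmin` = 30 Hz and Nyquist, `log(power + 1e-10)`.
All-zero audio therefore maps to the finite floor `log(1e-10)`.

The detector does not consume raw spectrogram frames. Each epoch is pooled
per Mel bin into three temporal statistics — mean, standard deviation and the
10th percentile over frames. The mean captures sustained band energy
(breathing level, stationary noise), the standard deviation captures
transient structure (recovery gasps, bursty noise), and the low percentile
estimates the between-breath noise floor, letting later layers reference
burst energy against the background. This pooling is the first, fixed stage
of the feature extractor; it reduces a 30-s epoch to `3 × mel_bins` numbers
and makes whole-night training tractable on one CPU.

## Detector

The architecture contract is a per-epoch feature extractor followed by a
multiepoch stage. The realization here is a small, fully deterministic numpy
network with explicit backpropagation:

- input standardization by training-set feature mean/SD, **clipped at ±5 SD**
  (`DetectorConfig.input_clip`). Heavily corrupted audio otherwise produces
  features hundreds of SDs outside the clean distribution, which destabilizes
  any gradient that flows through the corrupted branch;
- extractor: two ReLU layers shared across epochs (hidden sizes 32/64/128 for
  the `tiny`/`small`/`large` presets);
- multiepoch stage: a valid convolution along the epoch axis whose kernel
  (input − output + 1 = 5 epochs) trims 14 input epochs to the middle 10,
  ReLU, then a linear 3-class layer with softmax;
- an auxiliary per-epoch linear head used only by the 1-to-1 pretraining
  stage.

A night is covered by stride-10 windows with two context epochs replicated at
the edges; when the night length is not a multiple of 10 the last window is
shifted left and its predictions win on the overlap, so every epoch receives
exactly one prediction. Prediction for epoch *t* needs only epochs ≤ *t* + 2
(the window lookahead), which is what makes the detector streamable in
principle; this is documented, not enforced.

Gradients of the full loss are spot-checked against central finite
differences (relative tolerance 1e-3) in the test suite.

## Training

Two steps, plain SGD throughout, 10 training epochs each:

1. **1-to-1 pretraining** of extractor + per-epoch head with class-weighted
   cross-entropy (weights 1.0 / 1.3 / 2.1 for no-event / apnea / hypopnea),
   initial LR 0.01, divided by 10 whenever validation macro F1 has not
   improved for 3 consecutive epochs.
2. **14-to-10 training** starting from the pretrained extractor, slanted
   triangular LR (peak 0.1, warmup fraction 0.1, cut ratio 32) and gradual
   unfreezing (detector stage first, then one extractor layer per training
   epoch). Batch size 4 windows: the scaled synthetic runs have on the order
   of 100 windows, and larger batches leave too few SGD steps per epoch to
   train at all.

With consistency weight λ > 0 each window is also corrupted: noise clips are
drawn with replacement from the training split of the library, concatenated
until they cover the 7-minute window, truncated, scaled to a single random
SNR drawn uniformly from [−20, 5] dB (SNR is defined on the mean squared
amplitude of the full window; one global gain, no frame-wise tracking) and
added in the waveform domain. The loss is the weighted cross-entropy of the
clean branch plus λ × the mean squared difference between the clean and
corrupted probability outputs (λ = 1 by default, i.e. a plain summation of
the two terms).

Two choices here were genuinely open and are resolved as follows:

- **Stop-gradient on the clean branch** (default): the consistency term
  backpropagates only through the corrupted branch, so the clean branch acts
  as a teacher shaped by the supervised term alone. Letting the MSE flow
  through both branches gives the optimizer a shortcut — dragging the clean
  predictions toward the class prior — which measurably collapses clean
  accuracy as λ grows. Configurable via `consistency_through_clean`.
- **Checkpoint selection**: the best checkpoint is the one with the highest
  validation macro F1. For consistency training the validation set consists
  of the clean validation nights plus noise-corrupted copies at SNRs
  {5, −5, −15} dB built from training-split noise, mirroring the
  simulated-home distribution the model is trained for. The control model
  (λ = 0) keeps clean-only validation and reduces exactly to supervised
  training on clean audio — its loss trajectory is bit-identical whether or
  not a noise library is supplied.

Pitch-shift augmentation is implemented (phase-vocoder time stretch plus
resampling; a pure tone moves by 2^(semitones/12) and duration is preserved)
but **off by default**: on the synthetic breathing signal — noise bursts
under an envelope — vocoder artifacts shift the pooled features by about 2.5
training-set SDs, which at the scale of these experiments acts as
distribution-breaking corruption of the supervised branch and measurably
degrades training. It can be re-enabled via `pitch_shift_prob` /
`pitch_shift_semitones`.

## AHI estimation

Events split across epochs and short events sharing an epoch make the
apneic-epoch count a biased event counter, so the apneic-epoch rate (epochs
called apnea or hypopnea per *recording* hour — total sleep time is not
modeled) is mapped to AHI by a linear fit robust to outlier nights: RANSAC
with minimal subsets of 2, up to 1000 trials, residual threshold equal to
the median absolute deviation of a preliminary least-squares fit (floored at
a tiny positive value so noiseless data is recovered exactly), refit on the
consensus inliers, seeded. Estimates are floored at 0 events/hour. Severity
uses the standard cutoffs with boundaries rounding up: AHI < 5 normal,
5 ≤ AHI < 15 mild, 15 ≤ AHI < 30 moderate, ≥ 30 severe.

## Evaluation

Epoch metrics come from the confusion matrix (rows = reference): accuracy,
unweighted macro F1 (a class absent from both reference and prediction
scores 0 with a warning), Cohen κ, and one-vs-rest sensitivity/specificity.
The 2-class view merges apnea and hypopnea. Screening at a cutoff binarizes
the reference AHI and reports sensitivity/specificity of the binarized
estimate plus AUC with the continuous estimate as score (midrank ties).
Bland–Altman agreement reports the mean difference (estimate − reference),
limits of agreement at ±1.96 sample SD, MAE, and the Pearson correlation —
NaN with a warning when a vector has zero variance, never silently 0.

## Synthetic data

The generator encodes the acoustic phenomenology the detector relies on, not
respiratory physiology:

- **breathing**: band-passed Gaussian noise (300–2000 Hz) under raised-cosine
  bursts (1.2 s) at 14 breaths/min with ~8% timing and ~15% amplitude
  jitter, plus a low sensor floor;
- **apnea**: breath bursts silenced for the event duration, then a single
  1-s, wider-band recovery gasp at 3× the base amplitude;
- **hypopnea**: bursts attenuated to ~35% with extra per-breath amplitude
  irregularity;
- events are placed by rejection sampling, non-overlapping with a ≥10-s gap,
  durations uniform on [10, 60] s; the reference AHI equals the placed event
  count per hour by construction;
- **noise**: nine categories stand in for the home-noise groups via distinct
  spectral bands, either stationary (filtered noise, e.g. fan 40–400 Hz) or
  event-driven (sparse band-limited transients, e.g. clock ticks, speech-like
  syllable bursts). The mapping is structural, not claimed acoustically
  faithful. Train/test splits are disjoint by clip.

Synthetic cohorts span the severity strata (18% / 32% / 32% / 18% across
AHI < 5, 5–15, 15–30, ≥ 30 by largest-remainder apportionment), with per-night
AHI drawn uniformly inside each stratum (severe capped at 55 events/hour so
non-overlapping placement stays feasible).

What passing these experiments shows: the pipeline is internally consistent,
the detector can learn the generator's class signatures from labeled audio,
consistency training confers measurable noise robustness relative to an
identically trained clean-only control, and AHI recovery through the robust
fit tracks the generated truth. What it does not show: performance on real
breathing sounds — real snoring, position changes, co-sleepers, room
acoustics, sensor variety and hypopnea subtlety are all absent from the
generator, and the clinical numbers of the original study are out of reach
by design.

## Problem sizes of the shipped experiments

Chosen once for the package's standard runs: the learnability experiment
uses 20 one-hour nights at 8 kHz (13 train / 2 validation / 5 test); the
robustness comparison uses 26 half-hour nights (18 / 2 / 6) with a noise
library of 9 categories × 6 clips × 60 s, three training seeds on one
cohort, and a paired SNR sweep (clean, then 5 → −30 dB in 5-dB steps) in
which every model sees identical corrupted test features.

## Known limitations

- The feature pooling discards within-epoch timing beyond second-order and
  floor statistics; events shorter than ~10 s of acoustic consequence would
  be invisible.
- The numpy network is intentionally small; the `large` preset mirrors
  the 14→10 interface, not the original model's capacity.
- SNR is a whole-window quantity; perceptual loudness and room acoustics are
  not modeled.
- AHI normalizes by recording time, not sleep time, so it underestimates AHI
  for recordings with long wake periods.
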