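# apnea-acoustics

Detect obstructive sleep apnea (OSA) events from overnight breathing-sound
recordings, keep the detector working in a noisy home, and turn its per-epoch
calls into an apnea–hypopnea index (AHI).

The package is aimed at researchers prototyping contactless, audio-based
sleep-apnea screening: it provides the full pipeline — respiratory-event
annotation parsing and 30-second epoch labeling, log-Mel features, a windowed
3-class detector, home-noise consistency training, robust AHI regression,
and the evaluation/screening statistics of the field — together with a
seeded synthetic-data generator so that every stage is testable without any
clinical recordings.

## The method

A night is scored on 30-second epochs. Each epoch gets one of three classes:
`no_event`, `apnea` (obstructive; acoustically a breathing cessation followed
by a loud recovery gasp) or `hypopnea` (attenuated, irregular breathing).
When two event types overlap one epoch, the type with the longer within-epoch
overlap wins. Central and mixed apneas are excluded.

The detector consumes a sliding window of 14 consecutive epoch spectrograms
and emits class probabilities for the middle 10 (2 context epochs per side).
It has two parts: a per-epoch feature extractor shared across epochs, and a
multiepoch stage that classifies each epoch from its neighborhood.
Training is class-weighted (1.0 / 1.3 / 2.1 for no-event / apnea / hypopnea)
and proceeds in two steps: 1-to-1 pretraining of the per-epoch classifier
(initial LR 0.01, divided by 10 after 3 stagnant validation epochs), then
14-to-10 training for 10 epochs of SGD with a slanted triangular LR and
gradual unfreezing.

Noise robustness comes from *consistency training*: each training window is
additionally corrupted by a cover of concatenated noise clips scaled to a
random SNR in [−20, 5] dB, and the loss

    L = CE_w(clean prediction, labels) + λ · MSE(clean prediction, corrupted prediction)

pushes the corrupted prediction toward the clean one. A *control* model
(λ = 0) trains on clean audio only.

The overnight AHI is estimated from the apneic-epoch rate (epochs called
apnea/hypopnea per recording hour) through a RANSAC linear fit against
reference AHI, then thresholded at 5 / 15 / 30 events/hour for severity
screening.

## Worked example

```python
import numpy as np
from apnea_acoustics import (FeatureConfig, label_night,
                             night_mel_spectrograms)
from apnea_acoustics.audio_features import pool_night_features
from apnea_acoustics.synthetic import SyntheticNightSpec, generate_night

spec = SyntheticNightSpec(duration_hours=0.5, target_event_rate=20,
                          rng_seed=1)
audio, events, reference_ahi = generate_night(spec, sample_rate=8000)
night = label_night(events, audio.duration, reference_ahi=reference_ahi)
labels = np.array([int(l) for l in night.labels])
print(f"epochs: {labels.size}, class counts: {np.bincount(labels, minlength=3)}")
print(f"reference AHI: {reference_ahi:.1f} events/hour")
```

prints

```
epochs: 60, class counts: [41 10  9]
reference AHI: 20.0 events/hour
```

— a half-hour night of 60 epochs, 10 of them apneic and 9 hypopneic, with
the generated event rate equal to the reference AHI by construction.

The same objects drive the CLI:

```bash
apnea-acoustics simulate cohort --n 8 --seed 7 --hours 0.5 --out data/
apnea-acoustics simulate noise --seed 7 --out noise/
apnea-acoustics train --manifest data/manifest.csv \
    --noise-manifest noise/noise_manifest.csv --out model.ckpt.npz
apnea-acoustics predict --audio data/S000.wav --checkpoint model.ckpt.npz \
    --out predictions.csv
apnea-acoustics evaluate --predictions predictions.csv --labels labels.csv \
    --out metrics.json
```

`experiment snr-sweep`, `experiment noise-matrix` and
`experiment noise-fraction` reproduce the robustness study designs at
reduced scale on synthetic data.

## Scope

The clinical datasets behind the original study (PSG and smartphone audio)
are not distributed and their headline numbers are not reproducible here;
all shipped experiments run on the synthetic generator and demonstrate the
pipeline's properties and qualitative trends. See `docs/methods.md` for the
model details, parameter choices and known limitations.
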