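"""Audio loading, epoch segmentation, log-Mel spectrograms and detector windows.

The detector consumes 14 consecutive epoch spectrograms and emits predictions
for the middle 10, so a night is cut into stride-10 windows with 2 context
epochs replicated at the recording edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

from .annotations import EpochGrid


@dataclass
class AudioSignal:
    """Mono audio samples (float) at a fixed sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D)")
        if self.samples.size < 1:
            raise ValueError("AudioSignal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal amplitudes must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class FeatureConfig:
    """Log-Mel spectrogram parameters.

    50 ms windows with 25 ms hop resolve individual breath bursts within a
    30 s epoch; 64 Mel bins up to Nyquist cover the breathing band.  The log
    floor ``log_epsilon`` keeps silent epochs finite.
    """

    sample_rate: int = 16_000
    mel_bins: int = 64
    window_sec: float = 0.050
    hop_sec: float = 0.025
    fmin: float = 30.0
    fmax: float | None = None  # defaults to Nyquist
    log_epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if self.fmax is None:
            self.fmax = self.sample_rate / 2
        if not (0 <= self.fmin < self.fmax <= self.sample_rate / 2):
            raise ValueError("need 0 <= fmin < fmax <= Nyquist")

    @property
    def n_fft(self) -> int:
        return int(round(self.window_sec * self.sample_rate))

    @property
    def hop(self) -> int:
        return int(round(self.hop_sec * self.sample_rate))


@dataclass
class MelSpectrogram:
    """Log-scaled Mel energies, shape (mel_bins, frames)."""

    values: np.ndarray
    mel_bins: int
    frame_hop: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape[0] != self.mel_bins:
            raise ValueError("values row count must equal mel_bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Mel energies must be finite")


@dataclass
class MelWindow:
    """One detector input: 14 epoch spectrograms, predictions for the middle 10.

    ``input_epoch_indices`` are the absolute epoch indices the 14 members were
    taken from (edge epochs replicated past the recording ends);
    ``center_epoch_indices`` are the 10 absolute indices the detector's
    outputs belong to.
    """

    epochs: list[MelSpectrogram]
    input_epoch_indices: np.ndarray
    center_epoch_indices: np.ndarray


def load_audio(path: str | Path, target_rate: int) -> AudioSignal:
    """Read a WAV file as mono float audio resampled to ``target_rate``.

    Integer PCM is scaled to [-1, 1]; multichannel audio is averaged across
    channels.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"empty WAV file {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        data = resample_poly(data, target_rate // g, rate // g)
    return AudioSignal(samples=data, sample_rate=int(target_rate))


def save_audio(signal: AudioSignal, path: str | Path) -> None:
    wavfile.write(Path(path), signal.sample_rate,
                  signal.samples.astype(np.float32))


def segment_epochs(signal: AudioSignal, grid: EpochGrid | None = None
                   ) -> list[AudioSignal]:
    """Cut a night into 30 s epoch signals; a trailing partial epoch is dropped."""
    if grid is None:
        grid = EpochGrid(signal.duration)
    n = int(round(grid.epoch_length * signal.sample_rate))
    k = min(grid.n_epochs, signal.samples.size // n)
    return [AudioSignal(signal.samples[i * n:(i + 1) * n], signal.sample_rate)
            for i in range(k)]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(config: FeatureConfig) -> np.ndarray:
    """Triangular Mel filterbank, shape (mel_bins, n_fft//2 + 1).

    Filter centers are equally spaced on the Mel scale between ``fmin`` and
    ``fmax``; each triangle peaks at 1 at its center and reaches zero at the
    neighboring centers.
    """
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, config.sample_rate / 2, n_bins)
    mel_pts = np.linspace(hz_to_mel(config.fmin), hz_to_mel(config.fmax),
                          config.mel_bins + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((config.mel_bins, n_bins))
    for m in range(config.mel_bins):
        lo, center, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(center - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_bin_center_hz(config: FeatureConfig, m: int) -> float:
    """Center frequency (Hz) of Mel bin ``m`` under this configuration."""
    mel_pts = np.linspace(hz_to_mel(config.fmin), hz_to_mel(config.fmax),
                          config.mel_bins + 2)
    return float(mel_to_hz(mel_pts[m + 1]))


def _power_frames(x: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Power spectrogram frames, shape (n_fft//2+1, frames)."""
    w, h = config.n_fft, config.hop
    if x.size < w:
        raise ValueError("segment shorter than one analysis window")
    n_frames = 1 + (x.size - w) // h
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    frames = x[idx] * get_window("hann", w, fftbins=True)[None, :]
    spec = np.fft.rfft(frames, axis=1)
    return (spec.real ** 2 + spec.imag ** 2).T


def mel_spectrogram(segment: AudioSignal, config: FeatureConfig) -> MelSpectrogram:
    """Log-Mel spectrogram of one 30 s epoch (deterministic for fixed input)."""
    if segment.sample_rate != config.sample_rate:
        raise ValueError("segment sample rate does not match feature config")
    power = _power_frames(np.asarray(segment.samples, dtype=np.float64), config)
    mel = mel_filterbank(config) @ power
    return MelSpectrogram(values=np.log(mel + config.log_epsilon),
                          mel_bins=config.mel_bins, frame_hop=config.hop_sec)


def night_mel_spectrograms(signal: AudioSignal, config: FeatureConfig
                           ) -> list[MelSpectrogram]:
    return [mel_spectrogram(seg, config) for seg in segment_epochs(signal)]


@dataclass(frozen=True)
class WindowLayout:
    """Index bookkeeping for one detector window (no feature payload)."""

    input_epoch_indices: np.ndarray
    center_epoch_indices: np.ndarray


def window_layouts(n_epochs: int, input_epochs: int = 14,
                   output_epochs: int = 10) -> list[WindowLayout]:
    """Stride-``output_epochs`` window index layouts covering a night.

    Context epochs past either end replicate the terminal epoch.  When the
    night length is not a multiple of the stride, the final window is shifted
    left so its outputs end at the last epoch; its predictions take precedence
    on the overlap.  Nights shorter than ``output_epochs`` produce a single
    window whose trailing output slots repeat the last epoch.
    """
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    if (input_epochs - output_epochs) % 2:
        raise ValueError("input_epochs - output_epochs must be even")
    context = (input_epochs - output_epochs) // 2
    starts = list(range(0, max(n_epochs - output_epochs, 0) + 1, output_epochs))
    if starts[-1] + output_epochs < n_epochs:
        starts.append(n_epochs - output_epochs)
    layouts = []
    for s in starts:
        centers = np.clip(np.arange(s, s + output_epochs), 0, n_epochs - 1)
        inputs = np.clip(np.arange(s - context, s - context + input_epochs),
                         0, n_epochs - 1)
        layouts.append(WindowLayout(inputs, centers))
    return layouts


def make_windows(night: list[MelSpectrogram], input_epochs: int = 14,
                 output_epochs: int = 10) -> list[MelWindow]:
    """Build the detector's sliding windows for a whole night of spectrograms."""
    layouts = window_layouts(len(night), input_epochs, output_epochs)
    return [MelWindow(epochs=[night[i] for i in lay.input_epoch_indices],
                      input_epoch_indices=lay.input_epoch_indices,
                      center_epoch_indices=lay.center_epoch_indices)
            for lay in layouts]


def pool_epoch_features(mel: MelSpectrogram) -> np.ndarray:
    """Summarize one epoch spectrogram per Mel bin: temporal mean, std and
    10th percentile over frames.

    The mean captures sustained energy per band (breathing level, stationary
    noise); the std captures transient structure (recovery gasps, burst-like
    noise); the low percentile estimates the per-band noise floor between
    breaths, which lets downstream layers reference burst energy against the
    background.  Output length is ``3 * mel_bins``.
    """
    v = mel.values
    return np.concatenate([v.mean(axis=1), v.std(axis=1),
                           np.percentile(v, 10, axis=1)])


def pool_night_features(night: list[MelSpectrogram]) -> np.ndarray:
    """Pooled features for every epoch of a night, shape (n_epochs, 2*mel_bins)."""
    return np.stack([pool_epoch_features(m) for m in night])
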