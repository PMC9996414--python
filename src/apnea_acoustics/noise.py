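"""Noise corruption at controlled SNR, noise libraries, and pitch shifting.

Corruption is additive in the waveform domain: a cover of concatenated noise
clips is scaled so that 10*log10(P_signal / P_noise) equals the requested SNR
and added to the clean signal.  Training draws the SNR uniformly from
[-20, 5] dB; evaluation sweeps a wider grid down to -30 dB.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window, resample_poly

from .audio_features import AudioSignal, load_audio

#: The nine home-noise categories.
NOISE_CATEGORIES = (
    "home_appliance",
    "room_noise",
    "contents",
    "clock",
    "speech",
    "animal",
    "air_conditioner_fan",
    "rain_wind",
    "car_motorbike",
)

TRAIN_SNR_RANGE = (-20.0, 5.0)


@dataclass
class NoiseClip:
    audio: AudioSignal
    category: str
    split: str = "train"  # train | test
    kind: str | None = None  # stationary | event_driven (when known)

    def __post_init__(self) -> None:
        if self.category not in NOISE_CATEGORIES:
            raise ValueError(f"unknown noise category {self.category!r}")
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be train or test, got {self.split!r}")


@dataclass
class NoiseLibrary:
    clips: list[NoiseClip]

    def subset(self, split: str | None = None,
               categories: Sequence[str] | None = None) -> list[NoiseClip]:
        out = self.clips
        if split is not None:
            out = [c for c in out if c.split == split]
        if categories is not None:
            cats = set(categories)
            out = [c for c in out if c.category in cats]
        return out


@dataclass
class CorruptionSpec:
    """How to corrupt one window: target SNR, eligible categories, RNG seed."""

    snr_db: float
    categories: tuple[str, ...] = NOISE_CATEGORIES
    rng_seed: int = 0
    split: str = "train"

    def __post_init__(self) -> None:
        if len(self.categories) == 0:
            raise ValueError("categories must be nonempty")


def load_noise_library(manifest: str | Path, sample_rate: int) -> NoiseLibrary:
    """Load a noise library from a CSV manifest ``path,category,split``."""
    manifest = Path(manifest)
    frame = pd.read_csv(manifest)
    for col in ("path", "category", "split"):
        if col not in frame.columns:
            raise ValueError(f"{manifest}: missing column {col!r}")
    clips = []
    for row in frame.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest.parent / p
        clips.append(NoiseClip(audio=load_audio(p, sample_rate),
                               category=row.category, split=row.split))
    return NoiseLibrary(clips)


def mean_power(audio: AudioSignal | np.ndarray) -> float:
    """Mean squared amplitude of a signal."""
    x = audio.samples if isinstance(audio, AudioSignal) else np.asarray(audio)
    if x.size == 0:
        raise ValueError("cannot compute power of an empty signal")
    x = x.astype(np.float64, copy=False)
    return float(x @ x) / x.size


def snr_gain(signal_power: float, noise_power: float, target_snr_db: float) -> float:
    """Gain g so that signal_power / (g^2 * noise_power) = 10^(SNR/10)."""
    if signal_power <= 0 or noise_power <= 0:
        raise ValueError("signal and noise power must both be positive")
    return float(np.sqrt(signal_power / (noise_power * 10.0 ** (target_snr_db / 10.0))))


def sample_noise_cover(library: NoiseLibrary, needed_seconds: float,
                       spec: CorruptionSpec) -> AudioSignal:
    """Concatenate randomly drawn clips until they cover ``needed_seconds``.

    Clips are drawn with replacement from the requested split and categories
    and concatenated whole; the result is truncated to exactly the needed
    length.  Fully reproducible from ``spec.rng_seed``.
    """
    eligible = library.subset(split=spec.split, categories=spec.categories)
    if not eligible:
        raise ValueError(
            f"no {spec.split} noise clips in categories {spec.categories}")
    rng = np.random.default_rng(spec.rng_seed)
    rate = eligible[0].audio.sample_rate
    needed = int(round(needed_seconds * rate))
    parts, total = [], 0
    while total < needed:
        clip = eligible[rng.integers(len(eligible))]
        if clip.audio.sample_rate != rate:
            raise ValueError("noise library mixes sample rates")
        parts.append(clip.audio.samples)
        total += clip.audio.samples.size
    return AudioSignal(np.concatenate(parts)[:needed], rate)


def corrupt(clean: AudioSignal, library: NoiseLibrary,
            spec: CorruptionSpec) -> AudioSignal:
    """Additively corrupt ``clean`` with a scaled noise cover at ``spec.snr_db``."""
    cover = sample_noise_cover(library, clean.duration, spec)
    if cover.sample_rate != clean.sample_rate:
        raise ValueError("noise and signal sample rates differ")
    g = snr_gain(mean_power(clean), mean_power(cover), spec.snr_db)
    scaled = g * cover.samples.astype(np.float64)
    return AudioSignal(clean.samples.astype(np.float64) + scaled,
                       clean.sample_rate)


# ---------------------------------------------------------------------------
# Pitch shifting (phase-vocoder time stretch + resampling)
# ---------------------------------------------------------------------------

def _stft(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    pad = np.concatenate([np.zeros(n_fft // 2, dtype=x.dtype), x,
                          np.zeros(n_fft, dtype=x.dtype)])
    n_frames = 1 + (pad.size - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    w = get_window("hann", n_fft, fftbins=True).astype(x.dtype)
    return np.fft.rfft(pad[idx] * w[None, :], axis=1)


def _istft(frames: np.ndarray, n_fft: int, hop: int, length: int) -> np.ndarray:
    w = get_window("hann", n_fft, fftbins=True).astype(np.float32)
    x = (np.fft.irfft(frames, n=n_fft, axis=1) * w[None, :]).astype(np.float32)
    n_frames = frames.shape[0]
    total = hop * (n_frames - 1) + n_fft
    out = np.zeros(total)
    norm = np.zeros(total)
    # vectorized overlap-add: frames i, i+g, i+2g, ... (g = n_fft // hop)
    # within one residue class are exactly adjacent, so each class is one
    # reshaped copy instead of a per-frame loop
    w2 = w ** 2
    if n_fft % hop == 0:
        g = n_fft // hop
        for r in range(min(g, n_frames)):
            blk = x[r::g]
            seg = slice(r * hop, r * hop + blk.shape[0] * n_fft)
            out[seg] += blk.reshape(-1)
            norm[seg] += np.tile(w2, blk.shape[0])
    else:  # pragma: no cover - non-divisible hop fallback
        for i in range(n_frames):
            out[i * hop:i * hop + n_fft] += x[i]
            norm[i * hop:i * hop + n_fft] += w2
    out = out[n_fft // 2:n_fft // 2 + length]
    norm = norm[n_fft // 2:n_fft // 2 + length]
    return out / np.maximum(norm, 1e-8)


def time_stretch(audio: AudioSignal, rate: float, n_fft: int = 1024,
                 hop: int = 512) -> AudioSignal:
    """Phase-vocoder time stretch: output duration = input duration * rate."""
    if rate <= 0:
        raise ValueError("stretch rate must be positive")
    x = np.asarray(audio.samples, dtype=np.float32)
    spec = _stft(x, n_fft, hop)
    all_mag = np.abs(spec).astype(np.float32)
    all_phase = np.angle(spec).astype(np.float32)
    n_out = max(2, int(round(spec.shape[0] * rate)))
    # fractional analysis positions for each synthesis frame
    pos = np.linspace(0, spec.shape[0] - 1, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, spec.shape[0] - 1)
    frac = (pos - lo)[:, None].astype(np.float32)
    mag = (1 - frac) * all_mag[lo] + frac * all_mag[hi]
    # phase advance between consecutive analysis frames, unwrapped around the
    # expected bin advance, then re-accumulated at the synthesis hop
    omega = (2 * np.pi * np.arange(spec.shape[1]) * hop / n_fft
             ).astype(np.float32)
    dphi = all_phase[hi] - all_phase[lo] - omega[None, :]
    dphi -= (2 * np.pi * np.round(dphi / (2 * np.pi))).astype(np.float32)
    step = omega[None, :] + dphi
    phase = all_phase[0][None, :] + np.concatenate(
        [np.zeros((1, spec.shape[1]), dtype=np.float32),
         np.cumsum(step[:-1], axis=0, dtype=np.float32)])
    out = _istft(mag * np.exp(1j * phase), n_fft, hop,
                 int(round(x.size * rate)))
    return AudioSignal(out, audio.sample_rate)


def pitch_shift(audio: AudioSignal, semitones: float) -> AudioSignal:
    """Shift pitch by ``semitones`` while preserving duration.

    Implemented as a phase-vocoder stretch by 2^(s/12) followed by resampling
    back to the original length, which multiplies all frequencies by the same
    factor.
    """
    if abs(semitones) > 12:
        raise ValueError("pitch shift limited to +/-12 semitones")
    if semitones == 0:
        return AudioSignal(np.array(audio.samples, copy=True), audio.sample_rate)
    factor = 2.0 ** (semitones / 12.0)
    stretched = time_stretch(audio, factor)
    ratio = Fraction(stretched.samples.size, audio.samples.size).limit_denominator(1000)
    y = resample_poly(stretched.samples, ratio.denominator, ratio.numerator)
    n = audio.samples.size
    if y.size < n:
        y = np.pad(y, (0, n - y.size))
    return AudioSignal(y[:n], audio.sample_rate)
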