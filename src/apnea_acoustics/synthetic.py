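"""Seeded synthetic nights, noise clips and cohorts.

The generator encodes the acoustic phenomenology of obstructive events:
quasi-periodic breath bursts (band-limited noise under raised-cosine
envelopes); apnea as a cessation of breathing followed by a louder, wider-band
recovery gasp; hypopnea as attenuated, irregular breathing.  Synthetic noise
clips emulate the nine home-noise groups with distinct spectral bands and are
either stationary (time-constant spectrum) or event-driven (sparse
transients).  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .annotations import EventType, RespiratoryEvent, save_events
from .audio_features import AudioSignal, save_audio
from .noise import NOISE_CATEGORIES, NoiseClip, NoiseLibrary


@dataclass
class BreathingModel:
    """Quasi-periodic breathing as enveloped band-limited noise bursts."""

    breath_rate: float = 14.0  # breaths per minute
    burst_seconds: float = 1.2  # inhalation burst length
    band_hz: tuple[float, float] = (300.0, 2000.0)
    base_amplitude: float = 0.1
    timing_jitter: float = 0.08  # fractional SD of the breath period
    amplitude_jitter: float = 0.15  # fractional SD of per-breath amplitude
    background_amplitude: float = 0.002  # sensor/room floor

    def __post_init__(self) -> None:
        if self.breath_rate <= 0:
            raise ValueError("breath_rate must be positive")
        if min(self.base_amplitude, self.burst_seconds) <= 0:
            raise ValueError("burst parameters must be positive")


@dataclass
class SyntheticNightSpec:
    duration_hours: float = 8.0
    target_event_rate: float = 10.0  # events per hour == reference AHI
    apnea_fraction: float = 0.5  # share of events that are obstructive apneas
    event_duration_range: tuple[float, float] = (10.0, 60.0)
    gasp_gain: float = 3.0  # recovery-gasp amplitude multiplier
    hypopnea_attenuation: float = 0.35  # amplitude fraction kept
    min_event_gap: float = 10.0
    breathing: BreathingModel = field(default_factory=BreathingModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.event_duration_range
        if not (10.0 <= lo <= hi <= 60.0):
            raise ValueError("event durations must lie within [10, 60] s")
        if not 0.0 < self.hypopnea_attenuation < 1.0:
            raise ValueError("hypopnea_attenuation must be in (0, 1)")
        if not 0.0 <= self.apnea_fraction <= 1.0:
            raise ValueError("apnea_fraction must be in [0, 1]")
        if self.duration_hours <= 0 or self.target_event_rate < 0:
            raise ValueError("duration and event rate must be nonnegative")


#: Spectral band, kind and transient parameters standing in for the nine
#: home-noise groups.  Bands are clamped to 0.45 * sample_rate.
NOISE_GROUP_TABLE: dict[str, dict] = {
    "home_appliance": dict(kind="event_driven", band=(400, 3000), rate=0.8, burst=0.20),
    "room_noise": dict(kind="stationary", band=(100, 1000)),
    "contents": dict(kind="event_driven", band=(200, 3000), rate=2.5, burst=0.25),
    "clock": dict(kind="event_driven", band=(800, 3500), rate=1.0, burst=0.03,
                  regular=True),
    "speech": dict(kind="event_driven", band=(120, 2800), rate=3.5, burst=0.15),
    "animal": dict(kind="event_driven", band=(600, 3500), rate=0.6, burst=0.30),
    "air_conditioner_fan": dict(kind="stationary", band=(40, 400)),
    "rain_wind": dict(kind="stationary", band=(200, 3800)),
    "car_motorbike": dict(kind="stationary", band=(30, 250)),
}


@dataclass
class SyntheticNoiseSpec:
    category: str
    duration_seconds: float = 30.0
    kind: str | None = None  # default: the category's kind
    band_hz: tuple[float, float] | None = None
    transient_rate: float | None = None  # events per second (event_driven)
    burst_seconds: float | None = None
    amplitude: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in NOISE_GROUP_TABLE:
            raise ValueError(f"unknown noise category {self.category!r}")
        if self.duration_seconds <= 0:
            raise ValueError("duration must be positive")
        table = NOISE_GROUP_TABLE[self.category]
        if self.kind is None:
            self.kind = table["kind"]
        if self.band_hz is None:
            self.band_hz = table["band"]
        if self.kind == "event_driven":
            if self.transient_rate is None:
                self.transient_rate = table.get("rate", 1.0)
            if self.burst_seconds is None:
                self.burst_seconds = table.get("burst", 0.2)


def _bandpass_sos(band: tuple[float, float], sample_rate: int):
    lo = max(band[0], 1.0)
    hi = min(band[1], 0.45 * sample_rate)
    if hi <= lo:
        raise ValueError(f"band {band} infeasible at {sample_rate} Hz")
    return butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _place_events(spec: SyntheticNightSpec, rng: np.random.Generator
                  ) -> list[RespiratoryEvent]:
    total = spec.duration_hours * 3600.0
    n_events = int(round(spec.target_event_rate * spec.duration_hours))
    if n_events == 0:
        return []
    lo, hi = spec.event_duration_range
    durations = rng.uniform(lo, hi, size=n_events)
    gap = spec.min_event_gap
    placed: list[tuple[float, float]] = []
    events: list[RespiratoryEvent] = []
    n_apnea = int(round(spec.apnea_fraction * n_events))
    types = [EventType.OBSTRUCTIVE_APNEA] * n_apnea + \
        [EventType.HYPOPNEA] * (n_events - n_apnea)
    types = [types[i] for i in rng.permutation(n_events)]
    for d, t in zip(durations, types):
        if total - d - gap <= gap:
            raise ValueError("night too short to place an event of "
                             f"duration {d:.0f} s")
        for _ in range(2000):
            onset = rng.uniform(gap, total - d - gap)
            if all(onset + d + gap <= s or onset >= s + dd + gap
                   for s, dd in placed):
                placed.append((onset, d))
                events.append(RespiratoryEvent(onset=float(onset),
                                               duration=float(d), event_type=t))
                break
        else:
            raise ValueError(
                f"cannot place {n_events} non-overlapping events at rate "
                f"{spec.target_event_rate}/h in {spec.duration_hours} h")
    return sorted(events, key=lambda e: e.onset)


def generate_night(spec: SyntheticNightSpec, sample_rate: int = 16_000
                   ) -> tuple[AudioSignal, list[RespiratoryEvent], float]:
    """Synthesize one night: audio, its event annotations and the true AHI."""
    rng = np.random.default_rng(spec.rng_seed)
    bm = spec.breathing
    n = int(round(spec.duration_hours * 3600.0 * sample_rate))
    events = _place_events(spec, rng)

    # per-breath bump schedule
    period = 60.0 / bm.breath_rate
    times, amps = [], []
    t = rng.uniform(0, period)
    total = spec.duration_hours * 3600.0
    while t < total - bm.burst_seconds:
        times.append(t)
        amps.append(max(0.0, 1.0 + bm.amplitude_jitter * rng.standard_normal()))
        t += period * max(0.2, 1.0 + bm.timing_jitter * rng.standard_normal())
    times = np.asarray(times)
    amps = np.asarray(amps)

    # event modulation: apneas silence breaths, hypopneas attenuate + roughen
    gasps = []
    for e in events:
        inside = (times >= e.onset) & (times < e.end)
        if e.event_type is EventType.OBSTRUCTIVE_APNEA:
            amps[inside] = 0.0
            gasps.append(e.end)
        else:
            amps[inside] *= spec.hypopnea_attenuation * rng.uniform(
                0.6, 1.4, size=int(inside.sum()))

    envelope = np.zeros(n)
    burst_n = int(round(bm.burst_seconds * sample_rate))
    bump = _raised_cosine(burst_n)
    for t0, a in zip(times, amps):
        if a <= 0:
            continue
        i = int(round(t0 * sample_rate))
        j = min(i + burst_n, n)
        envelope[i:j] += a * bump[:j - i]

    sos = _bandpass_sos(bm.band_hz, sample_rate)
    carrier = sosfilt(sos, rng.standard_normal(n))
    carrier /= max(np.sqrt(np.mean(carrier ** 2)), 1e-12)
    audio = bm.base_amplitude * envelope * carrier
    audio += bm.background_amplitude * rng.standard_normal(n)

    # recovery gasps: louder, wider-band bursts right after each apnea
    gasp_n = int(round(1.0 * sample_rate))
    gasp_sos = _bandpass_sos((100.0, 0.44 * sample_rate), sample_rate)
    gasp_bump = _raised_cosine(gasp_n)
    for t0 in gasps:
        i = int(round(t0 * sample_rate))
        j = min(i + gasp_n, n)
        if j <= i:
            continue
        seg = sosfilt(gasp_sos, rng.standard_normal(j - i))
        seg /= max(np.sqrt(np.mean(seg ** 2)), 1e-12)
        audio[i:j] += spec.gasp_gain * bm.base_amplitude * gasp_bump[:j - i] * seg

    reference_ahi = len(events) / spec.duration_hours
    return (AudioSignal(audio.astype(np.float32), sample_rate), events,
            reference_ahi)


def generate_noise_clip(spec: SyntheticNoiseSpec, sample_rate: int = 16_000,
                        split: str = "train") -> NoiseClip:
    """Synthesize one noise clip of the requested category and kind."""
    rng = np.random.default_rng(spec.rng_seed)
    n = int(round(spec.duration_seconds * sample_rate))
    sos = _bandpass_sos(spec.band_hz, sample_rate)
    if spec.kind == "stationary":
        x = sosfilt(sos, rng.standard_normal(n))
        x /= max(np.sqrt(np.mean(x ** 2)), 1e-12)
        x *= spec.amplitude
    elif spec.kind == "event_driven":
        x = 0.01 * spec.amplitude * rng.standard_normal(n)  # near-silence
        burst_n = max(8, int(round(spec.burst_seconds * sample_rate)))
        bump = _raised_cosine(burst_n)
        regular = NOISE_GROUP_TABLE[spec.category].get("regular", False)
        if regular:
            period = 1.0 / spec.transient_rate
            starts = np.arange(rng.uniform(0, period), spec.duration_seconds,
                               period)
        else:
            k = rng.poisson(spec.transient_rate * spec.duration_seconds)
            starts = np.sort(rng.uniform(0, spec.duration_seconds, size=k))
        for t0 in starts:
            i = int(round(t0 * sample_rate))
            j = min(i + burst_n, n)
            if j <= i:
                continue
            seg = sosfilt(sos, rng.standard_normal(j - i))
            seg /= max(np.sqrt(np.mean(seg ** 2)), 1e-12)
            x[i:j] += spec.amplitude * rng.uniform(0.5, 1.5) * bump[:j - i] * seg
    else:
        raise ValueError(f"unknown noise kind {spec.kind!r}")
    return NoiseClip(audio=AudioSignal(x.astype(np.float32), sample_rate),
                     category=spec.category, split=split, kind=spec.kind)


def generate_noise_library(sample_rate: int = 16_000,
                           clip_seconds: float = 30.0,
                           clips_per_category: int = 4,
                           rng_seed: int = 0,
                           categories=NOISE_CATEGORIES) -> NoiseLibrary:
    """A balanced synthetic library; within each category the clips are split
    half train / half test (disjoint by construction)."""
    seeds = np.random.SeedSequence(rng_seed).generate_state(
        len(categories) * clips_per_category)
    clips, i = [], 0
    for cat in categories:
        for j in range(clips_per_category):
            split = "train" if j < (clips_per_category + 1) // 2 else "test"
            clips.append(generate_noise_clip(
                SyntheticNoiseSpec(category=cat, duration_seconds=clip_seconds,
                                   rng_seed=int(seeds[i])),
                sample_rate=sample_rate, split=split))
            i += 1
    return NoiseLibrary(clips)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Severity strata (AHI intervals) and the cohort proportions used when
#: emulating a screening-style test population.
SEVERITY_STRATA = (
    ((0.5, 4.5), 0.18),
    ((5.0, 14.0), 0.32),
    ((15.0, 29.0), 0.32),
    ((30.0, 55.0), 0.18),
)


def strata_counts(n_subjects: int, proportions=None) -> list[int]:
    """Largest-remainder apportionment of subjects across severity strata."""
    props = [p for _, p in SEVERITY_STRATA] if proportions is None else list(proportions)
    raw = [n_subjects * p for p in props]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(n_subjects - sum(counts)):
        counts[order[i]] += 1
    return counts


@dataclass
class SyntheticNight:
    subject_id: str
    audio: AudioSignal
    events: list[RespiratoryEvent]
    reference_ahi: float
    duration_hours: float


def generate_cohort_data(n_subjects: int, rng_seed: int = 0,
                         duration_hours: float = 8.0,
                         sample_rate: int = 16_000,
                         proportions=None) -> list[SyntheticNight]:
    """In-memory cohort spanning the severity strata (seeded)."""
    counts = strata_counts(n_subjects, proportions)
    rng = np.random.default_rng(rng_seed)
    night_seeds = np.random.SeedSequence(rng_seed + 1).generate_state(n_subjects)
    nights, k = [], 0
    for (ahi_lo, ahi_hi), cnt in zip((s for s, _ in SEVERITY_STRATA), counts):
        for _ in range(cnt):
            target = float(rng.uniform(ahi_lo, ahi_hi))
            spec = SyntheticNightSpec(duration_hours=duration_hours,
                                      target_event_rate=target,
                                      rng_seed=int(night_seeds[k]))
            audio, events, ref = generate_night(spec, sample_rate)
            nights.append(SyntheticNight(f"S{k:03d}", audio, events, ref,
                                         duration_hours))
            k += 1
    return nights


def generate_cohort(n_subjects: int, out_dir: str | Path, rng_seed: int = 0,
                    duration_hours: float = 8.0, sample_rate: int = 16_000,
                    proportions=None) -> pd.DataFrame:
    """Write a cohort (WAVs + annotation CSVs) and return/save its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for night in generate_cohort_data(n_subjects, rng_seed, duration_hours,
                                      sample_rate, proportions):
        wav = out / f"{night.subject_id}.wav"
        ann = out / f"{night.subject_id}_events.csv"
        save_audio(night.audio, wav)
        save_events(night.events, ann)
        rows.append({"subject_id": night.subject_id, "audio_path": wav.name,
                     "annotation_path": ann.name,
                     "reference_ahi": night.reference_ahi,
                     "hours": night.duration_hours})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
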