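"""Respiratory-event annotations and 30-second epoch labeling.

A night of sleep audio is scored on a grid of 30-second epochs.  Each
annotated respiratory event (obstructive apnea, hypopnea, central apnea, ...)
covers an interval ``[onset, onset + duration)`` in seconds from the start of
the recording.  Only obstructive events count here: central and mixed apneas
are excluded before labeling, so every epoch receives one of three classes --
``no_event``, ``apnea`` (obstructive) or ``hypopnea``.

When two event types overlap one epoch, the epoch takes the type whose
within-epoch overlap is longer; equal overlaps go to apnea, the more severe
class.  A trailing partial segment shorter than 30 s is dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

EPOCH_SECONDS = 30.0


class EventType(str, Enum):
    OBSTRUCTIVE_APNEA = "obstructive_apnea"
    HYPOPNEA = "hypopnea"
    CENTRAL_APNEA = "central_apnea"
    MIXED_APNEA = "mixed_apnea"
    OTHER = "other"


#: Event types that contribute to obstructive-sleep-apnea labeling.
OBSTRUCTIVE_TYPES = (EventType.OBSTRUCTIVE_APNEA, EventType.HYPOPNEA)


class EpochClass(int, Enum):
    """The three epoch-level classes, in the canonical order used everywhere."""

    NO_EVENT = 0
    APNEA = 1
    HYPOPNEA = 2


CLASS_NAMES = ("no_event", "apnea", "hypopnea")


@dataclass(frozen=True)
class RespiratoryEvent:
    """One annotated respiratory event.

    Parameters
    ----------
    onset : float
        Seconds from recording start, >= 0.
    duration : float
        Event length in seconds, > 0.
    event_type : EventType
        The scored event type; unknown strings map to ``EventType.OTHER``.
    """

    onset: float
    duration: float
    event_type: EventType

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class EpochGrid:
    """Half-open 30-second epochs ``[30k, 30(k+1))`` covering a recording."""

    recording_duration: float
    epoch_length: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.recording_duration < 0:
            raise ValueError("recording duration must be >= 0")
        if self.epoch_length <= 0:
            raise ValueError("epoch length must be > 0")

    @property
    def n_epochs(self) -> int:
        return int(self.recording_duration // self.epoch_length)

    def bounds(self, k: int) -> tuple[float, float]:
        return k * self.epoch_length, (k + 1) * self.epoch_length


@dataclass
class EpochLabel:
    epoch_index: int
    label: EpochClass
    overlap_seconds_by_type: dict[EventType, float] = field(default_factory=dict)


@dataclass
class LabeledNight:
    subject_id: str
    epoch_labels: list[EpochLabel]
    reference_ahi: float | None = None

    @property
    def labels(self) -> list[EpochClass]:
        return [e.label for e in self.epoch_labels]


_REQUIRED_COLUMNS = ("event_type", "onset_sec", "duration_sec")


def _coerce_event(event_type: str, onset: float, duration: float,
                  where: str) -> RespiratoryEvent:
    try:
        etype = EventType(str(event_type).strip().lower())
    except ValueError:
        etype = EventType.OTHER
    try:
        onset = float(onset)
        duration = float(duration)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: non-numeric onset/duration") from exc
    try:
        return RespiratoryEvent(onset=onset, duration=duration, event_type=etype)
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def load_events(path: str | Path) -> list[RespiratoryEvent]:
    """Load respiratory events from a CSV or JSON annotation file.

    CSV needs the header ``event_type,onset_sec,duration_sec``; JSON is a list
    of objects with the same keys.  Events come back sorted by onset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise ValueError(f"{path}: JSON annotations must be a list of objects")
        events = [
            _coerce_event(r.get("event_type"), r.get("onset_sec"),
                          r.get("duration_sec"), f"{path} item {i}")
            for i, r in enumerate(records)
        ]
    else:
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"{path}: could not parse CSV ({exc})") from exc
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        events = [
            _coerce_event(row.event_type, row.onset_sec, row.duration_sec,
                          f"{path} line {i + 2}")
            for i, row in enumerate(frame.itertuples(index=False))
        ]
    return sorted(events, key=lambda e: e.onset)


def save_events(events: Iterable[RespiratoryEvent], path: str | Path) -> None:
    """Write events as the CSV annotation schema (sorted by onset)."""
    rows = [
        {"event_type": e.event_type.value, "onset_sec": e.onset,
         "duration_sec": e.duration}
        for e in sorted(events, key=lambda e: e.onset)
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


def filter_obstructive(events: Sequence[RespiratoryEvent]) -> list[RespiratoryEvent]:
    """Keep only obstructive apneas and hypopneas.

    Central and mixed apneas (and unknown types) are excluded: only
    obstructive events count toward the apnea/hypopnea epoch classes.
    """
    return [e for e in events if e.event_type in OBSTRUCTIVE_TYPES]


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_epochs(
    events: Sequence[RespiratoryEvent],
    grid: EpochGrid,
    *,
    compare: str = "overlap",
) -> list[EpochLabel]:
    """Assign one 3-class label per epoch from filtered obstructive events.

    Per epoch, overlap seconds are summed per event type; the label is the
    type with the larger overlap (ties -> apnea), or ``no_event`` when no
    event touches the epoch.  ``compare="total_duration"`` switches the
    two-type tie-break quantity from within-epoch overlap to the total
    duration of the overlapping events.
    """
    if compare not in ("overlap", "total_duration"):
        raise ValueError(f"unknown comparison rule {compare!r}")
    for e in events:
        if e.event_type not in OBSTRUCTIVE_TYPES:
            raise ValueError(
                f"label_epochs expects filtered events, got {e.event_type}")
    out: list[EpochLabel] = []
    for k in range(grid.n_epochs):
        lo, hi = grid.bounds(k)
        overlaps = {t: 0.0 for t in OBSTRUCTIVE_TYPES}
        scores = {t: 0.0 for t in OBSTRUCTIVE_TYPES}
        for e in events:
            ov = _overlap(lo, hi, e.onset, e.end)
            if ov > 0.0:
                overlaps[e.event_type] += ov
                scores[e.event_type] += ov if compare == "overlap" else e.duration
        if overlaps[EventType.OBSTRUCTIVE_APNEA] == 0.0 and \
                overlaps[EventType.HYPOPNEA] == 0.0:
            label = EpochClass.NO_EVENT
        elif scores[EventType.OBSTRUCTIVE_APNEA] >= scores[EventType.HYPOPNEA]:
            label = EpochClass.APNEA
        else:
            label = EpochClass.HYPOPNEA
        out.append(EpochLabel(k, label, {t: v for t, v in overlaps.items() if v > 0}))
    return out


def label_night(
    events: Sequence[RespiratoryEvent],
    recording_duration: float,
    subject_id: str = "",
    reference_ahi: float | None = None,
) -> LabeledNight:
    """Filter to obstructive events and label a whole night in one call."""
    grid = EpochGrid(recording_duration)
    labels = label_epochs(filter_obstructive(events), grid)
    return LabeledNight(subject_id, labels, reference_ahi)
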