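import numpy as np
import pytest

from apnea_acoustics import FeatureConfig
from apnea_acoustics.annotations import EpochClass, EventType, RespiratoryEvent


@pytest.fixture(scope="session")
def fast_feature_config():
    """Low-rate feature config keeping unit tests quick."""
    return FeatureConfig(sample_rate=2000, mel_bins=24, window_sec=0.064,
                         hop_sec=0.032)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_events(rng, recording_duration, n_events, grid_step=0.01,
                  types=(EventType.OBSTRUCTIVE_APNEA, EventType.HYPOPNEA)):
    """Random obstructive events with onsets/durations on a 0.01-s lattice."""
    events = []
    for _ in range(n_events):
        onset = round(float(rng.uniform(0, recording_duration - 1)), 2)
        max_d = recording_duration - onset
        duration = round(float(rng.uniform(grid_step, min(90.0, max_d))), 2)
        duration = max(duration, grid_step)
        events.append(RespiratoryEvent(
            onset=onset, duration=duration,
            event_type=types[int(rng.integers(len(types)))]))
    return events


def brute_force_labels(events, grid, dt=0.01):
    """Independent labeling oracle: rasterize time at ``dt`` and sum per-type
    occupancy per epoch; apnea wins ties."""
    n_cells = int(round(grid.epoch_length / dt))
    labels = []
    for k in range(grid.n_epochs):
        lo = k * grid.epoch_length
        occupancy = {EventType.OBSTRUCTIVE_APNEA: 0.0, EventType.HYPOPNEA: 0.0}
        cells = lo + dt * np.arange(n_cells)
        for e in events:
            inside = (cells >= e.onset - dt / 2) & (cells < e.end - dt / 2)
            occupancy[e.event_type] += dt * int(inside.sum())
        a, h = (occupancy[EventType.OBSTRUCTIVE_APNEA],
                occupancy[EventType.HYPOPNEA])
        if a < dt / 2 and h < dt / 2:
            labels.append(EpochClass.NO_EVENT)
        elif a >= h:
            labels.append(EpochClass.APNEA)
        else:
            labels.append(EpochClass.HYPOPNEA)
    return labels
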