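"""AHI estimation from epoch predictions and OSA severity classification.

A respiratory event can straddle two or three 30-second epochs, and two short
events can share one, so the apneic-epoch count is not the event count.  The
apneic-epoch rate (epochs predicted apnea or hypopnea per recording hour) is
therefore mapped to an AHI estimate by a robust linear fit learned on nights
with a reference AHI: a RANSAC regression (minimal subsets of 2, inlier
consensus under a residual threshold set to the MAD of a preliminary
least-squares fit, 1000 trials, seeded), refit on the consensus inliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .annotations import EpochClass
from .detector import NightPrediction

SEVERITY_CUTOFFS = (5.0, 15.0, 30.0)


class SeverityClass(str, Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass
class ApneicEpochRate:
    apneic_epoch_count: int
    recording_hours: float

    def __post_init__(self) -> None:
        if self.recording_hours <= 0:
            raise ValueError("recording_hours must be positive")
        if self.apneic_epoch_count < 0:
            raise ValueError("apneic_epoch_count must be >= 0")

    @property
    def rate(self) -> float:
        return self.apneic_epoch_count / self.recording_hours


@dataclass
class AHIRegressor:
    """Affine map from apneic-epochs/hour to estimated AHI (events/hour)."""

    slope: float
    intercept: float
    inlier_mask: np.ndarray | None = None
    rng_seed: int = 0
    n_train: int = 0

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"slope": self.slope, "intercept": self.intercept,
                       "seed": self.rng_seed, "n_train": self.n_train}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "AHIRegressor":
        with open(path) as fh:
            d = json.load(fh)
        return cls(slope=d["slope"], intercept=d["intercept"],
                   rng_seed=d.get("seed", 0), n_train=d.get("n_train", 0))


def apneic_rate(night: NightPrediction | Sequence, recording_hours: float
                ) -> ApneicEpochRate:
    """Count epochs called apnea or hypopnea, per recording hour."""
    classes = night.classes if isinstance(night, NightPrediction) else night
    count = sum(1 for c in classes
                if EpochClass(int(c)) in (EpochClass.APNEA, EpochClass.HYPOPNEA))
    return ApneicEpochRate(apneic_epoch_count=count,
                           recording_hours=recording_hours)


def fit_ahi_regressor(rates: Sequence[float], reference_ahis: Sequence[float],
                      rng_seed: int = 0, n_trials: int = 1000) -> AHIRegressor:
    """Robust linear fit of reference AHI against apneic-epoch rate."""
    x = np.asarray(rates, dtype=float)
    y = np.asarray(reference_ahis, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two (rate, AHI) training nights")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("rates and reference AHIs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("all rates identical; the slope is unidentifiable")

    # residual threshold from a preliminary least-squares fit
    coef = np.polyfit(x, y, 1)
    resid = np.abs(y - np.polyval(coef, x))
    mad = float(np.median(np.abs(resid - np.median(resid))))
    threshold = max(mad, 1e-8 * (1.0 + float(np.median(np.abs(y)))))

    ransac = RANSACRegressor(
        estimator=LinearRegression(),
        min_samples=2,
        residual_threshold=threshold,
        max_trials=n_trials,
        random_state=rng_seed,
    )
    ransac.fit(x[:, None], y)
    return AHIRegressor(
        slope=float(ransac.estimator_.coef_[0]),
        intercept=float(ransac.estimator_.intercept_),
        inlier_mask=ransac.inlier_mask_.copy(),
        rng_seed=rng_seed,
        n_train=x.size,
    )


def estimate_ahi(regressor: AHIRegressor, rate: ApneicEpochRate | float) -> float:
    """Affine estimate ``slope * rate + intercept``, floored at 0 events/hour."""
    r = rate.rate if isinstance(rate, ApneicEpochRate) else float(rate)
    return max(0.0, regressor.slope * r + regressor.intercept)


def classify_severity(ahi: float) -> SeverityClass:
    """OSA severity at the standard 5/15/30 cutoffs (boundaries round up)."""
    if ahi < 0:
        raise ValueError("AHI must be >= 0")
    if ahi < SEVERITY_CUTOFFS[0]:
        return SeverityClass.NORMAL
    if ahi < SEVERITY_CUTOFFS[1]:
        return SeverityClass.MILD
    if ahi < SEVERITY_CUTOFFS[2]:
        return SeverityClass.MODERATE
    return SeverityClass.SEVERE
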