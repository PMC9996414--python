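"""End-to-end experiment harnesses on synthetic cohorts.

These reproduce, at reduced scale, the robustness study designs: the SNR
sweep comparing the consistency-trained model against a clean-only control,
the noise-group cross-testing matrix, and the noise-fraction saturation
curve.  All of them operate on synthetic nights and synthetic noise
libraries, so results are qualitative trends, not clinical numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import label_night
from .audio_features import FeatureConfig, night_mel_spectrograms, \
    pool_night_features
from .detector import DetectorConfig, EventDetector, build_detector
from .evaluation import confusion, epoch_metrics
from .noise import NOISE_CATEGORIES, CorruptionSpec, NoiseLibrary, corrupt
from .synthetic import SyntheticNight, generate_cohort_data, \
    generate_noise_library
from .training import (Checkpoint, TrainingConfig, TrainingNight,
                       fit_normalization, pretrain_1to1, train_14to10)


@dataclass
class ExperimentSpec:
    """Grid and model roster for the robustness experiments."""

    snr_grid: tuple[float, ...] = (5, 0, -5, -10, -15, -20, -25, -30)
    include_clean: bool = True
    models: tuple[str, ...] = ("consistency", "control")
    noise_categories: tuple[str, ...] = NOISE_CATEGORIES
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if len(self.snr_grid) == 0:
            raise ValueError("snr_grid must be nonempty")


def prepare_training_night(night: SyntheticNight,
                           feature_config: FeatureConfig,
                           keep_audio: bool = True) -> TrainingNight:
    """Label a synthetic night on the epoch grid and pool its features."""
    labeled = label_night(night.events, night.audio.duration,
                          night.subject_id, night.reference_ahi)
    mels = night_mel_spectrograms(night.audio, feature_config)
    labels = np.asarray([int(l) for l in labeled.labels])[:len(mels)]
    return TrainingNight(
        subject_id=night.subject_id,
        features=pool_night_features(mels),
        labels=labels,
        audio=night.audio if keep_audio else None,
        reference_ahi=night.reference_ahi,
    )


@dataclass
class ExperimentData:
    train: list[TrainingNight]
    val: list[TrainingNight]
    test: list[TrainingNight]
    noise_library: NoiseLibrary
    feature_config: FeatureConfig


def make_experiment_data(n_subjects: int, duration_hours: float,
                         feature_config: FeatureConfig, rng_seed: int,
                         val_subjects: int = 2, test_subjects: int = 4,
                         noise_clip_seconds: float = 60.0,
                         noise_clips_per_category: int = 4) -> ExperimentData:
    """Synthetic cohort + noise library, split into train/val/test nights."""
    nights = generate_cohort_data(n_subjects, rng_seed, duration_hours,
                                  feature_config.sample_rate)
    rng = np.random.default_rng(rng_seed + 7)
    order = rng.permutation(len(nights))
    test_idx = set(order[:test_subjects])
    val_idx = set(order[test_subjects:test_subjects + val_subjects])
    prepared = [prepare_training_night(n, feature_config) for n in nights]
    library = generate_noise_library(
        feature_config.sample_rate, clip_seconds=noise_clip_seconds,
        clips_per_category=noise_clips_per_category, rng_seed=rng_seed + 13)
    return ExperimentData(
        train=[p for i, p in enumerate(prepared) if i not in test_idx | val_idx],
        val=[p for i, p in enumerate(prepared) if i in val_idx],
        test=[p for i, p in enumerate(prepared) if i in test_idx],
        noise_library=library,
        feature_config=feature_config,
    )


def train_model(data: ExperimentData, training_config: TrainingConfig,
                detector_config: DetectorConfig,
                noise_categories: Sequence[str] | None = None,
                noise_library: NoiseLibrary | None = None
                ) -> tuple[EventDetector, Checkpoint]:
    """Run the full 2-step procedure (pretraining then 14-to-10 training)."""
    detector = build_detector(replace(
        detector_config, feature_dim=data.train[0].features.shape[1]))
    fit_normalization(detector, data.train)
    pre = pretrain_1to1(detector, data.train, data.val, training_config)
    ckpt = train_14to10(detector, data.train, data.val, training_config,
                        noise_library=noise_library or data.noise_library,
                        feature_config=data.feature_config, pretrained=pre,
                        noise_categories=noise_categories)
    return detector, ckpt


def train_consistency_and_control(data: ExperimentData,
                                  training_config: TrainingConfig,
                                  detector_config: DetectorConfig
                                  ) -> dict[str, EventDetector]:
    """The paired models of the robustness comparison (shared pretraining seed)."""
    consistency, _ = train_model(data, training_config, detector_config)
    control, _ = train_model(
        data, replace(training_config, consistency_weight=0.0),
        detector_config)
    return {"consistency": consistency, "control": control}


def _corrupted_test_features(night: TrainingNight, data: ExperimentData,
                             snr_db: float, rng_seed: int,
                             categories: Sequence[str] | None = None
                             ) -> np.ndarray:
    spec = CorruptionSpec(
        snr_db=snr_db,
        categories=tuple(categories) if categories else NOISE_CATEGORIES,
        rng_seed=rng_seed, split="test")
    noisy = corrupt(night.audio, data.noise_library, spec)
    return pool_night_features(
        night_mel_spectrograms(noisy, data.feature_config))


def evaluate_macro_f1(models: dict[str, EventDetector],
                      data: ExperimentData, snr_db: float | None,
                      rng_seed: int,
                      categories: Sequence[str] | None = None
                      ) -> dict[str, float]:
    """Macro F1 of each model on the test nights, optionally noise-corrupted.

    All models see identical corrupted features so the comparison is paired.
    """
    refs: list[int] = []
    preds: dict[str, list[int]] = {m: [] for m in models}
    for i, night in enumerate(data.test):
        feats = (night.features if snr_db is None else
                 _corrupted_test_features(night, data, snr_db,
                                          rng_seed + 1000 * i, categories))
        refs.extend(int(l) for l in night.labels)
        for name, det in models.items():
            preds[name].extend(
                int(c) for c in det.predict_night(feats).classes)
    return {name: epoch_metrics(confusion(refs, p)).macro_f1
            for name, p in preds.items()}


def run_snr_sweep(models: dict[str, EventDetector], data: ExperimentData,
                  spec: ExperimentSpec | None = None,
                  rng_seed: int = 0) -> pd.DataFrame:
    """Macro F1 per (model, SNR); the clean column uses no corruption.

    Rows are models; columns are ``clean`` plus the SNR grid in the given
    (descending) order.
    """
    spec = spec or ExperimentSpec()
    columns: list[tuple[str, float | None]] = []
    if spec.include_clean:
        columns.append(("clean", None))
    columns.extend((str(s), float(s)) for s in spec.snr_grid)
    table: dict[str, dict[str, float]] = {m: {} for m in models}
    for label, snr in columns:
        scores = evaluate_macro_f1(models, data, snr, rng_seed,
                                   spec.noise_categories)
        for m, f1 in scores.items():
            table[m][label] = f1
    return pd.DataFrame(table).T[[c for c, _ in columns]]


def run_noise_group_matrix(data: ExperimentData,
                           training_config: TrainingConfig,
                           detector_config: DetectorConfig,
                           snr_db: float = -5.0,
                           rng_seed: int = 0) -> pd.DataFrame:
    """Cross-testing matrix: 9 single-group models + all-group model (rows)
    against 9 single-group test corruptions + the combined set (columns)."""
    rows = {}
    for cat in NOISE_CATEGORIES:
        det, _ = train_model(data, training_config, detector_config,
                             noise_categories=(cat,))
        rows[cat] = det
    det_all, _ = train_model(data, training_config, detector_config)
    rows["all"] = det_all
    out = {}
    for name, det in rows.items():
        scores = {}
        for cat in NOISE_CATEGORIES:
            scores[cat] = evaluate_macro_f1({"m": det}, data, snr_db,
                                            rng_seed, (cat,))["m"]
        scores["combined"] = evaluate_macro_f1({"m": det}, data, snr_db,
                                               rng_seed)["m"]
        out[name] = scores
    return pd.DataFrame(out).T


def run_noise_fraction_curve(data: ExperimentData,
                             training_config: TrainingConfig,
                             detector_config: DetectorConfig,
                             fractions: Sequence[float] = (0.05, 0.1, 0.2,
                                                           0.5, 1.0),
                             snr_db: float = -5.0,
                             rng_seed: int = 0) -> pd.DataFrame:
    """Macro F1 (at ``snr_db``) vs the fraction of training noise clips used.

    Fraction 0 means no noise at all, i.e. the control model.
    """
    rng = np.random.default_rng(rng_seed)
    train_clips = data.noise_library.subset(split="train")
    test_clips = data.noise_library.subset(split="test")
    rows = []
    for frac in fractions:
        if frac == 0:
            det, _ = train_model(
                data, replace(training_config, consistency_weight=0.0),
                detector_config)
        else:
            k = max(1, int(round(frac * len(train_clips))))
            chosen = [train_clips[i]
                      for i in rng.choice(len(train_clips), k, replace=False)]
            det, _ = train_model(data, training_config, detector_config,
                                 noise_library=NoiseLibrary(chosen + test_clips))
        f1 = evaluate_macro_f1({"m": det}, data, snr_db, rng_seed)["m"]
        rows.append({"fraction": frac, "macro_f1": f1})
    return pd.DataFrame(rows)
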