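"""YAML configuration shared by the CLI subcommands.

The file has up to three blocks mirroring the library dataclasses::

    features:  {sample_rate: 16000, mel_bins: 64, window_sec: 0.05, ...}
    detector:  {preset: tiny, input_epochs: 14, output_epochs: 10, ...}
    training:  {consistency_weight: 1.0, snr_range: [-20, 5], ...}

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .audio_features import FeatureConfig
from .detector import DetectorConfig
from .training import ClassWeights, TrainingConfig


def _build(cls, block: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown keys in {name!r} config block: {sorted(unknown)}")
    return cls(**block)


def load_config(path: str | Path | None) -> dict:
    """Load the global YAML config into dataclass instances (defaults if None)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    training_block = dict(raw.get("training", {}))
    if "snr_range" in training_block:
        training_block["snr_range"] = tuple(training_block["snr_range"])
    if "class_weights" in training_block:
        training_block["class_weights"] = _build(
            ClassWeights, training_block["class_weights"], "class_weights")
    return {
        "features": _build(FeatureConfig, dict(raw.get("features", {})),
                           "features"),
        "detector": _build(DetectorConfig, dict(raw.get("detector", {})),
                           "detector"),
        "training": _build(TrainingConfig, training_block, "training"),
    }
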