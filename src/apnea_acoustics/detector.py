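"""The 14-epoch -> 10-epoch acoustic event detector.

Two core elements mirror the architecture contract: a per-epoch feature
extractor (temporal pooling of the log-Mel spectrogram followed by a
two-layer MLP, shared across epochs) and a multiepoch detector (a valid
convolution across the epoch axis whose receptive field trims the 14 input
epochs to the middle 10, then a linear classifier per epoch).  An auxiliary
per-epoch head supports the 1-to-1 pretraining stage.

The network is plain numpy with explicit forward/backward passes so that
training is fully deterministic from a seed and runs on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .annotations import CLASS_NAMES, EpochClass
from .audio_features import (MelSpectrogram, MelWindow, pool_epoch_features,
                             pool_night_features, window_layouts)

PRESETS = {
    "tiny": (32, 32, 32),
    "small": (64, 64, 64),
    "large": (128, 128, 128),
}


@dataclass
class DetectorConfig:
    input_epochs: int = 14
    output_epochs: int = 10
    n_classes: int = 3
    preset: str = "tiny"
    feature_dim: int = 128  # 3 * mel_bins of the feature config in use
    #: standardized inputs are clipped to +/- this many training-set SDs so
    #: heavily corrupted audio cannot blow up the activations
    input_clip: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.output_epochs > self.input_epochs:
            raise ValueError("output_epochs must be <= input_epochs")
        if (self.input_epochs - self.output_epochs) % 2:
            raise ValueError("input_epochs - output_epochs must be even")
        if self.n_classes != 3:
            raise ValueError("the detector is a 3-class model")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be positive")

    @property
    def kernel(self) -> int:
        return self.input_epochs - self.output_epochs + 1


@dataclass
class EpochPrediction:
    """Per-epoch class probabilities; the argmax is the final call."""

    probabilities: np.ndarray
    predicted_class: EpochClass
    confidence: float

    @classmethod
    def from_probabilities(cls, p: np.ndarray) -> "EpochPrediction":
        p = np.asarray(p, dtype=float)
        if p.shape != (3,) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("probabilities must be a normalized triple")
        k = int(np.argmax(p))
        return cls(p, EpochClass(k), float(p[k]))


@dataclass
class NightPrediction:
    epoch_predictions: list[EpochPrediction]
    subject_id: str = ""

    @property
    def classes(self) -> list[EpochClass]:
        return [e.predicted_class for e in self.epoch_predictions]

    @property
    def probabilities(self) -> np.ndarray:
        return np.stack([e.probabilities for e in self.epoch_predictions])


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class EventDetector:
    """Numpy realization of the extractor + multiepoch detector."""

    #: parameter names grouped by unfreezing stage, deepest last
    EXTRACTOR_STAGES = (("W2", "b2"), ("W1", "b1"))

    def __init__(self, config: DetectorConfig):
        self.config = config
        h1, h2, h3 = PRESETS[config.preset]
        rng = np.random.default_rng(config.rng_seed)
        f, k, c = config.feature_dim, config.kernel, config.n_classes

        def he(shape, fan_in, scale=1.0):
            return rng.standard_normal(shape) * scale * np.sqrt(2.0 / fan_in)

        self.params: dict[str, np.ndarray] = {
            "W1": he((f, h1), f), "b1": np.zeros(h1),
            "W2": he((h1, h2), h1), "b2": np.zeros(h2),
            "Wc": he((k, h2, h3), k * h2), "bc": np.zeros(h3),
            "Wo": he((h3, c), h3, scale=0.01), "bo": np.zeros(c),
            "Wp": he((h2, c), h2, scale=0.01), "bp": np.zeros(c),
        }
        # input standardization, set from training data; identity by default
        self.feat_mean = np.zeros(f)
        self.feat_std = np.ones(f)

    def set_normalization(self, mean: np.ndarray, std: np.ndarray) -> None:
        """Fix the input standardization (from training-set statistics)."""
        self.feat_mean = np.asarray(mean, dtype=float).reshape(-1)
        self.feat_std = np.maximum(np.asarray(std, dtype=float).reshape(-1), 1e-8)
        if self.feat_mean.size != self.config.feature_dim:
            raise ValueError("normalization size does not match feature_dim")

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------
    def _extract(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        p = self.params
        c = self.config.input_clip
        x = np.clip((x - self.feat_mean) / self.feat_std, -c, c)
        a1 = x @ p["W1"] + p["b1"]
        h1 = _relu(a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = _relu(a2)
        return h2, {"x": x, "a1": a1, "h1": h1, "a2": a2}

    def forward_window(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Window logits.  ``x``: (batch, input_epochs, feature_dim)."""
        cfg, p = self.config, self.params
        if x.ndim != 3 or x.shape[1] != cfg.input_epochs or \
                x.shape[2] != cfg.feature_dim:
            raise ValueError(
                f"expected (batch, {cfg.input_epochs}, {cfg.feature_dim}), "
                f"got {x.shape}")
        h2, cache = self._extract(x)
        k = cfg.kernel
        ac = sum(h2[:, i:i + cfg.output_epochs, :] @ p["Wc"][i]
                 for i in range(k)) + p["bc"]
        hc = _relu(ac)
        z = hc @ p["Wo"] + p["bo"]
        cache.update({"h2": h2, "ac": ac, "hc": hc})
        return z, cache

    def backward_window(self, dz: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        g: dict[str, np.ndarray] = {}
        hc, ac, h2 = cache["hc"], cache["ac"], cache["h2"]
        g["Wo"] = np.einsum("bto,btc->oc", hc, dz)
        g["bo"] = dz.sum(axis=(0, 1))
        dhc = dz @ p["Wo"].T
        dac = dhc * (ac > 0)
        g["bc"] = dac.sum(axis=(0, 1))
        g["Wc"] = np.stack([
            np.einsum("bth,btc->hc", h2[:, i:i + cfg.output_epochs, :], dac)
            for i in range(cfg.kernel)])
        dh2 = np.zeros_like(h2)
        for i in range(cfg.kernel):
            dh2[:, i:i + cfg.output_epochs, :] += dac @ p["Wc"][i].T
        self._backward_extract(dh2, cache, g)
        return g

    def forward_epoch(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Per-epoch logits through the pretraining head.  ``x``: (n, feature_dim)."""
        h2, cache = self._extract(x)
        z = h2 @ self.params["Wp"] + self.params["bp"]
        cache["h2"] = h2
        return z, cache

    def backward_epoch(self, dz: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        g: dict[str, np.ndarray] = {}
        h2 = cache["h2"]
        g["Wp"] = h2.reshape(-1, h2.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
        g["bp"] = dz.reshape(-1, dz.shape[-1]).sum(axis=0)
        self._backward_extract(dz @ self.params["Wp"].T, cache, g)
        return g

    def _backward_extract(self, dh2: np.ndarray, cache: dict,
                          g: dict[str, np.ndarray]) -> None:
        p = self.params

        def mat(a, b):
            return a.reshape(-1, a.shape[-1]).T @ b.reshape(-1, b.shape[-1])

        da2 = dh2 * (cache["a2"] > 0)
        g["W2"] = mat(cache["h1"], da2)
        g["b2"] = da2.reshape(-1, da2.shape[-1]).sum(axis=0)
        da1 = (da2 @ p["W2"].T) * (cache["a1"] > 0)
        g["W1"] = mat(cache["x"], da1)
        g["b1"] = da1.reshape(-1, da1.shape[-1]).sum(axis=0)

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float,
                 trainable: set[str] | None = None) -> None:
        for name, grad in grads.items():
            if trainable is None or name in trainable:
                self.params[name] -= lr * grad

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------
    def predict_window(self, window: MelWindow | np.ndarray) -> list[EpochPrediction]:
        """Predictions for the middle ``output_epochs`` of one window."""
        if isinstance(window, MelWindow):
            if len(window.epochs) != self.config.input_epochs:
                raise ValueError("window has the wrong number of epochs")
            x = np.stack([pool_epoch_features(m) for m in window.epochs])
        else:
            x = np.asarray(window)
        z, _ = self.forward_window(x[None])
        probs = softmax(z)[0]
        return [EpochPrediction.from_probabilities(p) for p in probs]

    def predict_night(self, night: list[MelSpectrogram] | np.ndarray,
                      subject_id: str = "") -> NightPrediction:
        """One prediction per epoch, stitched from stride-10 windows.

        On the overlap created by a non-multiple-of-stride night the later
        window's prediction wins.
        """
        feats = (pool_night_features(night) if isinstance(night, list)
                 else np.asarray(night))
        if feats.ndim != 2 or feats.shape[0] < 1:
            raise ValueError("night must contain at least one epoch")
        cfg = self.config
        n = feats.shape[0]
        out = np.empty((n, cfg.n_classes))
        for lay in window_layouts(n, cfg.input_epochs, cfg.output_epochs):
            z, _ = self.forward_window(feats[lay.input_epoch_indices][None])
            probs = softmax(z)[0]
            out[lay.center_epoch_indices] = probs  # later windows overwrite
        preds = [EpochPrediction.from_probabilities(p) for p in out]
        return NightPrediction(preds, subject_id)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a self-describing checkpoint (config JSON + parameters)."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload["norm_mean"] = self.feat_mean
        payload["norm_std"] = self.feat_std
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(Path(path), **payload)

    @classmethod
    def load(cls, path: str | Path) -> "EventDetector":
        with np.load(Path(path)) as data:
            cfg = DetectorConfig(**json.loads(bytes(data["config_json"]).decode()))
            det = cls(cfg)
            for k in det.params:
                det.params[k] = data[f"param_{k}"]
            det.set_normalization(data["norm_mean"], data["norm_std"])
        return det

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


def build_detector(config: DetectorConfig) -> EventDetector:
    """Construct a detector; initialization is reproducible from the seed."""
    return EventDetector(config)


def predictions_to_frame(night: NightPrediction):
    """Night predictions as the CSV schema used by the CLI."""
    import pandas as pd

    rows = []
    for i, ep in enumerate(night.epoch_predictions):
        rows.append({
            "epoch_index": i,
            "p_no_event": ep.probabilities[0],
            "p_apnea": ep.probabilities[1],
            "p_hypopnea": ep.probabilities[2],
            "predicted_class": CLASS_NAMES[ep.predicted_class],
            "confidence": ep.confidence,
        })
    return pd.DataFrame(rows)
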