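"""Losses and the 2-step training procedure.

Step 1 (1-to-1 pretraining) trains the per-epoch extractor with a class-
weighted cross-entropy and a reduce-on-plateau learning rate: start at 0.01
and divide by 10 whenever the validation macro F1 has not improved for 3
consecutive training epochs.

Step 2 (14-to-10 training) fine-tunes the windowed model for exactly 10
training epochs of SGD under a slanted triangular learning rate with gradual
unfreezing of the pretrained extractor.  With consistency training enabled
(weight lambda > 0), every window is also corrupted by a freshly sampled
noise cover at a random SNR in [-20, 5] dB, and the loss is

    L = weighted_CE(clean prediction, labels) + lambda * MSE(clean, corrupted)

where the MSE compares the two predicted probability vectors and
backpropagates through both branches.  lambda = 0 recovers the control
model: plain supervised training on clean audio.

The checkpoint with the highest validation macro F1 is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audio_features import (AudioSignal, FeatureConfig,
                             night_mel_spectrograms, pool_night_features,
                             window_layouts)
from .detector import EventDetector, softmax
from .evaluation import confusion, epoch_metrics
from .noise import (TRAIN_SNR_RANGE, CorruptionSpec, NoiseLibrary, corrupt,
                    pitch_shift)


@dataclass
class ClassWeights:
    """Per-class loss weights countering the dominance of no-event epochs."""

    no_event: float = 1.0
    apnea: float = 1.3
    hypopnea: float = 2.1

    def __post_init__(self) -> None:
        if min(self.no_event, self.apnea, self.hypopnea) <= 0:
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.no_event, self.apnea, self.hypopnea])


@dataclass
class TrainingConfig:
    initial_lr_pretrain: float = 0.01
    lr_decay_factor: float = 10.0
    patience: int = 3
    optimizer: str = "sgd"
    n_training_epochs: int = 10
    consistency_weight: float = 1.0
    #: backpropagate the consistency term through the clean branch as well;
    #: off by default — the clean branch then acts as a fixed teacher and the
    #: supervised term alone shapes it
    consistency_through_clean: bool = False
    snr_range: tuple[float, float] = TRAIN_SNR_RANGE
    pitch_shift_prob: float = 0.0
    pitch_shift_semitones: float = 2.0
    #: SNRs of the corrupted validation copies used (with the clean copy) to
    #: select the checkpoint when consistency training is on
    val_corruption_snrs: tuple[float, ...] = (5.0, -5.0, -15.0)
    max_lr_main: float = 0.1
    stlr_warmup_frac: float = 0.1
    stlr_cut_ratio: float = 32.0
    batch_size: int = 4
    class_weights: ClassWeights = field(default_factory=ClassWeights)
    gradual_unfreeze: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError("only plain SGD is supported")
        if self.snr_range[0] >= self.snr_range[1]:
            raise ValueError("snr_range must be (low, high) with low < high")
        for name in ("initial_lr_pretrain", "lr_decay_factor", "patience",
                     "n_training_epochs", "max_lr_main", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Checkpoint:
    params: dict[str, np.ndarray]
    val_macro_f1: float
    epoch_index: int
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.val_macro_f1 <= 1.0:
            raise ValueError("validation macro F1 must lie in [0, 1]")


@dataclass
class TrainingNight:
    """One night prepared for training: pooled features, labels, raw audio.

    ``audio`` may be omitted for clean-only (control) training; consistency
    training needs it to build corrupted windows.
    """

    subject_id: str
    features: np.ndarray  # (n_epochs, feature_dim)
    labels: np.ndarray  # (n_epochs,) ints in {0,1,2}
    audio: AudioSignal | None = None
    reference_ahi: float | None = None

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def weighted_cross_entropy(predicted: np.ndarray, labels: Sequence,
                           weights: ClassWeights | np.ndarray = None,
                           eps: float = 1e-12) -> float:
    """Mean over epochs of ``-w(label) * ln p(label)`` on probability triples."""
    p = np.asarray(predicted, dtype=float).reshape(-1, 3)
    y = np.asarray([int(l) for l in labels])
    if p.shape[0] != y.size:
        raise ValueError("predictions and labels differ in length")
    if weights is None:
        weights = ClassWeights()
    w = weights.as_array() if isinstance(weights, ClassWeights) else np.asarray(weights)
    picked = p[np.arange(y.size), y]
    if (picked <= 0).any():
        warnings.warn("zero probability at a true label; clamped by epsilon")
        picked = np.maximum(picked, eps)
    return float(np.mean(-w[y] * np.log(picked)))


def consistency_loss(clean_pred: np.ndarray, corrupted_pred: np.ndarray) -> float:
    """Mean squared difference between clean and corrupted probability triples."""
    a = np.asarray(clean_pred, dtype=float)
    b = np.asarray(corrupted_pred, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction shapes differ")
    return float(np.mean((a - b) ** 2))


def combined_loss(ce: float, cons: float, lam: float) -> float:
    """Weighted sum of the supervised and consistency terms: ce + lam * cons."""
    return float(ce) + float(lam) * float(cons)


def _ce_grad_from_logits(z: np.ndarray, y: np.ndarray, w: np.ndarray
                         ) -> tuple[float, np.ndarray]:
    """Weighted CE and its gradient w.r.t. logits; shapes (..., 3)."""
    zf = z.reshape(-1, z.shape[-1])
    yf = y.reshape(-1)
    p = softmax(zf)
    n = yf.size
    loss = float(np.mean(-w[yf] * np.log(np.maximum(p[np.arange(n), yf], 1e-300))))
    onehot = np.zeros_like(p)
    onehot[np.arange(n), yf] = 1.0
    dz = (w[yf, None] * (p - onehot)) / n
    return loss, dz.reshape(z.shape)


def _consistency_grad_from_logits(z_clean: np.ndarray, z_corr: np.ndarray
                                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """MSE between softmax outputs and its gradients w.r.t. both logit sets."""
    pc = softmax(z_clean)
    pn = softmax(z_corr)
    diff = pc - pn
    loss = float(np.mean(diff ** 2))
    g = 2.0 * diff / diff.size

    def chain(p, gp):
        return p * (gp - (gp * p).sum(axis=-1, keepdims=True))

    return loss, chain(pc, g), chain(pn, -g)


# ---------------------------------------------------------------------------
# learning-rate schedules
# ---------------------------------------------------------------------------

class PlateauScheduler:
    """Divide the LR by ``factor`` after ``patience`` stagnant validations."""

    def __init__(self, initial_lr: float, factor: float = 10.0,
                 patience: int = 3):
        self.lr = float(initial_lr)
        self.factor = float(factor)
        self.patience = int(patience)
        self.best = -np.inf
        self.stagnant = 0
        self.n_decays = 0

    def update(self, metric: float) -> float:
        """Report one validation metric; returns the LR for the next epoch."""
        if metric > self.best:
            self.best = metric
            self.stagnant = 0
        else:
            self.stagnant += 1
            if self.stagnant >= self.patience:
                self.lr /= self.factor
                self.n_decays += 1
                self.stagnant = 0
        return self.lr


def slanted_triangular_lr(step: int, total_steps: int, max_lr: float,
                          warmup_frac: float = 0.1,
                          cut_ratio: float = 32.0) -> float:
    """Linear warmup to ``max_lr`` then linear decay to ``max_lr / cut_ratio``."""
    if total_steps <= 1:
        return max_lr
    cut = max(1, int(total_steps * warmup_frac))
    if step < cut:
        p = step / cut
    else:
        p = 1.0 - (step - cut) / max(total_steps - cut, 1)
    return max_lr * (1.0 + p * (cut_ratio - 1.0)) / cut_ratio


# ---------------------------------------------------------------------------
# validation helper
# ---------------------------------------------------------------------------

def _validation_macro_f1(detector: EventDetector,
                         nights: Sequence[TrainingNight],
                         extra_features: Sequence[tuple[np.ndarray, np.ndarray]]
                         = ()) -> float:
    refs, preds = [], []
    for night in nights:
        pred = detector.predict_night(night.features)
        preds.extend(int(c) for c in pred.classes)
        refs.extend(int(l) for l in night.labels)
    for feats, labels in extra_features:
        pred = detector.predict_night(feats)
        preds.extend(int(c) for c in pred.classes)
        refs.extend(int(l) for l in labels)
    return epoch_metrics(confusion(refs, preds)).macro_f1


def _corrupted_validation_copies(val_nights: Sequence[TrainingNight],
                                 noise_library: NoiseLibrary,
                                 feature_config: FeatureConfig,
                                 snrs: Sequence[float], rng_seed: int,
                                 categories: tuple[str, ...] | None
                                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Noise-corrupted feature copies of the validation nights.

    Consistency training selects its checkpoint on clean plus corrupted
    validation copies, mirroring the simulated-home distribution it trains
    for; the copies are fixed up front so selection is consistent across
    training epochs.
    """
    cats = categories or tuple(sorted({c.category
                                       for c in noise_library.clips}))
    copies = []
    for i, night in enumerate(val_nights):
        if night.audio is None:
            raise ValueError("corrupted validation copies need night audio")
        for j, snr in enumerate(snrs):
            spec = CorruptionSpec(snr_db=float(snr), categories=cats,
                                  rng_seed=rng_seed + 101 * i + j,
                                  split="train")
            noisy = corrupt(night.audio, noise_library, spec)
            feats = _pooled_from_audio(noisy, feature_config,
                                       night.n_epochs)
            copies.append((feats, night.labels))
    return copies


def fit_normalization(detector: EventDetector,
                      nights: Sequence[TrainingNight]) -> None:
    """Standardize detector inputs with training-set feature statistics."""
    feats = np.concatenate([n.features for n in nights], axis=0)
    detector.set_normalization(feats.mean(axis=0), feats.std(axis=0))


# ---------------------------------------------------------------------------
# step 1: 1-to-1 pretraining
# ---------------------------------------------------------------------------

def pretrain_1to1(detector: EventDetector,
                  train_nights: Sequence[TrainingNight],
                  val_nights: Sequence[TrainingNight],
                  config: TrainingConfig) -> Checkpoint:
    """Train the per-epoch classifier (extractor + epoch head) on single epochs."""
    if not train_nights:
        raise ValueError("no training nights")
    x = np.concatenate([n.features for n in train_nights], axis=0)
    y = np.concatenate([n.labels for n in train_nights], axis=0).astype(int)
    w = config.class_weights.as_array()
    rng = np.random.default_rng(config.rng_seed)
    sched = PlateauScheduler(config.initial_lr_pretrain,
                             config.lr_decay_factor, config.patience)
    batch = max(config.batch_size * 16, 64)  # plain per-epoch rows, cheap

    best = Checkpoint(detector.copy_params(), 0.0, -1)
    lr = sched.lr
    log: list[dict] = []
    for ep in range(config.n_training_epochs):
        order = rng.permutation(y.size)
        losses = []
        for i in range(0, y.size, batch):
            idx = order[i:i + batch]
            z, cache = detector.forward_epoch(x[idx])
            loss, dz = _ce_grad_from_logits(z, y[idx], w)
            detector.sgd_step(detector.backward_epoch(dz, cache), lr)
            losses.append(loss)
        val_f1 = _validation_macro_f1_epochwise(detector, val_nights)
        log.append({"stage": "pretrain", "epoch": ep, "lr": lr,
                    "train_ce": float(np.mean(losses)), "val_macro_f1": val_f1})
        if val_f1 > best.val_macro_f1 or best.epoch_index < 0:
            best = Checkpoint(detector.copy_params(), val_f1, ep)
        lr = sched.update(val_f1)
    best.log = log
    detector.set_params(best.params)
    return best


def _validation_macro_f1_epochwise(detector: EventDetector,
                                   nights: Sequence[TrainingNight]) -> float:
    refs, preds = [], []
    for night in nights:
        z, _ = detector.forward_epoch(night.features)
        preds.extend(np.argmax(z, axis=1).tolist())
        refs.extend(int(l) for l in night.labels)
    return epoch_metrics(confusion(refs, preds)).macro_f1


# ---------------------------------------------------------------------------
# step 2: 14-to-10 training (consistency or control)
# ---------------------------------------------------------------------------

def _window_audio(night: TrainingNight, input_indices: np.ndarray,
                  sample_rate: int, epoch_seconds: float = 30.0) -> AudioSignal:
    n = int(round(epoch_seconds * sample_rate))
    parts = [night.audio.samples[i * n:(i + 1) * n] for i in input_indices]
    return AudioSignal(np.concatenate(parts), sample_rate)


def _pooled_from_audio(audio: AudioSignal, feature_config: FeatureConfig,
                       n_epochs: int) -> np.ndarray:
    mels = night_mel_spectrograms(audio, feature_config)
    if len(mels) < n_epochs:
        raise RuntimeError("window audio does not split into the expected epochs")
    return pool_night_features(mels[:n_epochs])


def train_14to10(detector: EventDetector,
                 train_nights: Sequence[TrainingNight],
                 val_nights: Sequence[TrainingNight],
                 config: TrainingConfig,
                 noise_library: NoiseLibrary | None = None,
                 feature_config: FeatureConfig | None = None,
                 pretrained: Checkpoint | None = None,
                 noise_categories: Sequence[str] | None = None) -> Checkpoint:
    """Fine-tune the windowed detector; lambda = 0 is the clean-only control.

    Each iteration with lambda > 0 draws, per window, one pitch-shift decision,
    one noise cover from the training split of ``noise_library`` and one SNR
    uniform in ``config.snr_range``, forms the corrupted window, and descends
    the combined loss.  SNR draws are recorded in the returned checkpoint log.
    """
    if not train_nights:
        raise ValueError("no training nights")
    if config.gradual_unfreeze and pretrained is None:
        raise ValueError("gradual unfreezing requires a pretrained extractor")
    lam = config.consistency_weight
    if lam > 0:
        if noise_library is None or feature_config is None:
            raise ValueError("consistency training needs a noise library and "
                             "a feature configuration")
        for night in train_nights:
            if night.audio is None:
                raise ValueError("consistency training needs night audio")
    if pretrained is not None:
        detector.set_params(pretrained.params)

    cfg_d = detector.config
    windows = [(ni, lay) for ni, night in enumerate(train_nights)
               for lay in window_layouts(night.n_epochs, cfg_d.input_epochs,
                                         cfg_d.output_epochs)]
    w = config.class_weights.as_array()
    rng = np.random.default_rng(config.rng_seed)
    total_steps = config.n_training_epochs * max(
        1, int(np.ceil(len(windows) / config.batch_size)))
    cats = tuple(noise_categories) if noise_categories else None
    val_copies: list[tuple[np.ndarray, np.ndarray]] = []
    if lam > 0 and val_nights:
        val_copies = _corrupted_validation_copies(
            val_nights, noise_library, feature_config,
            config.val_corruption_snrs, config.rng_seed + 90_001, cats)

    best = Checkpoint(detector.copy_params(), 0.0, -1)
    log: list[dict] = []
    step = 0
    for ep in range(config.n_training_epochs):
        trainable = _trainable_at_stage(detector, config, ep)
        order = rng.permutation(len(windows))
        ep_ce, ep_cons, ep_snrs = [], [], []
        for i in range(0, len(order), config.batch_size):
            chunk = order[i:i + config.batch_size]
            x_clean, x_corr, y = [], [], []
            for j in chunk:
                ni, lay = windows[j]
                night = train_nights[ni]
                y.append(night.labels[lay.center_epoch_indices])
                if lam == 0:
                    x_clean.append(night.features[lay.input_epoch_indices])
                    continue
                audio = _window_audio(night, lay.input_epoch_indices,
                                      feature_config.sample_rate)
                if rng.random() < config.pitch_shift_prob:
                    semis = rng.uniform(-config.pitch_shift_semitones,
                                        config.pitch_shift_semitones)
                    audio = pitch_shift(audio, semis)
                    x_clean.append(_pooled_from_audio(
                        audio, feature_config, cfg_d.input_epochs))
                else:
                    x_clean.append(night.features[lay.input_epoch_indices])
                snr = rng.uniform(*config.snr_range)
                ep_snrs.append(snr)
                spec = CorruptionSpec(
                    snr_db=snr, rng_seed=int(rng.integers(2 ** 31)),
                    categories=cats or tuple(
                        sorted({c.category for c in noise_library.clips})),
                    split="train")
                x_corr.append(_pooled_from_audio(
                    corrupt(audio, noise_library, spec), feature_config,
                    cfg_d.input_epochs))
            xb = np.stack(x_clean)
            yb = np.stack(y).astype(int)
            lr = slanted_triangular_lr(step, total_steps, config.max_lr_main,
                                       config.stlr_warmup_frac,
                                       config.stlr_cut_ratio)
            z_clean, cache_c = detector.forward_window(xb)
            ce, dz_clean = _ce_grad_from_logits(z_clean, yb, w)
            if lam > 0:
                z_corr, cache_n = detector.forward_window(np.stack(x_corr))
                cons, dc, dn = _consistency_grad_from_logits(z_clean, z_corr)
                if config.consistency_through_clean:
                    dz_clean = dz_clean + lam * dc
                grads = detector.backward_window(dz_clean, cache_c)
                for k, v in detector.backward_window(lam * dn, cache_n).items():
                    grads[k] = grads[k] + v
            else:
                cons = 0.0
                grads = detector.backward_window(dz_clean, cache_c)
            detector.sgd_step(grads, lr, trainable)
            ep_ce.append(ce)
            ep_cons.append(cons)
            step += 1
        val_f1 = _validation_macro_f1(detector, val_nights, val_copies)
        log.append({"stage": "14to10", "epoch": ep,
                    "train_ce": float(np.mean(ep_ce)),
                    "train_consistency": float(np.mean(ep_cons)),
                    "val_macro_f1": val_f1,
                    "val_clean_macro_f1": _validation_macro_f1(detector,
                                                               val_nights),
                    "snrs": ep_snrs})
        if val_f1 > best.val_macro_f1 or best.epoch_index < 0:
            best = Checkpoint(detector.copy_params(), val_f1, ep)
    best.log = log
    detector.set_params(best.params)
    return best


def _trainable_at_stage(detector: EventDetector, config: TrainingConfig,
                        training_epoch: int) -> set[str] | None:
    """Gradual unfreezing: detector head first, then one extractor stage per epoch."""
    if not config.gradual_unfreeze:
        return None
    names = {"Wc", "bc", "Wo", "bo", "Wp", "bp"}
    for stage in range(min(training_epoch, len(EventDetector.EXTRACTOR_STAGES))):
        names.update(EventDetector.EXTRACTOR_STAGES[stage])
    return names
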