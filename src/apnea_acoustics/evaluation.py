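"""Epoch-level, screening and agreement metrics.

Epoch metrics (accuracy, Cohen kappa, macro F1, one-vs-rest sensitivity and
specificity) are computed directly from the confusion matrix.  Screening
metrics binarize the reference AHI at a cutoff and score the estimated AHI
both as a binary decision (sensitivity/specificity at the same cutoff) and as
a continuous score (AUC).  Agreement between estimated and reference AHI is
summarized Bland-Altman style: mean difference, 1.96 SD limits, MAE and the
Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .annotations import CLASS_NAMES

__all__ = [
    "ConfusionMatrix", "EpochMetrics", "ScreeningMetrics", "AgreementStats",
    "confusion", "epoch_metrics", "collapse_two_class", "screening",
    "bland_altman", "confidence_summary",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = reference class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EpochMetrics:
    accuracy: float
    macro_f1: float
    cohen_kappa: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    per_class_f1: dict[str, float]


@dataclass
class ScreeningMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass
class AgreementStats:
    mean_difference: float
    loa_lower: float
    loa_upper: float
    mean_absolute_error: float
    correlation: float  # NaN flags an undefined (zero-variance) correlation


def _as_int_labels(seq) -> np.ndarray:
    return np.asarray([int(s) for s in seq], dtype=np.int64)


def confusion(reference, predicted, class_names: tuple[str, ...] = CLASS_NAMES
              ) -> ConfusionMatrix:
    """Confusion counts; ``reference`` and ``predicted`` are label sequences."""
    ref = _as_int_labels(reference)
    pred = _as_int_labels(predicted)
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction lengths differ")
    k = len(class_names)
    if ref.size and (ref.min() < 0 or ref.max() >= k or
                     pred.min() < 0 or pred.max() >= k):
        raise ValueError("labels out of range for the class set")
    counts = np.bincount(ref * k + pred, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, class_names)


def epoch_metrics(cm: ConfusionMatrix) -> EpochMetrics:
    """Accuracy, macro F1, Cohen kappa and one-vs-rest sensitivity/specificity."""
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    ref_tot = c.sum(axis=1)
    pred_tot = c.sum(axis=0)

    accuracy = tp.sum() / total
    pe = (ref_tot * pred_tot).sum() / total ** 2
    kappa = 1.0 if pe == 1.0 else (accuracy - pe) / (1.0 - pe)

    f1s, sens, spec = {}, {}, {}
    for i, name in enumerate(cm.class_names):
        if ref_tot[i] == 0 and pred_tot[i] == 0:
            warnings.warn(f"class {name!r} absent from reference and "
                          "prediction; its F1 is reported as 0")
            f1s[name] = 0.0
        else:
            f1s[name] = 2 * tp[i] / (ref_tot[i] + pred_tot[i])
        sens[name] = tp[i] / ref_tot[i] if ref_tot[i] else np.nan
        tn = total - ref_tot[i] - pred_tot[i] + tp[i]
        neg = total - ref_tot[i]
        spec[name] = tn / neg if neg else np.nan
    return EpochMetrics(
        accuracy=float(accuracy),
        macro_f1=float(np.mean(list(f1s.values()))),
        cohen_kappa=float(kappa),
        sensitivity=sens, specificity=spec, per_class_f1=f1s,
    )


def collapse_two_class(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Merge apnea and hypopnea into one apneic class (2x2 matrix)."""
    if len(cm.class_names) != 3:
        raise ValueError("expected a 3-class confusion matrix")
    c = cm.counts
    merged = np.array([
        [c[0, 0], c[0, 1] + c[0, 2]],
        [c[1, 0] + c[2, 0], c[1:, 1:].sum()],
    ])
    return ConfusionMatrix(merged, ("no_event", "apnea_hypopnea"))


def screening(reference_ahis, estimated_ahis, cutoff: float) -> ScreeningMetrics:
    """OSA screening at one AHI cutoff.

    Sensitivity/specificity compare the binarized estimate against the
    binarized reference; AUC treats the continuous estimate as the score
    (midrank tie handling).  AUC is NaN when one class is absent.
    """
    ref = np.asarray(reference_ahis, dtype=float)
    est = np.asarray(estimated_ahis, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ValueError("reference and estimate vectors must match")
    ref_pos = ref >= cutoff
    est_pos = est >= cutoff
    pos, neg = ref_pos.sum(), (~ref_pos).sum()
    sensitivity = (est_pos & ref_pos).sum() / pos if pos else np.nan
    specificity = (~est_pos & ~ref_pos).sum() / neg if neg else np.nan
    auc = roc_auc_score(ref_pos, est) if 0 < pos < ref.size else np.nan
    return ScreeningMetrics(cutoff=float(cutoff), sensitivity=float(sensitivity),
                            specificity=float(specificity), auc=float(auc))


def bland_altman(reference_ahis, estimated_ahis) -> AgreementStats:
    """Bland-Altman agreement of estimated vs reference AHI.

    Differences are estimate minus reference; limits of agreement are the
    mean difference +/- 1.96 sample SD.  Correlation is Pearson's r, NaN
    (with a warning) when either vector has zero variance.
    """
    ref = np.asarray(reference_ahis, dtype=float)
    est = np.asarray(estimated_ahis, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1 or ref.size < 1:
        raise ValueError("need matching nonempty vectors")
    diff = est - ref
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    if ref.std() == 0 or est.std() == 0:
        warnings.warn("zero-variance input; correlation undefined (NaN)")
        corr = np.nan
    else:
        corr = float(stats.pearsonr(ref, est).statistic)
    return AgreementStats(
        mean_difference=mean_diff,
        loa_lower=mean_diff - 1.96 * sd,
        loa_upper=mean_diff + 1.96 * sd,
        mean_absolute_error=float(np.abs(diff).mean()),
        correlation=corr,
    )


def confidence_summary(night_probabilities: np.ndarray, predicted, reference
                       ) -> tuple[float, float]:
    """Mean confidence (max probability) over correct and incorrect epochs.

    Returns ``(mean_correct, mean_incorrect)``; a partition with no members
    yields NaN for its mean.
    """
    probs = np.asarray(night_probabilities, dtype=float)
    pred = _as_int_labels(predicted)
    ref = _as_int_labels(reference)
    if probs.shape[0] != pred.size or pred.size != ref.size:
        raise ValueError("probabilities, predictions and references must align")
    conf = probs.max(axis=1)
    correct = pred == ref
    mean_c = float(conf[correct].mean()) if correct.any() else np.nan
    mean_i = float(conf[~correct].mean()) if (~correct).any() else np.nan
    return mean_c, mean_i


def bland_altman_plot(reference_ahis, estimated_ahis, path) -> None:
    """Write a Bland-Altman plot (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference_ahis, dtype=float)
    est = np.asarray(estimated_ahis, dtype=float)
    stats_ = bland_altman(ref, est)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + est) / 2, est - ref, s=14)
    for y, style in ((stats_.mean_difference, "-"),
                     (stats_.loa_lower, "--"), (stats_.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of estimated and reference AHI (events/h)")
    ax.set_ylabel("estimated - reference AHI (events/h)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
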