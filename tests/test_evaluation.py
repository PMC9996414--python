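"""Metric correctness against independent reference implementations."""

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, cohen_kappa_score, f1_score,
                             roc_auc_score)

from apnea_acoustics.evaluation import (ConfusionMatrix, bland_altman,
                                        collapse_two_class,
                                        confidence_summary, confusion,
                                        epoch_metrics, screening)


def labels_from_cm(counts):
    """Expand a confusion matrix back into reference/prediction vectors."""
    ref, pred = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            ref.extend([i] * counts[i, j])
            pred.extend([j] * counts[i, j])
    return np.array(ref), np.array(pred)


class TestConfusion:
    def test_identical_sequences_diagonal(self):
        cm = confusion([0, 1, 2, 1], [0, 1, 2, 1])
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_enumerated_counts(self):
        cm = confusion([1, 1, 0], [1, 0, 0])
        assert cm.counts[1, 1] == 1 and cm.counts[1, 0] == 1
        assert cm.counts[0, 0] == 1 and cm.total == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestEpochMetrics:
    def test_perfect_diagonal(self):
        m = epoch_metrics(ConfusionMatrix(np.diag([5, 5, 5])))
        assert m.accuracy == 1.0 and m.macro_f1 == 1.0 and m.cohen_kappa == 1.0

    def test_hand_computed_case(self):
        cm = ConfusionMatrix(np.array([[90, 5, 5], [10, 80, 10], [20, 30, 50]]))
        m = epoch_metrics(cm)
        assert m.accuracy == pytest.approx(220 / 300, abs=1e-9)
        assert m.macro_f1 == pytest.approx(0.722810, abs=1e-6)
        assert m.sensitivity["no_event"] == pytest.approx(0.9)
        assert m.specificity["apnea"] == pytest.approx(1 - 35 / 200, abs=1e-9)

    def test_matches_sklearn_on_random_matrices(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 40, size=(3, 3))
            counts[0, 0] += 1  # nonempty
            ref, pred = labels_from_cm(counts)
            m = epoch_metrics(ConfusionMatrix(counts))
            assert m.accuracy == pytest.approx(
                accuracy_score(ref, pred), abs=1e-9)
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    expect_f1 = f1_score(ref, pred, average="macro",
                                         labels=[0, 1, 2], zero_division=0)
                    expect_k = cohen_kappa_score(ref, pred, labels=[0, 1, 2])
                    got = m.macro_f1
            assert got == pytest.approx(expect_f1, abs=1e-9)
            if np.isfinite(expect_k):
                assert m.cohen_kappa == pytest.approx(expect_k, abs=1e-9)

    def test_kappa_near_zero_under_independence(self):
        g = np.random.default_rng(77)
        ref = g.integers(0, 3, size=10_000)
        pred = g.integers(0, 3, size=10_000)
        m = epoch_metrics(confusion(ref, pred))
        assert abs(m.cohen_kappa) < 0.05

    def test_absent_class_warns_and_scores_zero(self):
        counts = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="hypopnea"):
            m = epoch_metrics(ConfusionMatrix(counts))
        assert m.per_class_f1["hypopnea"] == 0.0


class TestCollapseTwoClass:
    def test_diagonal_stays_diagonal(self):
        cm = ConfusionMatrix(np.diag([4, 3, 2]))
        two = collapse_two_class(cm)
        assert np.array_equal(two.counts, np.array([[4, 0], [0, 5]]))

    def test_hypopnea_called_apnea_becomes_correct(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[2, 1] = 7  # hypopnea predicted as apnea
        two = collapse_two_class(ConfusionMatrix(counts))
        assert two.counts[1, 1] == 7

    def test_totals_preserved(self, rng):
        counts = rng.integers(0, 20, size=(3, 3))
        cm = ConfusionMatrix(counts)
        assert collapse_two_class(cm).total == cm.total

    def test_two_class_accuracy_never_lower(self, rng):
        for _ in range(25):
            counts = rng.integers(0, 30, size=(3, 3))
            counts[0, 0] += 1
            cm = ConfusionMatrix(counts)
            assert epoch_metrics(collapse_two_class(cm)).accuracy >= \
                epoch_metrics(cm).accuracy - 1e-12


class TestScreening:
    def test_perfect_estimates(self):
        m = screening([2, 10, 20, 40], [2, 10, 20, 40], 15)
        assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.auc == 1.0

    def test_constant_estimate_gives_half_auc(self):
        m = screening([2, 10, 20, 40], [9, 9, 9, 9], 15)
        assert m.auc == pytest.approx(0.5)

    def test_enumerated_two_by_two(self):
        m = screening([4, 10, 20, 40], [3, 12, 25, 38], 15)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        ref = rng.uniform(0, 50, 40)
        est = rng.uniform(0, 50, 40)
        a = screening(ref, est, 15).auc
        b = screening(ref, np.exp(est / 10), 15).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        ref = rng.uniform(0, 50, 60)
        est = ref + rng.normal(0, 8, 60)
        m = screening(ref, est, 15)
        assert m.auc == pytest.approx(
            roc_auc_score(ref >= 15, est), abs=1e-12)


class TestBlandAltman:
    def test_identical_vectors(self):
        s = bland_altman([1.0, 5.0, 9.0], [1.0, 5.0, 9.0])
        assert s.mean_difference == 0.0
        assert (s.loa_lower, s.loa_upper) == (0.0, 0.0)
        assert s.mean_absolute_error == 0.0
        assert s.correlation == pytest.approx(1.0)

    def test_constant_offset(self):
        s = bland_altman([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert s.mean_difference == pytest.approx(2.0)
        assert s.loa_lower == pytest.approx(2.0) and s.loa_upper == pytest.approx(2.0)

    def test_hand_computed_case(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            s = bland_altman([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert s.mean_difference == pytest.approx(0.0)
        assert s.loa_upper == pytest.approx(1.96)
        assert s.loa_lower == pytest.approx(-1.96)
        assert s.mean_absolute_error == pytest.approx(2 / 3)
        assert np.isnan(s.correlation)

    def test_limits_symmetric_about_mean(self, rng):
        ref = rng.uniform(0, 50, 30)
        est = ref + rng.normal(0, 5, 30)
        s = bland_altman(ref, est)
        mid = (s.loa_lower + s.loa_upper) / 2
        assert mid == pytest.approx(s.mean_difference, abs=1e-12)


class TestConfidenceSummary:
    def test_trained_model_more_confident_when_correct(self):
        from test_training import tiny_nights

        from apnea_acoustics.detector import DetectorConfig, build_detector
        from apnea_acoustics.training import (TrainingConfig,
                                              fit_normalization,
                                              pretrain_1to1, train_14to10)

        cfg, nights = tiny_nights(seed=300, n_nights=4, duration_hours=0.25)
        train, val = nights[:3], nights[3:]
        tc = TrainingConfig(rng_seed=5, consistency_weight=0.0,
                            n_training_epochs=5)
        det = build_detector(DetectorConfig(
            preset="tiny", feature_dim=train[0].features.shape[1],
            rng_seed=5))
        fit_normalization(det, train)
        pre = pretrain_1to1(det, train, val, tc)
        train_14to10(det, train, val, tc, pretrained=pre)
        night = val[0]
        pred = det.predict_night(night.features)
        mean_correct, mean_incorrect = confidence_summary(
            pred.probabilities, [int(c) for c in pred.classes], night.labels)
        assert mean_correct > mean_incorrect

    def test_all_correct(self):
        probs = np.array([[0.9, 0.05, 0.05], [0.9, 0.05, 0.05]])
        mean_c, mean_i = confidence_summary(probs, [0, 0], [0, 0])
        assert mean_c == pytest.approx(0.9)
        assert np.isnan(mean_i)

    def test_mixed_partition(self):
        probs = np.array([[0.8, 0.1, 0.1], [0.6, 0.3, 0.1]])
        mean_c, mean_i = confidence_summary(probs, [0, 0], [0, 1])
        assert mean_c == pytest.approx(0.8)
        assert mean_i == pytest.approx(0.6)
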