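"""Loss closed forms, LR schedules, gradients, and the 2-step procedure."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from apnea_acoustics.audio_features import AudioSignal, FeatureConfig, \
    night_mel_spectrograms, pool_night_features
from apnea_acoustics.detector import DetectorConfig, build_detector, softmax
from apnea_acoustics.synthetic import SyntheticNightSpec, generate_night, \
    generate_noise_library
from apnea_acoustics.training import (Checkpoint, ClassWeights,
                                      PlateauScheduler, TrainingConfig,
                                      TrainingNight, _ce_grad_from_logits,
                                      _consistency_grad_from_logits,
                                      combined_loss, consistency_loss,
                                      fit_normalization, pretrain_1to1,
                                      slanted_triangular_lr, train_14to10,
                                      weighted_cross_entropy)
from apnea_acoustics.annotations import label_night


class TestLossClosedForms:
    def test_perfect_one_hot_gives_zero(self):
        pred = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assert weighted_cross_entropy(pred, [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_hypopnea_weighted(self):
        pred = np.array([[1 / 3, 1 / 3, 1 / 3]])
        assert weighted_cross_entropy(pred, [2]) == pytest.approx(
            2.1 * np.log(3), abs=1e-9)

    def test_uniform_no_event(self):
        pred = np.array([[1 / 3, 1 / 3, 1 / 3]])
        assert weighted_cross_entropy(pred, [0]) == pytest.approx(
            np.log(3), abs=1e-9)

    def test_zero_probability_clamped_with_warning(self):
        pred = np.array([[0.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="clamped"):
            loss = weighted_cross_entropy(pred, [0])
        assert np.isfinite(loss)

    def test_consistency_identical_zero(self):
        p = np.array([[0.2, 0.3, 0.5]])
        assert consistency_loss(p, p) == 0.0

    def test_consistency_hand_case(self):
        a = np.array([[0.2, 0.3, 0.5]])
        b = np.array([[0.4, 0.3, 0.3]])
        assert consistency_loss(a, b) == pytest.approx(0.08 / 3, abs=1e-9)

    def test_consistency_opposite_one_hot(self):
        a = np.array([[1.0, 0.0, 0.0]])
        b = np.array([[0.0, 1.0, 0.0]])
        assert consistency_loss(a, b) == pytest.approx(2 / 3, abs=1e-9)

    @pytest.mark.parametrize("ce,cons,lam,expected", [
        (1.0, 0.5, 0.0, 1.0),
        (1.0, 0.5, 1.0, 1.5),
        (2.0, 0.25, 2.0, 2.5),
    ])
    def test_combined_loss(self, ce, cons, lam, expected):
        assert combined_loss(ce, cons, lam) == pytest.approx(expected)

    def test_combined_monotone(self):
        assert combined_loss(1.1, 0.5, 1.0) >= combined_loss(1.0, 0.5, 1.0)
        assert combined_loss(1.0, 0.6, 1.0) >= combined_loss(1.0, 0.5, 1.0)


class TestSchedules:
    def test_plateau_decays_after_three_stagnant_epochs(self):
        sched = PlateauScheduler(0.01, 10.0, 3)
        for f1 in [0.5, 0.5, 0.5, 0.5]:
            lr = sched.update(f1)
        assert lr == pytest.approx(0.001)
        assert sched.n_decays == 1

    def test_plateau_no_decay_when_improving(self):
        sched = PlateauScheduler(0.01, 10.0, 3)
        for f1 in [0.1, 0.2, 0.3, 0.4, 0.5]:
            lr = sched.update(f1)
        assert lr == pytest.approx(0.01)
        assert sched.n_decays == 0

    def test_slanted_triangle_shape(self):
        total, max_lr = 100, 0.2
        lrs = [slanted_triangular_lr(t, total, max_lr) for t in range(total)]
        peak = int(np.argmax(lrs))
        assert peak == 10  # warmup fraction 0.1
        assert lrs[peak] == pytest.approx(max_lr)
        assert all(a <= b + 1e-12 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))
        assert all(a >= b - 1e-12 for a, b in zip(lrs[peak:], lrs[peak + 1:]))
        assert min(lrs) >= max_lr / 32 - 1e-12


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        det = build_detector(DetectorConfig(preset="tiny", feature_dim=6,
                                            rng_seed=2))
        x_clean = rng.standard_normal((2, 14, 6))
        x_corr = rng.standard_normal((2, 14, 6))
        y = rng.integers(0, 3, size=(2, 10))
        w = ClassWeights().as_array()
        lam = 1.0

        def loss_value():
            zc, _ = det.forward_window(x_clean)
            zn, _ = det.forward_window(x_corr)
            ce, _ = _ce_grad_from_logits(zc, y, w)
            cons, _, _ = _consistency_grad_from_logits(zc, zn)
            return ce + lam * cons

        zc, cache_c = det.forward_window(x_clean)
        zn, cache_n = det.forward_window(x_corr)
        _, dz_ce = _ce_grad_from_logits(zc, y, w)
        _, dc, dn = _consistency_grad_from_logits(zc, zn)
        grads = det.backward_window(dz_ce + lam * dc, cache_c)
        for k, v in det.backward_window(lam * dn, cache_n).items():
            grads[k] = grads[k] + v

        eps = 1e-6
        rng_idx = np.random.default_rng(0)
        for name in ("W1", "W2", "Wc", "Wo", "b2", "bc"):
            param = det.params[name]
            for _ in range(4):
                idx = tuple(rng_idx.integers(s) for s in param.shape)
                orig = param[idx]
                param[idx] = orig + eps
                up = loss_value()
                param[idx] = orig - eps
                down = loss_value()
                param[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)


def tiny_nights(seed, n_nights=2, duration_hours=1 / 6, rate=2000):
    """Small synthetic nights with audio, prepared for training."""
    cfg = FeatureConfig(sample_rate=rate, mel_bins=16, window_sec=0.064,
                        hop_sec=0.032)
    nights = []
    for i in range(n_nights):
        spec = SyntheticNightSpec(duration_hours=duration_hours,
                                  target_event_rate=20, rng_seed=seed + i)
        audio, events, ahi = generate_night(spec, rate)
        labeled = label_night(events, audio.duration)
        mels = night_mel_spectrograms(audio, cfg)
        nights.append(TrainingNight(
            subject_id=f"n{i}", features=pool_night_features(mels),
            labels=np.array([int(l) for l in labeled.labels])[:len(mels)],
            audio=audio, reference_ahi=ahi))
    return cfg, nights


@pytest.fixture(scope="module")
def tiny_setup():
    cfg, nights = tiny_nights(seed=100, n_nights=3)
    library = generate_noise_library(sample_rate=2000, clip_seconds=30,
                                     clips_per_category=2, rng_seed=5)
    return cfg, nights[:2], nights[2:], library


def quick_config(**kw):
    defaults = dict(rng_seed=3, n_training_epochs=3, batch_size=4,
                    pitch_shift_prob=0.25)
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestPretraining:
    def test_checkpoint_stores_best_validation_f1(self, tiny_setup):
        cfg, train, val, _ = tiny_setup
        det = build_detector(DetectorConfig(
            preset="tiny", feature_dim=train[0].features.shape[1], rng_seed=1))
        fit_normalization(det, train)
        ckpt = pretrain_1to1(det, train, val, quick_config())
        history = [row["val_macro_f1"] for row in ckpt.log]
        assert ckpt.val_macro_f1 == pytest.approx(max(history))
        assert ckpt.epoch_index == int(np.argmax(history))

    def test_empty_training_set_rejected(self, tiny_setup):
        cfg, train, val, _ = tiny_setup
        det = build_detector(DetectorConfig(
            preset="tiny", feature_dim=train[0].features.shape[1]))
        with pytest.raises(ValueError):
            pretrain_1to1(det, [], val, quick_config())


class TestTrain14to10:
    def _detector(self, train, seed=1):
        det = build_detector(DetectorConfig(
            preset="tiny", feature_dim=train[0].features.shape[1],
            rng_seed=seed))
        fit_normalization(det, train)
        return det

    def test_unfreezing_requires_pretraining(self, tiny_setup):
        cfg, train, val, lib = tiny_setup
        det = self._detector(train)
        with pytest.raises(ValueError, match="pretrained"):
            train_14to10(det, train, val, quick_config(), noise_library=lib,
                         feature_config=cfg, pretrained=None)

    def test_snr_draws_stay_in_range_and_logged(self, tiny_setup):
        cfg, train, val, lib = tiny_setup
        det = self._detector(train)
        pre = pretrain_1to1(det, train, val, quick_config())
        ckpt = train_14to10(det, train, val, quick_config(), noise_library=lib,
                           feature_config=cfg, pretrained=pre)
        snrs = [s for row in ckpt.log for s in row["snrs"]]
        assert len(snrs) > 0
        assert all(-20.0 <= s <= 5.0 for s in snrs)

    def test_lambda_zero_is_clean_supervised_control(self, tiny_setup):
        cfg, train, val, lib = tiny_setup
        results = []
        for library in (lib, None):  # the control path never touches noise
            det = self._detector(train)
            pre = pretrain_1to1(det, train, val,
                                quick_config(consistency_weight=0.0))
            ckpt = train_14to10(det, train, val,
                               quick_config(consistency_weight=0.0),
                               noise_library=library, feature_config=cfg,
                               pretrained=pre)
            assert all(row["train_consistency"] == 0.0 for row in ckpt.log)
            assert all(len(row["snrs"]) == 0 for row in ckpt.log)
            results.append([row["train_ce"] for row in ckpt.log])
        assert results[0] == results[1]

    def test_seeded_trajectories_bit_identical(self, tiny_setup):
        cfg, train, val, lib = tiny_setup
        histories = []
        for _ in range(2):
            det = self._detector(train)
            pre = pretrain_1to1(det, train, val, quick_config())
            ckpt = train_14to10(det, train, val, quick_config(),
                               noise_library=lib, feature_config=cfg,
                               pretrained=pre)
            histories.append(([row["train_ce"] for row in ckpt.log],
                              {k: v.copy() for k, v in ckpt.params.items()}))
        assert histories[0][0] == histories[1][0]
        for k in histories[0][1]:
            assert np.array_equal(histories[0][1][k], histories[1][1][k])

    def test_invalid_checkpoint_f1_rejected(self):
        with pytest.raises(ValueError):
            Checkpoint(params={}, val_macro_f1=1.5, epoch_index=0)
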