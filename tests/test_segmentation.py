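"""Joint Dice+BCE loss identities, metrics arithmetic, augmentation closure,
and the training-loop contract."""

import numpy as np
import pytest

from scarmetry.scene import Label
from scarmetry.segmentation import (
    LossConfig,
    TrainConfig,
    augment_pair,
    bce_loss,
    build_segnet,
    dice_loss,
    hard_mask,
    joint_loss,
    load_checkpoint,
    mask_to_onehot,
    predict_masks,
    save_checkpoint,
    segmentation_metrics,
    train_segnet,
)


def _random_pairs(rng, n=6, size=64):
    """Tiny random image/mask pairs (no scene rendering needed)."""
    pairs = []
    for _ in range(n):
        img = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
        mask = rng.integers(0, 3, size=(size, size), dtype=np.int64)
        pairs.append((img, mask))
    return pairs


class TestJointLoss:
    def test_perfect_onehot_prediction_gives_zero_loss(self, rng):
        g = (rng.random((2, 16, 16)) > 0.6).astype(float)
        assert joint_loss(g.copy(), g) == pytest.approx(0.0, abs=1e-5)

    def test_bce_is_ln2_for_uniform_half_prediction(self, rng):
        g = (rng.random((2, 16, 16)) > 0.5).astype(float)
        p = np.full_like(g, 0.5)
        assert bce_loss(p, g) == pytest.approx(np.log(2), rel=1e-9)

    def test_dice_eps_guard_on_empty_masks(self):
        z = np.zeros((1, 8, 8))
        assert dice_loss(z, z, eps=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_loss_decomposes_into_dice_plus_bce(self, rng):
        p = rng.random((2, 12, 12))
        g = (rng.random((2, 12, 12)) > 0.5).astype(float)
        total = joint_loss(p, g, LossConfig(eps=1.0))
        parts = np.mean([dice_loss(p[c], g[c]) + bce_loss(p[c], g[c]) for c in range(2)])
        assert total == pytest.approx(parts, abs=1e-6)

    def test_one_minus_dice_equals_dsc_for_hard_masks(self, rng):
        # with eps -> 0 and binary predictions, 1 - L_Dice is the Dice
        # similarity coefficient computed from confusion counts
        pred = (rng.random((20, 20)) > 0.5).astype(float)
        gt = (rng.random((20, 20)) > 0.5).astype(float)
        d = 1.0 - dice_loss(pred, gt, eps=1e-12)
        m = segmentation_metrics(pred.astype(int), gt.astype(int), cls=1)
        assert d == pytest.approx(m.dsc, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(np.zeros((2, 8, 8)), np.zeros((2, 8, 9)))


class TestMetrics:
    def test_identity_prediction_is_perfect(self, rng):
        gt = rng.integers(0, 3, size=(10, 10))
        if not (gt == 1).any():
            gt[0, 0] = 1
        m = segmentation_metrics(gt, gt, "scar")
        assert (m.dsc, m.sen, m.spe) == (1.0, 1.0, 1.0)

    def test_constructed_confusion_counts(self):
        # 10x10 toy mask: 10 positives in gt, 8 hit, 2 missed, 2 false alarms
        gt = np.zeros((10, 10), dtype=int)
        gt.ravel()[:10] = 1
        pred = np.zeros((10, 10), dtype=int)
        pred.ravel()[:8] = 1     # TP=8, FN=2
        pred.ravel()[10:12] = 1  # FP=2 -> TN=88
        m = segmentation_metrics(pred, gt, cls=1)
        assert (m.tp, m.fp, m.fn, m.tn) == (8, 2, 2, 88)
        assert m.dsc == pytest.approx(0.8000, abs=5e-5)
        assert m.sen == pytest.approx(0.8000, abs=5e-5)
        assert m.spe == pytest.approx(0.9778, abs=5e-5)

    def test_absent_class_flags_sen_undefined_not_zero(self):
        gt = np.zeros((5, 5), dtype=int)
        pred = np.zeros((5, 5), dtype=int)
        m = segmentation_metrics(pred, gt, "scar")
        assert np.isnan(m.sen)
        assert m.spe == 1.0


class TestAugmentation:
    def test_flips_and_rotation_preserve_mask_class_counts(self, rng):
        img = rng.random((3, 32, 32))
        mask = rng.integers(0, 3, size=(32, 32))
        cfg = TrainConfig(rotation_deg=30.0)
        # rotation uses nearest-neighbour for masks, so labels stay admissible
        # and (for flips) counts are exactly preserved
        flip_cfg = TrainConfig(rotation_deg=0.0)
        aimg, amask = augment_pair(img, mask, np.random.default_rng(0), flip_cfg)
        assert np.array_equal(np.bincount(amask.ravel(), minlength=3),
                              np.bincount(mask.ravel(), minlength=3))
        rimg, rmask = augment_pair(img, mask, np.random.default_rng(1), cfg)
        assert set(np.unique(rmask)) <= {0, 1, 2}
        assert rimg.shape == img.shape and rmask.shape == mask.shape


class TestTraining:
    def test_loss_decreases_over_short_run(self, rng):
        pairs = _random_pairs(rng, n=6, size=32)
        model = build_segnet(base_width=2, blocks=(1, 1, 1, 1), seed=0)
        cfg = TrainConfig(input_size=(32, 32), epochs=3, batch_size=2, seed=0,
                          rotation_deg=0.0)
        model, history = train_segnet(model, pairs, cfg)
        assert len(history) == 3
        assert history[-1] < history[0]

    def test_empty_dataset_rejected(self):
        model = build_segnet(base_width=2, blocks=(1, 1, 1, 1), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_segnet(model, [], TrainConfig())

    def test_predict_is_deterministic_and_order_preserving(self, rng):
        model = build_segnet(base_width=2, blocks=(1, 1, 1, 1), seed=0)
        imgs = [rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8) for _ in range(3)]
        a = predict_masks(model, imgs)
        b = predict_masks(model, imgs)
        assert np.array_equal(a, b)
        assert a.shape == (3, 2, 32, 32)
        solo = predict_masks(model, imgs[1])
        assert np.allclose(a[1], solo[0])

    def test_hard_mask_thresholds_and_resolves_conflicts(self):
        probs = np.zeros((2, 2, 2))
        probs[0, 0, 0] = 0.9              # scar wins
        probs[1, 0, 1] = 0.8              # scale wins
        probs[:, 1, 0] = [0.7, 0.6]       # both above threshold -> higher (scar)
        probs[:, 1, 1] = [0.6, 0.7]       # both above threshold -> higher (scale)
        hm = hard_mask(probs)
        assert hm[0, 0] == Label.SCAR
        assert hm[0, 1] == Label.SCALE
        assert hm[1, 0] == Label.SCAR
        assert hm[1, 1] == Label.SCALE

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = build_segnet(base_width=2, blocks=(1, 1, 1, 1), seed=3)
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        before = predict_masks(model, img)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, TrainConfig(), path)
        again = load_checkpoint(path)
        assert np.allclose(predict_masks(again, img), before)

    def test_onehot_encoding_covers_foreground_classes(self):
        mask = np.array([[0, 1], [2, 1]])
        oh = mask_to_onehot(mask)
        assert oh.shape == (2, 2, 2)
        assert oh[0].sum() == 2  # two scar pixels
        assert oh[1].sum() == 1  # one scale pixel
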