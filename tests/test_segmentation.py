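"""Segmentation: loss oracles, augmentation contracts, architecture parity
and the trained-model contract."""

import numpy as np
import pytest

from echostrain import nn
from echostrain import phantom as ph
from echostrain import segmentation as seg
from echostrain.nn import Tensor


def one_hot(target, c=3):
    b, h, w = target.shape
    out = np.zeros((b, c, h, w))
    for k in range(c):
        out[:, k] = target == k
    return out


class TestSoftDiceCeLoss:
    def test_perfect_prediction_near_zero(self):
        target = np.random.default_rng(0).integers(0, 3, (2, 8, 8))
        prob = one_hot(target) * (1 - 3e-7) + 1e-7
        assert float(seg.soft_dice_ce_loss(prob, target).data) < 1e-5

    def test_everywhere_wrong_dice_term_saturates(self):
        target = np.zeros((1, 8, 8), dtype=int)
        wrong = one_hot(np.ones((1, 8, 8), dtype=int))
        loss = float(seg.soft_dice_ce_loss(wrong + 1e-9, target).data)
        # dice contribution: class 0 and class 1 fully missed -> ~2/3 mean,
        # plus a large CE term
        assert loss > 2.0 / 3.0

    def test_uniform_probability_matches_direct_summation(self):
        # independent 10-line oracle: uniform prob 1/3, single-class target
        b, h, w = 1, 6, 6
        n = b * h * w
        target = np.ones((b, h, w), dtype=int)
        prob = np.full((b, 3, h, w), 1.0 / 3.0)
        eps = 1e-6
        dice_terms = []
        for k in range(3):
            inter = (1.0 / 3.0) * (n if k == 1 else 0)
            denom = n / 3.0 + (n if k == 1 else 0)
            dice_terms.append(1.0 - (2 * inter + eps) / (denom + eps))
        expected = np.mean(dice_terms) + n * (-np.log(1.0 / 3.0)) / n
        got = float(seg.soft_dice_ce_loss(prob, target).data)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_truth_beats_corruption(self):
        rng = np.random.default_rng(1)
        target = rng.integers(0, 3, (2, 10, 10))
        clean = one_hot(target) * (1 - 3e-7) + 1e-7
        corrupt = target.copy()
        flip = rng.random(corrupt.shape) < 0.2
        corrupt[flip] = (corrupt[flip] + 1) % 3
        corrupted = one_hot(corrupt) * (1 - 3e-7) + 1e-7
        assert (float(seg.soft_dice_ce_loss(clean, target).data)
                < float(seg.soft_dice_ce_loss(corrupted, target).data))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.soft_dice_ce_loss(np.zeros((1, 3, 4, 4)), np.zeros((1, 5, 5)))


class TestAugment:
    def test_identity_transform_is_resize_only(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        mask = (img > 0.5).astype(np.uint8)
        cfg = seg.SegConfig(input_size=64, rotation_range=0.0,
                            crop_scale_range=(1.0, 1.0))
        out_img, out_mask = seg.augment(img, mask, cfg, seed=1)
        assert np.allclose(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_output_contract(self):
        rng = np.random.default_rng(0)
        cfg = seg.SegConfig(input_size=64)
        img = rng.random((80, 80))
        mask = rng.integers(0, 3, (80, 80)).astype(np.uint8)
        for s in range(25):
            out_img, out_mask = seg.augment(img, mask, cfg, seed=s)
            assert out_img.shape == (64, 64) and out_mask.shape == (64, 64)
            assert set(np.unique(out_mask)) <= {0, 1, 2}

    def test_crop_area_stays_in_configured_range(self):
        cfg = seg.SegConfig(input_size=32, rotation_range=0.0)
        rng = np.random.default_rng(0)
        draws = [rng2.uniform(*cfg.crop_scale_range)
                 for rng2 in [np.random.default_rng(s) for s in range(1000)]]
        assert min(draws) >= 0.6 and max(draws) <= 1.0
        # and a crop at the lower bound keeps >= 60% of the pixels
        img = np.arange(100.0 * 100).reshape(100, 100)
        mask = np.zeros((100, 100), dtype=np.uint8)
        lo = seg.SegConfig(input_size=32, rotation_range=0.0,
                           crop_scale_range=(0.6, 0.6))
        out_img, _ = seg.augment(img, mask, lo, seed=3)
        span = out_img.max() - out_img.min()
        assert span <= 0.85 * (img.max() - img.min())

    def test_invalid_crop_range_rejected(self):
        with pytest.raises(ValueError):
            seg.SegConfig(crop_scale_range=(0.0, 1.0)).validate()


class TestArchitectureParity:
    @pytest.mark.parametrize("arch", seg.ARCHITECTURES)
    def test_shared_io_contract(self, arch):
        cfg = seg.SegConfig(arch=arch, input_size=32, base_channels=4, seed=0)
        net = seg.build_network(cfg)
        x = Tensor(np.random.default_rng(0).random((2, 1, 32, 32)))
        y = net(x)
        assert y.shape == (2, 3, 32, 32)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            seg.SegConfig(arch="vit").validate()


class TestTrainedModel:
    def test_loss_decreases(self, seg_experiment):
        log = seg_experiment["model"].loss_log
        assert log[-1] < log[0]

    def test_lr_schedule_endpoints(self, seg_experiment):
        lrs = seg_experiment["model"].lr_log
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[-1] == pytest.approx(0.0, abs=1e-6)

    def test_heldout_cavity_dice(self, seg_experiment):
        assert seg_experiment["dsc_cavity"].mean() >= 0.85

    def test_segmentation_deterministic(self, seg_experiment):
        frame = seg_experiment["val"][0][0]
        model = seg_experiment["model"]
        a = seg.segment(model, ph.EchoSequence(frames=[frame]))
        b = seg.segment(model, ph.EchoSequence(frames=[frame]))
        assert np.array_equal(a[0], b[0])

    def test_blank_image_total(self, seg_experiment):
        blank = np.zeros((64, 64))
        out = seg.segment(seg_experiment["model"],
                          ph.EchoSequence(frames=[blank]))
        assert out[0].shape == (64, 64)

    def test_checkpoint_roundtrip(self, seg_experiment, tmp_path):
        model = seg_experiment["model"]
        path = str(tmp_path / "seg.ckpt.npz")
        seg.save_checkpoint(model, path)
        back = seg.load_checkpoint(path)
        frame = seg_experiment["val"][0][0]
        a = seg.segment(model, ph.EchoSequence(frames=[frame]))
        b = seg.segment(back, ph.EchoSequence(frames=[frame]))
        assert np.array_equal(a[0], b[0])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            seg.train_segmenter([], config=seg.SegConfig(epochs=1))
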