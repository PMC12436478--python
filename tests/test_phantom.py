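"""Phantom generator: analytic strain truth, scene structure, fixtures, I/O."""

import numpy as np
import pytest
from scipy import ndimage

from echostrain import phantom as ph


def identity_scale(t, T):
    return np.ones_like(t, dtype=float)


class TestMakePhantom:
    def test_no_deformation_gives_zero_strain(self):
        params = ph.PhantomParams(frames=8, scale_fn=identity_scale)
        _, _, truth = ph.make_phantom(params, seed=0)
        assert np.allclose(truth.true_strain, 0.0)

    def test_peak_true_strain_is_smax_minus_one(self):
        params = ph.PhantomParams(s_max=1.25, frames=40)
        _, _, truth = ph.make_phantom(params, seed=0)
        assert truth.true_strain.max() == pytest.approx(0.25)

    def test_cavity_is_single_component_inside_sector(self):
        seq, masks, truth = ph.make_phantom(seed=7)
        sector = ph._sector_mask((seq.height, seq.width),
                                 truth.sector["apex"],
                                 truth.sector["span_deg"],
                                 truth.sector["radius"])
        for mask in masks.masks:
            cavity = mask == ph.CAVITY
            _, n = ndimage.label(cavity)
            assert n == 1
            assert np.all(sector[cavity])

    def test_r_peak_frame_has_unit_scale(self):
        _, _, truth = ph.make_phantom(ph.PhantomParams(frames=30), seed=3)
        assert truth.scale_values[truth.r_peak_index] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        a = ph.make_phantom(ph.PhantomParams(frames=3), seed=11)
        b = ph.make_phantom(ph.PhantomParams(frames=3), seed=11)
        for fa, fb in zip(a[0].frames, b[0].frames):
            assert np.array_equal(fa, fb)
        for ma, mb in zip(a[1].masks, b[1].masks):
            assert np.array_equal(ma, mb)

    @pytest.mark.parametrize("kwargs", [
        {"size": 0}, {"frames": 0}, {"wall_thickness": 0}, {"s_max": 1.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ph.make_phantom(ph.PhantomParams(**kwargs), seed=0)


class TestFixtures:
    def test_truncated_bottom_mask_touches_last_row(self):
        _, masks = ph.make_fixture("b", seed=0)
        bottom = masks[0][-1] > 0
        runs = np.diff(np.flatnonzero(np.diff(
            np.concatenate([[0], bottom.astype(int), [0]]))))[::2]
        assert runs.max() >= 20

    def test_black_region_covers_tenth_of_cavity(self):
        seq, masks = ph.make_fixture("e", seed=0)
        cavity = masks[0] == ph.CAVITY
        dark_frac = (seq.frames[0][cavity] < 0.05).mean()
        assert dark_frac >= 0.10

    def test_single_chamber_fixture_lacks_lv(self):
        params = ph.PhantomParams(frames=1, scale_fn=identity_scale)
        seq, _ = ph.make_fixture("a", seed=0)
        clean_seq, _, _ = ph.make_phantom(params, seed=0)
        geom = params._geom()
        lv = ph._ellipse_mask(clean_seq.frames[0].shape, geom["lv_center"],
                              geom["lv_semiaxes"])
        # clean scene has a dark LV blood pool there; the fixture has tissue
        assert clean_seq.frames[0][lv].mean() < 0.25
        assert seq.frames[0][lv].mean() > 2.0 * clean_seq.frames[0][lv].mean()

    def test_beyond_sector_fixture_exceeds_five_percent(self):
        seq, masks = ph.make_fixture("c", seed=0)
        m = masks[0] > 0
        outside = m & (seq.frames[0] == 0.0)
        assert outside.sum() / m.sum() >= 0.05

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ph.make_fixture("z", seed=0)


class TestIO:
    def test_png_roundtrip(self, tmp_path):
        seq, masks, _ = ph.make_phantom(
            ph.PhantomParams(size=64, frames=3), seed=0)
        ph.write_sequence_png(seq, str(tmp_path))
        ph.write_masks_png(masks, str(tmp_path))
        seq2 = ph.read_sequence_png(str(tmp_path))
        masks2 = ph.read_masks_png(str(tmp_path))
        assert seq2.frame_count == 3
        assert np.abs(seq2.frames[0] - seq.frames[0]).max() < 1 / 255 + 1e-9
        assert np.array_equal(masks2[0], masks[0])

    def test_tiff_stack_written(self, tmp_path):
        import tifffile

        seq, _, _ = ph.make_phantom(ph.PhantomParams(size=32, frames=4), seed=0)
        path = str(tmp_path / "seq.tiff")
        ph.write_sequence_tiff(seq, path)
        assert tifffile.imread(path).shape == (4, 32, 32)

    def test_truth_json(self, tmp_path):
        import json

        _, _, truth = ph.make_phantom(ph.PhantomParams(size=32, frames=4), seed=0)
        path = tmp_path / "truth.json"
        ph.write_truth_json(truth, str(path))
        data = json.loads(path.read_text())
        assert len(data["scale_values"]) == 4
        assert data["r_peak_index"] == truth.r_peak_index


def test_sequence_invariants_enforced():
    with pytest.raises(ValueError):
        ph.EchoSequence(frames=[])
    with pytest.raises(ValueError):
        ph.EchoSequence(frames=[np.zeros((4, 4)), np.zeros((5, 5))])
    with pytest.raises(ValueError):
        ph.EchoSequence(frames=[np.zeros((4, 4))], r_peak_index=5)
    with pytest.raises(ValueError):
        ph.LabelMaskSequence(masks=[np.full((4, 4), 7)])
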