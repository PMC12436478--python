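"""Strain extraction: contour fidelity, the strain formula, resampling and
the phantom oracle."""

import numpy as np
import pytest

from echostrain import phantom as ph
from echostrain import strain as st


def disc_mask(radius, size=None, center=None):
    size = size or int(2 * radius + 28)
    center = center or (size / 2, size / 2)
    rows, cols = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[(rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius ** 2] = 1
    return mask


class TestContour:
    def test_disc_perimeter_within_two_percent(self):
        poly = st.extract_contour(disc_mask(50))
        assert st.contour_length(poly) == pytest.approx(2 * np.pi * 50, rel=0.02)

    def test_largest_component_rule(self):
        mask = disc_mask(18, size=100, center=(50, 35))
        mask[10:13, 80:83] = 1  # a 9-px distractor component
        poly = st.extract_contour(mask)
        assert st.contour_length(poly) == pytest.approx(2 * np.pi * 18, rel=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(st.EmptyCavityError):
            st.extract_contour(np.zeros((10, 10), dtype=np.uint8))


class TestContourLength:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert st.contour_length(square) == pytest.approx(4.0)

    def test_right_triangle_3_4_5(self):
        tri = np.array([[0, 0], [3, 0], [3, 4]], dtype=float)
        assert st.contour_length(tri) == pytest.approx(12.0)

    def test_regular_360gon(self):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        poly = 10 * np.column_stack([np.cos(theta), np.sin(theta)])
        assert st.contour_length(poly) == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            st.contour_length(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestBaseFrame:
    def test_r_peak_passthrough(self):
        assert st.select_base_frame([120, 100, 110, 90], r_peak_index=3) == 3

    def test_argmin_without_ecg(self):
        assert st.select_base_frame([120, 100, 110]) == 1

    def test_all_equal_tie_breaks_to_zero(self):
        assert st.select_base_frame([100.0, 100.0, 100.0]) == 0

    def test_out_of_range_r_peak(self):
        with pytest.raises(ValueError):
            st.select_base_frame([100, 110], r_peak_index=5)


class TestStrainCurve:
    def test_formula(self):
        curve = st.strain_curve(np.array([100.0, 110.0, 105.0]), 0)
        assert np.allclose(curve.values, [0.0, 0.10, 0.05])
        assert curve.values[curve.base_index] == 0.0

    def test_constant_lengths_zero_curve(self):
        curve = st.strain_curve(np.full(5, 80.0), 2)
        assert np.allclose(curve.values, 0.0)

    def test_negative_strain_permitted(self):
        curve = st.strain_curve(np.array([100.0, 80.0]), 0)
        assert curve.values[1] == pytest.approx(-0.20)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            st.strain_curve(np.array([100.0, 0.0]), 0)


class TestResampling:
    def test_identity_at_30_frames(self):
        curve = st.StrainCurve(values=np.arange(30.0), base_index=0)
        out = st.resample_equidistant(curve)
        assert np.array_equal(out.values, curve.values)

    def test_59_frames_takes_every_other(self):
        curve = st.StrainCurve(values=np.arange(59.0), base_index=0)
        out = st.resample_equidistant(curve)
        assert np.array_equal(out.values, np.arange(0.0, 59.0, 2.0))

    def test_too_few_frames_raises(self):
        curve = st.StrainCurve(values=np.arange(10.0), base_index=0)
        with pytest.raises(st.InsufficientFramesError):
            st.resample_equidistant(curve)

    def test_endpoints_always_kept(self):
        curve = st.StrainCurve(values=np.arange(47.0), base_index=0)
        out = st.resample_equidistant(curve)
        assert out.values[0] == 0.0 and out.values[-1] == 46.0
        assert len(out.values) == 30


class TestPeakStrain:
    def test_maximum(self):
        assert st.peak_strain(np.array([0.0, 0.10, 0.05])) == 0.10

    def test_zero_curve(self):
        assert st.peak_strain(np.zeros(5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.peak_strain(np.array([]))


class TestSequenceToStrain:
    def test_phantom_truth_recovered_everywhere(self):
        params = ph.PhantomParams(s_max=1.25, frames=40)
        seq, masks, truth = ph.make_phantom(params, seed=0)
        curve = st.sequence_to_strain(masks, r_peak_index=seq.r_peak_index,
                                      resample=False)
        assert np.abs(curve.values - truth.true_strain).max() <= 0.01

    def test_constant_masks_zero_curve(self):
        mask = disc_mask(40)
        masks = ph.LabelMaskSequence(masks=[mask.copy() for _ in range(30)])
        curve = st.sequence_to_strain(masks)
        assert np.allclose(curve.values, 0.0)

    def test_missing_cavity_names_frame(self):
        mask = disc_mask(40)
        frames = [mask.copy() for _ in range(5)]
        frames[3] = np.zeros_like(mask)
        with pytest.raises(st.EmptyCavityError, match="frame 3"):
            st.sequence_to_strain(ph.LabelMaskSequence(masks=frames),
                                  resample=False)

    def test_scale_equivariance(self):
        # doubling every radius doubles every length and cancels in the ratio
        radii = [40, 44, 48, 44]
        small = ph.LabelMaskSequence(masks=[disc_mask(r, size=220) for r in radii])
        large = ph.LabelMaskSequence(
            masks=[disc_mask(2 * r, size=220) for r in radii])
        c_small = st.sequence_to_strain(small, r_peak_index=0, resample=False)
        c_large = st.sequence_to_strain(large, r_peak_index=0, resample=False)
        assert np.abs(c_small.values - c_large.values).max() < 0.005
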