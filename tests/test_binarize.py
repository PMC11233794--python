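import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from tumorgrade.binarize import (
    StructuringElement,
    ThresholdParams,
    adaptive_threshold,
    clean_mask,
    dilate,
    erode,
    fits,
    hits,
    tumor_area,
)

from .oracles import adaptive_threshold_loops, dilate_loops, erode_loops, se_probe_loops

binary_images = hnp.arrays(
    np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=12),
    elements=st.integers(0, 1))


def random_se(rng, max_side=4):
    shape = (int(rng.integers(1, max_side + 1)), int(rng.integers(1, max_side + 1)))
    m = (rng.random(shape) < 0.6).astype(np.uint8)
    if m.sum() == 0:
        m[0, 0] = 1
    origin = (int(rng.integers(0, shape[0])), int(rng.integers(0, shape[1])))
    return StructuringElement(m, origin)


class TestAdaptiveThreshold:
    def test_constant_image_all_foreground_with_positive_c(self):
        out = adaptive_threshold(np.full((9, 9), 50.0), ThresholdParams(3, 2.0))
        assert out.all()  # v > v - 2 everywhere (borders even lower)

    def test_tie_is_background(self):
        # C = 0 on a constant image: interior threshold equals the pixel
        out = adaptive_threshold(np.full((9, 9), 50.0), ThresholdParams(3, 0.0))
        assert not out[1:-1, 1:-1].any()

    def test_bright_patch_on_dark_field(self):
        img = np.full((9, 9), 10.0)
        img[3:6, 3:6] = 200.0
        out = adaptive_threshold(img, ThresholdParams(9, 5.0))
        # primary check: per-pixel agreement with the brute-force oracle
        np.testing.assert_array_equal(out, adaptive_threshold_loops(img, 9, 5.0))
        assert out[3:6, 3:6].all()  # the bright patch is foreground
        # dark pixels whose window mostly covers the image stay background
        # (at the corners the zero-padded mean dips below pixel - C)
        center_dark = out[2:7, 2:7].copy()
        center_dark[1:4, 1:4] = 0
        assert not center_dark.any()

    def test_mean_plus_c_mode(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 200.0
        out = adaptive_threshold(img, ThresholdParams(9, 5.0, "mean_plus_c"))
        np.testing.assert_array_equal(
            out, adaptive_threshold_loops(img, 9, 5.0, plus=True))
        assert out[4, 4] == 1 and out.sum() == 1

    @settings(deadline=None, max_examples=25)
    @given(shift=st.floats(-50, 50))
    def test_invariant_to_constant_shift(self, shift):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 200, (9, 9)).astype(float)
        p = ThresholdParams(3, 5.0)
        a = adaptive_threshold(img, p)
        b = adaptive_threshold(img + shift, p)
        # interior pixels: the window mean shifts by exactly the same amount
        np.testing.assert_array_equal(a[1:-1, 1:-1], b[1:-1, 1:-1])

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            ThresholdParams(4, 1.0)
        with pytest.raises(ValueError):
            ThresholdParams(3, 1.0, "otsu")


class TestFitsHits:
    def test_all_ones_probe_on_all_ones_region(self):
        f = np.ones((5, 5), dtype=np.uint8)
        s = StructuringElement(np.ones((2, 2), dtype=np.uint8), (0, 0))
        assert fits(f, s, (2, 2)) and hits(f, s, (2, 2))

    def test_single_one_probe_on_zero_pixel(self):
        f = np.zeros((4, 4), dtype=np.uint8)
        s = StructuringElement(np.array([[1]], dtype=np.uint8), (0, 0))
        assert not fits(f, s, (1, 1)) and not hits(f, s, (1, 1))

    def test_agreement_with_set_oracle_on_all_positions(self, rng):
        f = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        s = random_se(rng, 3)
        need = int(s.matrix.sum())
        for y in range(8):
            for x in range(8):
                count = se_probe_loops(f, s.matrix, s.origin, y, x)
                assert fits(f, s, (y, x)) == (count == need)
                assert hits(f, s, (y, x)) == (count > 0)

    def test_position_outside_image_rejected(self):
        s = StructuringElement.square(3)
        with pytest.raises(ValueError):
            fits(np.zeros((4, 4), dtype=np.uint8), s, (4, 0))


class TestErodeDilate:
    def test_erosion_strips_border_of_all_ones(self):
        f = np.ones((10, 10), dtype=np.uint8)
        s = StructuringElement.square(3)
        expected = np.zeros((10, 10), dtype=np.uint8)
        expected[1:-1, 1:-1] = 1
        np.testing.assert_array_equal(erode(f, s), expected)

    def test_dilation_of_single_pixel_is_se_footprint(self):
        f = np.zeros((7, 7), dtype=np.uint8)
        f[3, 3] = 1
        s = StructuringElement.square(3)
        expected = np.zeros((7, 7), dtype=np.uint8)
        expected[2:5, 2:5] = 1
        np.testing.assert_array_equal(dilate(f, s), expected)

    def test_all_zero_images_are_fixed(self):
        f = np.zeros((6, 6), dtype=np.uint8)
        s = StructuringElement.square(3)
        assert not erode(f, s).any() and not dilate(f, s).any()

    def test_matches_loop_oracles_on_random_images(self, rng):
        for _ in range(25):
            f = (rng.random((12, 12)) < 0.5).astype(np.uint8)
            s = random_se(rng)
            np.testing.assert_array_equal(erode(f, s),
                                          erode_loops(f, s.matrix, s.origin))
            np.testing.assert_array_equal(dilate(f, s),
                                          dilate_loops(f, s.matrix, s.origin))

    @settings(deadline=None, max_examples=25)
    @given(f=binary_images)
    def test_erosion_dilation_duality_under_complement(self, f):
        """With hit-based dilation, NOT(erode(f, s)) = dilate(NOT f, s).

        Checked away from the border on a zero-padded canvas so the
        out-of-image convention does not enter.
        """
        rng = np.random.default_rng(7)
        s = random_se(rng, 3)
        pad = 4
        canvas = np.zeros((f.shape[0] + 2 * pad, f.shape[1] + 2 * pad), dtype=np.uint8)
        canvas[pad:-pad, pad:-pad] = f
        lhs = 1 - erode(canvas, s)
        rhs = dilate(1 - canvas, s)
        np.testing.assert_array_equal(lhs[pad:-pad, pad:-pad],
                                      rhs[pad:-pad, pad:-pad])

    @settings(deadline=None, max_examples=25)
    @given(f=binary_images)
    def test_anti_extensive_and_extensive(self, f):
        rng = np.random.default_rng(11)
        s = random_se(rng, 3)
        m = s.matrix.copy()
        m[s.origin] = 1  # the origin pixel must be set for the containments
        s = StructuringElement(m, s.origin)
        e, d = erode(f, s), dilate(f, s)
        assert (e <= f).all() and (f <= d).all()

    def test_outputs_are_binary(self, rng):
        f = (rng.random((9, 9)) < 0.5).astype(np.uint8)
        s = random_se(rng)
        for out in (erode(f, s), dilate(f, s), clean_mask(f, s)):
            assert set(np.unique(out)) <= {0, 1}


class TestCleanMask:
    def test_square_blob_larger_than_se_survives_exactly(self):
        f = np.zeros((100, 100), dtype=np.uint8)
        f[30:60, 30:60] = 1
        assert tumor_area(clean_mask(f)) == 900

    def test_blob_smaller_than_default_se_is_erased(self):
        f = np.zeros((60, 60), dtype=np.uint8)
        f[20:30, 20:30] = 1
        assert tumor_area(clean_mask(f)) == 0

    def test_thin_ring_removed_blob_kept(self):
        f = np.zeros((40, 40), dtype=np.uint8)
        f[2:38, 2:4] = 1  # 2-pixel-wide strip, stand-in for a skull edge
        f[10:34, 10:34] = 1  # 24x24 blob
        s = StructuringElement.square(8)
        out = clean_mask(f, s)
        expected = erode_loops(f, s.matrix, s.origin)
        expected = dilate_loops(expected, s.matrix, s.origin)
        np.testing.assert_array_equal(out, expected)
        assert not out[:, 2:4].any()  # strip gone
        assert out[12:32, 12:32].all()  # blob interior kept

    @settings(deadline=None, max_examples=15)
    @given(f=binary_images)
    def test_opening_is_idempotent(self, f):
        # idempotence requires a symmetric structuring element: an odd
        # all-ones square; even squares have no central origin, and the
        # hit-based dilation then adds a one-pixel translation per pass
        s = StructuringElement.square(3)
        once = clean_mask(f, s)
        np.testing.assert_array_equal(clean_mask(once, s), once)


class TestTumorArea:
    def test_trivial_cases(self):
        assert tumor_area(np.zeros((5, 5), dtype=np.uint8)) == 0
        f = np.zeros((40, 40), dtype=np.uint8)
        f[5:35, 5:35] = 1
        assert tumor_area(f) == 900

    def test_equals_loop_sum(self, rng):
        f = (rng.random((15, 15)) < 0.4).astype(np.uint8)
        assert tumor_area(f) == sum(int(v) for row in f for v in row)


class TestStructuringElement:
    def test_validation(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((2, 2), dtype=np.uint8), (0, 0))
        with pytest.raises(ValueError):
            StructuringElement(np.ones((2, 2), dtype=np.uint8), (2, 0))
        with pytest.raises(ValueError):
            StructuringElement(np.array([[2]]), (0, 0))

    def test_default_square_22(self):
        s = StructuringElement.square()
        assert s.matrix.shape == (22, 22) and s.matrix.all()
        assert s.origin == (11, 11)

    def test_reflection_maps_origin(self):
        s = StructuringElement(np.array([[1, 0], [1, 1]], dtype=np.uint8), (0, 1))
        r = s.reflected()
        np.testing.assert_array_equal(r.matrix, [[1, 1], [0, 1]])
        assert r.origin == (1, 0)
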