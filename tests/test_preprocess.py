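"""Blur, histogram expansion, Otsu thresholding and despeckling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from nmjquant import (
    BinaryMask,
    Calibration,
    PreprocessParams,
    despeckle,
    expand_histogram,
    gaussian_blur,
    histogram_bounds,
    otsu_threshold,
)

from conftest import brute_force_otsu


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(gaussian_sigma=-1), dict(trim_fraction=0.5), dict(trim_fraction=-0.1),
         dict(despeckle_area_um2=-1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessParams(**kwargs)

    def test_defaults_match_reference_protocol(self):
        p = PreprocessParams()
        assert (p.gaussian_sigma, p.trim_fraction, p.despeckle_area_um2) == (1.0, 0.10, 0.043)


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16)).astype(np.uint8)
        np.testing.assert_array_equal(gaussian_blur(img, 0.0), img)

    def test_constant_image_preserved_by_normalized_kernel(self):
        img = np.full((12, 12), 37.0)
        np.testing.assert_allclose(gaussian_blur(img, 1.0), img)

    def test_point_source_conserves_intensity_and_keeps_center_maximal(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1000.0
        out = gaussian_blur(img, 1.0)
        # far from the boundary, reflect padding changes nothing
        assert out.sum() == pytest.approx(1000.0, rel=1e-6)
        assert np.unravel_index(out.argmax(), out.shape) == (10, 10)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), -0.5)


class TestHistogramExpansion:
    def test_bounds_for_full_range_8bit(self):
        rng, nmin, nmax = histogram_bounds(0, 255, 0.10)
        assert (rng, nmin, nmax) == (255, 25.5, 229.5)

    def test_bounds_formula_arithmetic(self):
        rng, nmin, nmax = histogram_bounds(10, 210, 0.10)
        assert (rng, nmin, nmax) == (200, 30.0, 190.0)

    def test_trimmed_endpoints_map_to_output_extremes(self):
        img = np.array([[0.0, 25.5, 127.5, 229.5, 255.0]])
        out = expand_histogram(img, 0.10, out_max=255.0)
        assert out[0, 0] == 0.0  # below NMin saturates at 0
        assert out[0, 1] == pytest.approx(0.0)
        assert out[0, 3] == pytest.approx(255.0)
        assert out[0, 4] == 255.0  # above NMax saturates at out_max

    def test_constant_image_returned_unchanged(self, caplog):
        img = np.full((8, 8), 42, dtype=np.uint8)
        with caplog.at_level("WARNING", logger="nmjquant"):
            out = expand_histogram(img)
        np.testing.assert_array_equal(out, img)

    def test_integer_input_keeps_dtype(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = expand_histogram(img)
        assert out.dtype == np.uint8

    @given(
        img=hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 255)),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_input_intensity(self, img):
        """Contrast stretch never reorders intensities."""
        if img.min() == img.max():
            return
        out = expand_histogram(img).astype(float)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= 0)


class TestOtsu:
    def test_perfectly_bimodal_histogram_matches_exhaustive_scan(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img.ravel()[:50] = 255
        thr, mask = otsu_threshold(img)
        assert thr == brute_force_otsu(img)
        assert mask.data.sum() == 50

    def test_skewed_histogram_matches_exhaustive_scan(self):
        img = np.full((10, 10), 10, dtype=np.uint8)
        img.ravel()[:10] = 200
        thr, mask = otsu_threshold(img)
        assert thr == brute_force_otsu(img) == 10
        assert mask.data.sum() == 10

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((5, 5), 7, dtype=np.uint8))

    def test_foreground_is_strictly_above_threshold(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        thr, mask = otsu_threshold(img)
        np.testing.assert_array_equal(mask.data, img > thr)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_random_images_match_exhaustive_variance_maximization(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        if img.min() == img.max():
            return
        thr, _ = otsu_threshold(img)
        assert thr == brute_force_otsu(img)


class TestDespeckle:
    def test_empty_mask_unchanged(self, cal):
        mask = BinaryMask(np.zeros((8, 8), dtype=bool))
        assert despeckle(mask, cal).data.sum() == 0

    def test_single_pixel_at_fine_calibration_removed(self):
        # 0.207 um/px -> one pixel is 0.0428 um^2 <= 0.043, removed
        cal = Calibration(pixel_size_um=0.207)
        data = np.zeros((8, 8), dtype=bool)
        data[4, 4] = True
        assert despeckle(BinaryMask(data), cal).data.sum() == 0

    def test_single_pixel_at_reference_calibration_survives(self, cal):
        # 0.21 um/px -> 0.0441 um^2 > 0.043, retained
        data = np.zeros((8, 8), dtype=bool)
        data[4, 4] = True
        assert despeckle(BinaryMask(data), cal).data.sum() == 1

    def test_three_by_three_square_retained(self, cal):
        data = np.zeros((8, 8), dtype=bool)
        data[2:5, 2:5] = True
        out = despeckle(BinaryMask(data), cal)
        assert out.data.sum() == 9

    def test_cutoff_is_inclusive(self):
        # 4 pixels at 0.1 um/px -> exactly 0.04 um^2; <= 0.04 removes it
        cal = Calibration(pixel_size_um=0.1)
        data = np.zeros((8, 8), dtype=bool)
        data[2:4, 2:4] = True
        assert despeckle(BinaryMask(data), cal, min_area_um2=0.04).data.sum() == 0

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_never_adds_foreground_and_idempotent(self, seed):
        cal = Calibration(pixel_size_um=0.21)
        rng = np.random.default_rng(seed)
        mask = BinaryMask(rng.random((24, 24)) > 0.7)
        once = despeckle(mask, cal, min_area_um2=0.2)
        assert not np.any(once.data & ~mask.data)
        twice = despeckle(once, cal, min_area_um2=0.2)
        np.testing.assert_array_equal(once.data, twice.data)
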