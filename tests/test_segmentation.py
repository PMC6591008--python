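"""Unit and property tests for the two-mask cluster segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptiq import (
    GaussianSpot,
    IntensityImage,
    SceneSpec,
    SegmentationParams,
    build_mask1,
    build_mask2,
    log_response,
    mad_normal_consistency,
    robust_sigma,
    segment_clusters,
    simulate_scene,
    smooth_mean3,
    total_clustered_intensity,
)


class TestSmoothMean3:
    def test_constant_image_unchanged(self, blank_image):
        out = smooth_mean3(blank_image)
        np.testing.assert_allclose(out.pixels, 10.0)

    def test_single_pixel_spreads_to_patch(self):
        px = np.zeros((9, 9))
        px[4, 4] = 9.0
        out = smooth_mean3(IntensityImage(px, 0.1)).pixels
        expected = np.zeros((9, 9))
        expected[3:6, 3:6] = 1.0
        np.testing.assert_allclose(out, expected)

    def test_linear_ramp_interior_preserved(self):
        px = np.tile(np.arange(16, dtype=float), (16, 1))
        out = smooth_mean3(IntensityImage(px, 0.1)).pixels
        np.testing.assert_allclose(out[1:-1, 1:-1], px[1:-1, 1:-1])

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            smooth_mean3(IntensityImage(np.ones((2, 5)), 0.1))


class TestRobustSigma:
    def test_constant_values_give_zero(self):
        assert robust_sigma([7.0] * 10) == 0.0

    def test_hand_computation_with_outlier(self):
        # median 3, |residuals| {2,1,0,1,97}, MAD 1
        assert robust_sigma([1, 2, 3, 4, 100]) == pytest.approx(1.4826)

    def test_consistent_for_gaussian_noise(self, rng):
        draws = rng.normal(0.0, 2.0, size=(512, 512))
        assert robust_sigma(draws) == pytest.approx(2.0, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            robust_sigma([])

    def test_consistency_factor_matches_rounded_constant(self):
        assert round(mad_normal_consistency(), 4) == 1.4826


class TestMask1:
    def test_constant_image_empty(self, blank_image):
        assert not build_mask1(blank_image, 2.0).any()

    def test_block_on_zero_background(self):
        # median 0 and MAD 0: every pixel of the smoothed block support
        # (block dilated by 1) exceeds the fallback threshold
        px = np.zeros((100, 100))
        px[40:50, 40:50] = 100.0
        mask = build_mask1(IntensityImage(px, 0.1), 2.0)
        expected = np.zeros((100, 100), dtype=bool)
        expected[39:51, 39:51] = True
        np.testing.assert_array_equal(mask, expected)

    def test_noise_only_low_exceedance(self, noise_scene):
        img, _ = simulate_scene(noise_scene)
        mask = build_mask1(img, 3.0)
        assert mask.mean() <= 0.01


class TestLogResponse:
    def test_constant_image_zero(self, blank_image):
        np.testing.assert_allclose(log_response(blank_image, 2.0), 0.0, atol=1e-9)

    def test_impulse_response_positive_peak_at_center(self):
        px = np.zeros((33, 33))
        px[16, 16] = 1.0
        resp = log_response(IntensityImage(px, 0.1), 2.0)
        assert resp[16, 16] == resp.max() > 0

    def test_scale_space_maximum_near_spot_width(self):
        spot = GaussianSpot((3.2, 3.2), 100.0, 0.2)  # sigma = 2 px
        img, _ = simulate_scene(
            SceneSpec(image_shape=(64, 64), spots=(spot,), noise_sd=0.0)
        )
        center_vals = {h: log_response(img, h)[32, 32] for h in (1.0, 2.0, 4.0)}
        assert max(center_vals, key=center_vals.get) == 2.0


class TestMask2:
    def test_constant_image_empty(self, blank_image, default_params):
        assert not build_mask2(blank_image, default_params).any()

    def test_bright_spot_center_in_mask(self, default_params):
        spot = GaussianSpot((6.4, 6.4), 100.0, 0.2)
        img, _ = simulate_scene(
            SceneSpec(spots=(spot,), background_level=100.0, noise_sd=5.0, seed=1)
        )
        assert build_mask2(img, default_params)[64, 64]

    def test_dark_spot_excluded_by_negative_rule(self, default_params):
        dark = 100.0 - 80.0 * np.exp(
            -((np.arange(64) - 32) ** 2)[:, None] / 8.0
            - ((np.arange(64) - 32) ** 2)[None, :] / 8.0
        )
        mask = build_mask2(IntensityImage(dark, 0.1), default_params)
        assert not mask[30:35, 30:35].any()


class TestSegmentClusters:
    def test_block_total_recovered_exactly(self, block_image):
        cs = segment_clusters(block_image)
        assert len(cs) == 1
        assert cs.background_level == pytest.approx(10.0)
        assert cs.clusters[0].total_intensity == pytest.approx(2500.0)
        # smoothing dilates a sharp block's support by one pixel; the ring
        # pixels are at background level and add nothing to the total
        assert cs.clusters[0].area_um2 >= 25 * 0.1 * 0.1

    def test_blank_image_empty_set(self, blank_image):
        cs = segment_clusters(blank_image)
        assert len(cs) == 0
        assert cs.background_level == pytest.approx(10.0)

    def test_two_separated_spots_recovered(self):
        spots = (
            GaussianSpot((3.0, 3.0), 100.0, 0.2),
            GaussianSpot((9.0, 9.0), 80.0, 0.2),
        )
        spec = SceneSpec(spots=spots, background_level=100.0, noise_sd=5.0, seed=3)
        img, truth = simulate_scene(spec)
        cs = segment_clusters(img)
        assert len(cs) == 2
        recovered = np.sort(cs.totals)
        expected = np.sort(truth.totals)
        np.testing.assert_allclose(recovered, expected, rtol=0.10)

    def test_noise_only_specificity(self, noise_scene):
        img, _ = simulate_scene(noise_scene)
        cs = segment_clusters(img)
        assert cs.final_mask.mean() <= 0.01

    def test_roi_fully_masked_raises(self):
        spot = GaussianSpot((3.2, 3.2), 500.0, 0.2)
        img, _ = simulate_scene(
            SceneSpec(image_shape=(64, 64), spots=(spot,), noise_sd=0.0)
        )
        roi = np.zeros((64, 64), dtype=bool)
        roi[31:34, 31:34] = True  # spot core only: no outside pixels left
        with pytest.raises(ValueError, match="background"):
            segment_clusters(img, roi=roi)

    def test_linearity_under_intensity_scaling(self, block_image):
        base = segment_clusters(block_image)
        scaled = segment_clusters(
            IntensityImage(block_image.pixels * 3.0, block_image.pixel_size_um)
        )
        np.testing.assert_allclose(scaled.totals, 3.0 * base.totals)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n1=st.floats(min_value=1.0, max_value=5.0),
        bump=st.floats(min_value=0.1, max_value=3.0),
    )
    def test_mask_shrinks_as_thresholds_rise(self, n1, bump):
        """Raising either threshold multiplier never enlarges the mask."""
        spot = GaussianSpot((3.2, 3.2), 80.0, 0.2)
        img, _ = simulate_scene(
            SceneSpec(image_shape=(64, 64), spots=(spot,), noise_sd=4.0, seed=8)
        )
        lo = build_mask1(img, n1)
        hi = build_mask1(img, n1 + bump)
        assert not (hi & ~lo).any()
        p_lo = SegmentationParams(n_mask2=2.0)
        p_hi = SegmentationParams(n_mask2=2.0 + bump)
        m_lo = build_mask2(img, p_lo)
        m_hi = build_mask2(img, p_hi)
        assert not (m_hi & ~m_lo).any()


class TestTotals:
    def test_empty_set_total_zero(self, blank_image):
        assert total_clustered_intensity(segment_clusters(blank_image)) == 0.0

    def test_sum_of_cluster_totals(self, block_image):
        cs = segment_clusters(block_image)
        assert total_clustered_intensity(cs) == pytest.approx(cs.totals.sum())
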