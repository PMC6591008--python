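"""Tests for per-cell synapse metrics, footprints and kymographs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptiq import (
    Cluster,
    ClusterSet,
    IntensityImage,
    build_kymograph,
    cell_footprint,
    cluster_fractions,
    clusters_to_quantile,
    csmac_fraction,
    is_csmac,
    mean_cluster_size,
    mean_distance_to_center,
    normalize_distance_series,
    searched_area,
)


def _cluster_set(totals, centroids=None, areas=None):
    empty = np.empty(0, dtype=int)
    n = len(totals)
    centroids = centroids or [(0.0, 0.0)] * n
    areas = areas or [1.0] * n
    clusters = [
        Cluster(i, empty, empty, tuple(c), a, t)
        for i, (t, c, a) in enumerate(zip(totals, centroids, areas))
    ]
    return ClusterSet(clusters, 0.0, None, (64, 64), 0.1)


class TestClusterFractions:
    def test_fractions_sorted_and_normalized(self):
        f = cluster_fractions(_cluster_set([1.0, 3.0, 4.0, 2.0]))
        np.testing.assert_allclose(f, [0.4, 0.3, 0.2, 0.1])

    def test_single_cluster_full_fraction(self):
        np.testing.assert_allclose(cluster_fractions(_cluster_set([5.0])), [1.0])

    def test_dominant_cluster_of_977_percent(self):
        # one cluster of four holding 97.7% of the antigen fluorescence
        rest = (1 - 0.977) / 3
        f = cluster_fractions(_cluster_set([0.977, rest, rest, rest]))
        assert f[0] == pytest.approx(0.977)
        assert clusters_to_quantile(f) == 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cluster_fractions(_cluster_set([0.0, 0.0]))


class TestCsmacCalls:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ([0.95, 0.05], True),
            ([0.5, 0.3, 0.2], False),  # top-2 = 0.8
            ([0.6, 0.31, 0.09], True),  # top-2 = 0.91
            ([0.9, 0.1], True),  # top-2 = 1.0
        ],
    )
    def test_top_two_rule(self, fractions, expected):
        assert is_csmac(fractions) is expected

    def test_threshold_is_strict(self):
        assert not is_csmac([0.45, 0.45, 0.10])  # exactly 0.9

    @pytest.mark.parametrize(
        "flags, expected",
        [([True] * 3 + [False] * 2, 60.0), ([False] * 4, 0.0), ([True] * 5, 100.0)],
    )
    def test_csmac_percentage(self, flags, expected):
        assert csmac_fraction(flags) == pytest.approx(expected)

    def test_empty_cell_list_rejected(self):
        with pytest.raises(ValueError):
            csmac_fraction([])


class TestClustersToQuantile:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ([0.1] * 10, 9),
            ([0.5, 0.3, 0.2], 3),
            ([0.95, 0.05], 1),
        ],
    )
    def test_hand_cases(self, fractions, expected):
        assert clusters_to_quantile(fractions, q=0.9) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=1, max_size=20)
    )
    def test_count_bounded_by_cluster_number(self, totals):
        f = cluster_fractions(_cluster_set(totals))
        k = clusters_to_quantile(f)
        assert 1 <= k <= len(totals)
        assert f[:k].sum() >= 0.9 - 1e-9


class TestDistanceToCenter:
    def test_single_cluster_zero_distance(self):
        assert mean_distance_to_center(_cluster_set([5.0], [(2.0, 3.0)])) == 0.0

    def test_symmetric_pair(self):
        cs = _cluster_set([1.0, 1.0], [(0.0, 0.0), (2.0, 0.0)])
        assert mean_distance_to_center(cs) == pytest.approx(1.0)

    def test_intensity_weighted_center(self):
        # intensities 3 at origin, 1 at (4,0): centre (1,0); distances 1 and 3
        cs = _cluster_set([3.0, 1.0], [(0.0, 0.0), (4.0, 0.0)])
        assert mean_distance_to_center(cs) == pytest.approx(2.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mean_distance_to_center(_cluster_set([]))


class TestNormalizeDistance:
    def test_divides_by_maximum(self):
        np.testing.assert_allclose(
            normalize_distance_series([2.0, 4.0, 3.0]), [0.5, 1.0, 0.75]
        )

    def test_all_zero_series_stays_zero(self):
        np.testing.assert_allclose(normalize_distance_series([0.0, 0.0]), 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=1, max_size=30))
    def test_output_in_unit_interval_with_max_one(self, series):
        out = normalize_distance_series(series)
        assert np.all((0 <= out) & (out <= 1))
        if max(series) > 0:
            assert out.max() == pytest.approx(1.0)


class TestClusterSize:
    def test_mean_of_areas(self):
        cs = _cluster_set([1.0, 1.0], areas=[1.0, 3.0])
        assert mean_cluster_size(cs) == pytest.approx(2.0)

    def test_empty_set_is_nan_not_zero(self):
        assert np.isnan(mean_cluster_size(_cluster_set([])))


class TestCellFootprint:
    def test_disk_area_recovered(self):
        yy, xx = np.mgrid[:64, :64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2).astype(float) * 100.0
        img = IntensityImage(disk + 1.0, pixel_size_um=0.1)
        mask, area = cell_footprint(img)
        assert area == pytest.approx(np.pi * 20**2 * 0.01, rel=0.03)

    def test_blank_image_zero_area(self, blank_image):
        mask, area = cell_footprint(blank_image)
        assert area == 0.0 and not mask.any()

    def test_largest_component_kept(self):
        px = np.zeros((64, 64))
        px[5:10, 5:10] = 100.0  # 25 px
        px[30:50, 30:50] = 100.0  # 400 px
        mask, area = cell_footprint(IntensityImage(px, 0.1))
        assert not mask[5:10, 5:10].any()
        assert mask[30:50, 30:50].all()

    def test_holes_filled(self):
        yy, xx = np.mgrid[:64, :64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        ring = ((r2 <= 400) & (r2 >= 100)).astype(float) * 100.0
        mask, _ = cell_footprint(IntensityImage(ring + 1.0, 0.1))
        assert mask[32, 32]


class TestSearchedArea:
    def test_identical_masks_area_of_one(self):
        m = np.zeros((32, 32), dtype=bool)
        m[:4, :4] = True
        assert searched_area([m, m, m], 0.1) == pytest.approx(16 * 0.01)

    def test_disjoint_masks_add(self):
        a = np.zeros((32, 32), dtype=bool)
        b = np.zeros((32, 32), dtype=bool)
        a[:4, :4] = True
        b[10:14, 10:14] = True
        assert searched_area([a, b], 0.1) == pytest.approx(32 * 0.01)

    def test_translated_disk_union_matches_geometry(self):
        # disk translated by its own radius: union = 2 circles - lens overlap
        yy, xx = np.mgrid[:128, :128]
        r = 20.0
        masks = [
            (yy - 60) ** 2 + (xx - 40 - int(r) * k) ** 2 <= r**2 for k in range(2)
        ]
        lens = 2 * r**2 * np.arccos(0.5) - (r / 2) * np.sqrt(4 * r**2 - r**2)
        expected_px = 2 * np.pi * r**2 - lens
        assert searched_area(masks, 1.0) == pytest.approx(expected_px, rel=0.03)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            searched_area([np.zeros((4, 4), bool), np.zeros((5, 5), bool)], 0.1)


class TestKymograph:
    def _series(self, moving):
        frames = []
        for t in range(6):
            px = np.zeros((32, 32))
            col = 5 + t if moving else 10
            px[16, col] = 100.0
            frames.append(IntensityImage(px, 1.0))
        return frames

    def test_static_point_gives_constant_row(self):
        kymo = build_kymograph(self._series(False), (0.0, 16.0), (31.0, 16.0))
        row = np.argmax(kymo, axis=0)
        assert np.all(row == row[0])
        assert np.all(kymo[row[0]] > 0)

    def test_moving_point_gives_unit_slope(self):
        kymo = build_kymograph(self._series(True), (0.0, 16.0), (31.0, 16.0))
        rows = np.argmax(kymo, axis=0)
        np.testing.assert_array_equal(np.diff(rows), 1)

    def test_drift_speed_recovered_by_regression(self):
        # bright streak moving 2 px/frame: fitted slope within 10%
        frames = []
        for t in range(10):
            px = np.zeros((64, 64))
            px[32, 4 + 2 * t] = 100.0
            px[32, 5 + 2 * t] = 100.0
            frames.append(IntensityImage(px, 1.0))
        kymo = build_kymograph(frames, (0.0, 32.0), (63.0, 32.0))
        pos = np.array(
            [(kymo[:, j] * np.arange(kymo.shape[0])).sum() / kymo[:, j].sum()
             for j in range(kymo.shape[1])]
        )
        slope = np.polyfit(np.arange(10), pos, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.10)

    def test_segment_outside_image_rejected(self):
        with pytest.raises(ValueError):
            build_kymograph(self._series(False), (0.0, 0.0), (99.0, 0.0))
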