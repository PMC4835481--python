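import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from tracermap.errors import ConfigurationError, DegenerateHistogramError, DomainError
from tracermap.labeling_detection import (
    DetectionParams,
    auto_threshold,
    disc_footprint,
    filter_by_size,
    histogram_256,
    injection_site_volume,
    label_clusters,
    measure_clusters,
    median_filter_binary,
    process_section,
    process_series,
    to_gray,
)
from tracermap.synthetic_fixtures import CALIBRATION_PROFILE, default_scene, make_fiber_image


def _params(**kw):
    kw.setdefault("gray_mode", "red")
    return DetectionParams(**kw)


class TestToGray:
    def test_raw_channel_inverted(self):
        rgb = np.array([[[10, 200, 200]]], dtype=np.uint8)
        assert to_gray(rgb, _params(gray_mode="red"))[0, 0] == 245.0

    def test_deconv_white_is_zero(self):
        rgb = np.full((3, 3, 3), 255, dtype=np.uint8)
        gray = to_gray(rgb, _params(gray_mode="deconv", profile=CALIBRATION_PROFILE))
        assert np.all(gray == 0)

    def test_constant_blue_channel(self):
        rgb = np.full((3, 3, 3), 77, dtype=np.uint8)
        assert np.all(to_gray(rgb, _params(gray_mode="blue")) == 255.0 - 77)

    def test_deconv_requires_profile(self):
        with pytest.raises(ConfigurationError):
            DetectionParams(gray_mode="deconv", profile=None)


class TestAutoThreshold:
    def test_otsu_separates_bimodal(self):
        img = np.repeat([40, 200], 512).astype(np.uint8).reshape(32, 32)
        t = auto_threshold(img, "otsu")
        assert 40 <= t < 200
        assert np.array_equal(img > t, img == 200)

    def test_mean_is_arithmetic_mean(self):
        img = np.repeat([40, 200], 512).astype(np.uint8).reshape(32, 32)
        assert auto_threshold(img, "mean") == pytest.approx(120.0, abs=0.5)

    def test_constant_image_raises_named_error(self):
        with pytest.raises(DegenerateHistogramError, match="otsu"):
            auto_threshold(np.full((8, 8), 7, dtype=np.uint8), "otsu")

    @pytest.mark.parametrize("seed", range(5))
    def test_otsu_matches_brute_force_criterion(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        t = auto_threshold(img, "otsu")
        counts, centers = histogram_256(img)
        k = int(np.argmin(np.abs(centers - t)))
        best = max(oracles.otsu_criterion(counts, centers, kk) for kk in range(256))
        assert oracles.otsu_criterion(counts, centers, k) == pytest.approx(best, rel=1e-12)

    @pytest.mark.parametrize("method", ["otsu", "mean", "yen"])
    def test_cross_check_scikit_image(self, method):
        """Independent library implementations land on the same bin."""
        from skimage import filters

        rng = np.random.default_rng(42)
        img = np.clip(
            np.concatenate([rng.normal(70, 15, 2048), rng.normal(190, 20, 2048)]), 0, 255
        ).astype(np.uint8).reshape(64, 64)
        ours = auto_threshold(img, method)
        theirs = {
            "otsu": filters.threshold_otsu,
            "mean": filters.threshold_mean,
            "yen": filters.threshold_yen,
        }[method](img)
        assert abs(ours - float(theirs)) <= 2.0  # within binning resolution


class TestMedianFilter:
    def test_disc_r2_has_13_pixels(self):
        assert disc_footprint(2).sum() == 13

    def test_constant_mask_invariant(self):
        mask = np.ones((16, 16), bool)
        assert np.array_equal(median_filter_binary(mask, 2), mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        assert not median_filter_binary(mask, 2).any()

    def test_radius_zero_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((16, 16)) > 0.5
        assert np.array_equal(median_filter_binary(mask, 0), mask)

    def test_negative_radius_rejected(self):
        with pytest.raises(DomainError):
            median_filter_binary(np.zeros((4, 4), bool), -1)


class TestComponents:
    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        _, sizes8 = label_clusters(mask, 8)
        _, sizes4 = label_clusters(mask, 4)
        assert len(sizes8) - 1 == 1
        assert len(sizes4) - 1 == 2

    def test_empty_mask(self):
        labels, sizes = label_clusters(np.zeros((4, 4), bool), 8)
        assert labels.max() == 0 and len(sizes) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_against_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) > 0.6
        labels, sizes = label_clusters(mask, connectivity)
        oracle = oracles.flood_fill_components(mask, connectivity)
        assert labels.max() == len(oracle)
        recs = measure_clusters(labels, pixel_size=1.0)
        ours = sorted((r.area_px, r.centroid_x_px, r.centroid_y_px) for r in recs)
        np.testing.assert_allclose(ours, oracles.component_summary(oracle), atol=1e-9)


class TestSizeFilter:
    @staticmethod
    def _mask_with_sizes():
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True  # size 1
        mask[2, 2:5] = True  # size 3
        mask[5:7, 5:8] = True  # size 6
        return mask

    def test_min_area_selection(self):
        labels, _ = label_clusters(self._mask_with_sizes(), 8)
        out_mask, out_labels = filter_by_size(labels, min_area=2)
        assert out_mask.sum() == 9
        assert len(np.unique(out_labels)) - 1 == 2

    def test_min_area_one_keeps_all(self):
        mask = self._mask_with_sizes()
        labels, _ = label_clusters(mask, 8)
        out_mask, _ = filter_by_size(labels, min_area=1)
        assert np.array_equal(out_mask, mask)

    def test_all_removed(self):
        labels, _ = label_clusters(self._mask_with_sizes(), 8)
        out_mask, out_labels = filter_by_size(labels, min_area=7)
        assert not out_mask.any() and out_labels.max() == 0

    def test_invalid_range_rejected(self):
        labels, _ = label_clusters(self._mask_with_sizes(), 8)
        with pytest.raises(ConfigurationError):
            filter_by_size(labels, min_area=5, max_area=2)

    @given(st.integers(0, 500))
    def test_idempotent_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        labels, _ = label_clusters(rng.random((24, 24)) > 0.6, 8)
        prev_area = np.inf
        for min_area in (1, 2, 4, 8):
            m1, l1 = filter_by_size(labels, min_area)
            m2, _ = filter_by_size(l1, min_area)
            assert np.array_equal(m1, m2)
            assert m1.sum() <= prev_area
            prev_area = m1.sum()


class TestMeasure:
    def test_square_cluster(self):
        labels = np.zeros((4, 4), int)
        labels[1:3, 1:3] = 1
        (rec,) = measure_clusters(labels, pixel_size=1.0)
        assert rec.area_px == 4
        assert (rec.centroid_x_px, rec.centroid_y_px) == (1.5, 1.5)

    def test_collinear_cluster_centroid(self):
        labels = np.zeros((4, 4), int)
        labels[0, 0] = labels[0, 1] = labels[0, 2] = 1
        (rec,) = measure_clusters(labels, pixel_size=1.0)
        assert (rec.centroid_x_px, rec.centroid_y_px) == (1.0, 0.0)

    def test_area_mm2_scaling(self):
        labels = np.zeros((4, 4), int)
        labels[1:3, 1:3] = 1
        (rec,) = measure_clusters(labels, pixel_size=10.0)
        assert rec.area_mm2 == pytest.approx(0.0004)


class TestPipeline:
    PARAMS = DetectionParams(
        gray_mode="deconv", profile=CALIBRATION_PROFILE,
        threshold_method="otsu", median_radius=2, min_area=30, pixel_size=2.0,
    )

    def test_strong_clusters_all_detected(self, scene_and_image):
        scene, rgb, truth = scene_and_image
        lmap, recs = process_section(rgb, self.PARAMS, "s1")
        strong = [c for c in scene.clusters if c.amplitude >= 3 * scene.noise_amplitude]
        assert strong
        for cluster in strong:
            assert lmap.mask[cluster.mask(scene.shape)].mean() > 0.5
            cx, cy = cluster.centroid_px
            assert any(
                abs(r.centroid_x_px - cx) < 2 and abs(r.centroid_y_px - cy) < 2 for r in recs
            ), f"planted cluster at {cluster.centroid_px} not detected"

    def test_deterministic(self, scene_and_image):
        _, rgb, _ = scene_and_image
        m1, r1 = process_section(rgb, self.PARAMS, "s")
        m2, r2 = process_section(rgb, self.PARAMS, "s")
        assert np.array_equal(m1.mask, m2.mask)
        assert m1.threshold == m2.threshold and r1 == r2

    def test_blank_image_auto_threshold_raises(self):
        white = np.full((32, 32, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateHistogramError):
            process_section(white, DetectionParams(gray_mode="red"), "w")

    def test_blank_image_fixed_threshold_empty_map(self):
        white = np.full((32, 32, 3), 255, dtype=np.uint8)
        lmap, recs = process_section(
            white,
            DetectionParams(gray_mode="red", threshold_method="fixed", fixed_threshold=10.0),
            "w",
        )
        assert not lmap.mask.any() and recs == []


class TestSeries:
    def test_aggregates_all_sections(self, scene_and_image):
        _, rgb, _ = scene_and_image
        sections = [(str(k), rgb) for k in range(4)]
        table, maps = process_series(sections, {"b": TestPipeline.PARAMS})
        _, recs = process_section(rgb, TestPipeline.PARAMS, "0")
        assert len(table) == 4 * len(recs)
        assert set(maps) == {"0", "1", "2", "3"}

    def test_batch_params_compose(self, scene_and_image):
        _, rgb, _ = scene_and_image
        loose = DetectionParams(
            gray_mode="deconv", profile=CALIBRATION_PROFILE,
            threshold_method="fixed", fixed_threshold=0.3, min_area=30,
        )
        table, maps = process_series(
            [("a", rgb), ("b", rgb)],
            {"b1": TestPipeline.PARAMS, "b2": loose},
            {"a": "b1", "b": "b2"},
        )
        single_a, _ = process_section(rgb, TestPipeline.PARAMS, "a")
        single_b, _ = process_section(rgb, loose, "b")
        assert np.array_equal(maps["a"].mask, single_a.mask)
        assert np.array_equal(maps["b"].mask, single_b.mask)

    def test_missing_batch_listed(self, scene_and_image):
        _, rgb, _ = scene_and_image
        with pytest.raises(ConfigurationError, match="orphan"):
            process_series(
                [("orphan", rgb)], {"b1": TestPipeline.PARAMS, "b2": TestPipeline.PARAMS}, {}
            )

    def test_empty_series(self):
        table, maps = process_series([], {"b": TestPipeline.PARAMS})
        assert table.empty and maps == {}


class TestInjectionVolume:
    def test_cavalieri_sum(self):
        assert injection_site_volume([0.5, 0.5], 0.1) == pytest.approx(0.1)

    def test_empty_and_single(self):
        assert injection_site_volume([], 0.2) == 0.0
        assert injection_site_volume([1.25], 0.05) == pytest.approx(0.0625)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(DomainError):
            injection_site_volume([1.0], 0.0)
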