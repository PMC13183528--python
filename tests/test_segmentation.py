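"""Kapur entropy, optimizer-driven thresholding and binary morphology."""
from dataclasses import replace

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings, strategies as st

from igwoderm.optimizer import IgwoConfig
from igwoderm.pipeline import iou
from igwoderm.preprocess import DermoscopyPreprocessor
from igwoderm.segmentation import (Histogram, KapurThresholder,
                                   SegmentationConfig, ThresholdVector,
                                   apply_thresholds, close_mask,
                                   exhaustive_thresholds, fill_holes,
                                   find_thresholds, gray_histogram,
                                   kapur_objective, largest_component,
                                   lesion_mask_from_labels, open_mask,
                                   segment_lesion)
from igwoderm.synthetic import BENIGN_PARAMS, MALIGNANT_PARAMS, make_lesion_image

E3 = np.ones((3, 3), dtype=bool)


class TestHistogram:
    def test_direct_counts(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        h = gray_histogram(img)
        assert h.ph[0] == 0.5 and h.ph[255] == 0.5
        assert h.ph.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_normalized_for_any_image(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (13, 17), dtype=np.uint8)
        h = gray_histogram(img)
        assert h.ph.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(h.counts, np.bincount(img.ravel(),
                                                            minlength=256))

    def test_pure_red_maps_to_luminance_bin(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        h = gray_histogram(img)
        assert h.counts[76] == 1  # round(0.299 * 255)

    def test_channel_mode_uses_raw_channel(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        assert gray_histogram(img, channel=0).counts[255] == 1

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            gray_histogram(np.zeros((0, 0), dtype=np.uint8))


class TestKapurObjective:
    def test_uniform_two_class_closed_form(self):
        counts = np.zeros(256, dtype=int)
        counts[:4] = 25
        h = Histogram.from_counts(counts)
        assert kapur_objective(h, [2]) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_single_bin_mass_gives_zero(self):
        counts = np.zeros(256, dtype=int)
        counts[100] = 50
        h = Histogram.from_counts(counts)
        for th in ([50], [150], [10, 200]):
            assert kapur_objective(h, th) == 0.0

    def test_threshold_order_irrelevant(self, bimodal_hist):
        assert kapur_objective(bimodal_hist, [80, 160]) == \
            kapur_objective(bimodal_hist, [160, 80])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), m=st.integers(2, 4))
    def test_non_negative_property(self, bimodal_hist, seed, m):
        rng = np.random.default_rng(seed)
        th = sorted(rng.choice(np.arange(1, 255), size=m - 1, replace=False))
        assert kapur_objective(bimodal_hist, th) >= 0.0

    def test_never_exceeds_exhaustive_maximum(self, bimodal_hist):
        _, j_max = exhaustive_thresholds(bimodal_hist, 2)
        rng = np.random.default_rng(1)
        for _ in range(100):
            th = [int(rng.integers(1, 255))]
            assert kapur_objective(bimodal_hist, th) <= j_max + 1e-12


class TestFindThresholds:
    def test_matches_brute_force_m2(self, bimodal_hist):
        th_ex, j_ex = exhaustive_thresholds(bimodal_hist, 2)
        tv = find_thresholds(bimodal_hist, m=2,
                             opt=IgwoConfig(pop_size=20, max_iter=60),
                             repeats=5, seed=0)
        assert abs(kapur_objective(bimodal_hist, tv) - j_ex) <= 1e-9

    def test_matches_brute_force_m3(self, bimodal_hist):
        _, j_ex = exhaustive_thresholds(bimodal_hist, 3)
        tv = find_thresholds(bimodal_hist, m=3,
                             opt=IgwoConfig(pop_size=30, max_iter=100),
                             repeats=5, seed=0)
        assert abs(kapur_objective(bimodal_hist, tv) - j_ex) <= 1e-6

    def test_thresholds_sorted_unique_in_range(self, bimodal_hist):
        tv = find_thresholds(bimodal_hist, m=4,
                             opt=IgwoConfig(pop_size=15, max_iter=30),
                             repeats=3, seed=1)
        th = np.asarray(tv.th)
        assert np.all(np.diff(th) > 0)
        assert th.min() >= 1 and th.max() <= 254

    def test_too_many_classes_rejected(self, bimodal_hist):
        with pytest.raises(ValueError):
            find_thresholds(bimodal_hist, m=1)


class TestApplyThresholds:
    def test_boundary_convention(self):
        img = np.array([[0, 127, 128, 255]], dtype=np.uint8)
        labels = apply_thresholds(img, [128])
        assert labels.tolist() == [[0, 0, 1, 1]]

    def test_three_classes_partition_range(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        labels = apply_thresholds(img, [85, 170])
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_label_count_bounded_by_m(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        labels = apply_thresholds(img, [64, 128, 192])
        assert len(np.unique(labels)) <= 4

    def test_foreground_polarity(self):
        labels = np.array([[0, 1], [1, 0]])
        np.testing.assert_array_equal(
            lesion_mask_from_labels(labels, 2, "dark"), labels == 0)
        np.testing.assert_array_equal(
            lesion_mask_from_labels(labels, 2, "bright"), labels == 1)


def _flood_fill_oracle(mask):
    """Independent hole filling: label background (8-connected, matching the
    3x3 element's reach), keep only regions touching the border."""
    bg_labels, n = ndi.label(~mask, structure=np.ones((3, 3)))
    border = set(np.unique(np.concatenate([
        bg_labels[0], bg_labels[-1], bg_labels[:, 0], bg_labels[:, -1]])))
    border.discard(0)
    holes = ~mask & ~np.isin(bg_labels, sorted(border))
    return mask | holes


class TestMorphology:
    def test_solid_square_unchanged_by_fill(self):
        m = np.zeros((12, 12), bool)
        m[3:9, 3:9] = True
        assert np.array_equal(fill_holes(m, E3), m)

    def test_ring_becomes_disk(self):
        m = np.zeros((15, 15), bool)
        m[4:11, 4:11] = True
        m[5:10, 5:10] = False  # enclosed cavity
        filled = fill_holes(m, E3)
        expected = np.zeros((15, 15), bool)
        expected[4:11, 4:11] = True
        assert np.array_equal(filled, expected)

    def test_c_shape_with_border_gap_unchanged(self):
        m = np.zeros((12, 12), bool)
        m[2:10, 2:4] = True
        m[2:4, 2:10] = True
        m[8:10, 2:10] = True  # open toward the right border
        assert np.array_equal(fill_holes(m, E3), m)

    def test_fill_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.random((24, 24)) > 0.55
            np.testing.assert_array_equal(fill_holes(m, E3),
                                          _flood_fill_oracle(m))

    def test_fill_is_extensive_and_idempotent(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = rng.random((20, 20)) > 0.5
            f = fill_holes(m, E3)
            assert (f | m).sum() == f.sum()  # f contains m
            assert np.array_equal(fill_holes(f, E3), f)

    def test_open_close_idempotent(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = rng.random((25, 25)) > 0.5
            o = open_mask(m, E3)
            c = close_mask(m, E3)
            assert np.array_equal(open_mask(o, E3), o)
            assert np.array_equal(close_mask(c, E3), c)

    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert not open_mask(m, E3).any()

    def test_closing_bridges_one_pixel_gap(self):
        m = np.zeros((9, 12), bool)
        m[3:6, 2:5] = True
        m[3:6, 6:9] = True  # one-column gap at x=5
        assert close_mask(m, E3)[4, 5]

    def test_closing_is_dual_of_opening(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.random((20, 20)) > 0.5
            np.testing.assert_array_equal(close_mask(m, E3),
                                          ~open_mask(~m, E3))

    def test_even_element_rejected(self):
        with pytest.raises(ValueError):
            open_mask(np.zeros((5, 5), bool), np.ones((2, 2), bool))


class TestSegmentLesion:
    def test_dark_lesion_high_iou(self):
        rng = np.random.default_rng(0)
        img, truth = make_lesion_image(replace(BENIGN_PARAMS, size=96), rng)
        pre = DermoscopyPreprocessor().transform_one(img)
        mask = segment_lesion(pre, SegmentationConfig(seed=0))
        assert iou(mask, truth) >= 0.90

    def test_single_connected_component(self):
        rng = np.random.default_rng(1)
        img, _ = make_lesion_image(replace(MALIGNANT_PARAMS, size=64), rng)
        mask = segment_lesion(img, SegmentationConfig(seed=1))
        _, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert n <= 1

    def test_bright_foreground_mirrors_dark_case(self):
        rng = np.random.default_rng(2)
        img, truth = make_lesion_image(replace(BENIGN_PARAMS, size=64), rng)
        inverted = (255 - img).astype(np.uint8)
        dark = segment_lesion(img, SegmentationConfig(seed=3))
        bright = segment_lesion(inverted, SegmentationConfig(seed=3,
                                                             foreground="bright"))
        assert iou(dark, truth) == pytest.approx(iou(bright, truth), abs=0.05)

    def test_empty_foreground_warns(self):
        # single-valued background plus isolated dark pixels spread over
        # several levels: the entropy criterion isolates the dark group
        # (it carries all the entropy) and the opening then removes it
        img = np.full((32, 32), 200, np.uint8)
        for v, (y, x) in zip((0, 10, 20, 30),
                             ((4, 4), (4, 20), (20, 4), (20, 20))):
            img[y, x] = v
        with pytest.warns(UserWarning):
            mask = segment_lesion(img, SegmentationConfig(
                seed=0, repeats=2,
                optimizer=IgwoConfig(pop_size=8, max_iter=10)))
        assert not mask.any()


class TestKapurThresholderEstimator:
    def test_fit_transform_on_batch(self, bimodal_hist):
        rng = np.random.default_rng(4)
        imgs = np.stack([make_lesion_image(replace(BENIGN_PARAMS, size=48),
                                           np.random.default_rng(s))[0]
                         for s in range(3)])
        est = KapurThresholder(m=2, repeats=3, pop_size=15, max_iter=30,
                               random_state=0)
        labels = est.fit(imgs).transform(imgs)
        assert labels.shape == imgs.shape
        assert isinstance(est.thresholds_, ThresholdVector)
        assert est.entropy_ > 0

    def test_unfitted_transform_rejected(self):
        with pytest.raises(AttributeError):
            KapurThresholder().transform(np.zeros((2, 16, 16), np.uint8))
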