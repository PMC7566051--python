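"""ISODATA thresholding, candidate selection, quality loop, convex hulls."""

import numpy as np
import pytest

from tvac import (
    InsufficientObjectsError,
    LungPair,
    QualityParams,
    area_opening,
    assess_quality,
    binarize,
    convex_hull_mask,
    generate_phantom,
    isodata_threshold,
    recursive_segment,
    select_lung_objects,
)
from tvac.phantom import PhantomSpec

from .oracles import isodata_fixed_points


def _img(values):
    values = np.asarray(values, dtype=float).ravel()
    return values.reshape(1, -1)


class TestIsodata:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0, 1, 1, 0, 1], 0.5),  # two-level image: midpoint of class means
            ([0, 0, 0, 0.9], 0.45),  # theta0 = 0.45 is already the fixed point
            ([0] * 4 + [0.1] * 4 + [0.8] * 8, 0.425),  # hand-iterated fixed point
        ],
    )
    def test_worked_examples(self, values, expected):
        assert isodata_threshold(_img(values)) == pytest.approx(expected, abs=1e-12)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            isodata_threshold(np.full((5, 5), 0.3))

    def test_fixed_point_property_random_histograms(self, rng):
        """Returned threshold is a fixed point, matching a brute-force scan."""
        for _ in range(25):
            values = rng.integers(0, 256, size=400).astype(float) / 255.0
            theta = isodata_threshold(values.reshape(20, 20))
            tol = (values.max() - values.min()) / 512.0
            fg, bg = values[values < theta], values[values >= theta]
            assert abs((fg.mean() + bg.mean()) / 2.0 - theta) < tol
            fixed = isodata_fixed_points(values)
            assert any(np.array_equal(values < theta, values < fp) for fp in fixed)


class TestBinarizeAndOpening:
    def test_binarize_extremes(self):
        img = np.linspace(0, 1, 16).reshape(4, 4)
        assert not binarize(img, 0.0).any()
        assert binarize(img, 1.1).all()

    def test_binarize_checkerboard(self):
        img = np.indices((6, 6)).sum(0) % 2 * 0.6 + 0.2  # {0.2, 0.8}
        np.testing.assert_array_equal(binarize(img, 0.5), img == 0.2)

    def test_area_opening_identity_and_removal(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:7, 2:4] = True  # 10 px
        assert np.array_equal(area_opening(mask, 1), mask)
        assert not area_opening(mask, 11).any()

    def test_area_opening_keeps_large_component(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[5:10, 5:15] = True  # 50 px
        mask[15:35, 20:45] = True  # 500 px
        opened = area_opening(mask, 100)
        assert opened.sum() == 500
        assert opened[20, 30]


def _blob(shape, center, half=5):
    m = np.zeros(shape, dtype=bool)
    r, c = center
    m[r - half : r + half, c - half : c + half] = True
    return m


class TestSelectLungObjects:
    def test_blobs_at_target_points(self):
        shape = (100, 100)
        mask = _blob(shape, (40, 25)) | _blob(shape, (40, 75))
        pair = select_lung_objects(mask)
        assert pair.right_lung[40, 25] and not pair.right_lung[40, 75]
        assert pair.left_lung[40, 75] and not pair.left_lung[40, 25]

    def test_distractor_at_bottom_center_ignored(self):
        shape = (100, 100)
        mask = _blob(shape, (40, 25)) | _blob(shape, (40, 75)) | _blob(shape, (88, 50))
        pair = select_lung_objects(mask)
        assert pair.right_lung[40, 25] and pair.left_lung[40, 75]
        assert not (pair.right_lung | pair.left_lung)[88, 50]

    def test_single_object_raises(self):
        with pytest.raises(InsufficientObjectsError):
            select_lung_objects(_blob((100, 100), (40, 25)))

    def test_border_hugging_component_excluded(self):
        shape = (100, 100)
        frame = np.zeros(shape, dtype=bool)
        frame[0:3, :] = True  # strip along the top border
        mask = frame | _blob(shape, (40, 25)) | _blob(shape, (40, 75))
        pair = select_lung_objects(mask)
        assert not pair.right_lung[0, 50] and not pair.left_lung[0, 50]


class TestAssessQuality:
    def _nominal_pair(self, shape=(200, 200)):
        # each lung ~10% of image area, centroid row ~0.4, fully lateralized
        right = np.zeros(shape, dtype=bool)
        right[40:120, 20:70] = True
        left = np.zeros(shape, dtype=bool)
        left[40:120, 130:180] = True
        return LungPair(right_lung=right, left_lung=left)

    def test_nominal_pair_passes_everything(self):
        report = assess_quality(self._nominal_pair())
        assert report.violation_count == 0
        assert report.satisfied
        assert all(all(v.values()) for v in report.per_criterion.values())

    def test_full_image_blob_fails_hard(self):
        full = np.ones((100, 100), dtype=bool)
        report = assess_quality(LungPair(right_lung=full, left_lung=full))
        assert not report.per_criterion["right_lung"]["C_gamma"]
        assert not report.per_criterion["left_lung"]["C_gamma"]
        assert not report.per_criterion["right_lung"]["C_alpha"]
        assert report.violation_count >= 4
        assert not report.satisfied

    def test_single_violation_is_tolerated(self):
        pair = self._nominal_pair()
        tiny = np.zeros_like(pair.left_lung)
        tiny[50:60, 150:170] = True  # 0.5% of image area: fails only C_delta
        report = assess_quality(LungPair(right_lung=pair.right_lung, left_lung=tiny))
        assert report.violation_count == 1
        assert report.satisfied

    def test_two_violations_rejected(self):
        pair = self._nominal_pair()
        tiny_r = np.zeros_like(pair.right_lung)
        tiny_r[50:60, 20:40] = True
        tiny_l = np.zeros_like(pair.left_lung)
        tiny_l[50:60, 150:170] = True
        report = assess_quality(LungPair(right_lung=tiny_r, left_lung=tiny_l))
        assert report.violation_count == 2
        assert not report.satisfied


class TestRecursiveSegment:
    def test_clean_phantom_passes_first_threshold(self, clean_phantom):
        pair, report = recursive_segment(clean_phantom.image)
        assert report.satisfied
        assert len(report.theta_history) == 1
        assert pair.right_lung.any() and pair.left_lung.any()
        assert not (pair.right_lung & pair.left_lung).any()

    def test_threshold_history_decreases_by_exact_factor(self, rng):
        noise = rng.random((128, 128))
        params = QualityParams(max_reductions=6)
        _, report = recursive_segment(noise, params)
        h = report.theta_history
        assert len(h) >= 2
        for a, b in zip(h, h[1:]):
            assert b == pytest.approx(a * params.reduction_factor, rel=1e-12)

    def test_five_percent_reduction_arithmetic(self):
        assert 0.40 * QualityParams().reduction_factor == pytest.approx(0.38)

    def test_image_without_two_lungs_fails_gracefully(self):
        # a pure vertical gradient yields one band-shaped object at every
        # threshold, so the recursion can never find a lung pair
        gradient = np.tile(np.linspace(0, 1, 128)[:, None], (1, 128))
        params = QualityParams(max_reductions=5)
        pair, report = recursive_segment(gradient, params)
        assert not report.satisfied
        assert len(report.theta_history) == params.max_reductions + 1
        assert not pair.right_lung.any() and not pair.left_lung.any()

    def test_noise_image_terminates_with_report(self, rng):
        noise = rng.random((128, 128))
        params = QualityParams(max_reductions=5)
        _, report = recursive_segment(noise, params)
        assert len(report.theta_history) <= params.max_reductions + 1
        assert report.violation_count >= 0

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            recursive_segment(np.full((64, 64), 0.5))


class TestConvexHull:
    def test_rectangle_is_its_own_hull(self):
        rect = np.zeros((40, 40), dtype=bool)
        rect[10:30, 5:25] = True
        np.testing.assert_array_equal(convex_hull_mask(rect), rect)

    def test_cross_shape_corners_filled(self):
        cross = np.zeros((30, 30), dtype=bool)
        cross[12:18, 5:25] = True
        cross[5:25, 12:18] = True
        hull = convex_hull_mask(cross)
        assert hull.sum() > cross.sum()
        assert (hull & cross).sum() == cross.sum()  # superset

    def test_hull_is_idempotent_up_to_rasterization(self, clean_phantom):
        hull = convex_hull_mask(clean_phantom.right_lung)
        hull2 = convex_hull_mask(hull)
        assert not (hull & ~hull2).any()  # hull of hull still contains hull
        assert (hull2 & ~hull).sum() <= 0.01 * hull.sum()

    def test_too_small_input_raises(self):
        tiny = np.zeros((10, 10), dtype=bool)
        tiny[5, 5] = True
        with pytest.raises(ValueError):
            convex_hull_mask(tiny)
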