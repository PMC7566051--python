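"""Stacked active contour: schedule accounting, evolution kernel, merging."""

import numpy as np
import pytest
import skimage.segmentation.morphsnakes as morphsnakes

from tvac import generate_phantom, merge_and_smooth, split_quadrants, stacked_acm
from tvac._mgac import evolve
from tvac.contour import ACMParams, edge_map
from tvac.metrics import dice
from tvac.preprocess import apply_clahe
from tvac.tv import denoise_pdhg


def _reset_reference_curvop():
    """Reset skimage's global curvature-operator cycle to a known phase."""
    morphsnakes._curvop = morphsnakes._fcycle(
        [
            lambda u: morphsnakes.sup_inf(morphsnakes.inf_sup(u)),
            lambda u: morphsnakes.inf_sup(morphsnakes.sup_inf(u)),
        ]
    )


class TestEvolutionKernel:
    @pytest.mark.parametrize("balloon", [1.0, -1.0, 0.0])
    @pytest.mark.parametrize("smoothing", [1, 2])
    def test_matches_reference_morphsnakes_exactly(self, rng, balloon, smoothing):
        """The compiled kernel reproduces the reference algorithm bit-for-bit."""
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.random((70, 85)), 3)
        g = edge_map(img, sigma=2)
        init = np.zeros(img.shape, np.int8)
        init[20:50, 25:60] = 1
        thr = float(np.percentile(g, 40))
        _reset_reference_curvop()
        ref = morphsnakes.morphological_geodesic_active_contour(
            g, 33, init_level_set=init, smoothing=smoothing, threshold=thr, balloon=balloon
        )
        ours, _ = evolve(g, thr, init, 33, balloon, smoothing, parity=0)
        np.testing.assert_array_equal(np.asarray(ours), ref)

    def test_monotone_phase_behavior_on_flat_image(self):
        flat_edge = edge_map(np.full((120, 120), 0.5))
        thr = 0.5  # below the flat edge-map value, so the balloon engages
        u = np.zeros((120, 120), np.int8)
        u[40:80, 35:85] = 1
        parity = 0
        areas = [int(u.sum())]
        for _ in range(30):
            u, parity = evolve(flat_edge, thr, u, 1, 1.0, 1, parity)
            areas.append(int(u.sum()))
        assert all(b >= a for a, b in zip(areas, areas[1:]))
        areas = [int(u.sum())]
        for _ in range(30):
            u, parity = evolve(flat_edge, thr, u, 1, -1.0, 1, parity)
            areas.append(int(u.sum()))
        assert all(b <= a for a, b in zip(areas, areas[1:]))


class TestSchedule:
    def test_default_schedule_totals_one_thousand(self):
        assert ACMParams().total_iterations == 1000

    def test_iteration_count_matches_schedule(self):
        flat = np.full((64, 64), 0.5)
        tmpl = np.zeros((64, 64), dtype=bool)
        tmpl[20:44, 20:44] = True
        _, n = stacked_acm(flat, tmpl, ACMParams(n_cycles=2, iters_per_phase=3))
        assert n == 12

    def test_flat_image_phases_approximately_cancel(self):
        flat = np.full((120, 120), 0.5)
        tmpl = np.zeros((120, 120), dtype=bool)
        tmpl[40:80, 35:85] = True
        final, n = stacked_acm(flat, tmpl)
        assert n == 1000
        assert abs(final.sum() - tmpl.sum()) / tmpl.sum() <= 0.10

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            stacked_acm(np.full((32, 32), 0.5), np.zeros((32, 32), dtype=bool))


class TestSplitQuadrants:
    def test_union_is_pixel_exact(self, clean_phantom):
        hull = clean_phantom.right_lung
        qs = split_quadrants(hull, 0.05)
        np.testing.assert_array_equal(qs.upper | qs.lower, hull)

    def test_zero_overlap_rectangle(self):
        rect = np.zeros((100, 50), dtype=bool)
        rect[20:80, 10:40] = True
        qs = split_quadrants(rect, 0.0)
        assert qs.overlap_rows == 0
        assert not (qs.upper & qs.lower).any()
        assert qs.upper[:qs.split_row].sum() == qs.upper.sum()

    def test_overlap_band_height(self):
        rect = np.zeros((300, 60), dtype=bool)
        rect[50:250, 10:50] = True  # 200-row hull
        qs = split_quadrants(rect, 0.05)
        assert qs.overlap_rows == 10
        assert (qs.upper & qs.lower).any(axis=1).sum() == 10

    def test_empty_hull_rejected(self):
        with pytest.raises(ValueError):
            split_quadrants(np.zeros((10, 10), dtype=bool))


class TestMergeAndSmooth:
    def test_identical_halves_roughly_preserved(self):
        yy, xx = np.mgrid[0:200, 0:200]
        ell = ((yy - 100) / 60.0) ** 2 + ((xx - 100) / 40.0) ** 2 <= 1
        out = merge_and_smooth((ell, ell))
        assert abs(int(out.sum()) - int(ell.sum())) / ell.sum() <= 0.10
        assert (out & ell).sum() / ell.sum() > 0.95

    def test_overlapping_halves_single_component(self):
        from scipy import ndimage

        yy, xx = np.mgrid[0:200, 0:120]
        top = ((yy - 80) / 50.0) ** 2 + ((xx - 60) / 30.0) ** 2 <= 1
        bottom = ((yy - 120) / 50.0) ** 2 + ((xx - 60) / 30.0) ** 2 <= 1
        out = merge_and_smooth((top, bottom))
        _, n = ndimage.label(out)
        assert n == 1

    def test_near_but_disjoint_halves_bridged(self):
        from scipy import ndimage

        top = np.zeros((100, 60), dtype=bool)
        top[10:48, 15:45] = True
        bottom = np.zeros((100, 60), dtype=bool)
        bottom[52:90, 15:45] = True  # 4-px gap < closing diameter
        out = merge_and_smooth((top, bottom))
        _, n = ndimage.label(out)
        assert n == 1
        assert out[49:51, 30].all()

    def test_empty_inputs_rejected(self):
        empty = np.zeros((20, 20), dtype=bool)
        with pytest.raises(ValueError):
            merge_and_smooth((empty, empty))


class TestRefinementQuality:
    def test_refinement_improves_on_hull(self, clean_phantom):
        """Quadrant-wise ACM on a hull template beats the raw hull's Dice."""
        from tvac.localize import convex_hull_mask, recursive_segment
        from tvac.preprocess import to_working

        working, _ = to_working(clean_phantom.image)
        denoised, _ = denoise_pdhg(apply_clahe(working))
        pair, _ = recursive_segment(denoised)
        g = edge_map(denoised)
        for cand, truth in (
            (pair.right_lung, clean_phantom.right_lung),
            (pair.left_lung, clean_phantom.left_lung),
        ):
            hull = convex_hull_mask(cand)
            qs = split_quadrants(hull)
            upper, _ = stacked_acm(denoised, qs.upper, edge=g)
            lower, _ = stacked_acm(denoised, qs.lower, edge=g)
            final = merge_and_smooth((upper, lower))
            assert dice(final, truth) >= dice(hull, truth)
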