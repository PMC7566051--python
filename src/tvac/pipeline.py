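"""End-to-end TVAC lung segmentation pipeline.

Stage order for one radiograph:

1. resample to the 512-row working height (aspect preserved);
2. CLAHE contrast normalization;
3. ROF total-variation denoising (PDHG) to diffuse wires and leads while
   keeping lung boundaries sharp;
4. recursive ISODATA binarization with quality checks, yielding one
   candidate object per lung;
5. convex hull of each candidate, recovering interior regions lost to
   binarization;
6. quadrant split and stacked active contour refinement of each hull
   (or whole-lung refinement when ``quadrant_mode`` is off);
7. merge, close, and smooth each lung; map masks back to the original
   resolution.

The pipeline is fully deterministic for a fixed input and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .contour import edge_map, merge_and_smooth, split_quadrants, stacked_acm
from .localize import QualityReport, convex_hull_mask, recursive_segment
from .preprocess import ResampleRecord, apply_clahe, restore_mask, to_working
from .tv import denoise_pdhg

__all__ = ["SegmentationResult", "segment_lungs"]

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    left_lung: np.ndarray
    right_lung: np.ndarray
    combined: np.ndarray
    quality: QualityReport
    resample: ResampleRecord
    config_echo: dict


def _refine_lung(
    denoised: np.ndarray, hull: np.ndarray, config: RunConfig, edge: np.ndarray
) -> np.ndarray:
    if config.quadrant_mode:
        qs = split_quadrants(hull, config.overlap_fraction)
        parts = []
        for part in (qs.upper, qs.lower):
            if part.any():
                refined, _ = stacked_acm(denoised, part, config.acm, edge=edge)
            else:
                refined = part
            parts.append(refined)
        return merge_and_smooth((parts[0], parts[1]), config.acm)
    refined, _ = stacked_acm(denoised, hull, config.acm, edge=edge)
    return merge_and_smooth((refined, refined), config.acm)


def segment_lungs(img: np.ndarray, config: RunConfig | None = None) -> SegmentationResult:
    """Segment both lung fields of a grayscale [0, 1] radiograph.

    Returns masks at the original resolution plus the localization quality
    report (including the threshold history) and an echo of the full
    configuration. If the quality loop exhausts its reductions the best
    attempt is still refined and returned, flagged via
    ``result.quality.satisfied``.
    """
    if config is None:
        config = RunConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.ptp(img) == 0:
        raise ValueError("constant image cannot be segmented")

    working, rec = to_working(img)
    normalized = apply_clahe(working, config.clahe_clip_limit, config.clahe_tile_grid)
    denoised, trace = denoise_pdhg(normalized, config.tv)
    logger.info("TV denoising: %d iterations, converged=%s", trace.iterations_run, trace.converged)

    pair, report = recursive_segment(denoised, config.quality)
    logger.info(
        "localization: %d thresholds tried (%.4f -> %.4f), satisfied=%s",
        len(report.theta_history),
        report.theta_history[0],
        report.theta_history[-1],
        report.satisfied,
    )

    edge = edge_map(denoised, config.acm.edge_sigma)
    finals = {}
    for name, mask in (("right", pair.right_lung), ("left", pair.left_lung)):
        if mask.sum() >= 3:
            hull = convex_hull_mask(mask)
            finals[name] = _refine_lung(denoised, hull, config, edge)
        else:
            finals[name] = np.zeros_like(mask)

    left = restore_mask(finals["left"], rec)
    right = restore_mask(finals["right"], rec)
    return SegmentationResult(
        left_lung=left,
        right_lung=right,
        combined=left | right,
        quality=report,
        resample=rec,
        config_echo=config.to_dict(),
    )
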