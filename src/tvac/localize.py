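"""Lung-field localization: recursive ISODATA binarization with quality checks.

The denoised radiograph is binarized at a global threshold chosen by the
ISODATA fixed-point iteration: starting from half the dynamic range, the
threshold is repeatedly replaced by the midpoint of the foreground and
background class means until it stops changing. Lungs are radiolucent, so
the foreground is the set of pixels BELOW the threshold.

Small components are removed by morphological area opening, and the two
lung candidates are picked as the components whose centroids lie nearest
the upper-left and upper-right expectation points. Each candidate pair is
scored against four quality criteria (lateral purity alpha, maximum
centroid row beta, maximum area fraction gamma, minimum area fraction
delta); if more than one check fails across the pair, the threshold is
reduced by 5% and binarization repeats, shrinking the masks toward the
darkest lung cores until an acceptable pair emerges.

Naming is anatomical: the patient's right lung sits on the image left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image, remove_small_objects

__all__ = [
    "QualityParams",
    "QualityReport",
    "LungPair",
    "InsufficientObjectsError",
    "isodata_threshold",
    "binarize",
    "area_opening",
    "select_lung_objects",
    "assess_quality",
    "recursive_segment",
    "convex_hull_mask",
]

CRITERIA = ("C_alpha", "C_beta", "C_gamma", "C_delta")


class InsufficientObjectsError(RuntimeError):
    """Fewer than two eligible lung candidates in a binarized image."""


@dataclass(frozen=True)
class QualityParams:
    """Thresholds of the four lung-candidate quality criteria.

    alpha
        Minimum fraction of an object's pixels on its designated side of
        the vertical midline (lateral purity).
    beta
        Maximum allowed centroid row after rescaling rows to a 256-row
        frame (lungs live in the upper thorax).
    gamma, delta
        Maximum / minimum object area as a fraction of image area.
    max_reductions, reduction_factor
        Recursion guard and the per-step threshold multiplier (0.95 = the
        5% reduction).
    """

    alpha: float = 0.98
    beta: float = 135.0
    gamma: float = 1.0 / 3.0
    delta: float = 1.0 / 100.0
    max_reductions: int = 40
    reduction_factor: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.delta < self.gamma <= 1:
            raise ValueError("need 0 < delta < gamma <= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.beta < 256:
            raise ValueError("beta must be in (0, 256)")
        if not 0 < self.reduction_factor < 1:
            raise ValueError("reduction_factor must be in (0, 1)")
        if self.max_reductions < 1:
            raise ValueError("max_reductions must be positive")


@dataclass
class QualityReport:
    per_criterion: dict[str, dict[str, bool]]
    violation_count: int
    satisfied: bool
    theta_history: list[float] = field(default_factory=list)


@dataclass
class LungPair:
    right_lung: np.ndarray  # anatomical right, image-left half
    left_lung: np.ndarray  # anatomical left, image-right half


def isodata_threshold(img: np.ndarray, max_iter: int = 500) -> float:
    """ISODATA fixed-point threshold of a grayscale image.

    theta_0 is half the dynamic range; each update sets theta to the mean of
    the foreground (pixels < theta) and background (pixels >= theta) class
    means, until the threshold stops changing. The update is monotone, so
    the iteration reaches an exact partition fixed point in finitely many
    steps; ``max_iter`` is only a safety guard.
    """
    vals = np.asarray(img, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("constant image has no ISODATA threshold")
    theta = (lo + hi) / 2.0
    for _ in range(max_iter):
        below = vals < theta
        fg = vals[below]
        bg = vals[~below]
        if fg.size == 0 or bg.size == 0:
            break
        new = (fg.mean() + bg.mean()) / 2.0
        if np.array_equal(vals < new, below):
            # update leaves the partition unchanged, so new is an exact fixed
            # point: re-applying the update returns new itself
            theta = new
            break
        theta = new
    return float(theta)


def binarize(img: np.ndarray, theta: float) -> np.ndarray:
    """Dark-foreground binarization: mask = 1 where ``img < theta``."""
    if not np.isfinite(theta):
        raise ValueError("threshold must be finite")
    return np.asarray(img) < theta


def area_opening(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_area`` pixels."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 1:
        return mask.copy()
    return remove_small_objects(mask, max_size=min_area - 1, connectivity=2)


def _border_fraction(region, shape: tuple[int, int]) -> float:
    """Fraction of a component's boundary pixels lying on the image frame.

    Boundary pixels are component pixels with a 4-neighbor outside the
    component (the bounding box is tight, so eroding the region image with
    zero padding marks them exactly).
    """
    img = region.image
    boundary = img & ~ndi.binary_erosion(img)
    total = int(boundary.sum())
    if total == 0:
        return 0.0
    r0, c0, r1, c1 = region.bbox
    on_frame = 0
    if r0 == 0:
        on_frame += int(boundary[0].sum())
    if r1 == shape[0]:
        on_frame += int(boundary[-1].sum())
    if c0 == 0:
        on_frame += int(boundary[:, 0].sum())
    if c1 == shape[1]:
        on_frame += int(boundary[:, -1].sum())
    return min(on_frame, total) / total


def select_lung_objects(mask: np.ndarray) -> LungPair:
    """Pick the two components nearest the upper-lateral expectation points.

    The anatomical right lung is the component whose centroid is nearest
    (0.375·rows, 0.25·cols); the anatomical left, nearest (0.375·rows,
    0.75·cols). Components with more than 25% of their boundary pixels on
    the image border are excluded (collimation / background guard).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    lab = label(mask, connectivity=2)
    regions = [r for r in regionprops(lab) if _border_fraction(r, mask.shape) <= 0.25]
    if len(regions) < 2:
        raise InsufficientObjectsError(
            f"need >= 2 eligible components, found {len(regions)}"
        )
    targets = {"right": (0.375 * rows, 0.25 * cols), "left": (0.375 * rows, 0.75 * cols)}

    def dist(region, tgt):
        return np.hypot(region.centroid[0] - tgt[0], region.centroid[1] - tgt[1])

    order_r = sorted(regions, key=lambda g: dist(g, targets["right"]))
    order_l = sorted(regions, key=lambda g: dist(g, targets["left"]))
    right, leftc = order_r[0], order_l[0]
    if right.label == leftc.label:
        # one component closest to both targets: give it to the closer side
        if dist(right, targets["right"]) <= dist(leftc, targets["left"]):
            leftc = next(g for g in order_l if g.label != right.label)
        else:
            right = next(g for g in order_r if g.label != leftc.label)
    return LungPair(right_lung=lab == right.label, left_lung=lab == leftc.label)


def assess_quality(pair: LungPair, params: QualityParams | None = None) -> QualityReport:
    """Evaluate the four criteria for each lung; at most one failure passes.

    The violation count runs over all eight (lung, criterion) checks and the
    pair is accepted when all but at most one are satisfied.
    """
    if params is None:
        params = QualityParams()
    rows, cols = pair.right_lung.shape
    image_area = rows * cols
    per: dict[str, dict[str, bool]] = {}
    for name, mask in (("right_lung", pair.right_lung), ("left_lung", pair.left_lung)):
        area = int(mask.sum())
        rr, cc = np.nonzero(mask)
        if area == 0:
            per[name] = {k: False for k in CRITERIA}
            continue
        if name == "right_lung":
            lateral = float(np.mean(cc < cols / 2.0))
        else:
            lateral = float(np.mean(cc >= cols / 2.0))
        centroid_row_256 = rr.mean() * 256.0 / rows
        per[name] = {
            "C_alpha": bool(lateral >= params.alpha),
            "C_beta": bool(centroid_row_256 <= params.beta),
            "C_gamma": bool(area <= params.gamma * image_area),
            "C_delta": bool(area >= params.delta * image_area),
        }
    violations = sum(not ok for checks in per.values() for ok in checks.values())
    return QualityReport(per_criterion=per, violation_count=violations, satisfied=violations <= 1)


def recursive_segment(
    img: np.ndarray, params: QualityParams | None = None
) -> tuple[LungPair, QualityReport]:
    """Binarize at the ISODATA threshold, reducing it by 5% until quality holds.

    Each attempt binarizes, area-opens (minimum area delta/2 of the image),
    selects the two lung candidates and scores them. The first attempt with
    at most one violation is returned; otherwise, after ``max_reductions``
    reductions, the best-scoring attempt is returned with
    ``satisfied=False``. ``theta_history`` lists every threshold tried.
    """
    if params is None:
        params = QualityParams()
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant image cannot be segmented")
    rows, cols = img.shape
    min_area = max(1, int(params.delta / 2.0 * rows * cols))

    theta = isodata_threshold(img)
    history: list[float] = []
    best: tuple[int, LungPair, QualityReport] | None = None
    for _ in range(params.max_reductions + 1):
        history.append(theta)
        try:
            opened = area_opening(binarize(img, theta), min_area)
            pair = select_lung_objects(opened)
            report = assess_quality(pair, params)
        except InsufficientObjectsError:
            pair = LungPair(
                right_lung=np.zeros((rows, cols), dtype=bool),
                left_lung=np.zeros((rows, cols), dtype=bool),
            )
            report = QualityReport(
                per_criterion={
                    "right_lung": {k: False for k in CRITERIA},
                    "left_lung": {k: False for k in CRITERIA},
                },
                violation_count=len(CRITERIA) * 2,
                satisfied=False,
            )
        if best is None or report.violation_count < best[0]:
            best = (report.violation_count, pair, report)
        if report.satisfied:
            report.theta_history = history
            return pair, report
        theta *= params.reduction_factor

    _, pair, report = best
    report.theta_history = history
    report.satisfied = False
    return pair, report


def convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of a mask's foreground pixels (a superset of it)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("convex hull requires at least 3 foreground pixels")
    return convex_hull_image(mask)
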