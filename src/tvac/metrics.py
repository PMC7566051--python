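"""Segmentation evaluation: Dice overlap, failure rule, cohort summaries.

The Sørensen–Dice coefficient between a predicted mask A and a ground-truth
mask B is ``2·TP / (2·TP + FP + FN)`` over pixel counts. A Dice below 0.70
is classified as a failed lung segmentation — the lowest overlap still
usable for downstream feature extraction. Cohort distributions are
summarized by mean, minimum and sample standard deviation, and by a
Gaussian kernel density estimate (the ingredient of a violin plot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAILURE_CUTOFF",
    "ConfusionCounts",
    "CohortSummary",
    "confusion_counts",
    "dice",
    "is_failure",
    "cohort_summary",
    "dice_kde",
    "silverman_bandwidth",
]

FAILURE_CUTOFF = 0.70


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int


@dataclass
class CohortSummary:
    n: int
    dice_mean: float
    dice_min: float
    dice_sd: float
    failures: int
    per_case: list[tuple[str, float, bool]]


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    return ConfusionCounts(TP=tp, FP=int(pred.sum()) - tp, FN=int(truth.sum()) - tp)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sørensen–Dice coefficient ``2TP/(2TP+FP+FN)``; 1.0 when both are empty."""
    c = confusion_counts(pred, truth)
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        return 1.0
    return 2.0 * c.TP / denom


def is_failure(d: float) -> bool:
    """Failed segmentation: Dice strictly under 0.70."""
    return d < FAILURE_CUTOFF


def cohort_summary(cases: list[tuple[str, np.ndarray, np.ndarray]]) -> CohortSummary:
    """Per-case Dice plus mean / min / sample SD (n-1) and failure count."""
    if not cases:
        raise ValueError("cohort_summary requires at least one case")
    per_case = []
    for case_id, pred, truth in cases:
        d = dice(pred, truth)
        per_case.append((str(case_id), d, is_failure(d)))
    ds = np.array([d for _, d, _ in per_case])
    if len(ds) == 1:
        warnings.warn("sample standard deviation undefined for n=1; reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(ds, ddof=1))
    return CohortSummary(
        n=len(ds),
        dice_mean=float(ds.mean()),
        dice_min=float(ds.min()),
        dice_sd=sd,
        failures=int(sum(f for _, _, f in per_case)),
        per_case=per_case,
    )


def silverman_bandwidth(points: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9·min(sd, IQR/1.34)·n^(-1/5)."""
    points = np.asarray(points, dtype=float)
    sd = points.std(ddof=1) if points.size > 1 else 0.0
    q75, q25 = np.percentile(points, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if (q75 > q25 and sd > 0) else max(sd, (q75 - q25) / 1.34)
    if spread == 0:
        spread = max(abs(points).max(), 1.0) * 0.01
    return 0.9 * spread * points.size ** (-0.2)


def dice_kde(
    dices: list[float], grid: np.ndarray, bandwidth: float | None = None
) -> np.ndarray:
    """Gaussian kernel density estimate of a Dice distribution on ``grid``.

    This is the density a violin plot mirrors. ``bandwidth`` is the kernel
    standard deviation; Silverman's rule when omitted.
    """
    pts = np.asarray(dices, dtype=float)
    if pts.size < 2:
        raise ValueError("kernel density estimate requires at least 2 points")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - pts[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (pts.size * bandwidth * np.sqrt(2 * np.pi))
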