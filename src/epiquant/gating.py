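"""Negative-sample elimination via the average proportion (AP) statistic.

Negative-control slides (no primary antibody) still show scattered dark
pixels, so a slide is only segmented when enough of its DAB channel is
dark.  The AP statistic is the percentage of pixels in the (cropped) DAB
grayscale image darker than a pixel-intensity threshold; a sample is
called positive when AP is at or above a cutoff calibrated by ROC/Youden
analysis on labeled controls (default 0.6%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GateParams:
    """Pixel darkness threshold and AP percentage cutoff."""

    pixel_threshold: float = 153.0  # 0.6 * 255 on the 8-bit DAB grayscale
    ap_cutoff: float = 0.6  # percent

    def __post_init__(self) -> None:
        if not 0 < self.pixel_threshold < 255:
            raise ValueError("pixel_threshold must be in (0, 255)")
        if not 0 < self.ap_cutoff <= 100:
            raise ValueError("ap_cutoff must be in (0, 100]")


@dataclass(frozen=True)
class GateResult:
    """AP value and the positive/negative call for one image."""

    ap_percent: float
    is_positive: bool
    pixel_threshold: float
    ap_cutoff: float


@dataclass(frozen=True)
class CalibrationResult:
    """ROC/Youden calibration of the AP cutoff on labeled controls."""

    best_cutoff: float
    auc: float
    youden_j: float
    roc_points: list[tuple[float, float]] = field(repr=False)


def average_proportion(
    dab_gray: np.ndarray,
    tissue: np.ndarray | None = None,
    pixel_threshold: float = GateParams.pixel_threshold,
) -> float:
    """AP = 100 * (pixels darker than threshold) / (pixels in the frame).

    The denominator is the whole (cropped) image frame; ``tissue`` is
    accepted for alignment checking only.
    """
    dab_gray = np.asarray(dab_gray)
    if dab_gray.size == 0:
        raise ValueError("empty evaluation region")
    if tissue is not None and np.asarray(tissue).shape != dab_gray.shape:
        raise ValueError("tissue mask is not aligned to the DAB image")
    return 100.0 * float(np.count_nonzero(dab_gray < pixel_threshold)) / dab_gray.size


def classify_sample(ap: float, ap_cutoff: float = GateParams.ap_cutoff) -> bool:
    """True (DAB-positive, proceed to segmentation) iff ``ap >= ap_cutoff``."""
    return ap >= ap_cutoff


def gate(
    dab_gray: np.ndarray,
    tissue: np.ndarray | None = None,
    params: GateParams = GateParams(),
) -> GateResult:
    """Compute AP and the positivity call in one step."""
    ap = average_proportion(dab_gray, tissue, params.pixel_threshold)
    return GateResult(
        ap_percent=ap,
        is_positive=classify_sample(ap, params.ap_cutoff),
        pixel_threshold=params.pixel_threshold,
        ap_cutoff=params.ap_cutoff,
    )


def calibrate_ap_cutoff(
    labeled: list[tuple[float, bool]],
    grid_min: float = 0.1,
    grid_max: float = 1.0,
    grid_step: float = 0.01,
) -> CalibrationResult:
    """Sweep AP cutoffs on a grid and maximize the Youden index.

    ``labeled`` holds ``(ap_percent, is_positive_label)`` pairs.  For each
    cutoff, predicted-positive means ``AP >= cutoff``; J = TPR - FPR is
    maximized (ties toward the smallest cutoff) and AUC is the trapezoid
    area of the grid ROC closed at (0,0) and (1,1).  Raises ``ValueError``
    when only one class is present.
    """
    aps = np.array([a for a, _ in labeled], float)
    ys = np.array([bool(l) for _, l in labeled])
    n_pos = int(ys.sum())
    n_neg = int((~ys).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cannot calibrate: both labels must be present")
    n = int(round((grid_max - grid_min) / grid_step))
    cutoffs = grid_min + grid_step * np.arange(n + 1)
    pred = aps[None, :] >= cutoffs[:, None]  # (n_cutoffs, n_samples)
    tpr = (pred & ys).sum(axis=1) / n_pos
    fpr = (pred & ~ys).sum(axis=1) / n_neg
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (smallest) cutoff on ties
    # ROC: cutoffs descending give FPR ascending; close the curve at the corners
    order = np.argsort(-cutoffs, kind="stable")
    roc_fpr = np.concatenate([[0.0], fpr[order], [1.0]])
    roc_tpr = np.concatenate([[0.0], tpr[order], [1.0]])
    auc = float(np.trapezoid(roc_tpr, roc_fpr))
    return CalibrationResult(
        best_cutoff=float(cutoffs[best]),
        auc=auc,
        youden_j=float(j[best]),
        roc_points=list(zip(roc_fpr.tolist(), roc_tpr.tolist())),
    )
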