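"""Evaluation metrics for midline predictions.

Two complementary metrics, both against the by-construction ground
truth of the synthetic data:

* point-wise MAPE — the mean absolute relative error of the predicted
  posterior/anterior coordinates; and
* midline mIoU — the mask is split into left/right vocal-fold areas by
  the ground-truth and the predicted midline, and the two side-wise
  intersection-over-union values are averaged.

Both are needed: a prediction slid along the true axis has a large MAPE
but still splits the area correctly (mIoU ~ 1), while a small MAPE can
hide a slope error that badly mis-assigns area to the two folds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .detectors import Midline

__all__ = [
    "EvalRecord",
    "mape_point",
    "split_by_midline",
    "miou_midline",
    "miou_segmentation",
    "cumulative_miou",
]


@dataclass
class EvalRecord:
    """One detector evaluation at one GAW peak.

    ``mape_P``/``mape_A`` use the relative-Euclidean-distance reading
    of the point error (``|pred - gt| / |gt|``); the coordinate-wise
    alternative is reported alongside as ``mape_P_coord``/``mape_A_coord``.
    """

    sequence_id: int
    peak_frame: int
    algorithm: str
    half_range: int
    pred_P: tuple | None
    pred_A: tuple | None
    mape_P: float
    mape_A: float
    miou: float
    mape_P_coord: float = float("nan")
    mape_A_coord: float = float("nan")
    failed: bool = False
    error: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def mape_point(pred, gt, euclidean: bool = False,
               percent: bool = False) -> float:
    """Mean absolute percentage error between two points.

    Coordinate-wise by default: the mean of ``|dx/x_gt|`` and
    ``|dy/y_gt|``, returned as a fraction.  With ``euclidean=True`` the
    alternative reading ``|pred - gt| / |gt|`` (relative Euclidean
    distance) is used.  ``percent`` multiplies by 100.
    """
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if euclidean:
        denom = np.linalg.norm(gt)
        if denom == 0:
            raise ValueError("ground-truth point at the origin: "
                             "relative error undefined")
        val = np.linalg.norm(pred - gt) / denom
    else:
        if np.any(gt == 0):
            raise ValueError("ground-truth coordinate is zero: "
                             "relative error undefined")
        val = float(np.mean(np.abs((gt - pred) / gt)))
    return 100.0 * val if percent else float(val)


def split_by_midline(mask: np.ndarray, midline: Midline):
    """Partition foreground pixels by the side of the (infinite)
    midline.

    "Left" is the negative side of the P->A direction's normal (for a
    downward axis this is the smaller-x side); pixel centers exactly on
    the line go left, so left + right always reproduces the mask.
    """
    mask = np.asarray(mask)
    fg = mask > 0
    H, W = mask.shape
    P = np.asarray(midline.P, dtype=float)
    d = midline.direction
    ys, xs = np.nonzero(fg)
    # signed distance: positive on the right of P->A
    s = (xs - P[0]) * d[1] - (ys - P[1]) * d[0]
    left = np.zeros_like(fg)
    right = np.zeros_like(fg)
    right_sel = s > 0
    left[ys[~right_sel], xs[~right_sel]] = True
    right[ys[right_sel], xs[right_sel]] = True
    return left, right


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU with the empty-set convention IoU(0, 0) = 1."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def miou_segmentation(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Plain mask IoU (used for segmentation heads)."""
    return _iou(np.asarray(gt_mask) > 0, np.asarray(pred_mask) > 0)


def miou_midline(mask: np.ndarray, gt_midline: Midline,
                 pred_midline: Midline) -> float:
    """Mean of the left- and right-side IoU of the two area splits."""
    gt_l, gt_r = split_by_midline(mask, gt_midline)
    pr_l, pr_r = split_by_midline(mask, pred_midline)
    return 0.5 * (_iou(gt_l, pr_l) + _iou(gt_r, pr_r))


def cumulative_miou(scores) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of mIoU scores.

    Returns ``(x, F)`` with x the sorted scores and F the fraction of
    scores <= x.  The ideal curve (all scores 1) is a single step at 1.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    if len(x) == 0:
        raise ValueError("no scores")
    F = np.arange(1, len(x) + 1) / len(x)
    return x, F
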