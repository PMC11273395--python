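"""Score-map post-processing and scan-/pixel-wise evaluation metrics.

A score map (ALM upscale or uncertainty map) becomes an anomaly
segmentation by strict thresholding (value > t, so a threshold of 0 flags
any nonzero uncertainty), morphological opening then dilation with disk
structuring elements, and removal of small connected components
(8-connectivity, area < s).

Scan-wise metrics: AUROC, average precision, and F1 at the Youden-index
operating point.  Pixel-wise metrics: Dice, IoU, sensitivity, specificity,
with the both-empty convention Dice = IoU = 1 so anomaly-free evaluation
images do not poison averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, opening
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class PostprocessConfig:
    """Desk-scale defaults; radii/area scale with resolution (s = 64 px^2 at
    480 px corresponds to ~5 px^2 at 128 px)."""

    threshold: float = 0.05
    opening_radius: int = 1
    dilation_radius: int = 2
    min_area: int = 5

    def validate(self) -> None:
        if self.opening_radius < 0 or self.dilation_radius < 0 or self.min_area < 0:
            raise ValueError("radii and min_area must be >= 0")


@dataclass
class ScanEvalReport:
    auroc: float
    average_precision: float
    f1_at_youden: float
    operating_threshold: float


@dataclass
class PixelEvalReport:
    per_image: pd.DataFrame            # columns: image, dice, iou, sensitivity, specificity
    summary: Dict[str, Tuple[float, float]]   # metric -> (mean, sd)


def binarize(score_map: np.ndarray, threshold: float) -> np.ndarray:
    """Strict thresholding: pixel is anomalous iff value > threshold."""
    m = np.asarray(score_map, dtype=np.float64)
    if not np.isfinite(m).all():
        raise ValueError("score map contains non-finite values")
    return m > threshold


def refine(binary: np.ndarray, cfg: PostprocessConfig) -> np.ndarray:
    """Opening, dilation, then removal of components with area < min_area."""
    cfg.validate()
    b = np.asarray(binary, dtype=bool)
    if cfg.opening_radius > 0:
        b = opening(b, disk(cfg.opening_radius)).astype(bool)
    if cfg.dilation_radius > 0:
        b = dilation(b, disk(cfg.dilation_radius)).astype(bool)
    if cfg.min_area > 0:
        lab, n = cc_label(b, connectivity=2, return_num=True)
        if n:
            areas = np.bincount(lab.ravel())
            keep = areas >= cfg.min_area
            keep[0] = False
            b = keep[lab]
    return b


# ---------------------------------------------------------------------------
# pixel-wise metrics
# ---------------------------------------------------------------------------

def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); both-empty convention: 1."""
    a, b = np.asarray(pred, dtype=bool), np.asarray(gt, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou_sens_spec(pred: np.ndarray, gt: np.ndarray) -> Tuple[float, float, float]:
    """(IoU, sensitivity, specificity); empty denominators with zero error
    count return 1."""
    a, b = np.asarray(pred, dtype=bool), np.asarray(gt, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    tp = np.logical_and(a, b).sum()
    fp = np.logical_and(a, ~b).sum()
    fn = np.logical_and(~a, b).sum()
    tn = np.logical_and(~a, ~b).sum()
    iou = 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
    sens = 1.0 if tp + fn == 0 else tp / (tp + fn)
    spec = 1.0 if tn + fp == 0 else tn / (tn + fp)
    return float(iou), float(sens), float(spec)


# ---------------------------------------------------------------------------
# scan-wise metrics
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC = P(random diseased score > random healthy score), ties 1/2."""
    s, y = np.asarray(scores, dtype=np.float64), np.asarray(labels, dtype=int)
    _check_two_classes(y)
    return float(roc_auc_score(y, s))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise average precision over descending-score thresholds."""
    s, y = np.asarray(scores, dtype=np.float64), np.asarray(labels, dtype=int)
    _check_two_classes(y)
    return float(average_precision_score(y, s))


def f1_at_youden(scores: Sequence[float], labels: Sequence[int]
                 ) -> Tuple[float, float]:
    """F1 at the threshold maximizing the Youden index (sens + spec - 1).

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores, plus one candidate below the minimum and one above the maximum
    (the all-positive / all-negative operating points).  Youden ties are
    broken toward higher specificity.
    """
    s, y = np.asarray(scores, dtype=np.float64), np.asarray(labels, dtype=int)
    _check_two_classes(y)
    uniq = np.unique(s)
    cand = [uniq[0] - 1.0] + list((uniq[:-1] + uniq[1:]) / 2.0) + [uniq[-1] + 1.0]
    best = None
    for t in cand:
        pred = s > t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            best = (key, f1, float(t))
    return best[1], best[2]


def scanwise_from_map(score_map: np.ndarray, threshold: float) -> float:
    """Scan score: sum of map values strictly above the threshold."""
    m = np.asarray(score_map, dtype=np.float64)
    if not np.isfinite(m).all():
        raise ValueError("score map contains non-finite values")
    return float(m[m > threshold].sum())


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def scan_eval(scores: Sequence[float], labels: Sequence[int]) -> ScanEvalReport:
    f1, thr = f1_at_youden(scores, labels)
    return ScanEvalReport(auroc=auroc(scores, labels),
                          average_precision=average_precision(scores, labels),
                          f1_at_youden=f1, operating_threshold=thr)


def pixel_eval(pairs: Sequence[Tuple[str, np.ndarray, np.ndarray]]
               ) -> PixelEvalReport:
    """Per-image Dice/IoU/sensitivity/specificity and mean ± sd summary.

    `pairs` holds (image name, predicted segmentation, ground-truth mask).
    """
    rows: List[dict] = []
    for name, pred, gt in pairs:
        d = dice(pred, gt)
        i, sn, sp = iou_sens_spec(pred, gt)
        rows.append({"image": name, "dice": d, "iou": i,
                     "sensitivity": sn, "specificity": sp})
    cols = ("dice", "iou", "sensitivity", "specificity")
    df = pd.DataFrame(rows, columns=("image",) + cols)
    summary = {m: (float(df[m].mean()), float(df[m].std(ddof=0))) for m in cols}
    return PixelEvalReport(per_image=df, summary=summary)
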