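"""Counting and segmentation metrics.

Counting quality over n images with true counts y_i and predictions
y_hat_i:

    RMSE = sqrt( (1/n) sum (y_i - y_hat_i)^2 )
    Bias = (1/n) sum (y_i - y_hat_i)
    R^2  = 1 - SS_res / SS_tot

Bias follows the printed formula mean(y - y_hat) literally: with this
sign, a positive Bias means the model under-counts.  Segmentation quality
uses mask IoU with greedy score-descending matching, the 101-point
interpolated average precision (COCO convention), and mAP averaged over
IoU thresholds 0.50:0.05:0.95, with mAP50/mAP75 at the fixed thresholds.
Images are stratified into four density levels by quartiles of their
ground-truth counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

RECALL_GRID = np.linspace(0.0, 1.0, 101)
MAP_THRESHOLDS = np.arange(0.50, 0.96, 0.05)


@dataclass(frozen=True)
class CountPair:
    image_id: int
    y: float
    y_hat: float

    def __post_init__(self) -> None:
        if self.y < 0:
            raise ValueError("true count must be >= 0")


@dataclass(frozen=True)
class CountingMetrics:
    rmse: float
    bias: float
    r2: float
    n: int


@dataclass(frozen=True)
class MatchResult:
    """Per-image detection outcomes at one IoU threshold."""

    scores: np.ndarray       # detection scores, any order
    is_tp: np.ndarray        # same length, boolean
    num_gt: int
    iou_threshold: float


@dataclass(frozen=True)
class ApResult:
    ap: float
    precision: np.ndarray
    recall: np.ndarray
    iou_threshold: float


def counting_metrics(pairs: list[CountPair]) -> CountingMetrics:
    """RMSE / Bias / R^2 over a set of (true, predicted) count pairs."""
    if not pairs:
        raise ValueError("no count pairs")
    y = np.array([p.y for p in pairs], float)
    yhat = np.array([p.y_hat for p in pairs], float)
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean(err))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant true counts: R^2 undefined", stacklevel=2)
        r2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return CountingMetrics(rmse=rmse, bias=bias, r2=r2, n=len(pairs))


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A n B| / |A u B| of two same-shape binary masks (0 when both empty)."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty: IoU defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_detections(detections, gt_masks, iou_threshold: float = 0.5,
                     iou_matrix: np.ndarray | None = None) -> MatchResult:
    """Greedy score-descending matching of detections to ground truth.

    ``detections`` is a list of objects with ``score`` and ``mask``
    attributes (or (score, mask) tuples); ``gt_masks`` a list of binary
    masks.  A detection is a TP if its best-IoU *unmatched* gt reaches the
    threshold, else a FP; unmatched gts are FNs.  ``iou_matrix`` may be
    passed to reuse precomputed detection x gt IoUs.
    """
    def unpack(d):
        if hasattr(d, "score"):
            return float(d.score), d.mask
        return float(d[0]), d[1]

    pairs = [unpack(d) for d in detections]
    scores = np.array([s for s, _ in pairs], float)
    order = np.argsort(-scores, kind="stable")
    if iou_matrix is None:
        iou_matrix = np.array([
            [mask_iou(m, g) if m is not None else 0.0 for g in gt_masks]
            for _, m in pairs
        ]).reshape(len(pairs), len(gt_masks))
    matched = np.zeros(len(gt_masks), bool)
    is_tp = np.zeros(len(pairs), bool)
    for i in order:
        if len(gt_masks) == 0:
            break
        ious = np.where(matched, -1.0, iou_matrix[i])
        best = int(ious.argmax())
        if ious[best] >= iou_threshold:
            matched[best] = True
            is_tp[i] = True
    return MatchResult(scores=scores, is_tp=is_tp, num_gt=len(gt_masks),
                       iou_threshold=iou_threshold)


def average_precision(results: list[MatchResult],
                      interpolation: str = "101point") -> ApResult:
    """AP from pooled per-image match results.

    ``interpolation``: "101point" (COCO recall grid) or "allpoint" (exact
    area under the precision envelope), the latter kept as the
    hand-checkable oracle variant.
    """
    num_gt = sum(r.num_gt for r in results)
    if num_gt == 0:
        raise ValueError("no ground-truth instances in the pool")
    scores = np.concatenate([r.scores for r in results]) if results else np.array([])
    flags = np.concatenate([r.is_tp for r in results]) if results else np.array([])
    thr = results[0].iou_threshold if results else 0.5
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(flags[order])
    fp = np.cumsum(~flags[order])
    recall = tp / num_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope (monotone nonincreasing from the right)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101point":
        idx = np.searchsorted(recall, RECALL_GRID, side="left")
        sampled = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
        if len(envelope) == 0:
            sampled = np.zeros_like(RECALL_GRID)
        ap = float(sampled.mean())
    elif interpolation == "allpoint":
        r_prev = np.concatenate([[0.0], recall])
        ap = float(np.sum((recall - r_prev[:-1]) * envelope))
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return ApResult(ap=ap, precision=precision, recall=recall,
                    iou_threshold=thr)


def map_suite(per_image: list[tuple[list, list]],
              thresholds: np.ndarray = MAP_THRESHOLDS,
              ) -> dict[str, float]:
    """Mask mAP over IoU thresholds 0.50:0.05:0.95 plus mAP50 / mAP75.

    ``per_image`` is a list of (detections, gt_masks) pairs.  IoUs are
    computed once per image and reused across thresholds.  Values are
    percentages.
    """
    cached = []
    for detections, gt_masks in per_image:
        def unpack(d):
            if hasattr(d, "score"):
                return float(d.score), d.mask
            return float(d[0]), d[1]
        pairs = [unpack(d) for d in detections]
        iou_matrix = np.array([
            [mask_iou(m, g) if m is not None else 0.0 for g in gt_masks]
            for _, m in pairs
        ]).reshape(len(pairs), len(gt_masks))
        cached.append((detections, gt_masks, iou_matrix))
    aps = {}
    for thr in thresholds:
        results = [
            match_detections(dets, gts, iou_threshold=float(thr),
                             iou_matrix=iou)
            for dets, gts, iou in cached
        ]
        aps[round(float(thr), 2)] = average_precision(results).ap
    return {
        "mAP": 100.0 * float(np.mean(list(aps.values()))),
        "mAP50": 100.0 * aps[0.5],
        "mAP75": 100.0 * aps[0.75],
    }


def stratify_by_density(counts: dict[int, int], n_levels: int = 4,
                        ) -> tuple[dict[int, int], list[float]]:
    """Bin images into density levels by quantiles of ground-truth count.

    Returns (image_id -> level in 1..n_levels, bin edges).  Ties at an
    edge go to the lower level; with too few distinct counts the top
    levels may be empty (degenerate-bin warning).
    """
    ids = list(counts)
    values = np.array([counts[i] for i in ids], float)
    edges = np.quantile(values, np.linspace(0, 1, n_levels + 1)[1:-1])
    if len(np.unique(values)) < n_levels:
        warnings.warn("fewer distinct counts than levels: degenerate bins",
                      stacklevel=2)
    levels = {
        i: int(np.searchsorted(edges, v, side="left")) + 1
        for i, v in zip(ids, values)
    }
    return levels, [float(e) for e in edges]
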