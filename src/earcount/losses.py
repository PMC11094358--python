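"""Training losses: prior matching, detection, classification, mask, density.

The composite objective is

    L_total = 1.0 * L_cla + 1.5 * (L_obj + L_box) + 6.125 * L_seg
              + w_density * L_density

with L_obj a binary cross-entropy on per-prior objectness (hard-negative
mined at 3:1 negatives per positive), L_box a smooth-L1 on encoded box
offsets over positive priors, L_cla a cross-entropy over prior class
labels (background for negatives), L_seg a per-pixel binary cross-entropy
between assembled prototype masks and rasterized ground-truth masks
(cropped to the ground-truth box), and L_density the mean over FPN levels
of the density-map MSE.  All components are nonnegative and averaged by
positive count (or counted priors) as noted per function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import encode_boxes
from .nn import Tensor, as_tensor, stack

DEFAULT_WEIGHTS = {"cla": 1.0, "det": 1.5, "seg": 6.125, "density": 1.0}

_EPS = 1e-12


@dataclass(frozen=True)
class LossBreakdown:
    """Component losses, weights, and the weighted total."""

    l_cla: float
    l_obj: float
    l_box: float
    l_seg: float
    l_density: float
    w_cla: float = 1.0
    w_det: float = 1.5
    w_seg: float = 6.125
    w_density: float = 1.0

    def __post_init__(self) -> None:
        for name in ("l_cla", "l_obj", "l_box", "l_seg", "l_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative loss component {name}")

    @property
    def total(self) -> float:
        return (self.w_cla * self.l_cla
                + self.w_det * (self.l_obj + self.l_box)
                + self.w_seg * self.l_seg
                + self.w_density * self.l_density)

    def as_dict(self) -> dict[str, float]:
        return {
            "l_cla": self.l_cla, "l_obj": self.l_obj, "l_box": self.l_box,
            "l_seg": self.l_seg, "l_density": self.l_density,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# matching


def box_iou_cxcywh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (cx, cy, w, h) box arrays -> (len(a), len(b))."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    ax0, ay0 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax1, ay1 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx0, by0 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx1, by1 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    ix = np.clip(np.minimum(ax1[:, None], bx1) - np.maximum(ax0[:, None], bx0), 0, None)
    iy = np.clip(np.minimum(ay1[:, None], by1) - np.maximum(ay0[:, None], by0), 0, None)
    inter = ix * iy
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    union = area_a[:, None] + area_b - inter
    return np.where(union > 0, inter / np.maximum(union, _EPS), 0.0)


def match_priors(priors: np.ndarray, gt_boxes: np.ndarray,
                 iou_pos: float = 0.5, iou_neg: float = 0.4) -> np.ndarray:
    """Assign each prior a ground-truth index, negative, or ignored.

    Returns an int array over priors: ``>= 0`` the matched gt index,
    ``-1`` negative (background), ``-2`` ignored (IoU between the two
    thresholds).  Every gt is guaranteed at least its best-IoU prior as a
    positive, even below ``iou_pos``.
    """
    p = len(priors)
    assign = np.full(p, -1, dtype=np.int64)
    gt_boxes = np.asarray(gt_boxes, float).reshape(-1, 4)
    if len(gt_boxes) == 0:
        return assign
    iou = box_iou_cxcywh(priors, gt_boxes)  # (P, G)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(p), best_gt]
    assign[best_iou >= iou_pos] = best_gt[best_iou >= iou_pos]
    assign[(best_iou < iou_pos) & (best_iou >= iou_neg)] = -2
    # best-prior guarantee, processed per gt so later gts can steal a
    # contested prior only if it is their own best
    best_prior = iou.argmax(axis=0)
    for g, pr in enumerate(best_prior):
        assign[pr] = g
    return assign


# ---------------------------------------------------------------------------
# component losses (autograd-aware: accept Tensors, return scalar Tensors)


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (stable via softplus)."""
    t = np.asarray(targets, float)
    # log(1+e^z) - t*z
    return logits.softplus() - logits * t


def detection_loss(outputs, assignments: np.ndarray, gt_boxes: np.ndarray,
                   priors: np.ndarray, neg_pos_ratio: int = 3,
                   ) -> tuple[Tensor, Tensor]:
    """(l_obj, l_box) for one image.

    l_obj: BCE of objectness over positives plus the hardest negatives at
    ``neg_pos_ratio`` per positive, averaged by the number of counted
    priors.  l_box: smooth-L1 over positive priors on encoded offsets,
    averaged by positive count (zero when there are no positives).
    """
    obj_logits = outputs.objectness_logits
    if obj_logits.ndim == 2:
        obj_logits = obj_logits.reshape(-1)
    box_offsets = outputs.box_offsets
    if box_offsets.ndim == 3:
        box_offsets = box_offsets.reshape(-1, 4)

    pos = np.where(assignments >= 0)[0]
    neg_pool = np.where(assignments == -1)[0]
    n_pos = len(pos)

    # hard-negative mining: highest-objectness negatives
    n_neg = min(len(neg_pool), max(neg_pos_ratio * n_pos, 1))
    neg_scores = obj_logits.data[neg_pool]
    neg = neg_pool[np.argsort(-neg_scores)[:n_neg]]

    counted = np.concatenate([pos, neg])
    targets = np.concatenate([np.ones(n_pos), np.zeros(len(neg))])
    bce = _bce_with_logits(obj_logits[counted], targets)
    denom = max(n_pos, 1)
    l_obj = bce.sum() * (1.0 / max(len(counted), 1))

    if n_pos == 0:
        return l_obj, as_tensor(0.0)
    gt_boxes = np.asarray(gt_boxes, float).reshape(-1, 4)
    encoded = encode_boxes(gt_boxes[assignments[pos]], priors[pos])
    diff = box_offsets[pos] - encoded
    absd = (diff ** 2 + _EPS) ** 0.5  # |x| with smooth gradient at 0
    quad = diff ** 2 * 0.5
    lin = absd - 0.5
    mask = (np.abs(diff.data) < 1.0).astype(float)
    smooth_l1 = quad * mask + lin * (1.0 - mask)
    l_box = smooth_l1.sum() * (1.0 / denom)
    return l_obj, l_box


def classification_loss(outputs, assignments: np.ndarray,
                        gt_labels: np.ndarray | None = None) -> Tensor:
    """Cross-entropy over counted priors (positives + negatives).

    Negatives take the background class 0; positives take their gt label
    (class 1 in the single-category setting).  Mean-reduced over counted
    priors; ignored priors do not contribute.
    """
    class_logits = outputs.class_logits
    if class_logits.ndim == 3:
        class_logits = class_logits.reshape(-1, class_logits.shape[-1])
    counted = np.where(assignments >= -1)[0]
    if len(counted) == 0:
        return as_tensor(0.0)
    labels = np.zeros(len(counted), dtype=np.int64)
    pos_mask = assignments[counted] >= 0
    if gt_labels is None:
        labels[pos_mask] = 1
    else:
        gt_labels = np.asarray(gt_labels, dtype=np.int64)
        labels[pos_mask] = gt_labels[assignments[counted][pos_mask]]
    logits = class_logits[counted]
    # log-softmax cross-entropy
    shifted = logits - as_tensor(logits.data.max(axis=1, keepdims=True))
    log_z = shifted.exp().sum(axis=1, keepdims=True).log()
    log_probs = shifted - log_z
    picked = log_probs[np.arange(len(counted)), labels]
    return -picked.mean()


def assemble_masks(prototypes: Tensor | np.ndarray,
                   coefficients: Tensor | np.ndarray,
                   bbox: tuple[float, float, float, float] | None = None,
                   ) -> Tensor:
    """sigmoid(sum_j coeff_j * prototype_j), cropped to ``bbox``.

    ``prototypes`` is (k, H, W); ``coefficients`` length k.  ``bbox`` is
    (x, y, w, h) normalized to [0, 1]; pixels outside it are zeroed.
    """
    protos = as_tensor(prototypes)
    coeff = as_tensor(coefficients)
    if coeff.shape[0] != protos.shape[0]:
        raise ValueError(
            f"{coeff.shape[0]} coefficients for {protos.shape[0]} prototypes"
        )
    k, h, w = protos.shape
    lin = (protos * coeff.reshape(k, 1, 1)).sum(axis=0)
    prob = lin.sigmoid()
    if bbox is not None:
        x, y, bw, bh = bbox
        x0 = int(np.clip(np.floor(x * w), 0, w))
        x1 = int(np.clip(np.ceil((x + bw) * w), 0, w))
        y0 = int(np.clip(np.floor(y * h), 0, h))
        y1 = int(np.clip(np.ceil((y + bh) * h), 0, h))
        crop = np.zeros((h, w))
        crop[y0:y1, x0:x1] = 1.0
        prob = prob * crop
    return prob


def mask_loss(outputs, assignments: np.ndarray, gt_masks: np.ndarray,
              gt_boxes: np.ndarray, max_masks: int = 32,
              rng: np.random.Generator | None = None) -> Tensor:
    """Assembled-mask BCE against rasterized gt masks, cropped to gt boxes.

    ``gt_masks`` is (G, Hp, Wp) binary at prototype resolution; ``gt_boxes``
    (G, 4) normalized cxcywh.  Per-positive BCE is averaged over the gt
    bbox pixels, then over positives.  At most ``max_masks`` positives are
    scored (sampled when exceeded) to bound cost.
    """
    protos = outputs.prototypes
    if protos.ndim == 4:
        protos = protos.reshape(protos.shape[1:])
    coefs = outputs.mask_coefficients
    if coefs.ndim == 3:
        coefs = coefs.reshape(-1, coefs.shape[-1])
    pos = np.where(assignments >= 0)[0]
    if len(pos) == 0:
        return as_tensor(0.0)
    if len(pos) > max_masks:
        rng = rng or np.random.default_rng(0)
        pos = rng.choice(pos, size=max_masks, replace=False)
    k, h, w = protos.shape
    gt_masks = np.asarray(gt_masks, float)
    gt_boxes = np.asarray(gt_boxes, float).reshape(-1, 4)
    per_mask = []
    for prior_idx in pos:
        g = assignments[prior_idx]
        cx, cy, bw, bh = gt_boxes[g]
        x0 = int(np.clip(np.floor((cx - bw / 2) * w), 0, w - 1))
        x1 = int(np.clip(np.ceil((cx + bw / 2) * w), x0 + 1, w))
        y0 = int(np.clip(np.floor((cy - bh / 2) * h), 0, h - 1))
        y1 = int(np.clip(np.ceil((cy + bh / 2) * h), y0 + 1, h))
        lin = (protos[:, y0:y1, x0:x1]
               * coefs[prior_idx].reshape(k, 1, 1)).sum(axis=0)
        target = gt_masks[g, y0:y1, x0:x1]
        bce = _bce_with_logits(lin, target)
        per_mask.append(bce.mean())
    return stack(per_mask).mean()


def density_branch_loss(outputs, targets: list) -> Tensor:
    """Mean over FPN levels of the density-map MSE."""
    preds = outputs.density
    if preds is None:
        raise ValueError("model has no density branch")
    if len(preds) != len(targets):
        raise ValueError(
            f"{len(preds)} predicted levels vs {len(targets)} targets"
        )
    levels = []
    for pred, target in zip(preds, targets):
        t = target.values if hasattr(target, "values") else np.asarray(target, float)
        p = pred
        while p.ndim > 2:
            p = p.reshape(p.shape[1:])
        if p.shape != t.shape:
            raise ValueError(f"density shape mismatch {p.shape} vs {t.shape}")
        levels.append(((p - as_tensor(t)) ** 2).mean())
    return stack(levels).mean()


def total_loss(l_cla, l_obj, l_box, l_seg, l_density,
               w_density: float = 1.0) -> LossBreakdown:
    """Compose the weighted objective into a :class:`LossBreakdown`."""
    def val(x):
        return float(x.data) if isinstance(x, Tensor) else float(x)

    return LossBreakdown(
        l_cla=val(l_cla), l_obj=val(l_obj), l_box=val(l_box),
        l_seg=val(l_seg), l_density=val(l_density), w_density=w_density,
    )
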