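"""Prediction: box decoding, density-fused scoring, NMS, mask assembly.

At inference the predicted density map modulates detection confidence:
a detection whose box center falls in a locally dense region is boosted,

    s' = s * (1 + alpha * d_local) / (1 + alpha * d_max),

where ``d_local`` is the predicted density sampled at the box center on
the finest FPN level and ``d_max`` the maximum of that map; the rescaled
score stays in [0, 1] and ``alpha = 0`` recovers the plain detection
score.  Survivors of greedy NMS get an assembled prototype mask,
thresholded at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import assemble_masks, box_iou_cxcywh
from .model import Model, decode_boxes
from .nn import Tensor


@dataclass(frozen=True)
class Detection:
    """One predicted instance: pixel-space bbox, score, binary mask."""

    bbox: tuple[float, float, float, float]  # (x, y, w, h) pixels
    score: float
    category: str = "ear"
    mask: np.ndarray | None = field(default=None, compare=False)
    coefficients: np.ndarray | None = field(default=None, compare=False)


def greedy_nms(boxes_cxcywh: np.ndarray, scores: np.ndarray,
               iou_threshold: float = 0.5) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = list(np.argsort(-np.asarray(scores)))
    keep: list[int] = []
    boxes = np.asarray(boxes_cxcywh, float)
    while order:
        i = order.pop(0)
        keep.append(i)
        if not order:
            break
        ious = box_iou_cxcywh(boxes[i], boxes[order])[0]
        order = [j for j, iou in zip(order, ious) if iou < iou_threshold]
    return keep


def _sample_density(density: np.ndarray, cx: float, cy: float) -> float:
    """Nearest-pixel read of a normalized-coordinate center."""
    h, w = density.shape
    col = int(np.clip(cx * w, 0, w - 1))
    row = int(np.clip(cy * h, 0, h - 1))
    return float(density[row, col])


def predict(model: Model, image: np.ndarray, score_threshold: float = 0.3,
            nms_iou: float = 0.5, density_alpha: float = 1.0,
            max_detections: int = 300,
            ) -> tuple[list[Detection], np.ndarray | None]:
    """Run one image through the model -> (detections, fused density map).

    ``image`` is (H, W, 3) float in [0, 1].  The returned density map is
    the finest-level prediction (None when the branch is disabled).
    """
    h, w = image.shape[:2]
    x = Tensor(np.ascontiguousarray(image.transpose(2, 0, 1))[None])
    out = model(x)

    from .nn.autograd import _stable_sigmoid

    obj = _stable_sigmoid(out.objectness_logits.data.reshape(-1))
    cls_logits = out.class_logits.data.reshape(-1, model.config.num_classes)
    shifted = cls_logits - cls_logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    fg = probs[:, 1:].max(axis=1)
    scores = obj * fg

    boxes = decode_boxes(out.box_offsets.data.reshape(-1, 4), model.priors)

    density_map = None
    if out.density is not None:
        density_map = out.density[0].data.reshape(out.density[0].shape[-2:])
        d_max = float(density_map.max())
        if density_alpha > 0 and d_max > 0:
            local = np.array([
                _sample_density(density_map, bx, by) for bx, by in boxes[:, :2]
            ])
            scores = scores * (1.0 + density_alpha * local) / (1.0 + density_alpha * d_max)

    keep = np.where(scores >= score_threshold)[0]
    if len(keep) == 0:
        return [], density_map
    # cap pre-NMS pool for tractability
    if len(keep) > 4 * max_detections:
        keep = keep[np.argsort(-scores[keep])[: 4 * max_detections]]
    kept = [keep[i] for i in greedy_nms(boxes[keep], scores[keep], nms_iou)]
    kept = kept[:max_detections]

    protos = out.prototypes.data.reshape(out.prototypes.shape[-3:])
    coefs = out.mask_coefficients.data.reshape(-1, model.config.num_prototypes)
    detections: list[Detection] = []
    stride = h // protos.shape[-2]
    for i in kept:
        cx, cy, bw, bh = boxes[i]
        bbox_norm = (cx - bw / 2, cy - bh / 2, bw, bh)
        prob = assemble_masks(protos, coefs[i], bbox=bbox_norm).data
        mask = prob >= 0.5
        if stride > 1:  # prototype resolution -> image resolution
            mask = mask.repeat(stride, axis=0).repeat(stride, axis=1)
        mask = mask[:h, :w]
        detections.append(Detection(
            bbox=(float(bbox_norm[0] * w), float(bbox_norm[1] * h),
                  float(bw * w), float(bh * h)),
            score=float(scores[i]),
            mask=mask,
            coefficients=coefs[i].copy(),
        ))
    return detections, density_map


def count_instances(detections: list[Detection], score_threshold: float = 0.5,
                    ) -> int:
    """Number of detections at or above the score threshold."""
    return sum(1 for d in detections if d.score >= score_threshold)
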