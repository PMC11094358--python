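"""SGD training loop with per-iteration loss logging.

Training follows stochastic gradient descent with momentum 0.9 from an
initial learning rate of 0.001 (scaled up for the CPU-scale tiny runs,
where the full-scale rate is impractically slow over a few hundred
iterations).  Every iteration logs a :class:`LossBreakdown`; a non-finite
loss aborts immediately, naming the first offending component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .annotations import PolygonAnnotation, instance_center, rasterize_polygon
from .density import DensityConfig, DensityMap, TargetCenters, multi_scale_targets
from .losses import (LossBreakdown, classification_loss, density_branch_loss,
                     detection_loss, mask_loss, match_priors, total_loss)
from .model import Model, ModelConfig
from .nn import SGD, Tensor, as_tensor, stack


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 8
    iterations: int = 200
    seed: int = 0
    w_density: float = 1.0
    grad_clip: float = 10.0
    max_masks_per_image: int = 32


@dataclass
class TrainingSample:
    """One prepared training example.

    image: (3, H, W) float in [0, 1]; boxes: (G, 4) normalized cxcywh;
    masks: (G, Hp, Wp) binary at prototype resolution; density_targets:
    ground-truth density map per FPN level; count: instance count.
    """

    image: np.ndarray
    boxes: np.ndarray
    masks: np.ndarray
    density_targets: list[DensityMap]
    count: int


def prepare_sample(image: np.ndarray, annotations: list[PolygonAnnotation],
                   config: ModelConfig,
                   density_config: DensityConfig | None = None,
                   ) -> TrainingSample:
    """Rasterize annotations into the tensors the training loop consumes."""
    h, w = image.shape[:2]
    density_config = density_config or DensityConfig(sigma=config.density_sigma)
    first = config.fpn_levels[0]
    proto_stride = first // 2 if first > 4 else first
    ph, pw = h // proto_stride, w // proto_stride
    boxes = []
    masks = []
    centers = []
    for ann in annotations:
        x0, y0, bw, bh = ann.bbox
        boxes.append(((x0 + bw / 2) / w, (y0 + bh / 2) / h, bw / w, bh / h))
        masks.append(rasterize_polygon(ann.vertices, (ph, pw),
                                       scale=1.0 / proto_stride))
        centers.append(instance_center(ann))
    density_targets = multi_scale_targets(
        TargetCenters(tuple(centers)), (h, w),
        config.level_shapes(), density_config,
    ) if config.density_branch else []
    return TrainingSample(
        image=np.ascontiguousarray(image.transpose(2, 0, 1)).astype(np.float64),
        boxes=np.asarray(boxes, float).reshape(-1, 4),
        masks=(np.asarray(masks, float) if masks
               else np.zeros((0, ph, pw))),
        density_targets=density_targets,
        count=len(annotations),
    )


def _image_loss(model: Model, outputs_slice, sample: TrainingSample,
                config: TrainConfig, rng: np.random.Generator):
    assignments = match_priors(model.priors, sample.boxes)
    l_obj, l_box = detection_loss(outputs_slice, assignments, sample.boxes,
                                  model.priors)
    l_cla = classification_loss(outputs_slice, assignments)
    l_seg = mask_loss(outputs_slice, assignments, sample.masks, sample.boxes,
                      max_masks=config.max_masks_per_image, rng=rng)
    if model.config.density_branch:
        l_den = density_branch_loss(outputs_slice, sample.density_targets)
    else:
        l_den = as_tensor(0.0)
    return l_cla, l_obj, l_box, l_seg, l_den


class _BatchSlice:
    """View of one image's outputs inside a batched forward pass."""

    def __init__(self, outputs, i: int):
        self.objectness_logits = outputs.objectness_logits[i]
        self.class_logits = outputs.class_logits[i]
        self.box_offsets = outputs.box_offsets[i]
        self.mask_coefficients = outputs.mask_coefficients[i]
        self.prototypes = outputs.prototypes[i]
        self.density = ([d[i] for d in outputs.density]
                        if outputs.density is not None else None)


def train(model: Model, samples: list[TrainingSample],
          config: TrainConfig = TrainConfig(),
          log_path: str | None = None,
          ) -> list[LossBreakdown]:
    """Train in place; returns the per-iteration loss history.

    Deterministic for a fixed seed: batch sampling, mask subsampling and
    parameter updates all derive from ``config.seed``.
    """
    if not samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model.parameters(), lr=config.learning_rate,
                    momentum=config.momentum, grad_clip=config.grad_clip)
    history: list[LossBreakdown] = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for iteration in range(config.iterations):
            idx = rng.choice(len(samples), size=min(config.batch_size,
                                                    len(samples)),
                             replace=len(samples) < config.batch_size)
            batch = [samples[i] for i in idx]
            images = Tensor(np.stack([s.image for s in batch]),
                            requires_grad=False)
            outputs = model(images)
            components = {k: [] for k in
                          ("l_cla", "l_obj", "l_box", "l_seg", "l_density")}
            for i, sample in enumerate(batch):
                sl = _BatchSlice(outputs, i)
                l_cla, l_obj, l_box, l_seg, l_den = _image_loss(
                    model, sl, sample, config, rng)
                components["l_cla"].append(l_cla)
                components["l_obj"].append(l_obj)
                components["l_box"].append(l_box)
                components["l_seg"].append(l_seg)
                components["l_density"].append(l_den)
            means = {k: stack(v).mean() for k, v in components.items()}
            for name, tensor in means.items():
                if not np.isfinite(tensor.data):
                    raise RuntimeError(
                        f"non-finite loss component {name!r} at iteration "
                        f"{iteration}"
                    )
            objective = (means["l_cla"]
                         + 1.5 * (means["l_obj"] + means["l_box"])
                         + 6.125 * means["l_seg"]
                         + config.w_density * means["l_density"])
            breakdown = total_loss(means["l_cla"], means["l_obj"],
                                   means["l_box"], means["l_seg"],
                                   means["l_density"],
                                   w_density=config.w_density)
            optimizer.zero_grad()
            objective.backward()
            optimizer.step()
            model.project()
            history.append(breakdown)
            if log_file:
                log_file.write(json.dumps(
                    {"iteration": iteration, **breakdown.as_dict()}) + "\n")
    finally:
        if log_file:
            log_file.close()
    return history


def save_checkpoint(model: Model, path: str, seed: int | None = None) -> None:
    """Single-file parameter archive with a config echo."""
    import dataclasses

    cfg = dataclasses.asdict(model.config)
    np.savez(path, __config__=json.dumps(cfg), __seed__=seed if seed is not None else -1,
             **model.state_dict())


def load_checkpoint(path: str) -> Model:
    archive = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(archive["__config__"]))
    att = cfg_dict.pop("attention")
    from .model import AttentionSettings
    for key in ("input_size", "fpn_levels", "aspect_ratios", "prior_scales"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(attention=AttentionSettings(**att), **cfg_dict)
    model = Model(config, seed=0)
    state = {k: archive[k] for k in archive.files
             if k not in ("__config__", "__seed__")}
    model.load_state_dict(state)
    return model
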