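"""YOLACT-style instance-segmentation network with a density branch.

Architecture: a convolutional backbone with a GeM-CBAM attention block
after each stage that feeds the feature pyramid (FPN); a shared prediction
head per FPN level emitting per-prior objectness, class scores, box
offsets and mask coefficients; a Protonet producing k image-wide prototype
masks at 1/4 resolution; and, per FPN level, a small density head (two 3x3
convolutions, softplus output) regressing a Gaussian density map whose
mass estimates the local ear count.

Two backbone presets exist: ``resnet101`` (bottleneck residual stages of
depths 3/4/23/3, the fidelity configuration) and ``tiny`` (a few-stage
reduced-width variant for CPU-scale training and tests).  Normalization
layers are omitted; convolutions carry biases instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .attention import CbamConfig, GemCbam
from .nn import Conv2d, Module, Tensor, concat


@dataclass(frozen=True)
class AttentionSettings:
    """GeM-CBAM settings applied at every backbone->FPN tap."""

    enabled: bool = True
    gem_pooling: bool = True  # False = classic CBAM (avg-pool descriptors, fixed p=1)
    reduction_ratio: int = 8
    p_channel_init: float = 11.0
    p_spatial_init: float = 19.0
    spatial_kernel: int = 7
    p_learnable: bool = True


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny"  # {"tiny", "resnet101"}
    input_size: tuple[int, int] = (128, 128)
    fpn_levels: tuple[int, ...] = (4, 8, 16)  # strides, ascending
    fpn_channels: int = 32
    num_prototypes: int = 8
    num_classes: int = 2  # background + ear
    aspect_ratios: tuple[float, ...] = (1.0, 0.5, 2.0)
    prior_scale_factor: float = 2.0  # prior side = factor * stride (aspect 1)
    prior_scales: tuple[float, ...] | None = (10.0, 14.0, 20.0)  # px per level
    attention: AttentionSettings = field(default_factory=AttentionSettings)
    density_branch: bool = True
    density_head_width: int = 16
    density_sigma: float = 2.0  # px at input resolution (default for 128^2 scenes)

    def __post_init__(self) -> None:
        if self.backbone not in ("tiny", "resnet101"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if list(self.fpn_levels) != sorted(self.fpn_levels):
            raise ValueError("fpn_levels strides must be ascending")
        if self.num_prototypes < 1 or self.num_classes < 2:
            raise ValueError("need k >= 1 prototypes and C >= 2 classes")
        if self.prior_scales is not None and \
                len(self.prior_scales) != len(self.fpn_levels):
            raise ValueError("prior_scales must match fpn_levels")

    @property
    def priors_per_position(self) -> int:
        return len(self.aspect_ratios)

    def level_shapes(self) -> list[tuple[int, int]]:
        h, w = self.input_size
        return [(h // s, w // s) for s in self.fpn_levels]


def resnet101_config(**overrides) -> ModelConfig:
    """Full-scale fidelity preset (ResNet-101 backbone, 1024^2 input)."""
    base = ModelConfig(
        backbone="resnet101",
        input_size=(1024, 1024),
        fpn_levels=(8, 16, 32),
        fpn_channels=256,
        num_prototypes=32,
        density_sigma=8.0,
        prior_scale_factor=3.0,
        prior_scales=None,
        attention=AttentionSettings(reduction_ratio=16),
    )
    return replace(base, **overrides)


@dataclass
class HeadOutputs:
    """Raw per-image network outputs (pre-activation where noted).

    objectness_logits: (P,) per-prior; class_logits: (P, C);
    box_offsets: (P, 4) encoded offsets; mask_coefficients: (P, k);
    prototypes: (k, Hp, Wp); density: list of (Hl, Wl) per FPN level
    (post-softplus, nonnegative).  All fields are autograd tensors during
    training.
    """

    objectness_logits: Tensor
    class_logits: Tensor
    box_offsets: Tensor
    mask_coefficients: Tensor
    prototypes: Tensor
    density: list[Tensor] | None


# ---------------------------------------------------------------------------
# priors

BOX_VARIANCES = (0.1, 0.2)  # SSD-style center / size encoding variances


def make_priors(config: ModelConfig) -> np.ndarray:
    """Prior boxes (cx, cy, w, h), normalized to [0, 1], for all levels.

    One prior per aspect ratio at each feature-map position; the aspect-1
    side length is ``prior_scale_factor * stride`` pixels.
    """
    h, w = config.input_size
    priors = []
    for li, stride in enumerate(config.fpn_levels):
        gh, gw = h // stride, w // stride
        scale = (config.prior_scales[li] if config.prior_scales is not None
                 else config.prior_scale_factor * stride)
        ys = (np.arange(gh) + 0.5) * stride / h
        xs = (np.arange(gw) + 0.5) * stride / w
        cy, cx = np.meshgrid(ys, xs, indexing="ij")
        # position-major, aspect-minor: matches the head's output layout
        per_aspect = []
        for ar in config.aspect_ratios:
            pw = scale * math.sqrt(ar) / w
            ph = scale / math.sqrt(ar) / h
            per_aspect.append(np.stack(
                [cx.ravel(), cy.ravel(),
                 np.full(gh * gw, pw), np.full(gh * gw, ph)], axis=1
            ))
        priors.append(np.stack(per_aspect, axis=1).reshape(-1, 4))
    out = np.concatenate(priors, axis=0)
    return np.clip(out, 0.0, 1.0)


def encode_boxes(gt_cxcywh: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Encode ground-truth boxes as SSD-style offsets from priors."""
    vc, vs = BOX_VARIANCES
    t = np.empty_like(gt_cxcywh)
    t[:, 0] = (gt_cxcywh[:, 0] - priors[:, 0]) / (priors[:, 2] * vc)
    t[:, 1] = (gt_cxcywh[:, 1] - priors[:, 1]) / (priors[:, 3] * vc)
    t[:, 2] = np.log(gt_cxcywh[:, 2] / priors[:, 2]) / vs
    t[:, 3] = np.log(gt_cxcywh[:, 3] / priors[:, 3]) / vs
    return t


def decode_boxes(offsets: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_boxes` -> (cx, cy, w, h) normalized."""
    vc, vs = BOX_VARIANCES
    out = np.empty_like(offsets)
    out[:, 0] = priors[:, 0] + offsets[:, 0] * priors[:, 2] * vc
    out[:, 1] = priors[:, 1] + offsets[:, 1] * priors[:, 3] * vc
    out[:, 2] = priors[:, 2] * np.exp(offsets[:, 2] * vs)
    out[:, 3] = priors[:, 3] * np.exp(offsets[:, 3] * vs)
    return out


# ---------------------------------------------------------------------------
# building blocks


class _ConvRelu(Module):
    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        self.conv = Conv2d(cin, cout, k, stride=stride, rng=rng)

    def __call__(self, x):
        return self.conv(x).relu()


class _Bottleneck(Module):
    """Residual bottleneck (1x1 down, 3x3, 1x1 up) without normalization."""

    def __init__(self, cin, cout, stride=1, rng=None):
        mid = cout // 4
        self.c1 = Conv2d(cin, mid, 1, rng=rng)
        self.c2 = Conv2d(mid, mid, 3, stride=stride, rng=rng)
        self.c3 = Conv2d(mid, cout, 1, rng=rng)
        self.shortcut = (
            Conv2d(cin, cout, 1, stride=stride, rng=rng)
            if (cin != cout or stride != 1) else None
        )

    def __call__(self, x):
        out = self.c3(self.c2(self.c1(x).relu()).relu())
        skip = self.shortcut(x) if self.shortcut is not None else x
        return (out + skip).relu()


class _TinyBackbone(Module):
    """Few-stage reduced-width backbone; taps at strides 4, 8 and 16."""

    widths = (16, 24, 32, 48, 64)

    def __init__(self, rng):
        w = self.widths
        self.stem = _ConvRelu(3, w[0], stride=2, rng=rng)      # /2
        self.s2 = _ConvRelu(w[0], w[1], stride=2, rng=rng)     # /4
        self.s2b = _ConvRelu(w[1], w[2], rng=rng)
        self.s3 = _ConvRelu(w[2], w[3], stride=2, rng=rng)     # /8
        self.s3b = _ConvRelu(w[3], w[3], rng=rng)
        self.s4 = _ConvRelu(w[3], w[4], stride=2, rng=rng)     # /16
        self.s4b = _ConvRelu(w[4], w[4], rng=rng)
        self.tap_channels = (w[2], w[3], w[4])
        self.tap_strides = (4, 8, 16)

    def __call__(self, x):
        c2 = self.s2b(self.s2(self.stem(x)))
        c3 = self.s3b(self.s3(c2))
        c4 = self.s4b(self.s4(c3))
        return [c2, c3, c4]


class _ResNetBackbone(Module):
    """Bottleneck residual backbone; depths 3/4/23/3 give ResNet-101."""

    def __init__(self, rng, depths=(3, 4, 23, 3), widths=(256, 512, 1024, 2048)):
        self.stem = _ConvRelu(3, 64, k=7, stride=2, rng=rng)   # /2
        self.pool = _ConvRelu(64, 64, stride=2, rng=rng)        # /4 (strided conv)
        blocks = []
        cin = 64
        for stage, (d, wdt) in enumerate(zip(depths, widths)):
            stage_blocks = []
            for i in range(d):
                stride = 2 if (i == 0 and stage > 0) else 1
                stage_blocks.append(_Bottleneck(cin, wdt, stride=stride, rng=rng))
                cin = wdt
            blocks.append(stage_blocks)
        self.stages = [b for stage in blocks for b in stage]
        self._stage_ends = np.cumsum(depths)
        self.tap_channels = tuple(widths[1:])
        self.tap_strides = (8, 16, 32)

    def __call__(self, x):
        x = self.pool(self.stem(x))
        taps = []
        for i, block in enumerate(self.stages):
            x = block(x)
            if (i + 1) in self._stage_ends[1:]:
                taps.append(x)
        return taps


class _PredictionHead(Module):
    """Shared per-level head: objectness, classes, boxes, mask coefficients."""

    def __init__(self, cin, num_classes, num_prototypes, priors_per_pos, rng):
        a = priors_per_pos
        self.tower = _ConvRelu(cin, cin, rng=rng)
        self.obj = Conv2d(cin, a, 1, rng=rng)
        self.cls = Conv2d(cin, a * num_classes, 1, rng=rng)
        self.box = Conv2d(cin, a * 4, 1, rng=rng)
        self.coef = Conv2d(cin, a * num_prototypes, 1, rng=rng)
        self.a = a
        self.num_classes = num_classes
        self.num_prototypes = num_prototypes
        # start objectness pessimistic so early training is not flooded
        # with false positives (focal-style prior bias)
        self.obj.bias.data[:] = -2.0

    def __call__(self, x):
        t = self.tower(x)
        n = x.shape[0]

        def flatten(out, d):
            # (N, a*d, H, W) -> (N, H*W*a, d)
            _, _, h, w = out.shape
            return (out.reshape(n, self.a, d, h, w)
                       .transpose(0, 3, 4, 1, 2)
                       .reshape(n, h * w * self.a, d))

        return (flatten(self.obj(t), 1),
                flatten(self.cls(t), self.num_classes),
                flatten(self.box(t), 4),
                flatten(self.coef(t), self.num_prototypes))


class _Protonet(Module):
    """Prototype branch on the finest FPN level -> k maps at stride 4."""

    def __init__(self, cin, k, rng, upsample: bool):
        self.c1 = _ConvRelu(cin, cin, rng=rng)
        self.c2 = _ConvRelu(cin, cin, rng=rng)
        self.out = Conv2d(cin, k, 1, rng=rng)
        self.upsample = upsample

    def __call__(self, p_fine):
        x = self.c1(p_fine)
        if self.upsample:  # stride 8 -> 4
            x = x.upsample2x()
        x = self.c2(x)
        return self.out(x).relu()


class _DensityHead(Module):
    """Two 3x3 convs -> 1 channel, softplus (nonnegative density)."""

    def __init__(self, cin, width, rng):
        self.c1 = _ConvRelu(cin, width, rng=rng)
        self.c2 = Conv2d(width, 1, 3, rng=rng)
        # softplus(-3) ~ 0.049: start near-zero density
        self.c2.bias.data[:] = -3.0

    def __call__(self, x):
        return self.c2(self.c1(x)).softplus()


class Model(Module):
    """The assembled network.  Forward maps (N, 3, H, W) to HeadOutputs."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        if config.backbone == "tiny":
            self.backbone = _TinyBackbone(rng)
        else:
            self.backbone = _ResNetBackbone(rng)
        taps = self.backbone.tap_channels
        if self.backbone.tap_strides != tuple(config.fpn_levels):
            raise ValueError(
                f"backbone taps {self.backbone.tap_strides} do not match "
                f"fpn_levels {config.fpn_levels}"
            )
        att = config.attention
        if att.enabled:
            self.cbam = [
                GemCbam(
                    CbamConfig(
                        channels=c,
                        reduction_ratio=att.reduction_ratio,
                        p_channel_init=att.p_channel_init if att.gem_pooling else 1.0,
                        p_spatial_init=att.p_spatial_init if att.gem_pooling else 1.0,
                        spatial_kernel=att.spatial_kernel,
                        p_learnable=att.p_learnable and att.gem_pooling,
                    ),
                    rng=rng,
                )
                for c in taps
            ]
        else:
            self.cbam = []
        f = config.fpn_channels
        self.lateral = [Conv2d(c, f, 1, rng=rng) for c in taps]
        self.smooth = [Conv2d(f, f, 3, rng=rng) for _ in taps]
        self.head = _PredictionHead(
            f, config.num_classes, config.num_prototypes,
            config.priors_per_position, rng,
        )
        self.protonet = _Protonet(f, config.num_prototypes, rng,
                                  upsample=config.fpn_levels[0] > 4)
        if config.density_branch:
            self.density_heads = [
                _DensityHead(f, config.density_head_width, rng) for _ in taps
            ]
        else:
            self.density_heads = []
        self.priors = make_priors(config)

    def __call__(self, images: Tensor) -> HeadOutputs:
        taps = self.backbone(images)
        if self.cbam:
            taps = [blk(t) for blk, t in zip(self.cbam, taps)]
        # top-down pathway
        feats = [None] * len(taps)
        prev = None
        for i in range(len(taps) - 1, -1, -1):
            lat = self.lateral[i](taps[i])
            if prev is not None:
                lat = lat + prev.upsample2x()
            prev = lat
            feats[i] = self.smooth[i](lat)

        objs, clss, boxes, coefs = [], [], [], []
        for f in feats:
            o, c, b, m = self.head(f)
            objs.append(o)
            clss.append(c)
            boxes.append(b)
            coefs.append(m)
        prototypes = self.protonet(feats[0])
        density = None
        if self.density_heads:
            density = [head(f) for head, f in zip(self.density_heads, feats)]
        n = images.shape[0]
        return HeadOutputs(
            objectness_logits=concat(objs, axis=1).reshape(n, -1),
            class_logits=concat(clss, axis=1),
            box_offsets=concat(boxes, axis=1),
            mask_coefficients=concat(coefs, axis=1),
            prototypes=prototypes,
            density=density,
        )

    def project(self) -> None:
        for blk in self.cbam:
            blk.project()


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Construct a model with deterministic seeded initialization."""
    return Model(config, seed=seed)
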