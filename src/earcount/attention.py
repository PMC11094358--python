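"""Generalized-mean (GeM) pooling and the GeM-CBAM attention block.

GeM pooling aggregates a set of activations x by the power mean

    GeM_p(x) = ( (1/n) * sum_i x_i^p )^(1/p),

which interpolates between average pooling (p = 1) and max pooling
(p -> infinity).  The convolutional block attention module (CBAM) gates a
feature map sequentially: a channel gate computed from a spatially pooled
descriptor, then a spatial gate computed from a channel-pooled descriptor.
In the variant implemented here every pooling operator inside CBAM is a
GeM pool with its own learnable exponent — a single GeM descriptor per
branch (so the channel MLP sees C inputs and the spatial convolution sees
one channel), with exponents initialized to 11 (channel branch) and 19
(spatial branch).

Inputs are clamped to a small positive floor before exponentiation so that
real p-th powers and their gradients are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, as_tensor


@dataclass(frozen=True)
class GemParams:
    """GeM exponent and numerical floor."""

    p: float = 3.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class CbamConfig:
    """GeM-CBAM hyperparameters.

    ``p_channel_init`` / ``p_spatial_init`` are the initial GeM exponents of
    the channel- and spatial-attention branches; ``reduction_ratio`` is the
    channel-MLP bottleneck divisor (bottleneck width clamped to >= 1);
    ``spatial_kernel`` is the odd spatial-gate convolution size.
    """

    channels: int
    reduction_ratio: int = 16
    p_channel_init: float = 11.0
    p_spatial_init: float = 19.0
    spatial_kernel: int = 7
    p_learnable: bool = True

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if self.p_channel_init < 1 or self.p_spatial_init < 1:
            raise ValueError("GeM exponent inits must be >= 1")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in feature map")


def _gem(x: Tensor, p: Tensor | float, epsilon: float, axis) -> Tensor:
    # computed as m * ((1/n) sum (x/m)^p)^(1/p) with m = max(x) held
    # constant: the identity holds exactly for any fixed m > 0, so the
    # value and gradients are unchanged while x^p can no longer overflow
    p = as_tensor(p)
    clamped = x.clamp_min(epsilon)
    m = np.maximum(clamped.data.max(axis=axis, keepdims=True), epsilon)
    scaled = clamped * (1.0 / m)
    powered = scaled.pow_tensor(p) if p.requires_grad else scaled ** float(p.data)
    pooled = powered.mean(axis=axis, keepdims=True)
    root = pooled.pow_tensor(1.0 / p) if p.requires_grad else \
        pooled ** (1.0 / float(p.data))
    return root * m


def gem_pool_spatial(feature_map, params: GemParams = GemParams()) -> np.ndarray:
    """GeM-pool each channel over its H x W extent -> vector of length C."""
    x = np.asarray(feature_map, dtype=np.float64)
    _check_finite(x)
    if x.ndim != 3:
        raise ValueError(f"expected (C, H, W), got shape {x.shape}")
    out = _gem(Tensor(x), params.p, params.epsilon, axis=(1, 2))
    return out.data.reshape(-1)


def gem_pool_channelwise(feature_map, params: GemParams = GemParams()) -> np.ndarray:
    """GeM-pool across channels at each position -> (1, H, W) map."""
    x = np.asarray(feature_map, dtype=np.float64)
    _check_finite(x)
    if x.ndim != 3:
        raise ValueError(f"expected (C, H, W), got shape {x.shape}")
    out = _gem(Tensor(x), params.p, params.epsilon, axis=0)
    return out.data


class GemCbam(Module):
    """CBAM block with GeM pooling in both attention branches.

    Applies the channel gate first, then the spatial gate (the standard
    CBAM order), each gate a sigmoid in (0, 1), so the output is
    elementwise bounded by the input in absolute value.
    """

    def __init__(self, config: CbamConfig, rng: np.random.Generator | None = None,
                 epsilon: float = 1e-6):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.epsilon = epsilon
        c = config.channels
        hidden = max(1, c // config.reduction_ratio)
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)
        self.spatial_conv = Conv2d(1, 1, config.spatial_kernel, rng=rng)
        self.p_channel = Tensor(float(config.p_channel_init),
                                requires_grad=config.p_learnable)
        self.p_spatial = Tensor(float(config.p_spatial_init),
                                requires_grad=config.p_learnable)

    # exponents must stay >= 1 for the power mean to be monotone and stable;
    # the trainer calls this after every optimizer step
    def project(self) -> None:
        self.p_channel.data = np.maximum(self.p_channel.data, 1.0)
        self.p_spatial.data = np.maximum(self.p_spatial.data, 1.0)

    def channel_gate(self, x: Tensor) -> Tensor:
        """Per-channel sigmoid gate, shape (N, C, 1, 1)."""
        n, c = x.shape[0], x.shape[1]
        desc = _gem(x, self.p_channel, self.epsilon, axis=(2, 3))  # (N, C, 1, 1)
        desc = desc.reshape(n, c)
        gate = self.fc2(self.fc1(desc).relu()).sigmoid()
        return gate.reshape(n, c, 1, 1)

    def spatial_gate(self, x: Tensor) -> Tensor:
        """Per-position sigmoid gate, shape (N, 1, H, W)."""
        desc = _gem(x, self.p_spatial, self.epsilon, axis=1)  # (N, 1, H, W)
        return self.spatial_conv(desc).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        x = x * self.channel_gate(x)
        x = x * self.spatial_gate(x)
        return x


def channel_attention(feature_map, block: GemCbam) -> np.ndarray:
    """Channel-attention gate vector in (0, 1), length C."""
    x = np.asarray(feature_map, dtype=np.float64)
    _check_finite(x)
    if x.shape[0] != block.config.channels:
        raise ValueError(
            f"feature map has {x.shape[0]} channels, block expects "
            f"{block.config.channels}"
        )
    return block.channel_gate(Tensor(x[None])).data.reshape(-1)


def spatial_attention(feature_map, block: GemCbam) -> np.ndarray:
    """Spatial-attention gate map in (0, 1), shape (1, H, W)."""
    x = np.asarray(feature_map, dtype=np.float64)
    _check_finite(x)
    if x.shape[0] != block.config.channels:
        raise ValueError(
            f"feature map has {x.shape[0]} channels, block expects "
            f"{block.config.channels}"
        )
    return block.spatial_gate(Tensor(x[None])).data[0]


def gem_cbam(feature_map, block: GemCbam) -> np.ndarray:
    """Apply the full GeM-CBAM block to a (C, H, W) feature map."""
    x = np.asarray(feature_map, dtype=np.float64)
    _check_finite(x)
    return block(Tensor(x[None])).data[0]
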