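"""Layers and optimizer built on the autograd core.

Initialization is He-style for convolutions and linear layers, drawn from
an explicit ``numpy.random.Generator`` so model construction is bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing {missing}, extra {extra}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class SGD:
    """Stochastic gradient descent with classical momentum.

    v <- momentum * v + grad;  p <- p - lr * v
    """

    def __init__(self, parameters: dict[str, Tensor], lr: float = 0.001,
                 momentum: float = 0.9, grad_clip: float | None = None):
        self.parameters = dict(parameters)
        self.lr = lr
        self.momentum = momentum
        self.grad_clip = grad_clip
        self._velocity = {k: np.zeros_like(p.data) for k, p in self.parameters.items()}

    def step(self) -> None:
        for k, p in self.parameters.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.grad_clip is not None:
                norm = float(np.sqrt(np.sum(g * g)))
                if norm > self.grad_clip:
                    g = g * (self.grad_clip / norm)
            v = self._velocity[k]
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.parameters.values():
            p.zero_grad()
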