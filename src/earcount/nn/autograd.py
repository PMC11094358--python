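"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the convolutional model in this
package: tensors wrap float64 numpy arrays, every op records its parents
and a backward closure, and :meth:`Tensor.backward` runs a topological
sweep accumulating gradients.  Broadcasting follows numpy; gradients of
broadcast operands are summed back to the operand's shape.

Only the ops the model needs are provided (elementwise arithmetic,
exp/log/clamp, relu/sigmoid/softplus, reductions, matmul, reshape /
transpose / concat / pad / slicing, power with a learnable exponent for
generalized-mean pooling, im2col convolution and nearest upsampling).
float64 is used throughout: the models here are small, and it keeps loss
values comparable with scalar-loop oracles at tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack"]


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            else:
                node.grad = g if node.grad is None else node.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor._make(
            self.data + o.data,
            (self, o),
            lambda g: (
                (self, _unbroadcast(g, self.shape)),
                (o, _unbroadcast(g, o.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor._make(
            self.data * o.data,
            (self, o),
            lambda g: (
                (self, _unbroadcast(g * o.data, self.shape)),
                (o, _unbroadcast(g * self.data, o.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor._make(
            self.data / o.data,
            (self, o),
            lambda g: (
                (self, _unbroadcast(g / o.data, self.shape)),
                (o, _unbroadcast(-g * self.data / (o.data ** 2), o.shape)),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e
        return Tensor._make(
            out_data,
            (self,),
            lambda g: ((self, g * e * self.data ** (e - 1.0)),),
        )

    def pow_tensor(self, exponent: "Tensor"):
        """x ** p with a learnable scalar exponent p (inputs must be > 0)."""
        p = as_tensor(exponent)
        out_data = self.data ** p.data
        def backward(g):
            return (
                (self, g * p.data * self.data ** (p.data - 1.0)),
                (p, _unbroadcast(g * out_data * np.log(self.data), p.shape)),
            )
        return Tensor._make(out_data, (self, p), backward)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: ((self, g / self.data),)
        )

    def clamp_min(self, floor: float):
        mask = (self.data >= floor).astype(np.float64)
        return Tensor._make(
            np.maximum(self.data, floor), (self,), lambda g: ((self, g * mask),)
        )

    def relu(self):
        mask = (self.data > 0).astype(np.float64)
        return Tensor._make(self.data * mask, (self,), lambda g: ((self, g * mask),))

    def sigmoid(self):
        out_data = _stable_sigmoid(self.data)
        return Tensor._make(
            out_data, (self,), lambda g: ((self, g * out_data * (1.0 - out_data)),)
        )

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = _stable_sigmoid(self.data)
        return Tensor._make(out_data, (self,), lambda g: ((self, g * sig),))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g2, shape).copy()),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                mask = (self.data == out_data).astype(np.float64)
                mask /= mask.sum()
                return ((self, g * mask),)
            g2, o2 = g, out_data
            if not keepdims:
                g2 = np.expand_dims(g, axis)
                o2 = np.expand_dims(out_data, axis)
            mask = (self.data == o2).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            return ((self, g2 * mask),)

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: ((self, g.reshape(old)),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: ((self, g.transpose(inv)),)
        )

    def __getitem__(self, key):
        out_data = self.data[key]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, key, g)
            return ((self, full),)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by ``pad`` on each side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return Tensor._make(out_data, (self,), lambda g: ((self, g[sl]),))

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        o = as_tensor(other)

        def backward(g):
            return (
                (self, g @ o.data.swapaxes(-1, -2)),
                (o, self.data.swapaxes(-1, -2) @ g),
            )

        return Tensor._make(self.data @ o.data, (self, o), backward)

    __matmul__ = matmul

    # -- spatial ops ----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution (NCHW) via im2col.

        ``weight`` is (C_out, C_in, kH, kW); ``bias`` is (C_out,).
        """
        x = self.pad2d(padding) if padding else self
        n, c, h, w = x.shape
        co, ci, kh, kw = weight.shape
        if ci != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1

        # im2col as a strided view, then a single matmul
        s0, s1, s2, s3 = x.data.strides
        cols = np.lib.stride_tricks.as_strided(
            x.data,
            shape=(n, c, kh, kw, oh, ow),
            strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        )
        cols_mat = cols.reshape(n, c * kh * kw, oh * ow)
        w_mat = weight.data.reshape(co, c * kh * kw)
        out_data = np.einsum("ok,nkp->nop", w_mat, cols_mat, optimize=True)
        out_data = out_data.reshape(n, co, oh, ow)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, co, 1, 1)

        def backward(g):
            g_mat = g.reshape(n, co, oh * ow)
            gw = np.einsum("nop,nkp->ok", g_mat, cols_mat, optimize=True)
            gw = gw.reshape(co, c, kh, kw)
            gcols = np.einsum("ok,nop->nkp", w_mat, g_mat, optimize=True)
            gcols = gcols.reshape(n, c, kh, kw, oh, ow)
            gx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + oh * stride : stride,
                       j : j + ow * stride : stride] += gcols[:, :, i, j]
            grads = [(x, gx), (weight, gw)]
            if bias is not None:
                grads.append((bias, g.sum(axis=(0, 2, 3))))
            return tuple(grads)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._make(out_data, parents, backward)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of the last two axes."""
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        h, w = self.shape[-2], self.shape[-1]

        def backward(g):
            g4 = g.reshape(*g.shape[:-2], h, 2, w, 2)
            return ((self, g4.sum(axis=(-3, -1))),)

        return Tensor._make(out_data, (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            grads.append((t, g[tuple(idx)]))
        return tuple(grads)

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        return tuple((t, parts[i]) for i, t in enumerate(tensors))

    return Tensor._make(out_data, tuple(tensors), backward)
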