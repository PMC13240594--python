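"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine carrying exactly the operations the adapter stack,
surrogate encoder and segmentation head need: broadcast add/multiply,
last-axis linear maps, exact (erf-based) GELU, reshape, 2x2 average pooling
and nearest-neighbour upsampling on (H, W, C) token grids, reductions, and a
numerically stable balanced binary cross-entropy with logits. Everything is
float64 and fully deterministic.

Tensors with ``requires_grad=False`` (frozen parameters, constants) take part
in the forward pass and let gradients flow *through* them, but never
accumulate gradients themselves.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Adam", "gelu_scalar"]

ArrayLike = Union[np.ndarray, float, int]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data: ArrayLike, requires_grad: bool = False,
                 name: Optional[str] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()
        self.name = name

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def _node(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [t]
            while stack:
                node = stack[-1]
                if id(node) in seen:
                    stack.pop()
                    continue
                pending = [p for p in node._parents if id(p) not in seen]
                if pending:
                    stack.extend(pending)
                else:
                    seen.add(id(node))
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                node._backward_dispatch(g, grads)

    def _backward_dispatch(self, g: np.ndarray, grads: dict) -> None:
        contribs = self._backward(g)  # type: ignore[misc]
        for parent, pg in zip(self._parents, contribs):
            if pg is None:
                continue
            key = id(parent)
            if key in grads:
                grads[key] = grads[key] + pg
            else:
                grads[key] = pg

    # -- arithmetic --------------------------------------------------------

    def _coerce(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

        return self._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return self._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        return self + (-self._coerce(other))

    # -- linear algebra ----------------------------------------------------

    def linear(self, weight: "Tensor", bias: Optional["Tensor"] = None) -> "Tensor":
        """Affine map over the last axis: x[..., a] @ W[a, b] (+ bias[b])."""
        x, W = self, weight
        out_data = np.tensordot(x.data, W.data, axes=([-1], [0]))

        def backward(g):
            gx = np.tensordot(g, W.data, axes=([-1], [1]))
            flat_x = x.data.reshape(-1, x.data.shape[-1])
            flat_g = g.reshape(-1, g.shape[-1])
            gW = flat_x.T @ flat_g
            return (gx, gW)

        out = self._node(out_data, (x, W), backward)
        if bias is not None:
            out = out + bias
        return out

    # -- nonlinearity ------------------------------------------------------

    def gelu(self) -> "Tensor":
        x = self
        cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
        out_data = x.data * cdf

        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data * x.data)
            return (g * (cdf + x.data * pdf),)

        return self._node(out_data, (x,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        x = self
        old = x.data.shape

        def backward(g):
            return (g.reshape(old),)

        return self._node(x.data.reshape(*shape), (x,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        x = self
        inv = np.argsort(axes)

        def backward(g):
            return (np.transpose(g, inv),)

        return self._node(np.transpose(x.data, axes), (x,), backward)

    def mean(self, axis=None) -> "Tensor":
        x = self
        out_data = x.data.mean(axis=axis)
        count = x.data.size / max(out_data.size, 1)

        def backward(g):
            if axis is None:
                return (np.full_like(x.data, g / x.data.size),)
            g_exp = np.expand_dims(g, axis=axis if isinstance(axis, int) else tuple(axis))
            return (np.broadcast_to(g_exp, x.data.shape) / count,)

        return self._node(out_data, (x,), backward)

    def sum(self) -> "Tensor":
        x = self

        def backward(g):
            return (np.full_like(x.data, g),)

        return self._node(x.data.sum(), (x,), backward)

    # -- token-grid ops on (H, W, C) ----------------------------------------

    def avg_pool2(self) -> "Tensor":
        """2x2 average pooling over the leading two (spatial) axes."""
        x = self
        H, W, C = x.data.shape
        if H % 2 or W % 2:
            raise ValueError(f"avg_pool2 needs even spatial dims, got {(H, W)}")
        out_data = x.data.reshape(H // 2, 2, W // 2, 2, C).mean(axis=(1, 3))

        def backward(g):
            g4 = g[:, None, :, None, :] / 4.0
            return (np.broadcast_to(g4, (H // 2, 2, W // 2, 2, C)).reshape(H, W, C),)

        return self._node(out_data, (x,), backward)

    def upsample_nearest(self, factor: int) -> "Tensor":
        """Nearest-neighbour upsampling of the leading two (spatial) axes."""
        x = self
        H, W, C = x.data.shape
        out_data = np.repeat(np.repeat(x.data, factor, axis=0), factor, axis=1)

        def backward(g):
            return (g.reshape(H, factor, W, factor, C).sum(axis=(1, 3)),)

        return self._node(out_data, (x,), backward)

    def depth_to_space(self, block: int) -> "Tensor":
        """(H, W, block*block) -> (H*block, W*block) pixel rearrangement."""
        x = self
        H, W, C = x.data.shape
        if C != block * block:
            raise ValueError(f"depth_to_space expects C == block^2, got C={C}")
        out_data = (
            x.data.reshape(H, W, block, block)
            .transpose(0, 2, 1, 3)
            .reshape(H * block, W * block)
        )

        def backward(g):
            gi = (
                g.reshape(H, block, W, block)
                .transpose(0, 2, 1, 3)
                .reshape(H, W, block * block)
            )
            return (gi,)

        return self._node(out_data, (x,), backward)

    # -- losses --------------------------------------------------------------

    def bce_with_logits(self, target: np.ndarray,
                        pos_weight: Union[float, np.ndarray] = 1.0) -> "Tensor":
        """Mean of pos_weight*t*softplus(-z) + (1-t)*softplus(z) over all pixels."""
        z = self
        t = np.asarray(target, dtype=np.float64)
        pw = np.asarray(pos_weight, dtype=np.float64)
        softplus_pos = np.logaddexp(0.0, z.data)   # softplus(z)
        softplus_neg = np.logaddexp(0.0, -z.data)  # softplus(-z)
        per_px = pw * t * softplus_neg + (1.0 - t) * softplus_pos
        n = z.data.size

        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-z.data))
            grad = (-pw * t * (1.0 - sig) + (1.0 - t) * sig) * (g / n)
            return (grad,)

        return self._node(per_px.mean(), (z,), backward)

    def __repr__(self) -> str:  # pragma: no cover
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}{tag})"


def gelu_scalar(x: float) -> float:
    """Exact GELU on a python float (handy in tests and docs)."""
    return float(0.5 * x * (1.0 + erf(x / _SQRT2)))


class Adam:
    """Adam optimizer over a list of trainable Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / (1.0 - self.b1 ** self.t)
            vhat = self.v[i] / (1.0 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
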