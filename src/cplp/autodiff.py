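"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the trainable pieces of the package:
the time-distance transformer image head, the text/tabular MLP heads, the
contrastive objective and the fusion classifiers. It implements exactly the
operations those models need — broadcast-aware elementwise arithmetic,
(batched) matmul, reductions, indexing, concatenation and a handful of
nonlinearities — plus an Adam optimizer and a cosine-annealing-with-warm-
restarts learning-rate schedule.

Gradients are accumulated by topological traversal of the tape; every
primitive is finite-difference checked in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "concatenate",
    "Adam",
    "CosineWarmRestarts",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, requires_grad=self.requires_grad,
                     _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bwd(g):
            g = np.asarray(g)
            if self.requires_grad:
                if self.data.ndim > 2 and other.data.ndim == 2:
                    da = np.matmul(g, other.data.T)
                else:
                    da = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(da)
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    # batched input @ shared weight: flatten batch dims so the
                    # weight gradient is one GEMM, not a stack of outer products
                    a2 = self.data.reshape(-1, self.data.shape[-1])
                    g2 = g.reshape(-1, g.shape[-1])
                    other._accum(a2.T @ g2)
                else:
                    other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))
        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val)
        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad,
                     _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - val * val))
        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad,
                     _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val * (1.0 - val))
        out._backward = bwd
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.asarray(g).reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.data.ndim)))
        out = Tensor(self.data.transpose(axes),
                     requires_grad=self.requires_grad, _parents=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(np.asarray(g).transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad,
                     _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    # -- composites --------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        # max is a constant shift; it carries no gradient
        shifted = self + (-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self + (-self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    def l2_normalize(self, axis: int = -1, eps: float = 1e-12) -> "Tensor":
        norm = ((self * self).sum(axis=axis, keepdims=True) + eps).sqrt()
        return self / norm


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bwd
    return out


def parameter(data: np.ndarray) -> Tensor:
    """Wrap an array as a trainable leaf."""
    return Tensor(np.asarray(data), requires_grad=True)


class Adam:
    """Adam with optional per-group learning-rate multipliers.

    `groups` maps a multiplier to a list of parameters; the effective step
    size for a parameter is lr * multiplier, which is how the fusion
    classifier trains its encoders at one tenth of the head's rate.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_mult: Sequence[float] | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_mult = list(lr_mult) if lr_mult is not None else [1.0] * len(self.params)
        if len(self.lr_mult) != len(self.params):
            raise ValueError("lr_mult length must match params")
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= (self.lr * self.lr_mult[i]) * mhat / (np.sqrt(vhat) + self.eps)


class CosineWarmRestarts:
    """Cosine-annealed learning rate with warm restarts (SGDR schedule).

    The cycle starts at `t0` epochs and multiplies by `t_mult` after each
    restart; `lr(epoch)` decays from `lr_max` to `lr_min` within a cycle.
    """

    def __init__(self, lr_max: float, t0: int = 100, t_mult: int = 2,
                 lr_min: float = 0.0):
        if t0 < 1:
            raise ValueError("t0 must be >= 1")
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.t0 = t0
        self.t_mult = t_mult

    def lr_at(self, epoch: int) -> float:
        t_i, t_cur = self.t0, epoch
        while t_cur >= t_i:
            t_cur -= t_i
            t_i *= self.t_mult
        frac = t_cur / t_i
        return self.lr_min + 0.5 * (self.lr_max - self.lr_min) * (1.0 + math.cos(math.pi * frac))
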