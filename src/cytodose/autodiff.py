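"""Minimal reverse-mode automatic differentiation on numpy arrays.

Sized to this package's models: small MLPs, a compact self-attention encoder,
and Runge–Kutta integration of a learned vector field. Supports broadcasting,
matmul, the elementwise nonlinearities used here (tanh, GELU, softplus,
sigmoid, exp, log), reductions, indexing/concat, and an Adam optimiser.

Gradients flow through a dynamically built tape; ``Tensor.backward`` walks it
in reverse topological order. Arrays are float64 throughout — model sizes are
tiny and double precision keeps the ODE/gradient checks tight.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "stack", "no_grad"]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference paths)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")
    __array_priority__ = 100  # so ndarray.__mul__ defers to us

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- graph plumbing --------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _grad_enabled and any(p.requires_grad for p in parents)
        t = Tensor(data, requires_grad=req)
        if req:
            t._parents = tuple(parents)
            t._backward = backward
        return t

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; tapes can be deep through ODE steps
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if o.requires_grad:
                o._accum(g)
        return Tensor._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __mul__(self, other):
        o = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * o.data)
            if o.requires_grad:
                o._accum(g * self.data)
        return Tensor._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        o = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g / o.data)
            if o.requires_grad:
                o._accum(-g * self.data / (o.data ** 2))
        return Tensor._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))
        return Tensor._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        o = self._wrap(other)
        a_vec = self.data.ndim == 1
        b_vec = o.data.ndim == 1

        def bw(g):
            ga = g[None, :] if a_vec and not b_vec else g
            if a_vec and b_vec:            # inner product: g is scalar
                if self.requires_grad:
                    self._accum(g * o.data)
                if o.requires_grad:
                    o._accum(g * self.data)
                return
            if self.requires_grad:
                if b_vec:                  # (…,n,m) @ (m,) -> (…,n)
                    self._accum(np.expand_dims(g, -1) * o.data)
                else:
                    self._accum(ga @ np.swapaxes(o.data, -1, -2))
            if o.requires_grad:
                if a_vec:                  # (m,) @ (m,k) -> (k,)
                    o._accum(np.outer(self.data, g))
                elif b_vec:                # (…,n,m) @ (m,) -> (…,n)
                    og = (self.data * np.expand_dims(g, -1)) \
                        .reshape(-1, self.data.shape[-1]).sum(axis=0)
                    o._accum(og)
                else:
                    o._accum(np.swapaxes(self.data, -1, -2) @ ga)
        return Tensor._make(self.data @ o.data, (self, o), bw)

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)
        return Tensor._make(out, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out ** 2))
        return Tensor._make(out, (self,), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out * (1.0 - out))
        return Tensor._make(out, (self,), bw)

    def softplus(self):
        # numerically stable: log(1+e^x) = max(x,0) + log1p(e^{-|x|})
        out = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))

        def bw(g):
            self._accum(g / (1.0 + np.exp(-self.data)))
        return Tensor._make(out, (self,), bw)

    def gelu(self):
        # tanh approximation (standard in transformer stacks)
        x = self.data
        inner = _SQRT_2_OVER_PI * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def bw(g):
            dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x ** 2)
            dt = (1.0 - t ** 2) * dinner
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))
        return Tensor._make(out, (self,), bw)

    def erf(self):
        from scipy.special import erf as _erf
        out = _erf(self.data)

        def bw(g):
            self._accum(g * (2.0 / math.sqrt(math.pi))
                        * np.exp(-self.data ** 2))
        return Tensor._make(out, (self,), bw)

    def abs(self):
        s = np.sign(self.data)

        def bw(g):
            self._accum(g * s)
        return Tensor._make(np.abs(self.data), (self,), bw)

    # ---- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g):
            self._accum(g.reshape(self.data.shape))
        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or None

        def bw(g):
            if axes is None:
                self._accum(g.T)
            else:
                inv = np.argsort(axes)
                self._accum(g.transpose(inv))
        return Tensor._make(self.data.transpose(*axes) if axes
                            else self.data.T, (self,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor._make(self.data[idx], (self,), bw)

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def clip_min(self, lo: float):
        mask = (self.data > lo).astype(np.float64)

        def bw(g):
            self._accum(g * mask)
        return Tensor._make(np.maximum(self.data, lo), (self,), bw)


def concat(tensors: Sequence[Tensor], axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bw)


def stack(tensors: Sequence[Tensor], axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, bw)


class Parameter(Tensor):
    """A leaf tensor updated by the optimiser."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with optional cosine learning-rate decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 total_steps: int | None = None,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.total_steps = total_steps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        lr = self.lr
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((p.grad ** 2).sum())
                                  for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mh / (np.sqrt(vh) + self.eps)
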