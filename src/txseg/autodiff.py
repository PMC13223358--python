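"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The segmentation policy and the deconvolution model are small, fixed
feed-forward architectures (a handful of affine maps, rectifiers, layer
normalisation and softmax heads).  This module provides exactly the
operations those models need: a :class:`Var` wrapping an ``ndarray``,
differentiable primitives, and an Adam optimiser.  Gradients are exercised
against central finite differences in the test suite.

All computation is float64 on CPU, which keeps training bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Var", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in
    ``.grad`` after :meth:`backward`.
    """

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Var, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.requires_grad = requires_grad

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Var":
        return x if isinstance(x, Var) else Var(x)

    @staticmethod
    def _node(data, parents: Sequence["Var"], backward) -> "Var":
        out = Var(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Var._lift(other)
        data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Var._node(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Var._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Var._lift(other))

    def __rsub__(self, other):
        return Var._lift(other) + (-self)

    def __mul__(self, other):
        other = Var._lift(other)
        data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Var._node(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Var._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Var._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Var._node(data, (self,), backward)

    def __matmul__(self, other):
        other = Var._lift(other)
        data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
            else:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            else:
                gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(np.asarray(ga), a.shape))
            other._accum(_unbroadcast(np.asarray(gb), b.shape))

        return Var._node(data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Var._node(self.data * mask, (self,), backward)

    def softplus(self):
        # numerically stable ln(1 + e^x); backward uses a stable sigmoid
        data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g * np.exp(self.data - data))

        return Var._node(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accum(g * data)

        return Var._node(data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Var._node(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float):
        """Elementwise maximum with a constant; gradient passes where unclipped."""
        mask = self.data > lo

        def backward(g):
            self._accum(g * mask)

        return Var._node(np.maximum(self.data, lo), (self,), backward)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Var._node(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Var._node(self.data.reshape(*shape), (self,), backward)

    # -- structured ops ----------------------------------------------------
    def gather(self, idx):
        """Row gather ``self[idx]`` (embedding lookup); idx may be any int array."""
        idx = np.asarray(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx.ravel(), g.reshape(-1, *self.data.shape[1:]))
            self._accum(full)

        return Var._node(self.data[idx], (self,), backward)

    def take_along(self, idx):
        """Pick one element per row of a 2-D array: out[i] = self[i, idx[i]]."""
        idx = np.asarray(idx)
        rows = np.arange(self.data.shape[0])

        def backward(g):
            full = np.zeros_like(self.data)
            full[rows, idx] = g
            self._accum(full)

        return Var._node(self.data[rows, idx], (self,), backward)

    def layer_norm(self, eps: float = 1e-5):
        """Normalise the last axis to zero mean, unit variance (no affine)."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        p = x.shape[-1]

        def backward(g):
            # standard layernorm backward over the last axis
            gsum = g.sum(axis=-1, keepdims=True)
            gx = (g - gsum / p - xhat * (g * xhat).sum(axis=-1, keepdims=True) / p) * inv
            self._accum(gx)

        return Var._node(xhat, (self,), backward)

    def log_softmax(self, axis: int = -1):
        x = self.data
        shifted = x - x.max(axis=axis, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out = shifted - logz
        soft = np.exp(out)

        def backward(g):
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Var._node(out, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def dropout(self, rate: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when ``rng`` is None or rate == 0."""
        if rng is None or rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate) / (1.0 - rate)

        def backward(g):
            self._accum(g * keep)

        return Var._node(self.data * keep, (self,), backward)

    @staticmethod
    def concat(parts: Sequence["Var"], axis: int = 0):
        parts = [Var._lift(p) for p in parts]
        data = np.concatenate([p.data for p in parts], axis=axis)
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                p._accum(g[tuple(sl)])

        return Var._node(data, tuple(parts), backward)

    # -- backward pass -----------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += g
        elif self._backward is not None:
            # intermediate node: stash gradient for its own backward call
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Var] = []
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if not node.requires_grad:
                    node.grad = None  # free intermediate gradients


class Adam:
    """Adam optimiser over a list of :class:`Var` parameters."""

    def __init__(self, params: Iterable[Var], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * p.grad ** 2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
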