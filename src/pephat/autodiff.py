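"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: broadcasting arithmetic,
matrix products, gather/segment scatter, the usual pointwise nonlinearities,
and a numerically stable log-sum-exp.  Everything is float64 on CPU.

Gradients are accumulated by a topological sweep over the recorded graph;
``no_grad()`` suppresses graph recording for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- shape helpers ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return Tensor._result(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._result(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
        return Tensor._result(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                b._accum(a.data.swapaxes(-1, -2) @ g)
        return Tensor._result(self.data @ other.data, (self, other), bwd)

    def __getitem__(self, idx):
        def bwd(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._result(self.data[idx], (self,), bwd)

    # -- reductions / reshapes ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())
        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        old = self.data.shape
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(old))
        return Tensor._result(self.data.reshape(*shape), (self,), bwd)

    @property
    def T(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.T)
        return Tensor._result(self.data.T, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(data, requires_grad=True)


# -- pointwise nonlinearities ------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    mask = np.where(x.data > 0, 1.0, slope)
    def bwd(g, a=x, m=mask):
        if a.requires_grad:
            a._accum(g * m)
    return Tensor._result(x.data * mask, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    def bwd(g, a=x, y=out):
        if a.requires_grad:
            a._accum(g * y * (1.0 - y))
    return Tensor._result(out, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    def bwd(g, a=x, y=out):
        if a.requires_grad:
            a._accum(g * (1.0 - y * y))
    return Tensor._result(out, (x,), bwd)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    def bwd(g, a=x, y=out):
        if a.requires_grad:
            a._accum(g * y)
    return Tensor._result(out, (x,), bwd)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    def bwd(g, a=x):
        if a.requires_grad:
            a._accum(g / a.data)
    return Tensor._result(np.log(x.data), (x,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g, ts=tensors, off=offsets):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tuple(tensors), bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    def bwd(g, ts=tensors):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    return Tensor._result(np.stack([t.data for t in tensors], axis=axis),
                          tuple(tensors), bwd)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Stable log(sum(exp(x))) along `axis`; gradient is the softmax."""
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = np.exp(x.data - m)
    s = shifted.sum(axis=axis, keepdims=True)
    out = m + np.log(s)
    soft = shifted / s
    if not keepdims:
        out = np.squeeze(out, axis=axis)
    def bwd(g, a=x, p=soft):
        if a.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(gg * p)
    return Tensor._result(out, (x,), bwd)


# -- segment operations (hypergraph attention) -------------------------------

def segment_sum(values: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `values` into `n_segments` buckets given by `segment_ids`."""
    values = as_tensor(values)
    seg = np.asarray(segment_ids)
    out = np.zeros((n_segments,) + values.data.shape[1:], dtype=np.float64)
    np.add.at(out, seg, values.data)
    def bwd(g, a=values, s=seg):
        if a.requires_grad:
            a._accum(g[s])
    return Tensor._result(out, (values,), bwd)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of `scores` normalized independently within each segment.

    `scores` has shape (P,) or (P, H); normalization is over rows sharing a
    segment id, per trailing column.  Max-subtraction keeps it stable.
    """
    scores = as_tensor(scores)
    seg = np.asarray(segment_ids)
    tail = scores.data.shape[1:]
    mx = np.full((n_segments,) + tail, -np.inf)
    np.maximum.at(mx, seg, scores.data)
    shifted = np.exp(scores.data - mx[seg])
    denom = np.zeros((n_segments,) + tail)
    np.add.at(denom, seg, shifted)
    out = shifted / denom[seg]
    def bwd(g, a=scores, y=out, s=seg):
        if a.requires_grad:
            dot = np.zeros((n_segments,) + tail)
            np.add.at(dot, s, y * g)
            a._accum(y * (g - dot[s]))
    return Tensor._result(out, (scores,), bwd)


# -- optimization -------------------------------------------------------------

def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
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
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
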