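"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the graph-convolution stack needs: broadcast
elementwise arithmetic, matrix products, row gather/scatter, segment
reductions (sum / max, used for per-destination attention softmax and
max-pool aggregation), pointwise nonlinearities, and an Adam optimizer.
Gradients are accumulated by topological-order backpropagation from a
scalar loss.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)
        return Tensor(self.data + other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return Tensor(-self.data, self.requires_grad, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return Tensor(self.data * other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))
        return Tensor(self.data / other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))
        return Tensor(self.data ** p, self.requires_grad, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        return Tensor(self.data @ other.data,
                      self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))
        return Tensor(self.data.reshape(*shape), self.requires_grad,
                      (self,), bwd)

    @property
    def T(self):
        def bwd(g):
            self._accum(g.T)
        return Tensor(self.data.T, self.requires_grad, (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      self.requires_grad, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx):
        idx = np.asarray(idx, dtype=int)

        def bwd(g):
            acc = np.zeros_like(self.data)
            if len(idx) > 4096:  # sort + reduceat beats scattered add.at
                order = np.argsort(idx, kind="stable")
                sorted_ids = idx[order]
                acc += _segment_sum_data(g[order], sorted_ids, len(acc))
            else:
                np.add.at(acc, idx, g)
            self._accum(acc)
        return Tensor(self.data[idx], self.requires_grad, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise nonlinearities ---------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accum(g * np.where(mask, 1.0, slope))
    return Tensor(np.where(mask, x.data, slope * x.data), x.requires_grad,
                  (x,), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accum(g * mask)
    return Tensor(np.where(mask, x.data, 0.0), x.requires_grad, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g):
        x._accum(g * s * (1 - s))
    return Tensor(s, x.requires_grad, (x,), bwd)


def exp(x: Tensor) -> Tensor:
    e = np.exp(np.clip(x.data, -500, 500))

    def bwd(g):
        x._accum(g * e)
    return Tensor(e, x.requires_grad, (x,), bwd)


def log(x: Tensor) -> Tensor:
    def bwd(g):
        x._accum(g / x.data)
    return Tensor(np.log(x.data), x.requires_grad, (x,), bwd)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def bwd(g):
        x._accum(g * 0.5 / r)
    return Tensor(r, x.requires_grad, (x,), bwd)


# -- structural ops --------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  any(t.requires_grad for t in tensors), tuple(tensors), bwd)


def _segment_sum_data(data: np.ndarray, segment_ids: np.ndarray,
                      n_segments: int) -> np.ndarray:
    out = np.zeros((n_segments,) + data.shape[1:])
    if len(segment_ids) == 0:
        return out
    if np.all(np.diff(segment_ids) >= 0):  # sorted: fast reduceat path
        starts = np.searchsorted(segment_ids, np.arange(n_segments))
        nonempty = starts < len(segment_ids)
        sums = np.add.reduceat(data, starts[nonempty], axis=0)
        # reduceat wraps on duplicate start offsets (empty segments); those
        # rows are overwritten by zero via the nonempty mask
        present = np.zeros(n_segments, dtype=bool)
        present[segment_ids] = True
        out[nonempty & present] = sums[present[nonempty]]
        return out
    np.add.at(out, segment_ids, data)
    return out


def segment_sum(values: Tensor, segment_ids, n_segments: int) -> Tensor:
    """Sum rows (or scalars) of ``values`` into ``n_segments`` buckets."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    out = _segment_sum_data(values.data, segment_ids, n_segments)

    def bwd(g):
        values._accum(g[segment_ids])
    return Tensor(out, values.requires_grad, (values,), bwd)


def segment_max(values: Tensor, segment_ids, n_segments: int) -> Tensor:
    """Elementwise max per segment; gradient flows to the (first) argmax."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    out = np.full((n_segments,) + values.data.shape[1:], -np.inf)
    np.maximum.at(out, segment_ids, values.data)
    is_max = values.data == out[segment_ids]
    # route each segment/feature's gradient to a single winner
    order = np.argsort(segment_ids, kind="stable")
    winner = np.zeros_like(is_max, dtype=bool)
    taken = np.zeros((n_segments,) + values.data.shape[1:], dtype=bool)
    for i in order:
        sel = is_max[i] & ~taken[segment_ids[i]]
        winner[i] = sel
        taken[segment_ids[i]] |= sel

    def bwd(g):
        values._accum(np.where(winner, g[segment_ids], 0.0))
    return Tensor(out, values.requires_grad, (values,), bwd)


def scatter_rows(values: Tensor, idx, n_rows: int) -> Tensor:
    """Place rows of ``values`` at positions ``idx`` of a zero (n_rows, F)."""
    idx = np.asarray(idx, dtype=int)
    out = np.zeros((n_rows,) + values.data.shape[1:])
    out[idx] = values.data

    def bwd(g):
        values._accum(g[idx])
    return Tensor(out, values.requires_grad, (values,), bwd)


def attention_mix(ex: Tensor, wh: Tensor) -> Tensor:
    """Batched attention aggregation: out[g,i,k,f] = sum_j ex[g,i,j,k] * wh[g,j,k,f].

    ``ex`` holds (unnormalized) attention weights over source nodes j per
    destination i and head k; ``wh`` the per-head source embeddings.
    """

    def bwd(g):
        ex._accum(np.einsum("gikf,gjkf->gijk", g, wh.data))
        wh._accum(np.einsum("gijk,gikf->gjkf", ex.data, g))
    out = np.einsum("gijk,gjkf->gikf", ex.data, wh.data)
    return Tensor(out, ex.requires_grad or wh.requires_grad, (ex, wh), bwd)


def log_softmax(x: Tensor) -> Tensor:
    """Row-wise log-softmax of a 2D tensor."""
    m = x.data.max(axis=1, keepdims=True)  # constant shift
    shifted = x - Tensor(m)
    lse = log(exp(shifted).sum(axis=1, keepdims=True))
    return shifted - lse


# -- parameters and optimization -------------------------------------------

class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Parameter:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-lim, lim, size=(fan_in, fan_out)))


class Adam:
    """Adaptive-moment gradient descent over a list of Parameters."""

    def __init__(self, params, lr: float = 5e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
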