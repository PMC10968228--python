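"""Local and global graph-convolution units.

The local unit (Lconv) runs GAT-style multi-head attention independently at
each spatial scale over the sequence-library edge sets, then concatenates
heads and scales. The global unit (Gconv) operates on root nodes only: it
learns an adjacency from the layer's input features (sigmoid Gram matrix of
batch-normalized embedded features, masked to cross-sequence root pairs,
sparsified at a threshold, plus identity) and applies a degree-normalized
graph convolution; non-root nodes pass through a plain embedding so widths
line up. A GraphSAGE max-pool aggregator is available as an alternative
global backend.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import (Adam, Parameter, Tensor, concat, glorot, leaky_relu,
                       scatter_rows, segment_max, segment_sum, sigmoid)

LEAKY_SLOPE = 0.2


class Module:
    """Lightweight container with recursive parameter discovery."""

    def parameters(self):
        out = []
        for v in vars(self).values():
            out.extend(_collect(v))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def norms(self):
        out = []
        for v in vars(self).values():
            out.extend(_collect(v, kind="norm"))
        return out

    def get_state(self):
        """Weights plus normalization running statistics."""
        state = [p.data.copy() for p in self.parameters()]
        for n in self.norms():
            state += [n.mean.copy(), n.var.copy(),
                      np.array([n.initialized])]
        return state

    def set_state(self, state):
        params = self.parameters()
        for p, s in zip(params, state):
            p.data = s.copy()
        rest = state[len(params):]
        for i, n in enumerate(self.norms()):
            n.mean = rest[3 * i].copy()
            n.var = rest[3 * i + 1].copy()
            n.initialized = bool(rest[3 * i + 2][0])


def _collect(v, kind="param"):
    if kind == "param" and isinstance(v, Parameter):
        return [v]
    if kind == "norm" and isinstance(v, _RunningNorm):
        return [v]
    if isinstance(v, Module):
        return v.parameters() if kind == "param" else v.norms()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item, kind))
        return out
    return []


def attention_coefficients(features: Tensor, src, dst, W, a,
                           n_nodes: int, slope: float = LEAKY_SLOPE) -> Tensor:
    """Per-edge normalized attention for in-edges ``src -> dst``.

    ``a`` is the length-2*Eo attention vector split over the destination and
    source halves of the concatenated embedded pair; the softmax normalizes
    over each destination's in-edges. Returns an (E, 1) tensor.
    """
    W = W if isinstance(W, Tensor) else Tensor(W)
    a = a if isinstance(a, Tensor) else Tensor(a)
    eo = W.shape[1]
    wh = features @ W
    a_dst = a.reshape(-1, 1).take_rows(np.arange(eo))
    a_src = a.reshape(-1, 1).take_rows(np.arange(eo, 2 * eo))
    score_dst = wh @ a_dst  # (N, 1)
    score_src = wh @ a_src
    e = leaky_relu(score_dst.take_rows(dst) + score_src.take_rows(src), slope)
    # subtract the (constant) per-destination max for a stable softmax
    dst = np.asarray(dst, dtype=int)
    m = np.full(n_nodes, -np.inf)
    np.maximum.at(m, dst, e.data[:, 0])
    ex = ad.exp(e - Tensor(m[dst, None]))
    denom = segment_sum(ex, dst, n_nodes)
    return ex / denom.take_rows(dst)


class LconvUnit(Module):
    """Multi-scale, multi-head local attention convolution.

    Output width is ``n_scales_used * n_heads * out_per_head``. With
    ``n_heads == 0`` the unit degenerates to a plain per-node embedding
    (the local convolution is disregarded).
    """

    def __init__(self, in_dim: int, out_dim: int, n_heads: int, scales: int,
                 include_scale0: bool = True, rng=None, slope=LEAKY_SLOPE):
        rng = np.random.default_rng(rng)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.n_heads, self.slope = n_heads, slope
        self.scale_list = list(range(0 if include_scale0 else 1, scales + 1))
        if n_heads == 0:
            self.W_plain = glorot(rng, in_dim, out_dim)
            return
        width = len(self.scale_list) * n_heads
        if out_dim % width:
            raise ValueError(
                f"out_dim {out_dim} not divisible by scales*heads {width}")
        eo = out_dim // width
        self.per_head = eo
        self.W = [[glorot(rng, in_dim, eo) for _ in range(n_heads)]
                  for _ in self.scale_list]
        self.a = [[Parameter(rng.uniform(-0.1, 0.1, size=2 * eo))
                   for _ in range(n_heads)]
                  for _ in self.scale_list]

    def forward(self, V: Tensor, bundle) -> Tensor:
        """All heads of one scale are evaluated in a single batched pass;
        the result equals per-head attention outputs concatenated. When the
        bundle carries the dense block structure, attention runs over
        per-sequence blocks; otherwise over the flat edge lists. The two
        paths compute the same quantity."""
        if self.n_heads == 0:
            return leaky_relu(V @ self.W_plain, self.slope)
        n = V.shape[0]
        K, eo = self.n_heads, self.per_head
        sel_dst = np.zeros((2 * eo, eo))
        sel_dst[:eo] = np.eye(eo)
        sel_src = np.zeros((2 * eo, eo))
        sel_src[eo:] = np.eye(eo)
        outs = []
        for si, s in enumerate(self.scale_list):
            Wcat = concat(self.W[si], axis=1)                  # (in, K*eo)
            a_all = concat([a.reshape(1, -1) for a in self.a[si]],
                           axis=0)                             # (K, 2*eo)
            a_dst = a_all @ Tensor(sel_dst)
            a_src = a_all @ Tensor(sel_src)
            wh = (V @ Wcat).reshape(n, K, eo)
            s_dst = (wh * a_dst.reshape(1, K, eo)).sum(axis=2)  # (N, K)
            s_src = (wh * a_src.reshape(1, K, eo)).sum(axis=2)
            bs = bundle.block_structure.get(s) \
                if getattr(bundle, "block_structure", None) else None
            if bs is not None:
                outs.append(self._scale_dense(wh, s_dst, s_src, bs, n))
            else:
                outs.append(self._scale_edges(wh, s_dst, s_src,
                                              bundle.local_edges[s], n))
        return concat(outs, axis=1) if len(outs) > 1 else outs[0]

    __call__ = forward

    def _scale_edges(self, wh, s_dst, s_src, e, n):
        K, eo = self.n_heads, self.per_head
        src, dst = e.src, e.dst
        escore = leaky_relu(s_dst.take_rows(dst) + s_src.take_rows(src),
                            self.slope)                        # (E, K)
        m = np.full((n, K), -np.inf)
        np.maximum.at(m, dst, escore.data)
        ex = ad.exp(escore - Tensor(m[dst]))
        denom = segment_sum(ex, dst, n)
        alpha = ex / denom.take_rows(dst)
        msg = (alpha.reshape(len(src), K, 1)
               * wh.take_rows(src)).reshape(len(src), K * eo)
        agg = segment_sum(msg, dst, n)
        return leaky_relu(agg, self.slope)

    def _scale_dense(self, wh, s_dst, s_src, bs, n):
        K, eo = self.n_heads, self.per_head
        G, A = bs.ids.shape
        C = bs.cross_ids.shape[1]
        flat = bs.ids.ravel()
        wh_b = wh.take_rows(flat).reshape(G, A, K, eo)
        sd_b = s_dst.take_rows(flat).reshape(G, A, 1, K)
        ss_b = s_src.take_rows(flat).reshape(G, 1, A, K)
        e_b = leaky_relu(sd_b + ss_b, self.slope)              # (G, A, A, K)
        cflat = bs.cross_ids.ravel()
        ss_c = s_src.take_rows(cflat).reshape(G, 1, C, K)
        sd_r = s_dst.take_rows(bs.ids[:, 0]).reshape(G, 1, 1, K)
        e_c = leaky_relu(sd_r + ss_c, self.slope)              # (G, 1, C, K)
        # constant per-destination shift for a stable softmax
        mb = np.where(bs.mask[:, None, :, None], e_b.data, -np.inf) \
            .max(axis=2)                                       # (G, A, K)
        mc = np.where(bs.cross_mask[:, None, :, None], e_c.data, -np.inf) \
            .max(axis=2)[:, 0]                                 # (G, K)
        mb[:, 0] = np.maximum(mb[:, 0], mc)
        src_mask = Tensor(bs.mask[:, None, :, None].astype(np.float64))
        ex_b = ad.exp(e_b - Tensor(mb[:, :, None, :])) * src_mask
        denom_b = ex_b.sum(axis=2)                             # (G, A, K)
        msg_b = ad.attention_mix(ex_b, wh_b)                   # (G, A, K, eo)
        cmask = Tensor(bs.cross_mask[:, None, :, None].astype(np.float64))
        ex_c = ad.exp(e_c - Tensor(mb[:, 0][:, None, None, :])) * cmask
        wh_c = wh.take_rows(cflat).reshape(G, C, K, eo)
        msg_c = ad.attention_mix(ex_c, wh_c).reshape(G, K, eo)
        denom_c = ex_c.sum(axis=2).reshape(G, K)

        root_rows = np.arange(G) * A
        msg_flat = msg_b.reshape(G * A, K, eo)
        den_flat = denom_b.reshape(G * A, K)
        numer_r = msg_flat.take_rows(root_rows) + msg_c
        denom_r = den_flat.take_rows(root_rows) + denom_c
        out_r = leaky_relu(numer_r / denom_r.reshape(G, K, 1), self.slope) \
            .reshape(G, K * eo)
        out = scatter_rows(out_r, bs.ids[:, 0], n)

        sel = np.flatnonzero(bs.mask.ravel()
                             & (np.arange(G * A) % A != 0))
        if len(sel):
            out_nr = leaky_relu(
                msg_flat.take_rows(sel)
                / den_flat.take_rows(sel).reshape(len(sel), K, 1),
                self.slope).reshape(len(sel), K * eo)
            out = out + scatter_rows(out_nr, flat[sel], n)
        if len(bs.absent):
            out_a = leaky_relu(wh.take_rows(bs.absent), self.slope) \
                .reshape(len(bs.absent), K * eo)
            out = out + scatter_rows(out_a, bs.absent, n)
        return out


def batch_norm(X: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Per-feature normalization over the current node set, learned affine."""
    mu = X.mean(axis=0, keepdims=True)
    xc = X - mu
    var = (xc * xc).mean(axis=0, keepdims=True)
    xn = xc / ad.sqrt(var + eps)
    return xn * gamma + beta


def agl_adjacency(S_root: Tensor, Wphi: Tensor, gamma: Tensor, beta: Tensor,
                  mask: np.ndarray | None = None,
                  threshold: float = 0.5) -> Tensor:
    """Learned root-node adjacency: sigmoid Gram of embedded, batch-normalized
    features, masked to cross-sequence pairs, sparsified, plus identity.

    Sparsification keeps off-diagonal entries >= ``threshold`` (a detached
    binary gate, so gradients flow only through surviving edges); the
    identity is added afterwards so self-loops always survive.
    """
    nr = S_root.shape[0]
    if nr < 2:
        raise ValueError("adaptive adjacency needs at least 2 root nodes")
    emb = batch_norm(S_root, gamma, beta) @ Wphi
    A = sigmoid(emb @ emb.T)
    gate = np.ones((nr, nr), dtype=bool) if mask is None else np.asarray(mask)
    gate = gate & ~np.eye(nr, dtype=bool)
    gate = gate & (A.data >= threshold)
    A = A * Tensor(gate.astype(np.float64))
    return A + Tensor(np.eye(nr))


def gconv_forward(S: Tensor, Wg: Tensor, A_tilde: Tensor,
                  root_idx: np.ndarray | None = None,
                  slope: float = LEAKY_SLOPE) -> Tensor:
    """Degree-normalized graph convolution H = sigma(D^-1/2 A D^-1/2 S Wg).

    With ``root_idx`` given, the convolution acts on the root rows only and
    the remaining rows receive the plain embedding sigma(S Wg).
    """
    Wg = Wg if isinstance(Wg, Tensor) else Tensor(Wg)
    if root_idx is None:
        S_r, n = S, None
    else:
        root_idx = np.asarray(root_idx, dtype=int)
        n = S.shape[0]
        S_r = S.take_rows(root_idx)
    deg = A_tilde.sum(axis=1, keepdims=True)
    dinv = deg ** -0.5
    A_hat = A_tilde * dinv * dinv.T
    H_r = leaky_relu(A_hat @ (S_r @ Wg), slope)
    if root_idx is None:
        return H_r
    non_root = np.setdiff1d(np.arange(n), root_idx)
    out = scatter_rows(H_r, root_idx, n)
    if len(non_root):
        H_nr = leaky_relu(S.take_rows(non_root) @ Wg, slope)
        out = out + scatter_rows(H_nr, non_root, n)
    return out


class _RunningNorm:
    """Batch-norm statistics holder: batch stats while training (with an
    exponential running update), frozen running stats at inference, so the
    unit behaves identically on graphs it has never seen."""

    def __init__(self, dim: int, momentum: float = 0.1):
        self.mean = np.zeros(dim)
        self.var = np.ones(dim)
        self.momentum = momentum
        self.initialized = False

    def normalize(self, X: Tensor, gamma, beta, training: bool,
                  eps: float = 1e-5) -> Tensor:
        if training:
            mu = X.data.mean(axis=0)
            var = X.data.var(axis=0)
            if not self.initialized:
                self.mean, self.var = mu.copy(), var.copy()
                self.initialized = True
            else:
                m = self.momentum
                self.mean = (1 - m) * self.mean + m * mu
                self.var = (1 - m) * self.var + m * var
            return batch_norm(X, gamma, beta, eps)
        xn = (X - Tensor(self.mean[None, :])) \
            / Tensor(np.sqrt(self.var + eps)[None, :])
        return xn * gamma + beta


class GconvUnit(Module):
    """Global convolution with adaptive graph learning on root nodes."""

    def __init__(self, in_dim: int, out_dim: int, agl_dim: int = 16,
                 threshold: float = 0.5, rng=None, slope=LEAKY_SLOPE):
        rng = np.random.default_rng(rng)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.threshold, self.slope = threshold, slope
        self.Wg = glorot(rng, in_dim, out_dim)
        self.Wphi = glorot(rng, in_dim, agl_dim)
        self.gamma = Parameter(np.ones(in_dim))
        self.beta = Parameter(np.zeros(in_dim))
        self.bn = _RunningNorm(in_dim)

    def adjacency(self, S: Tensor, root_idx, mask,
                  training: bool = True) -> Tensor:
        S_r = S.take_rows(root_idx)
        nr = S_r.shape[0]
        if nr < 2:
            raise ValueError("adaptive adjacency needs at least 2 root nodes")
        emb = self.bn.normalize(S_r, self.gamma, self.beta, training) \
            @ self.Wphi
        A = sigmoid(emb @ emb.T)
        gate = np.ones((nr, nr), dtype=bool) if mask is None \
            else np.asarray(mask)
        gate = gate & ~np.eye(nr, dtype=bool) & (A.data >= self.threshold)
        return A * Tensor(gate.astype(np.float64)) + Tensor(np.eye(nr))

    def forward(self, S: Tensor, root_idx, mask,
                training: bool = True) -> Tensor:
        A = self.adjacency(S, root_idx, mask, training)
        return gconv_forward(S, self.Wg, A, root_idx=root_idx,
                             slope=self.slope)

    __call__ = forward


def sage_maxpool_forward(H: Tensor, nbr_src, nbr_dst, Wpool: Tensor, b: Tensor,
                         Wk: Tensor, slope: float = LEAKY_SLOPE) -> Tensor:
    """Max-pool aggregation over neighbor sets, then embed [self || pooled]."""
    nbr_dst = np.asarray(nbr_dst, dtype=int)
    if len(nbr_dst) == 0 or len(np.unique(nbr_dst)) < H.shape[0]:
        raise ValueError("every node needs at least one neighbor")
    n = H.shape[0]
    transformed = leaky_relu(H.take_rows(nbr_src) @ Wpool + b, slope)
    pooled = segment_max(transformed, nbr_dst, n)
    return leaky_relu(concat([H, pooled], axis=1) @ Wk, slope)


class SageMaxPoolUnit(Module):
    """Global backend variant: neighbor sets from the learned adjacency,
    max-pool aggregation instead of the normalized matrix product."""

    def __init__(self, in_dim: int, out_dim: int, agl_dim: int = 16,
                 threshold: float = 0.5, rng=None, slope=LEAKY_SLOPE):
        rng = np.random.default_rng(rng)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.threshold, self.slope = threshold, slope
        self.Wpool = glorot(rng, in_dim, in_dim)
        self.b = Parameter(np.zeros(in_dim))
        self.Wk = glorot(rng, 2 * in_dim, out_dim)
        self.Wphi = glorot(rng, in_dim, agl_dim)
        self.gamma = Parameter(np.ones(in_dim))
        self.beta = Parameter(np.zeros(in_dim))
        self.bn = _RunningNorm(in_dim)

    def forward(self, S: Tensor, root_idx, mask,
                training: bool = True) -> Tensor:
        root_idx = np.asarray(root_idx, dtype=int)
        n = S.shape[0]
        S_r = S.take_rows(root_idx)
        nr = S_r.shape[0]
        emb = self.bn.normalize(S_r, self.gamma, self.beta, training) \
            @ self.Wphi
        A = sigmoid(emb @ emb.T)
        gate = np.ones((nr, nr), dtype=bool) if mask is None \
            else np.asarray(mask)
        gate = gate & ~np.eye(nr, dtype=bool) & (A.data >= self.threshold)
        A = A * Tensor(gate.astype(np.float64)) + Tensor(np.eye(nr))
        src, dst = np.nonzero(A.data.T > 0)  # (col, row): src -> dst
        H_r = sage_maxpool_forward(S_r, src, dst, self.Wpool, self.b, self.Wk,
                                   self.slope)
        non_root = np.setdiff1d(np.arange(n), root_idx)
        out = scatter_rows(H_r, root_idx, n)
        if len(non_root):
            S_nr = S.take_rows(non_root)
            pooled = leaky_relu(S_nr @ self.Wpool + self.b, self.slope)
            H_nr = leaky_relu(concat([S_nr, pooled], axis=1) @ self.Wk,
                              self.slope)
            out = out + scatter_rows(H_nr, non_root, n)
        return out

    __call__ = forward


GLOBAL_BACKENDS = {"gcn": GconvUnit, "sage_maxpool": SageMaxPoolUnit}


def make_global_unit(backend: str, *args, **kwargs):
    if backend not in GLOBAL_BACKENDS:
        raise NotImplementedError(
            f"global backend {backend!r} not implemented; "
            f"choose from {sorted(GLOBAL_BACKENDS)}")
    return GLOBAL_BACKENDS[backend](*args, **kwargs)
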