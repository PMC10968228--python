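"""Building blocks and the dense local-global network.

Two four-unit blocks are provided: the cross-talk block interleaves local
and global convolutions with residual aggregations at every layer, while the
sequential block completes both local convolutions before the two global
ones. The dense network embeds the input once to width ``d``, feeds block i
the concatenation of that embedding and all previous block outputs (input
widths d, 2d, ..., Md), concatenates all block outputs, and classifies each
node with a two-layer MLP head producing log-probabilities over the five
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, glorot, leaky_relu, log_softmax, relu
from .conv_units import (LEAKY_SLOPE, LconvUnit, Module, make_global_unit)
from .volume import N_CLASSES


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the dense network.

    ``d`` must be divisible by ``n_heads`` times the number of scale
    concatenands (scales+1 with scale 0 included) so that local and global
    unit outputs can be summed inside blocks.
    """

    block: str = "ct"            # "ct" (cross-talk) or "seq" (sequential)
    n_blocks: int = 3            # M
    d: int = 120                 # per-block output width
    n_heads: int = 8             # K; 0 disables the local units
    scales: int = 2              # S
    include_scale0: bool = True
    backend: str = "gcn"         # global unit: "gcn" or "sage_maxpool"
    threshold: float = 0.5       # adjacency sparsification cut-off
    agl_dim: int = 16            # embedding width of the learned adjacency
    head_uses_input: bool = True  # initial embedding joins the head concat
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.block not in ("ct", "seq"):
            raise ValueError(f"unknown block kind {self.block!r}")


class _BlockBase(Module):
    def __init__(self, in_dim: int, cfg: ModelConfig, rng):
        rng = np.random.default_rng(rng)
        d = cfg.d
        mk_l = lambda fi: LconvUnit(fi, d, cfg.n_heads, cfg.scales,
                                    cfg.include_scale0, rng=rng)
        mk_g = lambda fi: make_global_unit(cfg.backend, fi, d, cfg.agl_dim,
                                           cfg.threshold, rng=rng)
        self.lconv1 = mk_l(in_dim)
        self.lconv2 = mk_l(d)
        self.gconv1 = mk_g(d)
        self.gconv2 = mk_g(d)


class CTBlock(_BlockBase):
    """Cross-talk block: alternating local/global units with skip sums."""

    def forward(self, X: Tensor, bundle, root_idx, mask,
                training: bool = True) -> Tensor:
        Q1 = self.lconv1(X, bundle)
        H1 = self.gconv1(Q1, root_idx, mask, training)
        V1 = H1 + Q1
        Q2 = self.lconv2(V1, bundle)
        S1 = H1 + Q2
        H2 = self.gconv2(S1, root_idx, mask, training)
        return H2 + Q2

    __call__ = forward


class SEQBlock(_BlockBase):
    """Sequential block: two local units, then two global units, one sum."""

    def forward(self, X: Tensor, bundle, root_idx, mask,
                training: bool = True) -> Tensor:
        Q1 = self.lconv1(X, bundle)
        Q2 = self.lconv2(Q1, bundle)
        H1 = self.gconv1(Q2, root_idx, mask, training)
        H2 = self.gconv2(H1, root_idx, mask, training)
        return Q2 + H2

    __call__ = forward


BLOCK_KINDS = {"ct": CTBlock, "seq": SEQBlock}


class DenseGCN(Module):
    """Densely connected stack of local-global blocks with an MLP head."""

    def __init__(self, in_dim: int, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d, M = cfg.d, cfg.n_blocks
        self.embed0 = glorot(rng, in_dim, d)
        block_cls = BLOCK_KINDS[cfg.block]
        self.blocks = [block_cls(i * d, cfg, rng) for i in range(1, M + 1)]
        head_in = (M + 1) * d if cfg.head_uses_input else M * d
        self.W1 = glorot(rng, head_in, d)
        self.W2 = glorot(rng, d, cfg.n_classes)

    @property
    def block_input_widths(self):
        return [b.lconv1.in_dim for b in self.blocks]

    def forward(self, X: Tensor, bundle, root_idx=None, mask=None,
                training: bool = True) -> Tensor:
        from .graphs import global_edge_mask
        if root_idx is None:
            root_idx = bundle.node_table.root_indices
        if mask is None:
            mask = global_edge_mask(bundle.node_table)
        h0 = leaky_relu(X @ self.embed0, LEAKY_SLOPE)
        concatenands = [h0]
        outputs = []
        for block in self.blocks:
            zin = (concat(concatenands, axis=1)
                   if len(concatenands) > 1 else concatenands[0])
            zo = block(zin, bundle, root_idx, mask, training)
            outputs.append(zo)
            concatenands.append(zo)
        # the once-embedded input joins the final concatenation by the same
        # dense-skip convention that counts it as a block-input concatenand;
        # it preserves each node's own identity channel next to the
        # neighborhood-aggregated block outputs
        head_parts = ([h0] + outputs if self.cfg.head_uses_input
                      else outputs)
        z = concat(head_parts, axis=1) if len(head_parts) > 1 \
            else head_parts[0]
        logits = relu(z @ self.W1) @ self.W2
        return log_softmax(logits)

    __call__ = forward

    def predict_labels(self, X: Tensor, bundle,
                       root_idx=None, mask=None) -> np.ndarray:
        """Evaluation-mode argmax labels (frozen normalization stats)."""
        out = self.forward(X, bundle, root_idx, mask, training=False)
        return np.argmax(out.data, axis=1)


def cross_entropy_loss(log_probs: Tensor, labels, labeled_mask,
                       reduction: str = "mean") -> Tensor:
    """Negative log-probability of the true class over the labeled nodes."""
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    if not labeled_mask.any():
        raise ValueError("no labeled nodes")
    idx = np.flatnonzero(labeled_mask)
    labels = np.asarray(labels, dtype=int)[idx]
    rows = log_probs.take_rows(idx)
    onehot = np.zeros((len(idx), log_probs.shape[1]))
    onehot[np.arange(len(idx)), labels] = 1.0
    picked = (rows * Tensor(onehot)).sum(axis=1)
    total = -picked.sum()
    if reduction == "mean":
        return total * (1.0 / len(idx))
    if reduction == "sum":
        return total
    raise ValueError(f"unknown reduction {reduction!r}")


def save_model(model: DenseGCN, directory: str) -> None:
    """Checkpoint: flat parameter/statistics archive plus a JSON config."""
    import json
    import os
    from dataclasses import asdict

    os.makedirs(directory, exist_ok=True)
    state = model.get_state()
    np.savez(os.path.join(directory, "state.npz"),
             **{f"arr{i}": a for i, a in enumerate(state)})
    meta = {"config": asdict(model.cfg), "in_dim": int(model.embed0.shape[0]),
            "n_arrays": len(state)}
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(directory: str) -> DenseGCN:
    import json
    import os

    with open(os.path.join(directory, "config.json")) as fh:
        meta = json.load(fh)
    cfg = ModelConfig(**meta["config"])
    model = DenseGCN(meta["in_dim"], cfg, seed=0)
    with np.load(os.path.join(directory, "state.npz")) as data:
        state = [data[f"arr{i}"] for i in range(meta["n_arrays"])]
    model.set_state(state)
    return model
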