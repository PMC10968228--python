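"""Three-stage transductive segmentation, inductive and full-batch variants.

Stage 1 trains the dense network semi-supervised on the graph of an initial
target batch (atlas nodes labeled, target nodes unlabeled) and labels that
batch. Stage 2 sweeps the remaining candidate roots in out-of-sample
batches, each time warm-starting from the stage-1 weights and fine-tuning
for a few refresh epochs before labeling. Stage 3 labels every remaining
ROI voxel by a vote over nearby labeled nodes weighted by the product of
normalized spectral (l2 feature) and spatial (l1 coordinate) proximities.
Full-batch learning puts all candidates in stage 1 and skips stage 2; the
inductive variant trains only on the nearest labeled image and its own
library, never touching target data during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .atlas import AtlasLibrary, ROIMask, build_roi, cartilage_mask, \
    select_atlases
from .autodiff import Adam, Tensor
from .features import HogVolumeCache, hog_volume_descriptors
from .graphs import UNLABELED, build_graph, global_edge_mask, \
    sample_root_nodes
from .metrics import MetricsReport, evaluate_segmentation
from .models import DenseGCN, ModelConfig, cross_entropy_loss
from .volume import LabelMap, Volume


@dataclass
class TrainConfig:
    """Optimization and batching settings."""

    mode: str = "transductive"       # "transductive" | "inductive"
    batch: str = "mini"              # "mini" | "full"
    batch_size: int = 128            # initial and out-of-sample batch size
    n_candidates: int = 512          # target roots enumerated up front
    refresh_epochs: int = 20         # stage-2 fine-tuning epochs per batch
    max_epochs: int = 500
    patience_no_improve: int = 50    # epochs without validation improvement
    patience_increase: int = 10      # consecutive epochs of rising val loss
    lr: float = 1e-2
    betas: tuple = (0.9, 0.999)
    val_fraction: float = 0.1        # labeled nodes held out for stopping
    seed: int = 0
    max_nodes: int = 2_000_000       # full-batch graph size guard
    log_path: str | None = None      # JSON-lines per-epoch run log

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience_no_improve < 1 or self.patience_increase < 1:
            raise ValueError("patience values must be >= 1")


@dataclass
class VotingConfig:
    """Stage-3 voting settings (Chebyshev candidate search)."""

    search_radius: int = 2

    def __post_init__(self):
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


@dataclass
class LabeledNodes:
    """Labeled target root nodes accumulated over stages 1-2."""

    coords: np.ndarray    # (n, 3)
    features: np.ndarray  # (n, 20)
    labels: np.ndarray    # (n,)


@dataclass
class Stage1Result:
    model: DenseGCN
    initial_state: list            # W0, for stage-2 warm starts
    candidates: np.ndarray         # all enumerated target root coordinates
    batch_order: np.ndarray        # candidate visit order
    labeled: LabeledNodes          # stage-1 batch labels
    history: list = field(default_factory=list)
    training_images: list = field(default_factory=list)
    feature_stats: tuple | None = None  # frozen standardization (mu, sd)


@dataclass
class SegmentationResult:
    label_map: LabelMap
    labeled_nodes: LabeledNodes
    stage2_invoked: bool
    stage1: Stage1Result
    training_images: list = field(default_factory=list)

    def evaluate(self, truth: LabelMap, roi=None) -> MetricsReport:
        return evaluate_segmentation(self.label_map, truth, roi=roi)


def _write_log(cfg: TrainConfig, record: dict):
    if cfg.log_path:
        with open(cfg.log_path, "a") as fh:
            fh.write(json.dumps(record) + "\n")


def _feature_stats(table):
    """Per-feature mean/sd over one graph's nodes (for standardization)."""
    f = table.features
    mu = f.mean(axis=0, keepdims=True)
    sd = f.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return mu, sd


def _features_tensor(table, stats=None) -> Tensor:
    """Standardized node features for numerical conditioning.

    Raw descriptor entries span several orders of magnitude; z-scoring each
    feature keeps the first embedding well scaled. The statistics are
    computed once on the stage-1 graph and frozen for all later graphs, so
    the trained network sees a consistent input mapping. The stored (raw)
    features remain untouched for stage-3 distances.
    """
    mu, sd = _feature_stats(table) if stats is None else stats
    return Tensor((table.features - mu) / sd)


def _train_model(model: DenseGCN, bundle, cfg: TrainConfig, epochs: int,
                 early_stop: bool, rng: np.random.Generator,
                 stage: str = "stage1", stats=None):
    """Full-graph Adam training of the semi-supervised node loss."""
    t = bundle.node_table
    X = _features_tensor(t, stats)
    labeled = t.label != UNLABELED
    if not labeled.any():
        raise ValueError("no labeled nodes in graph")
    labeled_idx = np.flatnonzero(labeled)
    val_mask = np.zeros(t.n_nodes, dtype=bool)
    if early_stop and cfg.val_fraction > 0 and len(labeled_idx) >= 10:
        n_val = max(1, int(round(cfg.val_fraction * len(labeled_idx))))
        val_ids = rng.choice(labeled_idx, size=n_val, replace=False)
        val_mask[val_ids] = True
    train_mask = labeled & ~val_mask
    root_idx = t.root_indices
    mask = global_edge_mask(t)

    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    best_val, best_state, since_improve, rising = np.inf, None, 0, 0
    prev_val = np.inf
    history = []
    for epoch in range(epochs):
        log_probs = model(X, bundle, root_idx, mask)
        loss = cross_entropy_loss(log_probs, t.label, train_mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        rec = {"stage": stage, "epoch": epoch, "loss": float(loss.data)}
        if val_mask.any():
            val_loss = float(cross_entropy_loss(
                Tensor(log_probs.data), t.label, val_mask).data)
            rec["val_loss"] = val_loss
            if early_stop:
                if val_loss < best_val - 1e-9:
                    best_val, since_improve = val_loss, 0
                    best_state = model.get_state()
                else:
                    since_improve += 1
                rising = rising + 1 if val_loss > prev_val + 1e-12 else 0
                prev_val = val_loss
                if since_improve >= cfg.patience_no_improve:
                    rec["stop"] = "no_improvement"
                if rising >= cfg.patience_increase:
                    rec["stop"] = "validation_increase"
        history.append(rec)
        _write_log(cfg, rec)
        if "stop" in rec:
            break
    if early_stop and best_state is not None:
        model.set_state(best_state)
    return history


def _label_target_roots(model: DenseGCN, bundle,
                        stats=None) -> LabeledNodes:
    """Argmax-label the target root nodes of a trained graph."""
    t = bundle.node_table
    sel = np.flatnonzero(t.root_flag & (t.image_id == 0))
    preds = model.predict_labels(_features_tensor(t, stats), bundle)
    return LabeledNodes(t.coords[sel].copy(), t.features[sel].copy(),
                        preds[sel])


def fuse_remaining_voxels(labeled: LabeledNodes, lib: AtlasLibrary,
                          caches, cfg: VotingConfig | None = None) -> LabelMap:
    """Stage 3 with the full labeled vertex set, computed densely.

    Voting vertices are the model-labeled target roots plus every atlas
    voxel (each carries its atlas label); scores accumulate the product of
    the spectral and spatial kernels per class. The per-voxel weight
    normalizations of :func:`label_remaining_voxels` divide all classes by
    the same constants, so the argmax is unchanged and is computed here
    without them, with the atlas contribution vectorized per offset.
    """
    cfg = cfg or VotingConfig()
    r = cfg.search_radius
    shape = lib.target.shape
    out = np.zeros(shape, dtype=np.uint8)
    roi_coords = np.argwhere(lib.roi.data)
    lab_lut = {tuple(c): l for c, l in zip(labeled.coords, labeled.labels)}
    todo = np.array([i for i, c in enumerate(roi_coords)
                     if tuple(c) not in lab_lut], dtype=int)
    for c, l in lab_lut.items():
        out[c] = l
    if len(todo) == 0:
        return LabelMap(out)
    vox = roi_coords[todo]
    fv = caches[0].descriptors(vox)
    score = np.zeros((len(vox), 5))
    dim = np.asarray(shape)
    offsets = np.array([[dx, dy, dz]
                        for dx in range(-r, r + 1)
                        for dy in range(-r, r + 1)
                        for dz in range(-r, r + 1)])
    for (_, labmap), cache in zip(lib.atlases, caches[1:]):
        for o in offsets:
            cc = vox + o
            ok = np.all((cc >= 0) & (cc < dim), axis=1)
            if not ok.any():
                continue
            f = cache.descriptors(cc[ok])
            spec_w = 1.0 / (1.0 + np.linalg.norm(f - fv[ok], axis=1))
            w = spec_w * (1.0 / (1.0 + np.abs(o).sum()))
            lab = labmap.data[tuple(cc[ok].T)]
            np.add.at(score, (np.flatnonzero(ok), lab), w)
    # sparse labeled target roots join the same vote
    tree = cKDTree(labeled.coords)
    for i, cand in enumerate(tree.query_ball_point(vox, r=r, p=np.inf)):
        if not cand:
            continue
        cand = np.asarray(cand, dtype=int)
        spec_w = 1.0 / (1.0 + np.linalg.norm(
            labeled.features[cand] - fv[i], axis=1))
        spat_w = 1.0 / (1.0 + np.abs(labeled.coords[cand] - vox[i])
                        .sum(axis=1))
        np.add.at(score, (np.full(len(cand), i), labeled.labels[cand]),
                  spec_w * spat_w)
    out[tuple(vox.T)] = np.argmax(score, axis=1)
    return LabelMap(out)


def _library_caches(lib: AtlasLibrary):
    """One descriptor cache per image of the library (target first)."""
    return [HogVolumeCache(lib.target.data)] + \
        [HogVolumeCache(v.data) for v, _ in lib.atlases]


def train_stage1(lib: AtlasLibrary, mcfg: ModelConfig, tcfg: TrainConfig,
                 target_labelmap: LabelMap | None = None,
                 caches=None) -> Stage1Result:
    """Sample candidates, train on the initial batch, label it."""
    rng = np.random.default_rng(tcfg.seed)
    if caches is None:
        caches = _library_caches(lib)
    n_cand = min(tcfg.n_candidates, lib.roi.voxel_count)
    candidates = sample_root_nodes(lib.target, lib.roi, n_cand,
                                   seed=tcfg.seed)
    order = rng.permutation(len(candidates))
    if tcfg.batch == "full":
        n0 = len(candidates)
        est = n0 * (lib.n_atlases + 1) * (2 * mcfg.scales + 1) ** 3
        if est > tcfg.max_nodes:
            raise ValueError(
                f"full-batch graph of ~{est} nodes exceeds the configured "
                f"budget of {tcfg.max_nodes}; use mini-batch learning")
    else:
        n0 = min(tcfg.batch_size, len(candidates))
    batch0 = candidates[order[:n0]]
    bundle = build_graph(batch0, lib, scales=mcfg.scales,
                         target_labelmap=target_labelmap,
                         feature_caches=caches)
    model = DenseGCN(bundle.node_table.features.shape[1], mcfg,
                     seed=tcfg.seed)
    stats = _feature_stats(bundle.node_table)
    history = _train_model(model, bundle, tcfg, tcfg.max_epochs,
                           early_stop=True, rng=rng, stats=stats)
    labeled = _label_target_roots(model, bundle, stats)
    images = [lib.target] + [v for v, _ in lib.atlases]
    return Stage1Result(model, model.get_state(), candidates, order,
                         labeled, history, images, stats)


def train_stage2(stage1: Stage1Result, lib: AtlasLibrary, mcfg: ModelConfig,
                 tcfg: TrainConfig, caches=None) -> LabeledNodes:
    """Label the out-of-sample candidate batches with refreshing learning.

    Each batch's model starts bit-exactly from the stage-1 weights W0 and is
    fine-tuned for ``refresh_epochs`` epochs (0 = pure inference).
    """
    rng = np.random.default_rng(tcfg.seed + 1)
    if caches is None:
        caches = _library_caches(lib)
    model = stage1.model
    all_parts = [stage1.labeled]
    order = stage1.batch_order
    n0 = len(stage1.labeled.coords)
    for start in range(n0, len(order), tcfg.batch_size):
        batch = stage1.candidates[order[start:start + tcfg.batch_size]]
        bundle = build_graph(batch, lib, scales=mcfg.scales,
                             feature_caches=caches)
        model.set_state(stage1.initial_state)
        if tcfg.refresh_epochs > 0:
            _train_model(model, bundle, tcfg, tcfg.refresh_epochs,
                         early_stop=False, rng=rng, stage="stage2",
                         stats=stage1.feature_stats)
        all_parts.append(_label_target_roots(model, bundle,
                                             stage1.feature_stats))
    return LabeledNodes(
        np.concatenate([p.coords for p in all_parts]),
        np.concatenate([p.features for p in all_parts]),
        np.concatenate([p.labels for p in all_parts]))


def label_remaining_voxels(labeled: LabeledNodes, target: Volume,
                           roi: ROIMask,
                           cfg: VotingConfig | None = None,
                           cache: HogVolumeCache | None = None) -> LabelMap:
    """Stage 3: vote every remaining ROI voxel from nearby labeled nodes.

    Candidates are labeled nodes within the Chebyshev ``search_radius``
    (expanded as needed); each contributes the product of its normalized
    spectral (1/(1+l2 feature distance)) and spatial (1/(1+l1 coordinate
    distance)) weights to its class. Voxels outside the ROI are background.
    """
    cfg = cfg or VotingConfig()
    if len(labeled.coords) == 0:
        raise ValueError("no labeled nodes to vote from")
    out = np.zeros(target.shape, dtype=np.uint8)
    roi_coords = np.argwhere(roi.data)
    lab_set = {tuple(c): l for c, l in zip(labeled.coords, labeled.labels)}
    todo = np.array([i for i, c in enumerate(roi_coords)
                     if tuple(c) not in lab_set], dtype=int)
    for c, l in lab_set.items():
        out[c] = l
    if len(todo) == 0:
        return LabelMap(out)
    feats = (cache.descriptors(roi_coords[todo]) if cache is not None
             else hog_volume_descriptors(target.data, roi_coords[todo]))
    tree = cKDTree(labeled.coords)
    n_classes = 5
    groups = tree.query_ball_point(roi_coords[todo], r=cfg.search_radius,
                                   p=np.inf)
    for i, cand in zip(range(len(todo)), groups):
        voxel = roi_coords[todo[i]]
        r = cfg.search_radius
        while len(cand) == 0:  # auto-expand until a labeled node is found
            r *= 2
            cand = tree.query_ball_point(voxel, r=r, p=np.inf)
        cand = np.asarray(cand, dtype=int)
        spec = 1.0 / (1.0 + np.linalg.norm(
            labeled.features[cand] - feats[i], axis=1))
        spat = 1.0 / (1.0 + np.abs(
            labeled.coords[cand] - voxel).sum(axis=1))
        w = (spec / spec.sum()) * (spat / spat.sum())
        w /= w.sum()
        scores = np.bincount(labeled.labels[cand], weights=w,
                             minlength=n_classes)
        out[tuple(voxel)] = int(np.argmax(scores))
    return LabelMap(out)


def segment_transductive(lib: AtlasLibrary, mcfg: ModelConfig,
                         tcfg: TrainConfig,
                         vcfg: VotingConfig | None = None
                         ) -> SegmentationResult:
    """Stages 1-3 on one target; full-batch skips stage 2 entirely."""
    caches = _library_caches(lib)
    stage1 = train_stage1(lib, mcfg, tcfg, caches=caches)
    if tcfg.batch == "full":
        labeled, stage2_invoked = stage1.labeled, False
    else:
        labeled = train_stage2(stage1, lib, mcfg, tcfg, caches=caches)
        stage2_invoked = len(labeled.coords) > len(stage1.labeled.coords)
    label_map = fuse_remaining_voxels(labeled, lib, caches, vcfg)
    return SegmentationResult(label_map, labeled, stage2_invoked, stage1,
                              stage1.training_images)


def train_fullbatch(lib: AtlasLibrary, mcfg: ModelConfig, tcfg: TrainConfig,
                    vcfg: VotingConfig | None = None) -> SegmentationResult:
    """Full-batch special case: all candidates in stage 1, no stage 2."""
    cfg = TrainConfig(**{**vars(tcfg), "batch": "full"})
    return segment_transductive(lib, mcfg, cfg, vcfg)


def train_inductive(target: Volume, atlas_pool, mcfg: ModelConfig,
                    tcfg: TrainConfig, vcfg: VotingConfig | None = None,
                    n_atlases: int = 10, dilation_radius: int = 2
                    ) -> SegmentationResult:
    """Supervised variant: train on the pool image nearest to the target.

    The nearest neighbor T-hat (least ROI MSD) and its own library are used
    for a fully labeled stage-1 run; the target is then labeled by pure
    inference with the trained model, followed by stage-3 voting. Target
    data never enter a gradient step.
    """
    if len(atlas_pool) < 2:
        raise ValueError("atlas pool must contain at least 2 images")
    roi_t = build_roi([cartilage_mask(l) for _, l in atlas_pool],
                      dilation_radius=dilation_radius)
    target_lib = select_atlases(target, atlas_pool, roi_t,
                                n_atlases=min(n_atlases, len(atlas_pool)))
    nn_vol, nn_lab = target_lib.atlases[0]  # least MSD to the target

    rest = [(v, l) for v, l in atlas_pool if v is not nn_vol]
    roi_nn = build_roi([cartilage_mask(l) for _, l in rest],
                       dilation_radius=dilation_radius)
    nn_lib = select_atlases(nn_vol, rest, roi_nn,
                            n_atlases=min(n_atlases, len(rest)))
    stage1 = train_stage1(nn_lib, mcfg, tcfg, target_labelmap=nn_lab)

    # pure inference over the target's candidate roots, in batches
    rng = np.random.default_rng(tcfg.seed)
    n_cand = min(tcfg.n_candidates, target_lib.roi.voxel_count)
    candidates = sample_root_nodes(target, target_lib.roi, n_cand,
                                   seed=tcfg.seed)
    order = rng.permutation(len(candidates))
    caches = _library_caches(target_lib)
    parts = []
    for start in range(0, len(order), tcfg.batch_size):
        batch = candidates[order[start:start + tcfg.batch_size]]
        bundle = build_graph(batch, target_lib, scales=mcfg.scales,
                             feature_caches=caches)
        parts.append(_label_target_roots(stage1.model, bundle,
                                         stage1.feature_stats))
    labeled = LabeledNodes(np.concatenate([p.coords for p in parts]),
                           np.concatenate([p.features for p in parts]),
                           np.concatenate([p.labels for p in parts]))
    label_map = fuse_remaining_voxels(labeled, target_lib, caches, vcfg)
    return SegmentationResult(label_map, labeled, False, stage1,
                              stage1.training_images)
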