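"""Graph construction over aligned target/atlas node sequences.

Root nodes are sampled in the target ROI by spatial clustering and replicated
at the same voxel coordinate across the target and every atlas, forming
aligned sequences. Each sequence is expanded into multi-scale sequence
libraries: the cumulative neighborhoods R_s place 5x5x5 member patches on a
stride-2 center grid so that they exactly tile 9x9x9 (s=1) and 13x13x13
(s=2) volumes around the root. Local edges never cross sequences; the
global mask connects root nodes of *different* sequences only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import os

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .atlas import AtlasLibrary, ROIMask
from .features import hog_volume_descriptors
from .volume import Volume, LabelMap

UNLABELED = -1

# pool tags for local in-edges
POOL_SELF = 0    # from the destination's own (same-image) neighborhood
POOL_CROSS = 1   # from the other images' neighborhoods in the sequence library


@dataclass
class NodeTable:
    """Flat per-node records of the assembled graph."""

    features: np.ndarray        # (N, 20)
    coords: np.ndarray          # (N, 3) int
    image_id: np.ndarray        # (N,) 0 = target, 1..nA = atlas
    sequence_id: np.ndarray     # (N,)
    root_flag: np.ndarray       # (N,) bool
    scale_of_origin: np.ndarray  # (N,) int, 0 for roots
    label: np.ndarray           # (N,) int, UNLABELED for unlabeled

    @property
    def n_nodes(self) -> int:
        return len(self.features)

    @property
    def root_indices(self) -> np.ndarray:
        return np.flatnonzero(self.root_flag)


@dataclass
class Sequence:
    """One aligned root-node sequence: nA+1 nodes at one coordinate."""

    sequence_id: int
    member_node_ids: np.ndarray


@dataclass
class EdgeSet:
    """Directed in-edges (src -> dst) of one scale's subgraph."""

    src: np.ndarray
    dst: np.ndarray
    pool: np.ndarray  # POOL_SELF / POOL_CROSS per edge


@dataclass
class BlockStructure:
    """Dense view of one scale's local edges, for batched attention.

    Each (sequence, image) pair forms one block whose nodes all attend to
    each other (row 0 is the root); each block's root additionally attends
    to the other images' block members in the same sequence (``cross``).
    Nodes absent at this scale carry a plain self-loop.
    """

    ids: np.ndarray         # (G, amax) node ids, padded with 0
    mask: np.ndarray        # (G, amax) valid-entry mask
    cross_ids: np.ndarray   # (G, cmax) cross-image source ids, padded with 0
    cross_mask: np.ndarray  # (G, cmax)
    absent: np.ndarray      # node ids not present at this scale


@dataclass
class GraphBundle:
    """Node table plus per-scale local edge sets and count bookkeeping."""

    node_table: NodeTable
    local_edges: dict            # scale -> EdgeSet
    sequences: list              # of Sequence
    scales: int
    n_target_roots: int          # nT
    n_atlases: int               # nA
    nodes_at_scale: dict = field(default_factory=dict)  # scale -> |Xs|
    block_structure: dict = field(default_factory=dict)  # scale -> BlockStructure

    @property
    def n_roots(self) -> int:  # Nr = nT * (nA + 1)
        return self.n_target_roots * (self.n_atlases + 1)

    @property
    def n_nodes(self) -> int:
        return self.node_table.n_nodes


def sample_root_nodes(target: Volume, roi: ROIMask, n_clusters: int,
                      seed: int = 0) -> np.ndarray:
    """Spatially stratified root coordinates: k-means cluster centers of the
    ROI voxel coordinates, snapped to the nearest distinct in-ROI voxel."""
    coords = np.argwhere(roi.data)
    if n_clusters < 5:
        raise ValueError("n_clusters must be >= 5")
    if n_clusters > len(coords):
        raise ValueError(
            f"n_clusters ({n_clusters}) exceeds ROI size ({len(coords)})")
    if n_clusters == len(coords):
        return coords.copy()
    km = KMeans(n_clusters=n_clusters, n_init=1, max_iter=30,
                random_state=seed)
    km.fit(coords.astype(np.float64))
    tree = cKDTree(coords)
    used = set()
    out = np.empty((n_clusters, 3), dtype=int)
    for i, c in enumerate(km.cluster_centers_):
        k = 1
        while True:
            _, idx = tree.query(c, k=min(k + 3, len(coords)))
            idx = np.atleast_1d(idx)
            pick = next((j for j in idx if j not in used), None)
            if pick is not None:
                break
            k += 4
        used.add(pick)
        out[i] = coords[pick]
    return out


def neighborhood_offsets(scale: int):
    """Stride-2 member-patch offsets of the cumulative neighborhood R_s.

    Returns ``(offsets, origin)`` where ``origin[i]`` is the smallest scale
    whose neighborhood contains ``offsets[i]`` (0 for the root itself).
    5x5x5 patches at these centers exactly tile the 9^3 (s=1) and 13^3
    (s=2) volumes.
    """
    if scale < 0:
        raise ValueError("invalid scale")
    ax = np.arange(-2 * scale, 2 * scale + 1, 2)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    origin = np.max(np.abs(offsets), axis=1) // 2
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0], origin))
    return offsets[order], origin[order]


def build_neighborhood(center, scale: int, shape=None) -> np.ndarray:
    """Coordinates of R_s around ``center``; out-of-grid centers dropped."""
    offsets, _ = neighborhood_offsets(scale)
    coords = np.asarray(center, dtype=int)[None, :] + offsets
    if shape is not None:
        ok = np.all((coords >= 0) & (coords < np.asarray(shape)), axis=1)
        coords = coords[ok]
    return coords


def build_graph(roots: np.ndarray, lib: AtlasLibrary, scales: int = 2,
                target_labelmap: LabelMap | None = None,
                normalize_features: bool = False,
                feature_caches=None) -> GraphBundle:
    """Assemble the full multi-scale graph bundle for the given roots.

    Atlas nodes carry labels looked up in their label maps; target nodes are
    unlabeled unless ``target_labelmap`` is given (inductive training).
    """
    roots = np.atleast_2d(np.asarray(roots, dtype=int))
    shape = np.asarray(lib.target.shape)
    if np.any(roots < 0) or np.any(roots >= shape[None, :]):
        raise ValueError("root coordinate outside the image grid")
    nT, nA = len(roots), lib.n_atlases
    images = [lib.target] + [v for v, _ in lib.atlases]
    labelmaps = [target_labelmap] + [l for _, l in lib.atlases]
    offsets, origin = neighborhood_offsets(scales)

    coords_l, image_l, seq_l, rootf_l, orig_l = [], [], [], [], []
    # node ids grouped by (sequence, image), ordered by origin scale
    group_ids = [[None] * (nA + 1) for _ in range(nT)]
    n = 0
    for q in range(nT):
        base = roots[q]
        cand = base[None, :] + offsets
        ok = np.all((cand >= 0) & (cand < shape[None, :]), axis=1)
        cand, corig = cand[ok], origin[ok]
        k = len(cand)
        for m in range(nA + 1):
            coords_l.append(cand)
            image_l.append(np.full(k, m))
            seq_l.append(np.full(k, q))
            rootf_l.append(corig == 0)
            orig_l.append(corig)
            group_ids[q][m] = np.arange(n, n + k)
            n += k
    coords = np.concatenate(coords_l)
    image_id = np.concatenate(image_l)
    sequence_id = np.concatenate(seq_l)
    root_flag = np.concatenate(rootf_l)
    scale_of_origin = np.concatenate(orig_l)

    features = np.empty((n, 20))
    label = np.full(n, UNLABELED, dtype=int)
    for m in range(nA + 1):
        sel = image_id == m
        if feature_caches is not None:
            features[sel] = feature_caches[m].descriptors(
                coords[sel], normalize=normalize_features)
        else:
            features[sel] = hog_volume_descriptors(
                images[m].data, coords[sel], normalize=normalize_features)
        if labelmaps[m] is not None:
            cc = coords[sel]
            label[sel] = labelmaps[m].data[cc[:, 0], cc[:, 1], cc[:, 2]]

    table = NodeTable(features, coords, image_id, sequence_id, root_flag,
                      scale_of_origin, label)
    sequences = [Sequence(q, np.array([group_ids[q][m][0]
                                       for m in range(nA + 1)]))
                 for q in range(nT)]

    per_origin = scale_of_origin  # alias
    local_edges = {}
    nodes_at_scale = {}
    block_structure = {}
    for s in range(scales + 1):
        src_l, dst_l, pool_l = [], [], []
        blocks, crosses, absents = [], [], []
        for q in range(nT):
            members = [g[per_origin[g] <= s] for g in group_ids[q]]
            for m in range(nA + 1):
                own = members[m]
                blocks.append(own)
                crosses.append(np.concatenate(
                    [members[mm] for mm in range(nA + 1) if mm != m])
                    if nA else np.empty(0, dtype=int))
                a = len(own)
                # complete within-image neighborhood: every node (root and
                # non-root) attends to its own root's R_s
                src_l.append(np.tile(own, a))
                dst_l.append(np.repeat(own, a))
                pool_l.append(np.zeros(a * a, dtype=np.int8))
                # the root additionally attends to the other images' nodes
                root_id = own[0]
                others = np.concatenate(
                    [members[mm] for mm in range(nA + 1) if mm != m]) \
                    if nA + 1 > 1 else np.empty(0, dtype=int)
                if len(others):
                    src_l.append(others)
                    dst_l.append(np.full(len(others), root_id))
                    pool_l.append(np.ones(len(others), dtype=np.int8))
            # nodes absent at this scale keep a self-loop so every node has
            # a defined update at every scale
            absent = np.concatenate(
                [g[per_origin[g] > s] for g in group_ids[q]])
            absents.append(absent)
            if len(absent):
                src_l.append(absent)
                dst_l.append(absent)
                pool_l.append(np.zeros(len(absent), dtype=np.int8))
        src_s = np.concatenate(src_l)
        dst_s = np.concatenate(dst_l)
        pool_s = np.concatenate(pool_l)
        order = np.argsort(dst_s, kind="stable")  # sorted dst: fast segments
        local_edges[s] = EdgeSet(src_s[order], dst_s[order], pool_s[order])
        nodes_at_scale[s] = int(np.sum(per_origin <= s))
        block_structure[s] = _pad_blocks(blocks, crosses, absents)

    return GraphBundle(table, local_edges, sequences, scales, nT, nA,
                       nodes_at_scale, block_structure)


def _pad_blocks(blocks, crosses, absents) -> BlockStructure:
    amax = max(len(b) for b in blocks)
    cmax = max((len(c) for c in crosses), default=0)
    G = len(blocks)
    ids = np.zeros((G, amax), dtype=int)
    mask = np.zeros((G, amax), dtype=bool)
    cross_ids = np.zeros((G, max(cmax, 1)), dtype=int)
    cross_mask = np.zeros((G, max(cmax, 1)), dtype=bool)
    for g, (b, c) in enumerate(zip(blocks, crosses)):
        ids[g, :len(b)] = b
        mask[g, :len(b)] = True
        cross_ids[g, :len(c)] = c
        cross_mask[g, :len(c)] = True
    absent = (np.concatenate(absents) if absents
              else np.empty(0, dtype=int))
    return BlockStructure(ids, mask, cross_ids, cross_mask, absent)


def build_aligned_sequences(roots: np.ndarray, lib: AtlasLibrary,
                            target_labelmap: LabelMap | None = None):
    """Root-only construction (scale 0): nodes and sequences, no neighbors."""
    bundle = build_graph(roots, lib, scales=0, target_labelmap=target_labelmap)
    return bundle.node_table, bundle.sequences


def sequence_library(bundle: GraphBundle, sequence_id: int,
                     scale: int) -> np.ndarray:
    """Node ids of the sequence library SL_s of one sequence."""
    if scale < 0 or scale > bundle.scales:
        raise ValueError("invalid scale")
    t = bundle.node_table
    return np.flatnonzero((t.sequence_id == sequence_id)
                          & (t.scale_of_origin <= scale))


def global_edge_mask(table: NodeTable) -> np.ndarray:
    """(Nr, Nr) mask over root nodes: True iff sequences differ.

    Same-sequence pairs are handled by the local units and excluded here;
    the diagonal is False (self-loops re-enter via the identity term of the
    learned adjacency).
    """
    seq = table.sequence_id[table.root_indices]
    mask = seq[:, None] != seq[None, :]
    np.fill_diagonal(mask, False)
    return mask


def sparsify_adjacency(A: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out off-diagonal entries below ``threshold``; keep the diagonal."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    A = np.asarray(A, dtype=np.float64)
    out = A.copy()
    off = ~np.eye(len(A), dtype=bool)
    out[off & (A < threshold)] = 0.0
    return out


def save_bundle(bundle: GraphBundle, directory: str) -> None:
    """Serialize to a directory of flat arrays plus a JSON manifest."""
    os.makedirs(directory, exist_ok=True)
    t = bundle.node_table
    arrays = dict(features=t.features, coords=t.coords, image_id=t.image_id,
                  sequence_id=t.sequence_id, root_flag=t.root_flag,
                  scale_of_origin=t.scale_of_origin, label=t.label)
    for s, e in bundle.local_edges.items():
        arrays[f"edges{s}_src"] = e.src
        arrays[f"edges{s}_dst"] = e.dst
        arrays[f"edges{s}_pool"] = e.pool
    for name, arr in arrays.items():
        np.save(os.path.join(directory, name + ".npy"), arr)
    manifest = dict(scales=bundle.scales, n_target_roots=bundle.n_target_roots,
                    n_atlases=bundle.n_atlases,
                    nodes_at_scale={str(k): v
                                    for k, v in bundle.nodes_at_scale.items()},
                    n_nodes=bundle.n_nodes)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_bundle(directory: str) -> GraphBundle:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)

    def arr(name):
        return np.load(os.path.join(directory, name + ".npy"))

    table = NodeTable(arr("features"), arr("coords"), arr("image_id"),
                      arr("sequence_id"), arr("root_flag"),
                      arr("scale_of_origin"), arr("label"))
    edges = {s: EdgeSet(arr(f"edges{s}_src"), arr(f"edges{s}_dst"),
                        arr(f"edges{s}_pool"))
             for s in range(manifest["scales"] + 1)}
    sequences = []
    for q in range(manifest["n_target_roots"]):
        ids = np.flatnonzero((table.sequence_id == q) & table.root_flag)
        sequences.append(Sequence(q, ids))
    return GraphBundle(table, edges, sequences, manifest["scales"],
                       manifest["n_target_roots"], manifest["n_atlases"],
                       {int(k): v
                        for k, v in manifest["nodes_at_scale"].items()})
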