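"""Local attention and global convolution units vs scalar-loop oracles."""

import numpy as np
import pytest

from magseg.autodiff import Parameter, Tensor
from magseg.conv_units import (GconvUnit, LconvUnit, SageMaxPoolUnit,
                               agl_adjacency, attention_coefficients,
                               batch_norm, gconv_forward, make_global_unit,
                               sage_maxpool_forward)
from magseg.graphs import EdgeSet, GraphBundle, NodeTable


def leaky(x, s=0.2):
    return np.where(x > 0, x, s * x)


def toy_bundle(features, src, dst, n_roots=None, sequence_id=None):
    """Minimal single-scale bundle over explicit edges (edge-list path)."""
    n = len(features)
    root_flag = np.ones(n, dtype=bool)
    table = NodeTable(
        features=np.asarray(features, dtype=float),
        coords=np.zeros((n, 3), dtype=int),
        image_id=np.zeros(n, dtype=int),
        sequence_id=(np.arange(n) if sequence_id is None
                     else np.asarray(sequence_id)),
        root_flag=root_flag,
        scale_of_origin=np.zeros(n, dtype=int),
        label=np.zeros(n, dtype=int),
    )
    edges = {0: EdgeSet(np.asarray(src), np.asarray(dst),
                        np.zeros(len(src), dtype=np.int8))}
    return GraphBundle(table, edges, [], 0, n, 0, {0: n})


class TestAttentionCoefficients:
    def test_single_in_edge_gives_one(self, rng):
        f = Tensor(rng.normal(size=(2, 3)))
        alpha = attention_coefficients(f, [1], [0], rng.normal(size=(3, 2)),
                                       rng.normal(size=4), 2)
        assert alpha.data[0, 0] == pytest.approx(1.0)

    def test_identical_sources_split_evenly(self, rng):
        feats = np.array([[1.0, 2.0], [0.5, -1.0], [0.5, -1.0]])
        alpha = attention_coefficients(Tensor(feats), [1, 2], [0, 0],
                                       rng.normal(size=(2, 2)),
                                       rng.normal(size=4), 3)
        np.testing.assert_allclose(alpha.data.ravel(), [0.5, 0.5],
                                   atol=1e-12)

    def test_matches_scalar_softmax_oracle(self, rng):
        n, eo = 4, 3
        feats = rng.normal(size=(n, 5))
        W = rng.normal(size=(5, eo))
        a = rng.normal(size=2 * eo)
        src = np.array([0, 1, 2, 3, 1, 2])
        dst = np.array([0, 0, 0, 1, 1, 2])
        alpha = attention_coefficients(Tensor(feats), src, dst, W, a, n)
        # brute force per destination
        wh = feats @ W
        scores = np.array([
            leaky(a[:eo] @ wh[d] + a[eo:] @ wh[s])
            for s, d in zip(src, dst)])
        expected = np.zeros(len(src))
        for d in np.unique(dst):
            sel = dst == d
            e = np.exp(scores[sel])
            expected[sel] = e / e.sum()
        np.testing.assert_allclose(alpha.data.ravel(), expected, atol=1e-10)

    def test_normalization_sums_to_one(self, rng):
        n = 6
        feats = rng.normal(size=(n, 4))
        src = rng.integers(0, n, size=20)
        dst = np.repeat(np.arange(n), [4, 3, 5, 2, 5, 1])
        alpha = attention_coefficients(Tensor(feats), src[:20], dst,
                                       rng.normal(size=(4, 3)),
                                       rng.normal(size=6), n)
        sums = np.zeros(n)
        np.add.at(sums, dst, alpha.data.ravel())
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)


class TestLconv:
    def test_output_width(self, rng):
        feats = rng.normal(size=(4, 6))
        bundle = toy_bundle(feats, [0, 1, 2, 3], [0, 1, 2, 3])
        unit = LconvUnit(6, 12, n_heads=2, scales=0, rng=1)
        out = unit(Tensor(feats), bundle)
        assert out.shape == (4, 12)  # scales_used * K * Eo = 1*2*6

    def test_single_self_loop_single_head_reduces_to_sigma_wv(self, rng):
        feats = rng.normal(size=(3, 4))
        bundle = toy_bundle(feats, [0, 1, 2], [0, 1, 2])
        unit = LconvUnit(4, 5, n_heads=1, scales=0, rng=0)
        out = unit(Tensor(feats), bundle)
        W = unit.W[0][0].data
        np.testing.assert_allclose(out.data, leaky(feats @ W), atol=1e-10)

    def test_matches_per_head_oracle(self, rng):
        """Batched multi-head forward equals head-by-head brute force."""
        n = 5
        feats = rng.normal(size=(n, 4))
        src = np.array([0, 1, 2, 1, 3, 4, 2, 0])
        dst = np.array([0, 0, 1, 1, 2, 2, 3, 4])
        order = np.argsort(dst)
        bundle = toy_bundle(feats, src[order], dst[order])
        unit = LconvUnit(4, 6, n_heads=2, scales=0, rng=3)
        out = unit(Tensor(feats), bundle)
        pieces = []
        for k in range(2):
            W, a = unit.W[0][k].data, unit.a[0][k].data
            alpha = attention_coefficients(Tensor(feats), src, dst, W, a,
                                           n).data.ravel()
            wh = feats @ W
            agg = np.zeros((n, 3))
            for s, d, al in zip(src, dst, alpha):
                agg[d] += al * wh[s]
            pieces.append(leaky(agg))
        np.testing.assert_allclose(out.data, np.hstack(pieces), atol=1e-10)

    def test_zero_heads_is_plain_embedding(self, rng):
        feats = rng.normal(size=(4, 6))
        bundle = toy_bundle(feats, [0, 1, 2, 3], [0, 1, 2, 3])
        unit = LconvUnit(6, 12, n_heads=0, scales=0, rng=1)
        out = unit(Tensor(feats), bundle)
        np.testing.assert_allclose(out.data, leaky(feats @ unit.W_plain.data),
                                   atol=1e-12)

    def test_width_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            LconvUnit(6, 10, n_heads=3, scales=0, rng=0)


class TestAglAdjacency:
    def _params(self, rng, fin, fg):
        return (Tensor(rng.normal(size=(fin, fg))),
                Tensor(np.ones(fin)), Tensor(np.zeros(fin)))

    def test_symmetric_diag_geq_one_range(self, rng):
        S = Tensor(rng.normal(size=(6, 4)))
        Wphi, gamma, beta = self._params(rng, 4, 3)
        A = agl_adjacency(S, Wphi, gamma, beta, threshold=0.0)
        np.testing.assert_allclose(A.data, A.data.T, atol=1e-12)
        assert np.all(np.diag(A.data) >= 1.0)
        off = A.data[~np.eye(6, dtype=bool)]
        assert np.all((off >= 0) & (off < 1))

    def test_matches_direct_matrix_oracle(self, rng):
        S0 = rng.normal(size=(5, 3))
        Wphi, gamma, beta = self._params(rng, 3, 2)
        tau = 0.4
        A = agl_adjacency(Tensor(S0), Wphi, gamma, beta, threshold=tau)
        # oracle: batch-norm, embed, sigmoid Gram, sparsify, add identity
        mu, var = S0.mean(0), S0.var(0)
        E = ((S0 - mu) / np.sqrt(var + 1e-5)) @ Wphi.data
        G = 1.0 / (1.0 + np.exp(-(E @ E.T)))
        expected = np.where(G >= tau, G, 0.0)
        np.fill_diagonal(expected, 0.0)
        expected += np.eye(5)
        np.testing.assert_allclose(A.data, expected, atol=1e-10)

    def test_identical_rows_equal_entries(self, rng):
        S0 = rng.normal(size=(4, 3))
        S0[2] = S0[1]
        Wphi, gamma, beta = self._params(rng, 3, 2)
        A = agl_adjacency(Tensor(S0), Wphi, gamma, beta, threshold=0.0)
        np.testing.assert_allclose(A.data[1, [0, 3]], A.data[2, [0, 3]],
                                   atol=1e-10)

    def test_mask_zeroes_same_sequence_pairs(self, rng):
        S = Tensor(rng.normal(size=(4, 3)))
        Wphi, gamma, beta = self._params(rng, 3, 2)
        mask = np.ones((4, 4), dtype=bool)
        mask[0, 1] = mask[1, 0] = False
        A = agl_adjacency(S, Wphi, gamma, beta, mask=mask, threshold=0.0)
        assert A.data[0, 1] == 0.0 and A.data[1, 0] == 0.0

    def test_needs_two_nodes(self, rng):
        S = Tensor(rng.normal(size=(1, 3)))
        Wphi, gamma, beta = self._params(rng, 3, 2)
        with pytest.raises(ValueError):
            agl_adjacency(S, Wphi, gamma, beta)


class TestGconv:
    def test_identity_adjacency_reduces_to_embedding(self, rng):
        S0 = rng.normal(size=(4, 3))
        Wg = rng.normal(size=(3, 5))
        out = gconv_forward(Tensor(S0), Wg, Tensor(np.eye(4)))
        np.testing.assert_allclose(out.data, leaky(S0 @ Wg), atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        S0 = rng.normal(size=(3, 4))
        Wg = rng.normal(size=(4, 2))
        A = rng.random((3, 3)) + np.eye(3)
        A = (A + A.T) / 2
        out = gconv_forward(Tensor(S0), Wg, Tensor(A))
        D = np.diag(1.0 / np.sqrt(A.sum(axis=1)))
        np.testing.assert_allclose(out.data, leaky(D @ A @ D @ S0 @ Wg),
                                   atol=1e-10)

    def test_root_only_convolution_shape_and_passthrough(self, rng):
        S0 = rng.normal(size=(6, 4))
        Wg = rng.normal(size=(4, 3))
        root_idx = np.array([0, 2, 4])
        out = gconv_forward(Tensor(S0), Wg, Tensor(np.eye(3)),
                            root_idx=root_idx)
        assert out.shape == (6, 3)
        # non-root rows: plain embedding
        np.testing.assert_allclose(out.data[[1, 3, 5]],
                                   leaky(S0[[1, 3, 5]] @ Wg), atol=1e-10)

    def test_permutation_equivariance_with_symmetric_adjacency(self, rng):
        S0 = rng.normal(size=(5, 3))
        Wg = rng.normal(size=(3, 3))
        A = rng.random((5, 5))
        A = (A + A.T) / 2 + np.eye(5)
        out = gconv_forward(Tensor(S0), Wg, Tensor(A)).data
        p = np.array([3, 1, 4, 0, 2])
        out_p = gconv_forward(Tensor(S0[p]), Wg,
                              Tensor(A[np.ix_(p, p)])).data
        np.testing.assert_allclose(out_p, out[p], atol=1e-10)


class TestSageMaxPool:
    def test_matches_scalar_oracle(self, rng):
        n, fin, fo = 4, 3, 2
        H0 = rng.normal(size=(n, fin))
        Wpool = rng.normal(size=(fin, fin))
        b = rng.normal(size=fin)
        Wk = rng.normal(size=(2 * fin, fo))
        nbrs = {0: [0, 1], 1: [0, 1, 2], 2: [3, 2], 3: [3]}
        src = [s for d in range(n) for s in nbrs[d]]
        dst = [d for d in range(n) for _ in nbrs[d]]
        out = sage_maxpool_forward(Tensor(H0), src, dst, Tensor(Wpool),
                                   Tensor(b), Tensor(Wk))
        for v in range(n):
            pooled = np.max([leaky(Wpool.T @ H0[u] + b) for u in nbrs[v]],
                            axis=0)
            expected = leaky(np.concatenate([H0[v], pooled]) @ Wk)
            np.testing.assert_allclose(out.data[v], expected, atol=1e-10)

    def test_permutation_invariant_in_neighbor_order(self, rng):
        H0 = rng.normal(size=(3, 3))
        args = (Tensor(rng.normal(size=(3, 3))), Tensor(rng.normal(size=3)),
                Tensor(rng.normal(size=(6, 2))))
        out1 = sage_maxpool_forward(Tensor(H0), [0, 1, 2, 1, 2, 0],
                                    [0, 0, 0, 1, 2, 2], *args)
        out2 = sage_maxpool_forward(Tensor(H0), [2, 0, 1, 1, 0, 2],
                                    [0, 0, 0, 1, 2, 2], *args)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)

    def test_isolated_node_rejected(self, rng):
        H0 = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="neighbor"):
            sage_maxpool_forward(Tensor(H0), [0], [0],
                                 Tensor(np.eye(2)), Tensor(np.zeros(2)),
                                 Tensor(np.ones((4, 1))))


class TestBackendSelection:
    def test_known_backends(self):
        assert isinstance(make_global_unit("gcn", 4, 4, rng=0), GconvUnit)
        assert isinstance(make_global_unit("sage_maxpool", 4, 4, rng=0),
                          SageMaxPoolUnit)

    def test_unknown_backend_rejected(self):
        with pytest.raises(NotImplementedError, match="not implemented"):
            make_global_unit("cluster_gcn", 4, 4)


def test_batch_norm_standardizes(rng):
    X = rng.normal(3.0, 2.0, size=(50, 4))
    out = batch_norm(Tensor(X), Tensor(np.ones(4)), Tensor(np.zeros(4)))
    np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-3)


def test_dense_block_path_equals_edge_list_path(library):
    """The batched per-sequence attention path and the flat edge-list path
    compute identical Lconv outputs on a real graph."""
    from magseg.graphs import build_graph, sample_root_nodes

    roots = sample_root_nodes(library.target, library.roi, 5, seed=8)
    bundle = build_graph(roots, library, scales=1)
    feats = bundle.node_table.features
    feats = feats / (1.0 + np.abs(feats).max())
    unit = LconvUnit(20, 16, n_heads=2, scales=1, rng=5)
    dense = unit(Tensor(feats), bundle).data
    saved = bundle.block_structure
    bundle.block_structure = {}
    try:
        edges = unit(Tensor(feats), bundle).data
    finally:
        bundle.block_structure = saved
    np.testing.assert_allclose(dense, edges, atol=1e-12)


def test_running_norm_freezes_at_inference(rng):
    """Evaluation-mode Gconv output is independent of unrelated rows'
    statistics once the running stats are frozen."""
    unit = GconvUnit(4, 3, agl_dim=2, rng=0)
    S = rng.normal(size=(8, 4))
    root_idx = np.arange(8)
    mask = ~np.eye(8, dtype=bool)
    unit(Tensor(S), root_idx, mask, training=True)
    frozen_mean = unit.bn.mean.copy()
    out1 = unit(Tensor(S), root_idx, mask, training=False).data
    out2 = unit(Tensor(S * 1.0), root_idx, mask, training=False).data
    np.testing.assert_array_equal(unit.bn.mean, frozen_mean)
    np.testing.assert_array_equal(out1, out2)
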