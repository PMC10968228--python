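"""Three-stage procedure: contracts, determinism, voting, variants."""

import numpy as np
import pytest

from magseg.atlas import ROIMask, build_library
from magseg.graphs import build_graph
from magseg.models import ModelConfig
from magseg.phantom import PhantomSpec, generate_atlas_set, generate_phantom
from magseg.training import (LabeledNodes, TrainConfig, VotingConfig,
                             _label_target_roots, label_remaining_voxels,
                             segment_transductive, train_fullbatch,
                             train_inductive, train_stage1, train_stage2)
from magseg.volume import Volume


def tiny_mcfg(**kw):
    base = dict(n_blocks=1, d=8, n_heads=1, scales=1, agl_dim=4)
    base.update(kw)
    return ModelConfig(**base)


def tiny_tcfg(**kw):
    base = dict(batch_size=16, n_candidates=48, max_epochs=3,
                refresh_epochs=1, patience_no_improve=10, seed=0)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def stage1(library):
    return train_stage1(library, tiny_mcfg(), tiny_tcfg())


class TestStage1:
    def test_labels_initial_batch_of_target_roots(self, stage1, library):
        assert len(stage1.labeled.coords) == 16
        assert np.all(stage1.labeled.labels >= 0)
        assert np.all(stage1.labeled.labels <= 4)
        assert np.all(library.roi.data[tuple(stage1.labeled.coords.T)])

    def test_deterministic_given_seed(self, library, stage1):
        again = train_stage1(library, tiny_mcfg(), tiny_tcfg())
        np.testing.assert_array_equal(again.labeled.labels,
                                      stage1.labeled.labels)
        np.testing.assert_array_equal(again.labeled.coords,
                                      stage1.labeled.coords)

    def test_duplicate_library_matches_nearest_lookup(self, phantom_pair):
        """With atlases identical to the target, every target root has
        feature-identical labeled twins; accuracy must match duplicate
        lookup (the atlas label at the same coordinate)."""
        spec = PhantomSpec(shape=(48, 48, 48), noise_sd=0.0,
                           misalignment_sd=0.0, seed=7)
        tgt = generate_phantom(spec)
        atlases = generate_atlas_set(tgt, 3, spec)
        lib = build_library(tgt[0], atlases, n_atlases=3, dilation_radius=1)
        s1 = train_stage1(lib, tiny_mcfg(d=16, n_heads=2), tiny_tcfg(max_epochs=80, lr=1e-2, patience_no_improve=30))
        lookup = tgt[1].data[tuple(s1.labeled.coords.T)]
        acc = np.mean(s1.labeled.labels == lookup)
        assert acc > 0.9  # nearest-duplicate lookup is exact here

    def test_history_records_losses(self, stage1):
        assert len(stage1.history) >= 1
        assert all("loss" in r for r in stage1.history)


class TestStage2:
    def test_batches_partition_candidates(self, stage1, library):
        labeled = train_stage2(stage1, library, tiny_mcfg(), tiny_tcfg())
        assert len(labeled.coords) == len(stage1.candidates)
        got = set(map(tuple, labeled.coords))
        expected = set(map(tuple, stage1.candidates))
        assert got == expected  # every candidate labeled exactly once

    def test_warm_start_bit_exact_and_pure_inference(self, stage1, library):
        """refresh_epochs=0: stage-2 is inference with the stage-1 weights,
        and the model ends bit-identical to W0."""
        cfg = tiny_tcfg(refresh_epochs=0)
        train_stage2(stage1, library, tiny_mcfg(), cfg)
        for p, w0 in zip(stage1.model.parameters(), stage1.initial_state):
            np.testing.assert_array_equal(p.data, w0)

    def test_refresh0_labels_equal_direct_inference(self, stage1, library):
        cfg = tiny_tcfg(refresh_epochs=0)
        labeled = train_stage2(stage1, library, tiny_mcfg(), cfg)
        # recompute one out-of-sample batch by direct forward
        n0 = len(stage1.labeled.coords)
        batch = stage1.candidates[stage1.batch_order[n0:n0 + 16]]
        stage1.model.set_state(stage1.initial_state)
        bundle = build_graph(batch, library, scales=1)
        direct = _label_target_roots(stage1.model, bundle,
                                     stage1.feature_stats)
        lut = {tuple(c): l for c, l in zip(labeled.coords, labeled.labels)}
        for c, l in zip(direct.coords, direct.labels):
            assert lut[tuple(c)] == l


class TestStage3Voting:
    def test_unanimous_candidates_win_regardless_of_weights(self):
        target = Volume(np.zeros((40, 40, 40)))
        roi = np.zeros((40, 40, 40), dtype=bool)
        roi[10:14, 10:14, 10:14] = True
        coords = np.array([[10, 10, 10], [13, 13, 13]])
        labeled = LabeledNodes(coords, np.random.rand(2, 20),
                               np.array([3, 3]))
        lm = label_remaining_voxels(labeled, target, ROIMask(roi))
        assert np.all(lm.data[roi] == 3)
        assert np.all(lm.data[~roi] == 0)

    def test_single_candidate_transfers_its_label(self):
        target = Volume(np.zeros((40, 40, 40)))
        roi = np.zeros((40, 40, 40), dtype=bool)
        roi[20, 20, 20:23] = True
        labeled = LabeledNodes(np.array([[20, 20, 20]]),
                               np.ones((1, 20)), np.array([2]))
        lm = label_remaining_voxels(labeled, target, ROIMask(roi))
        assert np.all(lm.data[20, 20, 20:23] == 2)

    def test_two_candidate_hand_computed_oracle(self):
        """Weights follow the product of normalized 1/(1+l2) spectral and
        1/(1+l1) spatial kernels; the voxel takes the larger product."""
        rng = np.random.default_rng(0)
        data = rng.normal(size=(40, 40, 40))
        target = Volume(data)
        roi = np.zeros((40, 40, 40), dtype=bool)
        voxel = (20, 20, 20)
        c1, c2 = (19, 20, 20), (22, 21, 20)
        roi[voxel] = roi[c1] = roi[c2] = True
        from magseg.features import hog_volume_descriptors
        fv, f1, f2 = hog_volume_descriptors(data,
                                            np.array([voxel, c1, c2]))
        labeled = LabeledNodes(np.array([c1, c2]), np.stack([f1, f2]),
                               np.array([1, 4]))
        lm = label_remaining_voxels(labeled, target, ROIMask(roi),
                                    VotingConfig(search_radius=2))
        spec_w = np.array([1 / (1 + np.linalg.norm(f1 - fv)),
                           1 / (1 + np.linalg.norm(f2 - fv))])
        spat_w = np.array([1 / (1 + 1), 1 / (1 + 3)])
        w = (spec_w / spec_w.sum()) * (spat_w / spat_w.sum())
        w /= w.sum()
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        expected = [1, 4][int(np.argmax(w))]
        assert lm.data[voxel] == expected

    def test_every_roi_voxel_labeled_outside_background(self, library):
        labeled = LabeledNodes(
            np.argwhere(library.roi.data)[::50],
            np.zeros((len(np.argwhere(library.roi.data)[::50]), 20)),
            np.ones(len(np.argwhere(library.roi.data)[::50]), dtype=int))
        lm = label_remaining_voxels(labeled, library.target, library.roi)
        assert np.all(lm.data[library.roi.data] >= 0)
        assert np.all(lm.data[~library.roi.data] == 0)

    def test_auto_expands_radius_for_distant_voxels(self):
        target = Volume(np.zeros((40, 40, 40)))
        roi = np.zeros((40, 40, 40), dtype=bool)
        roi[5, 5, 5] = roi[30, 30, 30] = True
        labeled = LabeledNodes(np.array([[5, 5, 5]]), np.ones((1, 20)),
                               np.array([4]))
        lm = label_remaining_voxels(labeled, target, ROIMask(roi),
                                    VotingConfig(search_radius=1))
        assert lm.data[30, 30, 30] == 4  # found after expansion

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            VotingConfig(search_radius=0)


class TestFullBatch:
    def test_skips_stage2_and_labels_all_candidates(self, library):
        res = train_fullbatch(library, tiny_mcfg(),
                              tiny_tcfg(n_candidates=24))
        assert res.stage2_invoked is False
        assert len(res.labeled_nodes.coords) == 24

    def test_equals_minibatch_with_full_size_batch(self, library):
        tc_full = tiny_tcfg(batch="full", n_candidates=24)
        tc_mini = tiny_tcfg(batch_size=24, n_candidates=24,
                            refresh_epochs=0)
        r_full = segment_transductive(library, tiny_mcfg(), tc_full)
        r_mini = segment_transductive(library, tiny_mcfg(), tc_mini)
        np.testing.assert_array_equal(r_full.label_map.data,
                                      r_mini.label_map.data)

    def test_node_budget_guard(self, library):
        cfg = tiny_tcfg(batch="full", n_candidates=48)
        cfg.max_nodes = 100
        with pytest.raises(ValueError, match="budget"):
            train_fullbatch(library, tiny_mcfg(), cfg)


class TestInductive:
    def test_nearest_neighbor_is_exact_copy(self, phantom_pair,
                                            atlas_pairs):
        # a pool that contains an exact copy of the target
        pool = atlas_pairs + [(phantom_pair[0], phantom_pair[1])]
        res = train_inductive(phantom_pair[0], pool, tiny_mcfg(),
                              tiny_tcfg(), n_atlases=3)
        nn_vol = res.training_images[0]
        np.testing.assert_array_equal(nn_vol.data, phantom_pair[0].data)

    def test_target_never_enters_training(self, phantom_pair, atlas_pairs):
        res = train_inductive(phantom_pair[0], atlas_pairs, tiny_mcfg(),
                              tiny_tcfg(), n_atlases=3)
        for img in res.training_images:
            assert img is not phantom_pair[0]
            assert not np.array_equal(img.data, phantom_pair[0].data)

    def test_pool_too_small_rejected(self, phantom_pair):
        with pytest.raises(ValueError, match="at least 2"):
            train_inductive(phantom_pair[0], [(phantom_pair[0],
                                               phantom_pair[1])],
                            tiny_mcfg(), tiny_tcfg())

    def test_full_roi_coverage(self, phantom_pair, atlas_pairs):
        res = train_inductive(phantom_pair[0], atlas_pairs, tiny_mcfg(),
                              tiny_tcfg(), n_atlases=3)
        assert set(np.unique(res.label_map.data)) <= {0, 1, 2, 3, 4}


class TestDenseFusion:
    """The vectorized stage-3 path equals a scalar brute-force vote."""

    def test_matches_bruteforce_oracle(self):
        from magseg.features import HogVolumeCache
        from magseg.training import fuse_remaining_voxels
        from magseg.atlas import AtlasLibrary
        from magseg.volume import LabelMap as LM

        rng = np.random.default_rng(3)
        shape = (34, 34, 34)
        target = Volume(rng.normal(50, 10, size=shape))
        atlases = []
        for _ in range(2):
            vol = Volume(rng.normal(50, 10, size=shape))
            lab = LM(rng.integers(0, 5, size=shape))
            atlases.append((vol, lab))
        roi = np.zeros(shape, dtype=bool)
        roi[15:18, 15:18, 15:19] = True
        lib = AtlasLibrary(target=target, atlases=atlases, roi=ROIMask(roi))
        caches = [HogVolumeCache(target.data)] + \
            [HogVolumeCache(v.data) for v, _ in atlases]
        roots = np.array([[16, 16, 16], [15, 17, 18]])
        labeled = LabeledNodes(roots, caches[0].descriptors(roots),
                               np.array([2, 4]))
        lm = fuse_remaining_voxels(labeled, lib, caches,
                                   VotingConfig(search_radius=2))
        # scalar oracle over every remaining ROI voxel
        r = 2
        root_set = {tuple(c): l for c, l in zip(roots, labeled.labels)}
        for voxel in np.argwhere(roi):
            key = tuple(voxel)
            if key in root_set:
                assert lm.data[key] == root_set[key]
                continue
            fv = caches[0].descriptors(voxel[None, :])[0]
            scores = np.zeros(5)
            for (_, labmap), cache in zip(atlases, caches[1:]):
                for dx in range(-r, r + 1):
                    for dy in range(-r, r + 1):
                        for dz in range(-r, r + 1):
                            c = voxel + (dx, dy, dz)
                            if np.any(c < 0) or np.any(c >= shape):
                                continue
                            f = cache.descriptors(c[None, :])[0]
                            spec = 1 / (1 + np.linalg.norm(f - fv))
                            spat = 1 / (1 + abs(dx) + abs(dy) + abs(dz))
                            scores[labmap.data[tuple(c)]] += spec * spat
            for c, l in zip(roots, labeled.labels):
                if np.max(np.abs(c - voxel)) <= r:
                    f = caches[0].descriptors(c[None, :])[0]
                    spec = 1 / (1 + np.linalg.norm(f - fv))
                    spat = 1 / (1 + np.abs(c - voxel).sum())
                    scores[l] += spec * spat
            assert lm.data[key] == np.argmax(scores)
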