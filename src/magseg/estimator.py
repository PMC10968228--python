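"""Scikit-learn style front end for the whole segmentation pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .atlas import build_library
from .metrics import evaluate_segmentation
from .models import ModelConfig
from .preprocess import preprocess_chain
from .training import (SegmentationResult, TrainConfig, VotingConfig,
                       segment_transductive, train_inductive)
from .volume import LabelMap, Volume


class MultiAtlasSegmenter(BaseEstimator):
    """Multi-atlas graph-convolutional segmenter.

    ``fit`` stores (and optionally preprocesses) the labeled atlas pool;
    ``predict`` builds the target-specific atlas library and runs the
    transductive three-stage procedure (or the inductive variant) to return
    a full label map. Because learning is target-specific, the network is
    trained inside ``predict``; fitted attributes of the last prediction are
    kept on the estimator (``result_``, ``library_``).

    Parameters mirror the method's hyperparameters: ``n_atlases`` selected
    per target, attention heads ``n_heads``, spatial ``scales``, dense
    blocks ``n_blocks`` of width ``d``, adjacency sparsity ``threshold``,
    and the training-schedule settings.
    """

    def __init__(self, n_atlases=10, roi_dilation=2, block="ct", n_blocks=3,
                 d=120, n_heads=8, scales=2, include_scale0=True,
                 backend="gcn", threshold=0.5, agl_dim=16,
                 mode="transductive", batch="mini", batch_size=128,
                 n_candidates=512, refresh_epochs=20, max_epochs=500,
                 patience_no_improve=50, patience_increase=10, lr=1e-2,
                 val_fraction=0.1, search_radius=2, preprocess=True,
                 seed=0):
        self.n_atlases = n_atlases
        self.roi_dilation = roi_dilation
        self.block = block
        self.n_blocks = n_blocks
        self.d = d
        self.n_heads = n_heads
        self.scales = scales
        self.include_scale0 = include_scale0
        self.backend = backend
        self.threshold = threshold
        self.agl_dim = agl_dim
        self.mode = mode
        self.batch = batch
        self.batch_size = batch_size
        self.n_candidates = n_candidates
        self.refresh_epochs = refresh_epochs
        self.max_epochs = max_epochs
        self.patience_no_improve = patience_no_improve
        self.patience_increase = patience_increase
        self.lr = lr
        self.val_fraction = val_fraction
        self.search_radius = search_radius
        self.preprocess = preprocess
        self.seed = seed

    # -- configuration plumbing -------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(block=self.block, n_blocks=self.n_blocks, d=self.d,
                           n_heads=self.n_heads, scales=self.scales,
                           include_scale0=self.include_scale0,
                           backend=self.backend, threshold=self.threshold,
                           agl_dim=self.agl_dim)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(mode=self.mode, batch=self.batch,
                           batch_size=self.batch_size,
                           n_candidates=self.n_candidates,
                           refresh_epochs=self.refresh_epochs,
                           max_epochs=self.max_epochs,
                           patience_no_improve=self.patience_no_improve,
                           patience_increase=self.patience_increase,
                           lr=self.lr, val_fraction=self.val_fraction,
                           seed=self.seed)

    def _preprocess(self, volume: Volume, template: Volume) -> Volume:
        if not self.preprocess:
            return volume
        return preprocess_chain(volume, template=template)

    # -- estimator API -----------------------------------------------------
    def fit(self, atlas_pairs, y=None):
        """Store the labeled atlas pool: a list of (Volume, LabelMap)."""
        if len(atlas_pairs) == 0:
            raise ValueError("need at least one atlas")
        template = atlas_pairs[0][0]
        self.template_ = template
        self.atlases_ = [(self._preprocess(v, template), l)
                         for v, l in atlas_pairs]
        return self

    def predict(self, target: Volume) -> LabelMap:
        """Segment one target volume; returns the full label map."""
        if not hasattr(self, "atlases_"):
            raise RuntimeError("fit the estimator with an atlas pool first")
        target = self._preprocess(target, self.template_)
        mcfg, tcfg = self._model_config(), self._train_config()
        vcfg = VotingConfig(search_radius=self.search_radius)
        if self.mode == "inductive":
            result = train_inductive(target, self.atlases_, mcfg, tcfg, vcfg,
                                     n_atlases=self.n_atlases,
                                     dilation_radius=self.roi_dilation)
            self.library_ = None
        else:
            self.library_ = build_library(
                target, self.atlases_, n_atlases=self.n_atlases,
                dilation_radius=self.roi_dilation)
            result = segment_transductive(self.library_, mcfg, tcfg, vcfg)
        self.result_: SegmentationResult = result
        return result.label_map

    def score(self, target: Volume, truth: LabelMap) -> float:
        """Mean cartilage Dice fraction (classes 2 and 4) in [0, 1]."""
        pred = self.predict(target)
        roi = self.library_.roi if self.library_ is not None else None
        report = evaluate_segmentation(pred, truth, roi=roi)
        return float(np.mean([report.per_class[c]["dsc"]
                              for c in (2, 4)]) / 100.0)
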