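"""Per-target atlas library: ROI extraction, MSD ranking, atlas selection.

The region of interest is obtained by majority voting over the registered
atlas cartilage masks followed by a binary ball dilation; atlases are then
ranked by their mean squared intensity difference (MSD) to the target inside
the ROI, and the best ``n_atlases`` are kept. Registration itself is a
pluggable callable (identity by default): atlases are assumed to already
share the target's grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume, LabelMap

CARTILAGE_CLASSES = (2, 4)


@dataclass
class ROIMask:
    """Boolean sampling region over the target grid."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if not self.data.any():
            raise ValueError("empty ROI")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self):
        return self.data.shape


@dataclass
class AtlasLibrary:
    """Target volume plus its ranked, selected atlases and ROI."""

    target: Volume
    atlases: list  # of (Volume, LabelMap), ascending MSD order
    roi: ROIMask
    msd_scores: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        for vol, lab in self.atlases:
            if vol.shape != self.target.shape or lab.shape != self.target.shape:
                raise ValueError("atlas grid does not match target grid")
        if self.roi.shape != self.target.shape:
            raise ValueError("ROI grid does not match target grid")

    @property
    def n_atlases(self) -> int:
        return len(self.atlases)


def identity_registration(moving: Volume, moving_labels: LabelMap, fixed: Volume):
    """Default pluggable registration: assume images are pre-aligned."""
    return moving, moving_labels


def cartilage_mask(lab: LabelMap) -> np.ndarray:
    """Binary mask of the cartilage classes of a label map."""
    return np.isin(lab.data, CARTILAGE_CLASSES)


def build_roi(cartilage_masks, dilation_radius: int = 2) -> ROIMask:
    """Majority-vote the masks, then dilate with a discrete ball.

    A voxel enters the vote result iff strictly more than half of the input
    masks are true there.
    """
    masks = [np.asarray(m, dtype=bool) for m in cartilage_masks]
    if len(masks) == 0:
        raise ValueError("empty mask list")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks must share one shape")
    votes = np.sum(masks, axis=0)
    mv = votes > (len(masks) / 2.0)
    if not mv.any():
        raise ValueError("empty ROI after majority voting")
    if dilation_radius > 0:
        ball = _ball(dilation_radius)
        mv = ndimage.binary_dilation(mv, structure=ball)
    return ROIMask(mv)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return dx * dx + dy * dy + dz * dz <= r * r


def rank_atlases(target: Volume, atlases, roi: ROIMask):
    """MSD of each atlas to the target inside the ROI, plus ascending order.

    Returns ``(msd_scores, order)``; ties break stably by atlas index.
    """
    m = roi.data
    scores = []
    for vol in atlases:
        v = vol[0] if isinstance(vol, tuple) else vol
        if v.shape != target.shape:
            raise ValueError("atlas shape does not match target")
        diff = v.data[m] - target.data[m]
        scores.append(float(np.mean(diff * diff)))
    scores = np.asarray(scores)
    order = np.argsort(scores, kind="stable")
    return scores, order


def select_atlases(target: Volume, atlas_pairs, roi: ROIMask,
                   n_atlases: int = 10) -> AtlasLibrary:
    """Keep the ``n_atlases`` atlases with least ROI disagreement."""
    if n_atlases < 1 or n_atlases > len(atlas_pairs):
        raise ValueError(
            f"n_atlases must be in [1, {len(atlas_pairs)}], got {n_atlases}")
    scores, order = rank_atlases(target, [p[0] for p in atlas_pairs], roi)
    keep = order[:n_atlases]
    return AtlasLibrary(
        target=target,
        atlases=[atlas_pairs[i] for i in keep],
        roi=roi,
        msd_scores=scores[keep],
    )


def build_library(target: Volume, atlas_pairs, n_atlases: int = 10,
                  dilation_radius: int = 2,
                  registration=identity_registration) -> AtlasLibrary:
    """Full pipeline: register, extract ROI, rank, select."""
    registered = [registration(v, l, target) for v, l in atlas_pairs]
    roi = build_roi([cartilage_mask(l) for _, l in registered],
                    dilation_radius=dilation_radius)
    return select_atlases(target, registered, roi, n_atlases=n_atlases)
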