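"""Synthetic 5-class knee-like phantoms.

The phantom emulates the geometry the segmentation task cares about: a
dominant background, two ellipsoidal "bone" bodies separated by a joint gap,
and two thin curved "cartilage" sheets coating the facing bone surfaces.
Intensities are class means plus additive Gaussian noise. Atlas copies are
produced by warping the phantom with small random rigid shifts — standing in
for the residual misalignment left by imperfect affine registration — with
independent intensity noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume, LabelMap

#: Default class-mean intensities (background, FB, FC, TB, TC). Cartilage is
#: brighter than bone, bone brighter than background; the smallest pairwise
#: separation is 15 intensity units, i.e. 5x the default noise sd.
DEFAULT_CLASS_MEANS = (10.0, 55.0, 95.0, 40.0, 75.0)


@dataclass
class PhantomSpec:
    """Generation conditions for one phantom and its atlas copies."""

    shape: tuple = (64, 64, 64)
    class_means: tuple = DEFAULT_CLASS_MEANS
    noise_sd: float = 3.0
    cartilage_thickness: float = 2.5
    misalignment_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 32 for s in self.shape):
            raise ValueError("phantom shape must be 3D with all dims >= 32")
        if len(self.class_means) != 5:
            raise ValueError("need exactly 5 class means")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cartilage_thickness < 1:
            raise ValueError("cartilage_thickness must be >= 1 voxel")


def _ellipsoid_mask(shape, center, semiaxes):
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _phantom_labels(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = spec.shape
    # upper body ("femur") and lower body ("tibia"), separated by a joint gap
    femur = _ellipsoid_mask(spec.shape, (0.50 * X, 0.50 * Y, 0.70 * Z),
                            (0.32 * X, 0.32 * Y, 0.20 * Z))
    tibia = _ellipsoid_mask(spec.shape, (0.50 * X, 0.50 * Y, 0.28 * Z),
                            (0.34 * X, 0.34 * Y, 0.16 * Z))
    tibia &= ~femur
    bone = femur | tibia
    zz = np.arange(Z)[None, None, :]

    # cartilage sheets: thin shells within `thickness` of a bone surface, on
    # the side facing the joint gap, assigned to the nearer bone
    d_f = ndimage.distance_transform_edt(~femur)
    d_t = ndimage.distance_transform_edt(~tibia)
    t = spec.cartilage_thickness
    shell_f = (~bone) & (d_f > 0) & (d_f <= t) & (zz < 0.70 * Z)
    shell_t = (~bone) & (d_t > 0) & (d_t <= t) & (zz > 0.28 * Z)
    both = shell_f & shell_t
    shell_f_only = shell_f & ~both
    shell_t_only = shell_t & ~both
    closer_f = d_f <= d_t

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[femur] = 1
    labels[tibia] = 3
    labels[shell_f_only] = 2
    labels[shell_t_only] = 4
    labels[both & closer_f] = 2
    labels[both & ~closer_f] = 4

    present = np.unique(labels)
    if len(present) != 5:
        raise ValueError(
            f"phantom shape {spec.shape} too small: classes {present} only")
    return labels


def _clean_intensity(labels: np.ndarray, class_means) -> np.ndarray:
    return np.asarray(class_means, dtype=np.float64)[labels]


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Deterministically generate one (Volume, LabelMap) phantom pair."""
    labels = _phantom_labels(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    data = _clean_intensity(labels, spec.class_means)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return Volume(data), LabelMap(labels)


def generate_atlas_set(target: tuple[Volume, LabelMap], n_atlases: int,
                       spec: PhantomSpec) -> list[tuple[Volume, LabelMap]]:
    """Perturbed copies of the target phantom acting as registered atlases.

    Each atlas is the target geometry under a small random rigid shift
    (per-axis sd ``misalignment_sd`` voxels; trilinear intensity resampling,
    nearest-neighbor label resampling) with independent additive noise.
    """
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    _, lab = target
    clean = _clean_intensity(lab.data, spec.class_means)
    children = np.random.SeedSequence(spec.seed, spawn_key=(1,)).spawn(n_atlases)
    out = []
    for ss in children:
        rng = np.random.default_rng(ss)
        shift = rng.normal(0.0, spec.misalignment_sd, size=3)
        if spec.misalignment_sd == 0:
            shift = np.zeros(3)
        vol = ndimage.shift(clean, shift, order=1, mode="nearest")
        labw = ndimage.shift(lab.data, shift, order=0, mode="nearest",
                             output=np.uint8)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        out.append((Volume(vol), LabelMap(labw)))
    return out
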