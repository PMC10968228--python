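"""Volume and label-map containers with NIfTI I/O.

A :class:`Volume` is a 3D real-valued intensity grid together with its voxel
spacing and grid-to-world affine; a :class:`LabelMap` is an aligned integer
class grid over the five knee-joint classes (background, femoral bone,
femoral cartilage, tibial bone, tibial cartilage).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical class order shared by all label maps in the package.
CLASS_NAMES = (
    "background",
    "femoral_bone",
    "femoral_cartilage",
    "tibial_bone",
    "tibial_cartilage",
)
N_CLASSES = len(CLASS_NAMES)


@dataclass
class Volume:
    """3D intensity grid with physical metadata.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Finite voxel intensities.
    spacing : tuple of 3 floats
        Physical voxel size per axis, in mm.
    affine : ndarray, shape (4, 4)
        Grid-to-world transform.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError("all volume dimensions must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """3D integer class grid aligned with a :class:`Volume`."""

    data: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label map values must be integers")
            self.data = np.round(self.data).astype(np.uint8)
        if self.data.min() < 0 or self.data.max() >= len(self.class_names):
            raise ValueError(
                f"labels must lie in [0, {len(self.class_names) - 1}]"
            )
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self):
        return self.data.shape


def _load_nifti(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return data, img


def load_volume(path) -> Volume:
    """Read a NIfTI intensity volume, preserving spacing and affine."""
    data, img = _load_nifti(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=spacing,
                  affine=np.asarray(img.affine))


def load_labelmap(path) -> LabelMap:
    """Read a NIfTI label map (values 0..4)."""
    data, _ = _load_nifti(path)
    return LabelMap(data=data)


def save_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def save_labelmap(lab: LabelMap, path, affine=None, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a label map as unsigned 8-bit NIfTI."""
    img = nib.Nifti1Image(lab.data.astype(np.uint8), np.eye(4) if affine is None else affine)
    img.header.set_zooms(spacing)
    nib.save(img, path)
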