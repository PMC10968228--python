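"""3D histogram-of-oriented-gradients node descriptors.

Each graph node is a 5x5x5 patch around a central voxel. Its descriptor is a
20-bin histogram: per-voxel gradients (central differences over the patch
interior, so a constant patch yields the zero vector) are accumulated by
magnitude into the bin whose direction is most aligned with the gradient.
The 20 bin directions are the face normals of a regular icosahedron
(equivalently the vertices of a regular dodecahedron), covering the full
sphere in signed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

PATCH_SIZE = 5
N_BINS = 20


@dataclass(frozen=True)
class DirectionSet:
    """20 unit vectors closed under sign flip along each axis."""

    directions: np.ndarray  # (20, 3)

    def reflection_permutation(self, axis: int) -> np.ndarray:
        """Bin permutation induced by reflecting space along ``axis``."""
        flipped = self.directions.copy()
        flipped[:, axis] *= -1
        perm = np.empty(len(flipped), dtype=int)
        for i, f in enumerate(flipped):
            j = int(np.argmin(np.linalg.norm(self.directions - f, axis=1)))
            perm[i] = j
        return perm


@dataclass
class NodeDescriptor:
    """20 non-negative histogram entries for the patch at ``center``."""

    vector: np.ndarray
    center: tuple = (0, 0, 0)

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.shape != (N_BINS,):
            raise ValueError(f"descriptor must have {N_BINS} entries")


def hog_directions() -> DirectionSet:
    """Unit face normals of a regular icosahedron (dodecahedron vertices)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    inv = 1.0 / phi
    verts = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                verts.append((sx, sy, sz))
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            verts.append((0.0, s1 * inv, s2 * phi))
            verts.append((s1 * inv, s2 * phi, 0.0))
            verts.append((s1 * phi, 0.0, s2 * inv))
    dirs = np.asarray(verts, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return DirectionSet(dirs)


def _bin_gradients(grads: np.ndarray, dirs: np.ndarray):
    """Magnitudes and nearest-direction bin indices for gradient vectors.

    Ties break to the lowest bin index (argmax convention); zero gradients
    get magnitude 0 so their bin never contributes.
    """
    mags = np.linalg.norm(grads, axis=-1)
    dots = grads @ dirs.T
    bins = np.argmax(dots, axis=-1)
    return mags, bins


def _interior_gradients(patch: np.ndarray) -> np.ndarray:
    """Central-difference gradients at the 3x3x3 interior of a 5x5x5 patch."""
    c = slice(1, PATCH_SIZE - 1)
    gx = (patch[2:, c, c] - patch[:-2, c, c]) / 2.0
    gy = (patch[c, 2:, c] - patch[c, :-2, c]) / 2.0
    gz = (patch[c, c, 2:] - patch[c, c, :-2]) / 2.0
    return np.stack([gx, gy, gz], axis=-1)


def hog_descriptor(patch: np.ndarray, dirs: DirectionSet | None = None,
                   center=(0, 0, 0), normalize: bool = False) -> NodeDescriptor:
    """Descriptor of a single 5x5x5 patch."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (PATCH_SIZE,) * 3:
        raise ValueError(f"patch must be {PATCH_SIZE}^3, got {patch.shape}")
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    if dirs is None:
        dirs = hog_directions()
    grads = _interior_gradients(patch).reshape(-1, 3)
    mags, bins = _bin_gradients(grads, dirs.directions)
    vec = np.zeros(N_BINS)
    np.add.at(vec, bins[mags > 0], mags[mags > 0])
    if normalize:
        n = np.linalg.norm(vec)
        if n > 0:
            vec = vec / n
    return NodeDescriptor(vec, center=tuple(center))


class HogVolumeCache:
    """Precomputed per-bin box-filtered gradient magnitudes of one volume.

    Descriptor lookup for any set of patch centers becomes pure indexing,
    which makes repeated graph builds over the same volume cheap.
    """

    def __init__(self, data: np.ndarray, dirs: DirectionSet | None = None,
                 window: int = PATCH_SIZE):
        if dirs is None:
            dirs = hog_directions()
        data = np.asarray(data, dtype=np.float64)
        self.pad = 2
        p = np.pad(data, self.pad)
        gx = np.zeros_like(p)
        gy = np.zeros_like(p)
        gz = np.zeros_like(p)
        gx[1:-1, :, :] = (p[2:, :, :] - p[:-2, :, :]) / 2.0
        gy[:, 1:-1, :] = (p[:, 2:, :] - p[:, :-2, :]) / 2.0
        gz[:, :, 1:-1] = (p[:, :, 2:] - p[:, :, :-2]) / 2.0
        grads = np.stack([gx, gy, gz], axis=-1)
        mags, bins = _bin_gradients(grads, dirs.directions)
        kernel = np.ones((window,) * 3)
        self.summed = np.empty(p.shape + (N_BINS,))
        for b in range(N_BINS):
            contrib = np.where(bins == b, mags, 0.0)
            self.summed[..., b] = ndimage.correlate(contrib, kernel,
                                                    mode="constant")

    def descriptors(self, coords: np.ndarray,
                    normalize: bool = False) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=int)) + self.pad
        out = self.summed[coords[:, 0], coords[:, 1], coords[:, 2]].copy()
        if normalize:
            norms = np.linalg.norm(out, axis=1, keepdims=True)
            np.divide(out, norms, out=out, where=norms > 0)
        return out


def hog_volume_descriptors(data: np.ndarray, coords: np.ndarray,
                           dirs: DirectionSet | None = None,
                           normalize: bool = False,
                           window: int = PATCH_SIZE) -> np.ndarray:
    """Descriptors for many patch centers of one volume at once.

    Per-voxel gradients are central differences over the (zero-padded)
    volume, so every voxel of a node patch has a defined gradient; each
    descriptor accumulates the ``window``^3 voxels around its center. The
    default window is the full 5x5x5 patch. With ``window=3`` this matches
    :func:`hog_descriptor` applied to extracted patches, whose gradients
    exist only on the patch interior.
    """
    if dirs is None:
        dirs = hog_directions()
    data = np.asarray(data, dtype=np.float64)
    coords = np.atleast_2d(np.asarray(coords, dtype=int))
    pad = 2
    p = np.pad(data, pad)
    gx = np.zeros_like(p)
    gy = np.zeros_like(p)
    gz = np.zeros_like(p)
    gx[1:-1, :, :] = (p[2:, :, :] - p[:-2, :, :]) / 2.0
    gy[:, 1:-1, :] = (p[:, 2:, :] - p[:, :-2, :]) / 2.0
    gz[:, :, 1:-1] = (p[:, :, 2:] - p[:, :, :-2]) / 2.0
    grads = np.stack([gx, gy, gz], axis=-1)
    mags, bins = _bin_gradients(grads, dirs.directions)
    kernel = np.ones((window,) * 3)
    out = np.zeros(coords.shape[:1] + (N_BINS,))
    ix, iy, iz = (coords + pad).T
    for b in range(N_BINS):
        contrib = np.where(bins == b, mags, 0.0)
        summed = ndimage.correlate(contrib, kernel, mode="constant")
        out[:, b] = summed[ix, iy, iz]
    if normalize:
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        np.divide(out, norms, out=out, where=norms > 0)
    return out
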