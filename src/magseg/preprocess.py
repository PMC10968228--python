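"""Intensity preprocessing: histogram standardization and rescaling.

The default chain maps each image's histogram onto a template by
piecewise-linear landmark (decile) matching, then rescales intensities to a
common [0, 100] range. Heavier filters (denoising, bias-field correction)
can be supplied as plain ``Volume -> Volume`` callables via ``pre_hooks``.
"""

from __future__ import annotations

import numpy as np

from .volume import Volume


def rescale_intensity(v: Volume, lo: float = 0.0, hi: float = 100.0) -> Volume:
    """Affinely map intensities so the output spans exactly [lo, hi].

    A constant input volume maps to all-``lo``.
    """
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    d = v.data
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        out = np.full_like(d, lo)
    else:
        out = lo + (d - dmin) * ((hi - lo) / (dmax - dmin))
        out = np.clip(out, lo, hi)
        # pin the endpoints exactly against floating-point rounding
        out[d == dmin] = lo
        out[d == dmax] = hi
    return Volume(out, spacing=v.spacing, affine=v.affine)


def standardize_histogram(v: Volume, template: Volume, n_landmarks: int = 11) -> Volume:
    """Map ``v``'s histogram onto ``template``'s by landmark matching.

    Empirical quantiles of both images at ``n_landmarks`` evenly spaced
    percentiles (deciles by default) are matched by a monotone
    piecewise-linear transfer function. Output values never leave the
    template's [min, max] range.
    """
    if n_landmarks < 2:
        raise ValueError("need at least 2 landmarks")
    t = template.data
    if t.max() == t.min():
        raise ValueError("constant template")
    pct = np.linspace(0.0, 100.0, n_landmarks)
    src = np.percentile(v.data, pct)
    dst = np.percentile(t, pct)
    # np.interp requires strictly usable (non-decreasing) source knots; collapse
    # duplicate source landmarks to keep the map a function.
    keep = np.concatenate([[True], np.diff(src) > 0])
    src, dst = src[keep], dst[keep]
    if len(src) == 1:  # constant input: map everything to the matched landmark
        out = np.full_like(v.data, dst[0])
    else:
        out = np.interp(v.data, src, dst)
    return Volume(out, spacing=v.spacing, affine=v.affine)


def preprocess_chain(v: Volume, template: Volume | None = None,
                     n_landmarks: int = 11, lo: float = 0.0, hi: float = 100.0,
                     pre_hooks=()) -> Volume:
    """Apply optional pre-hooks, histogram standardization, and rescaling."""
    for hook in pre_hooks:
        v = hook(v)
    if template is not None:
        v = standardize_histogram(v, template, n_landmarks=n_landmarks)
    return rescale_intensity(v, lo=lo, hi=hi)
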