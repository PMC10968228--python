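"""Volumetric segmentation metrics: DSC, VOE, VD, precision, recall.

All per-class metrics are computed one-vs-rest inside the evaluation ROI,
on a 0-100 percent scale. VOE is derived from DSC via
``VOE = 100 * (1 - DSC / (200 - DSC))`` and VD is the signed relative
volume difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabelMap, N_CLASSES, CLASS_NAMES


def dsc(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Dice similarity coefficient in percent: 200|Y n Yhat| / (|Y|+|Yhat|)."""
    Y = np.asarray(Y, dtype=bool)
    Yhat = np.asarray(Yhat, dtype=bool)
    denom = Y.sum() + Yhat.sum()
    if denom == 0:
        raise ValueError("both masks empty")
    return float(100.0 * 2.0 * np.sum(Y & Yhat) / denom)


def voe(dsc_value: float) -> float:
    """Volume overlap error in percent, from a DSC percentage."""
    return float(100.0 * (1.0 - dsc_value / (200.0 - dsc_value)))


def vd(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Signed volumetric difference in percent: 100(|Yhat| - |Y|)/|Y|."""
    Y = np.asarray(Y, dtype=bool)
    ny = Y.sum()
    if ny == 0:
        raise ValueError("empty reference mask")
    return float(100.0 * (np.asarray(Yhat, dtype=bool).sum() - ny) / ny)


def precision_recall(Y: np.ndarray, Yhat: np.ndarray):
    """(precision, recall) in percent; undefined denominators yield NaN."""
    Y = np.asarray(Y, dtype=bool)
    Yhat = np.asarray(Yhat, dtype=bool)
    tp = np.sum(Y & Yhat)
    npred, ntrue = Yhat.sum(), Y.sum()
    precision = float(100.0 * tp / npred) if npred else float("nan")
    recall = float(100.0 * tp / ntrue) if ntrue else float("nan")
    return precision, recall


@dataclass
class MetricsReport:
    """Per-class metric table (classes 1..4; background excluded)."""

    per_class: dict  # class index -> dict of metric name -> value

    def as_table(self) -> str:
        hdr = f"{'class':<18}{'DSC':>8}{'VOE':>8}{'VD':>9}{'prec':>8}{'rec':>8}"
        lines = [hdr]
        for c, m in sorted(self.per_class.items()):
            lines.append(
                f"{CLASS_NAMES[c]:<18}{m['dsc']:>8.2f}{m['voe']:>8.2f}"
                f"{m['vd']:>9.2f}{m['precision']:>8.2f}{m['recall']:>8.2f}")
        return "\n".join(lines)

    def mean(self, metric: str, classes=(2, 4)) -> float:
        return float(np.mean([self.per_class[c][metric] for c in classes]))


def evaluate_segmentation(pred: LabelMap, truth: LabelMap,
                          roi=None) -> MetricsReport:
    """Per-class one-vs-rest report restricted to the ROI (if given)."""
    p, t = pred.data, truth.data
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    if roi is not None:
        m = roi.data if hasattr(roi, "data") else np.asarray(roi, dtype=bool)
        p, t = p[m], t[m]
    report = {}
    for c in range(1, N_CLASSES):
        Y, Yhat = t == c, p == c
        if Y.sum() + Yhat.sum() == 0:
            continue
        d = dsc(Y, Yhat)
        prec, rec = precision_recall(Y, Yhat)
        report[c] = dict(dsc=d, voe=voe(d),
                         vd=vd(Y, Yhat) if Y.sum() else float("nan"),
                         precision=prec, recall=rec)
    return MetricsReport(report)
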