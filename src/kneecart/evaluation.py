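"""Evaluation metrics: segmentation overlap, thickness error, grading
accuracy, and Bland-Altman agreement.

DSC = 2|A∩B| / (|A|+|B|) and IoU = |A∩B| / |A∪B| score mask overlap;
MAPE scores thickness agreement in percent; Bland-Altman summarises
paired-measurement agreement as bias and 1.96-SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .io_formats import FEMORAL_CLASS, TIBIAL_CLASS, LabelMask


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary: bias and 1.96-SD limits of agreement (mm)."""

    bias: float
    loa_low: float
    loa_high: float
    n: int


def _as_binary(a) -> np.ndarray:
    return np.asarray(a, dtype=bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dsc(a, b) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou(a, b) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def segmentation_scores(pred: LabelMask, ref: LabelMask, average: str = "micro") -> Dict[str, float]:
    """Per-class and total DSC/IoU for a predicted vs reference label mask.

    The total pools femoral and tibial pixel counts across classes (micro
    average) by default; ``average="macro"`` averages the per-class scores.
    """
    out: Dict[str, float] = {}
    inter = total = union = 0
    for name, cls in (("femur", FEMORAL_CLASS), ("tibia", TIBIAL_CLASS)):
        p, r = pred.class_mask(cls), ref.class_mask(cls)
        _check_shapes(p, r)
        out[f"dsc_{name}"] = dsc(p, r)
        out[f"iou_{name}"] = iou(p, r)
        inter += int((p & r).sum())
        total += int(p.sum()) + int(r.sum())
        union += int((p | r).sum())
    if average == "micro":
        out["dsc_total"] = 1.0 if total == 0 else 2.0 * inter / total
        out["iou_total"] = 1.0 if union == 0 else inter / union
    elif average == "macro":
        out["dsc_total"] = (out["dsc_femur"] + out["dsc_tibia"]) / 2.0
        out["iou_total"] = (out["iou_femur"] + out["iou_tibia"]) / 2.0
    else:
        raise ValueError("average must be 'micro' or 'macro'")
    return out


def mape(reference: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent. 0% is a perfect model."""
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted must have equal length")
    if ref.size == 0:
        raise ValueError("MAPE of empty input is undefined")
    if (ref <= 0).any():
        raise ValueError("MAPE undefined for non-positive reference values")
    return float(100.0 * np.mean(np.abs(ref - pred) / ref))


def grading_accuracy(reference_grades: Sequence[int], predicted_grades: Sequence[int]) -> float:
    """Percentage of exactly matching grade pairs."""
    ref = np.asarray(reference_grades)
    pred = np.asarray(predicted_grades)
    if ref.shape != pred.shape:
        raise ValueError("grade lists must have equal length")
    if ref.size == 0:
        raise ValueError("grading accuracy of empty input is undefined")
    return float(100.0 * np.mean(ref == pred))


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementStats:
    """Agreement between paired measurements: bias and limits of agreement.

    Differences d = a - b; bias = mean(d); limits = bias +/- 1.96 * sample
    SD of d (n-1 denominator).
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape:
        raise ValueError("paired measurements must have equal length")
    if a_arr.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    d = a_arr - b_arr
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=int(d.size)
    )
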