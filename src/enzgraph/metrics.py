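"""Micro-averaged multi-label classification metrics.

All metrics pool the confusion counts over every (item, class) cell
before computing ratios, so rare classes do not dominate.  Any 0/0 is
defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(probs: np.ndarray, targets: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets)
    if probs.shape != targets.shape:
        raise ValueError("probability and target shapes differ")
    pred = probs >= threshold
    pos = targets.astype(bool)
    return ConfusionCounts(tp=int(np.sum(pred & pos)),
                           fp=int(np.sum(pred & ~pos)),
                           fn=int(np.sum(~pred & pos)),
                           tn=int(np.sum(~pred & ~pos)))


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    accuracy = _safe_div(c.tp + c.tn, c.total)
    specificity = _safe_div(c.tn, c.tn + c.fp)
    mcc_den = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = _safe_div(float(c.tp) * c.tn - float(c.fp) * c.fn, mcc_den)
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy, "specificity": specificity, "mcc": mcc}


def micro_classification_metrics(probs: np.ndarray, targets: np.ndarray,
                                 threshold: float = 0.5) -> dict[str, float]:
    """Precision, recall, F1, accuracy, specificity and MCC, micro-averaged."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return metrics_from_counts(confusion_counts(probs, targets, threshold))


def threshold_sweep(probs: np.ndarray, targets: np.ndarray,
                    thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """One metrics row per confidence threshold (ascending)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for t in thresholds:
        row = {"threshold": t}
        row.update(micro_classification_metrics(probs, targets, threshold=t))
        rows.append(row)
    return pd.DataFrame(rows)


def plddt_group(per_residue_plddt: np.ndarray) -> str:
    """Structure-confidence group from per-residue pLDDT values.

    The chain is summarized by its mean pLDDT: High if > 90,
    Medium if in (70, 90], Low if <= 70.
    """
    values = np.asarray(per_residue_plddt, dtype=float)
    if values.size == 0:
        raise ValueError("empty pLDDT vector")
    if np.any((values < 0) | (values > 100)):
        raise ValueError("pLDDT values must lie in [0, 100]")
    mean = values.mean()
    if mean > 90:
        return "High"
    if mean > 70:
        return "Medium"
    return "Low"


def per_level_metrics(probs: np.ndarray, targets: np.ndarray,
                      level_masks: dict[int, np.ndarray],
                      threshold: float = 0.5) -> pd.DataFrame:
    """Micro metrics restricted to the classes of each hierarchy level."""
    rows = []
    for level, mask in sorted(level_masks.items()):
        if not mask.any():
            continue
        row = {"level": level}
        row.update(micro_classification_metrics(probs[:, mask],
                                                targets[:, mask], threshold))
        rows.append(row)
    return pd.DataFrame(rows)
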