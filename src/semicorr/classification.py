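"""Confusion-matrix construction and the four classification statistics.

Sens = TP/(TP+FN), Spec = TN/(TN+FP), Acc = (TP+TN)/All and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

The positive class is label 1 (active/irritant).  Any statistic whose
denominator is zero is reported as 0 by convention and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class StatBlock:
    sens: float
    spec: float
    acc: float
    mcc: float


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN for 0/1 labels and predictions."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must have equal length")
    tp = tn = fp = fn = 0
    for y, p in zip(labels, predictions):
        if y == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("%s has zero denominator: reported as 0", what)
        return 0.0
    return num / den


def stats(c: ConfusionCounts) -> StatBlock:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute statistics from all-zero counts")
    sens = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_div(c.tn, c.tn + c.fp, "specificity")
    acc = (c.tp + c.tn) / c.total
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, math.sqrt(den), "MCC")
    return StatBlock(sens=sens, spec=spec, acc=acc, mcc=mcc)


def mcc_from_vectors(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """MCC computed directly from raw label/prediction vectors."""
    return stats(confusion(labels, predictions)).mcc
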