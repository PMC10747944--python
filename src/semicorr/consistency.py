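"""The system of self-consistent models.

Models trained on independent random splits are cross-applied: entry (i, j)
of the consistency matrix is the MCC of model i evaluated on the validation
set of split j.  Agreement across the matrix — a high mean with a small
dispersion — shows that the modelling procedure, not one lucky split, is
responsible for the predictive performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classification import StatBlock, confusion, stats
from .descriptor import SemiCorrModel
from .splitter import Record, SplitDataset
from .tokenizer import tokenize


def evaluate_on(model: SemiCorrModel, records: Sequence[Record]) -> StatBlock:
    """Apply a model to labelled records and compute the four statistics."""
    labels = [r.label for r in records]
    preds = [model.predict_category(tokenize(r.smiles)) for r in records]
    return stats(confusion(labels, preds))


@dataclass
class ConsistencyMatrix:
    """k x k MCC matrix; rows index models, columns index validation sets."""

    mcc: np.ndarray
    split_ids: list[int]

    @property
    def k(self) -> int:
        return len(self.split_ids)


@dataclass
class ConsistencySummary:
    mean: float
    dispersion: float
    diag_mean: float
    diag_dispersion: float


def build_matrix(
    models: Sequence[SemiCorrModel], splits: Sequence[SplitDataset]
) -> ConsistencyMatrix:
    """Cross-apply every model to every split's validation set."""
    if len(models) != len(splits):
        raise ValueError("models and splits must be aligned one-to-one")
    k = len(models)
    m = np.zeros((k, k))
    for i, model in enumerate(models):
        for j, split in enumerate(splits):
            m[i, j] = evaluate_on(model, split.validation).mcc
    return ConsistencyMatrix(mcc=m, split_ids=[s.split_id for s in splits])


def summarize(matrix: ConsistencyMatrix) -> ConsistencySummary:
    """Mean and sample standard deviation of the MCC entries.

    Reported over all k^2 cells and, separately, over the diagonal
    (each model on its own validation set).
    """
    if matrix.k < 2:
        raise ValueError("need at least 2 splits to summarize consistency")
    cells = matrix.mcc.ravel()
    diag = np.diag(matrix.mcc)
    return ConsistencySummary(
        mean=float(cells.mean()),
        dispersion=float(cells.std(ddof=1)),
        diag_mean=float(diag.mean()),
        diag_dispersion=float(diag.std(ddof=1)),
    )
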