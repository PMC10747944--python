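"""Random partition of a labelled corpus into the four model-building subsets.

The workflow uses a structured training set: an *active training* set that
drives the weight optimization, a *passive training* set that cross-checks
the weights on molecules the optimizer never fits, a *calibration* set that
guards against overtraining (and is the sole source of the IIC term), and a
*validation* set that is never touched during model building.  Subsets are
of approximately equal size, drawn uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import SingleClassError
from .tokenizer import SUBSET_LABELS


class Record(NamedTuple):
    """One corpus entry: identifier, SMILES string, 0/1 activity label."""

    id: str
    smiles: str
    label: int


@dataclass
class SplitDataset:
    """One random split into the four disjoint subsets."""

    subsets: dict[str, list[Record]]
    split_id: int = 0
    seed: int = 0

    @property
    def active_training(self) -> list[Record]:
        return self.subsets["active_training"]

    @property
    def passive_training(self) -> list[Record]:
        return self.subsets["passive_training"]

    @property
    def calibration(self) -> list[Record]:
        return self.subsets["calibration"]

    @property
    def validation(self) -> list[Record]:
        return self.subsets["validation"]

    def all_records(self) -> list[Record]:
        return [r for label in SUBSET_LABELS for r in self.subsets[label]]


def make_split(
    dataset: Sequence[Record],
    seed: int,
    split_id: int = 0,
    stratify: bool = False,
) -> SplitDataset:
    """Partition `dataset` uniformly at random into four near-equal subsets.

    Deterministic given `seed`.  Subset sizes are n//4 with the remainder
    spread one-per-subset.  With ``stratify=True`` the partition is drawn
    within each class separately so class ratios match across subsets
    (off by default: the procedure modelled here divides plainly at random).
    """
    records = [Record(*r) for r in dataset]
    n = len(records)
    if n < 8:
        raise ValueError(f"need at least 8 molecules to split, got {n}")
    labels = {r.label for r in records}
    if labels <= {0} or labels <= {1}:
        raise SingleClassError("both activity classes must be present to split")

    rng = np.random.default_rng(seed)

    def assign(items: list[Record], order: np.ndarray) -> list[list[Record]]:
        m = len(items)
        base, rem = divmod(m, 4)
        sizes = [base + (1 if i < rem else 0) for i in range(4)]
        out, pos = [], 0
        for s in sizes:
            out.append([items[j] for j in order[pos : pos + s]])
            pos += s
        return out

    parts: list[list[Record]] = [[], [], [], []]
    if stratify:
        for cls in (1, 0):
            sub = [r for r in records if r.label == cls]
            for i, chunk in enumerate(assign(sub, rng.permutation(len(sub)))):
                parts[i].extend(chunk)
    else:
        parts = assign(records, rng.permutation(n))

    return SplitDataset(
        subsets=dict(zip(SUBSET_LABELS, parts)), split_id=split_id, seed=seed
    )


def make_splits(dataset: Sequence[Record], n_splits: int, seed: int, **kw) -> list[SplitDataset]:
    """Independent splits of the same corpus, seeded seed+0 .. seed+n_splits-1."""
    return [
        make_split(dataset, seed=seed + i, split_id=i + 1, **kw)
        for i in range(n_splits)
    ]


def overlap_report(splits: Sequence[SplitDataset]) -> np.ndarray:
    """Pairwise Jaccard overlap of the validation sets of several splits.

    Returns a symmetric k x k matrix with unit diagonal.  All splits must
    partition the same corpus.
    """
    if len(splits) < 2:
        raise ValueError("need at least 2 splits for an overlap report")
    universes = [frozenset(s.all_records()) for s in splits]
    if len(set(universes)) != 1:
        raise ValueError("splits were built on different datasets")
    vsets = [frozenset(r.id for r in s.validation) for s in splits]
    k = len(vsets)
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter = len(vsets[i] & vsets[j])
            union = len(vsets[i] | vsets[j])
            m[i, j] = m[j, i] = inter / union if union else 1.0
    return m
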