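"""Reading and writing corpora and splits as CSV/TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .splitter import Record, SplitDataset
from .tokenizer import SUBSET_LABELS


def read_corpus(path: str | Path) -> list[Record]:
    """Read a labelled corpus from CSV/TSV with columns id, smiles, label."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "smiles": str})
    missing = {"id", "smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"corpus file {path} lacks columns: {sorted(missing)}")
    return [
        Record(id=r.id, smiles=r.smiles, label=int(r.label))
        for r in df.itertuples(index=False)
    ]


def write_corpus(records: Sequence[Record], path: str | Path) -> None:
    pd.DataFrame(records, columns=["id", "smiles", "label"]).to_csv(path, index=False)


def write_split(split: SplitDataset, path: str | Path) -> None:
    """Write a split as corpus CSV plus a subset column."""
    rows = [
        {"id": r.id, "smiles": r.smiles, "label": r.label, "subset": label}
        for label in SUBSET_LABELS
        for r in split.subsets[label]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_split(path: str | Path, split_id: int = 0, seed: int = 0) -> SplitDataset:
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    subsets: dict[str, list[Record]] = {label: [] for label in SUBSET_LABELS}
    for r in df.itertuples(index=False):
        if r.subset not in subsets:
            raise ValueError(f"unknown subset label {r.subset!r} in {path}")
        subsets[r.subset].append(Record(id=r.id, smiles=r.smiles, label=int(r.label)))
    return SplitDataset(subsets=subsets, split_id=split_id, seed=seed)
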