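"""Transcribed reference tables from the published eye-irritation study.

Three fixtures ship with the package:

* the worked example — one molecule (2-butyne, ``CC#CC``) with the per-token
  correlation weights and the split-1 latent line used to demonstrate the
  descriptor arithmetic;
* the trained weight tables for the five random splits of the 5220-chemical
  eye-irritation corpus, with per-subset token frequencies and the
  active/blocked flag;
* the per-split, per-subset confusion counts and classification statistics.

Column-order note on the confusion counts
-----------------------------------------
The published count columns are headed "TN TP", but the printed
sensitivity/specificity/MCC values are arithmetically consistent only with
the FIRST count column being TP (e.g. split 1 validation: 1000/(1000+20) =
0.9804 = the printed sensitivity, and the corpus is ~74% positive, so the
larger count must be TP).  The loader therefore maps the first count column
to TP and the second to TN; the shipped CSV already carries the corrected
header.

The worked-example weights intentionally differ from the split-1 weight
table (e.g. the triple bond: 2.5018 vs -0.0018): the source presents both,
evidently from different optimization runs, and neither supersedes the
other.  They are exposed as separate fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .descriptor import SemiCorrModel, WeightTable
from .tokenizer import TokenFrequencies

#: Latent-line coefficients (C0, C1) of the five published split models.
SPLIT_COEFFICIENTS: dict[int, tuple[float, float]] = {
    1: (1.091, 0.03088),
    2: (1.111, 0.03304),
    3: (1.075, 0.02636),
    4: (1.129, 0.02883),
    5: (1.107, 0.04178),
}


@dataclass
class WorkedExample:
    smiles: str
    weights: WeightTable
    c0: float
    c1: float

    @property
    def model(self) -> SemiCorrModel:
        return SemiCorrModel(weights=self.weights, c0=self.c0, c1=self.c1)


def worked_example() -> WorkedExample:
    """The published single-molecule demonstration of the descriptor sum.

    CAS 503-17-3 (2-butyne, SMILES ``CC#CC``): four carbons at -0.8947 each
    and one triple bond at 2.5018 give DCW = -1.0770, and the split-1 line
    Y = 1.091 + 0.03088 * DCW yields Y = 1.0577 (active, Y >= 0.5).
    """
    weights = WeightTable(
        cw={"C": -0.8947, "#": 2.5018},
        active_set=frozenset({"C", "#"}),
        T=1,
        N=15,
    )
    c0, c1 = SPLIT_COEFFICIENTS[1]
    return WorkedExample(smiles="CC#CC", weights=weights, c0=c0, c1=c1)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("semicorr.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def split_weights_frame() -> pd.DataFrame:
    """All five splits' trained weights as one tidy frame."""
    return _read_csv("split_weights.csv")


def split_weight_table(split: int) -> WeightTable:
    """Trained weight table of one split (1-5), blocked tokens at 0."""
    df = split_weights_frame()
    sub = df[df["split"] == split]
    if sub.empty:
        raise KeyError(f"no reference weights for split {split}")
    cw = dict(zip(sub["token"], sub["cw"].astype(float)))
    active = frozenset(sub.loc[sub["active"], "token"])
    return WeightTable(cw=cw, active_set=active, T=1, N=15)


def split_frequencies(split: int) -> dict[str, TokenFrequencies]:
    """Per-subset molecule-level token frequencies of one split."""
    df = split_weights_frame()
    sub = df[df["split"] == split]
    if sub.empty:
        raise KeyError(f"no reference frequencies for split {split}")
    out = {}
    for label, col in (
        ("active_training", "freq_active"),
        ("passive_training", "freq_passive"),
        ("calibration", "freq_calibration"),
    ):
        tf = TokenFrequencies(subset_label=label)
        for tok, cnt in zip(sub["token"], sub[col].astype(int)):
            tf.counts[tok] = cnt
        out[label] = tf
    return out


def reference_model(split: int) -> SemiCorrModel:
    """Published weight table plus latent line for one split, as a model."""
    c0, c1 = SPLIT_COEFFICIENTS[split]
    return SemiCorrModel(weights=split_weight_table(split), c0=c0, c1=c1)


def confusion_table() -> pd.DataFrame:
    """Published per-split, per-subset statistics and confusion counts.

    Columns: split, subset, sens, spec, acc, mcc, tp, tn, fp, fn, n — with
    tp the first printed count column (see the module docstring).
    """
    return _read_csv("confusion_counts.csv")
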