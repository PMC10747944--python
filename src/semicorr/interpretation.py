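"""Mechanistic interpretation from repeated probe runs.

A token whose correlation weight is positive in every probe run is a
*promoter of increase* of the activity (class 1); one that is negative in
every run is a *promoter of decrease* (class 2); mixed signs — or an exact
zero in any run — leave the token's role *unclear* (class 3).  Frequencies
in the three training subsets accompany each role so rare, unreliable
features can be recognised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .descriptor import WeightTable
from .tokenizer import TokenFrequencies

INCREASE = "increase_promoter"
DECREASE = "decrease_promoter"
UNCLEAR = "unclear"


@dataclass
class FeatureRole:
    token: str
    cls: str
    probe_weights: list[float]
    freq_active: int
    freq_passive: int
    freq_calibration: int


def classify_features(
    probes: Sequence[WeightTable],
    freqs: Mapping[str, TokenFrequencies] | None = None,
) -> list[FeatureRole]:
    """Assign each always-active token to one of the three mechanistic classes.

    All probes must come from the same split (same active-token set);
    blocked tokens are excluded — they are not used in the simulation.
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probe runs to classify features")
    active_sets = {p.active_set for p in probes}
    if len(active_sets) != 1:
        raise ValueError("probe runs disagree on the active-token set; were they run on the same split?")
    freqs = freqs or {}
    fa = freqs.get("active_training")
    fp = freqs.get("passive_training")
    fc = freqs.get("calibration")
    roles = []
    for token in sorted(active_sets.pop()):
        ws = [p.cw[token] for p in probes]
        if all(w > 0 for w in ws):
            cls = INCREASE
        elif all(w < 0 for w in ws):
            cls = DECREASE
        else:
            cls = UNCLEAR
        roles.append(
            FeatureRole(
                token=token,
                cls=cls,
                probe_weights=ws,
                freq_active=fa[token] if fa else 0,
                freq_passive=fp[token] if fp else 0,
                freq_calibration=fc[token] if fc else 0,
            )
        )
    return roles


def roles_frame(roles: Sequence[FeatureRole]) -> pd.DataFrame:
    """Tabular view of feature roles (one probe-weight column per run)."""
    n_probes = len(roles[0].probe_weights) if roles else 0
    data = {
        "token": [r.token for r in roles],
        "class": [r.cls for r in roles],
        **{
            f"cw_probe_{i + 1}": [r.probe_weights[i] for r in roles]
            for i in range(n_probes)
        },
        "freq_active": [r.freq_active for r in roles],
        "freq_passive": [r.freq_passive for r in roles],
        "freq_calibration": [r.freq_calibration for r in roles],
    }
    return pd.DataFrame(data)


def promoter_presence_table(
    roles_per_split: Sequence[Sequence[FeatureRole]],
) -> pd.DataFrame:
    """Cross-split presence table of class-1 and class-2 promoters.

    Rows are (class, token); a "+" in a split column marks the token's
    presence in that split's promoter list, an empty string its absence.
    """
    if len(roles_per_split) < 2:
        raise ValueError("need at least 2 splits for a presence table")
    split_cols = [f"split_{i + 1}" for i in range(len(roles_per_split))]
    membership: dict[tuple[str, str], set[int]] = {}
    for s, roles in enumerate(roles_per_split):
        for r in roles:
            if r.cls in (INCREASE, DECREASE):
                membership.setdefault((r.cls, r.token), set()).add(s)
    rows = []
    for cls in (INCREASE, DECREASE):
        for (c, token), present in sorted(membership.items()):
            if c != cls:
                continue
            rows.append(
                {
                    "class": cls,
                    "token": token,
                    **{
                        col: ("+" if s in present else "")
                        for s, col in enumerate(split_cols)
                    },
                }
            )
    return pd.DataFrame(rows, columns=["class", "token", *split_cols])
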