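"""Optimal descriptor, latent regression and category rule.

The descriptor of a molecule is the sum of the correlation weights of its
attribute tokens,

    DCW(T, N) = sum_k CW(S_k),

where T is the frequency threshold separating active from blocked tokens and
N the number of Monte Carlo epochs used to fit the weights.  The latent
("semi-correlation") model is the straight line Y = C0 + C1 * DCW applied to
a 0/1 endpoint, with the category rule: active iff Y >= 0.5.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateFitError

logger = logging.getLogger(__name__)


@dataclass
class WeightTable:
    """Correlation weights CW(S_k) with the active/blocked token partition.

    Blocked tokens (not in `active_set`) always carry weight 0; the
    constructor enforces this.
    """

    cw: dict[str, float]
    active_set: frozenset[str] = field(default_factory=frozenset)
    T: int = 1
    N: int = 15

    def __post_init__(self) -> None:
        self.active_set = frozenset(self.active_set)
        self.cw = {t: (w if t in self.active_set else 0.0) for t, w in self.cw.items()}

    def weight(self, token: str) -> float:
        if token not in self.cw and token not in self.active_set:
            logger.debug("unknown token %r contributes 0 to DCW", token)
        if token not in self.active_set:
            return 0.0
        return self.cw.get(token, 0.0)


def dcw(tokens: Sequence[str], weights: WeightTable) -> float:
    """Sum of correlation weights over the token *list* of one molecule.

    Every occurrence contributes; blocked and unknown tokens contribute 0.
    """
    return float(sum(weights.weight(t) for t in tokens))


def classify(y: float) -> int:
    """Category rule: 1 (active) iff Y >= 0.5, else 0 (inactive)."""
    if not math.isfinite(y):
        raise ValueError(f"latent value must be finite, got {y!r}")
    return 1 if y >= 0.5 else 0


def fit_linear(
    dcw_values: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Ordinary least squares of the 0/1 endpoint on the descriptor.

    Returns (c0, c1).  Raises :class:`DegenerateFitError` if the descriptor
    vector is constant (the slope is then undefined).
    """
    d = np.asarray(dcw_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if d.size != y.size:
        raise ValueError("dcw_values and labels must have equal length")
    if d.size < 2:
        raise DegenerateFitError("need at least 2 points for the latent regression")
    var = float(np.var(d))
    if var == 0.0:
        raise DegenerateFitError("constant descriptor vector: slope undefined")
    c1 = float(np.cov(d, y, bias=True)[0, 1]) / var
    c0 = float(np.mean(y)) - c1 * float(np.mean(d))
    return c0, c1


@dataclass
class SemiCorrModel:
    """A trained semi-correlation model: weights plus the latent line."""

    weights: WeightTable
    c0: float
    c1: float

    def validate(self) -> "SemiCorrModel":
        """Enforce the trained-model invariant c1 != 0."""
        if self.c1 == 0.0:
            raise DegenerateFitError("trained model requires a nonzero slope C1")
        return self

    def predict_y(self, tokens: Sequence[str]) -> float:
        """Latent value Y = C0 + C1 * DCW for one tokenized molecule."""
        return self.c0 + self.c1 * dcw(tokens, self.weights)

    def predict_category(self, tokens: Sequence[str]) -> int:
        return classify(self.predict_y(tokens))

    def predict_many(self, token_lists: Iterable[Sequence[str]]) -> list[int]:
        return [self.predict_category(t) for t in token_lists]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "c0": self.c0,
            "c1": self.c1,
            "T": self.weights.T,
            "N": self.weights.N,
            "weights": dict(self.weights.cw),
            "active_set": sorted(self.weights.active_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SemiCorrModel":
        wt = WeightTable(
            cw=dict(d["weights"]),
            active_set=frozenset(d["active_set"]),
            T=int(d["T"]),
            N=int(d["N"]),
        )
        return cls(weights=wt, c0=float(d["c0"]), c1=float(d["c1"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SemiCorrModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict_y(model: SemiCorrModel, tokens: Sequence[str]) -> float:
    """Functional alias for :meth:`SemiCorrModel.predict_y`."""
    return model.predict_y(tokens)
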