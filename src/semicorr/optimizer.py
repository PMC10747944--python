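"""Monte Carlo optimization of correlation weights.

One run maximizes a target function (TF0 or TF1) by seeded coordinate hill
climbing: an epoch is one pass over the active tokens in random order; for
each token, perturbations are proposed and kept only if the target strictly
increases.  Proposal magnitudes are drawn log-uniformly over a few decades
below `step` (random sign), so a single pass mixes coarse moves that carry a
weight across its range with fine moves that polish it; proposals on a token
continue until `patience` consecutive rejections (at most
`proposals_per_token` tries).  r_AT and r_PT are computed on the active and
passive training sets, the IIC term on the calibration set only, and the
validation set is never touched.

Correlations for the TF are computed between the 0/1 labels and the raw
descriptor DCW; Pearson r is invariant under the positive-slope affine map
to Y, and this avoids any dependence on refitting order.  The latent line
(C0, C1) is refit by ordinary least squares on the active training set at
every proposal, since the IIC residuals are taken on the Y scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .descriptor import SemiCorrModel, WeightTable
from .errors import DegenerateFitError
from .metrics import TargetFunctionConfig, iic, tf0, tf1
from .splitter import Record, SplitDataset
from .tokenizer import count_frequencies, select_active_tokens, tokenize


@dataclass
class MonteCarloConfig:
    """Knobs of one optimization run.

    T is the token-frequency threshold (tokens at or below it are blocked),
    N the number of epochs and `init_range` the uniform initialization
    interval of the weights.  `step` is the *largest* proposal magnitude;
    magnitudes are spread log-uniformly over `scale_decades` decades below
    it.  Each token gets up to `proposals_per_token` tries per epoch,
    stopping after `patience` consecutive rejections.
    """

    T: int = 1
    N: int = 15
    seed: int = 0
    step: float = 1.0
    init_range: tuple[float, float] = (-0.5, 0.5)
    target: str = "tf1"
    tf_cfg: TargetFunctionConfig = field(default_factory=TargetFunctionConfig)
    proposals_per_token: int = 12
    patience: int = 3
    scale_decades: float = 2.5

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("need at least one epoch (N >= 1)")
        if self.step <= 0:
            raise ValueError("proposal step must be positive")
        if self.target not in ("tf0", "tf1"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.proposals_per_token < 1 or self.patience < 1:
            raise ValueError("proposals_per_token and patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    tf: float
    r_at: float
    r_pt: float
    iic: float
    accepted: int


@dataclass
class TrainingTrace:
    """Per-epoch snapshots of the accepted state (epoch 0 = initial state)."""

    records: list[EpochRecord] = field(default_factory=list)

    @property
    def tf_values(self) -> list[float]:
        return [r.tf for r in self.records]


def _count_matrix(records: Sequence[Record], columns: Sequence[str]) -> np.ndarray:
    """Occurrence counts per molecule (rows) of each active token (columns)."""
    index = {t: j for j, t in enumerate(columns)}
    x = np.zeros((len(records), len(columns)))
    for i, rec in enumerate(records):
        for tok, cnt in Counter(tokenize(rec.smiles)).items():
            j = index.get(tok)
            if j is not None:
                x[i, j] = cnt
    return x


def _pearson0(y: np.ndarray, d: np.ndarray, y_sd: float) -> float:
    """Pearson r, with 0 for a constant descriptor (undefined-correlation rule)."""
    d_sd = d.std()
    if d_sd == 0.0 or y_sd == 0.0:
        return 0.0
    r = float(np.mean((y - y.mean()) * (d - d.mean())) / (y_sd * d_sd))
    return max(-1.0, min(1.0, r))


class _Objective:
    """Evaluates the target function for a candidate weight vector's descriptors."""

    def __init__(
        self,
        y_at: np.ndarray,
        y_pt: np.ndarray,
        y_c: np.ndarray,
        cfg: MonteCarloConfig,
    ) -> None:
        self.y_at, self.y_pt, self.y_c = y_at, y_pt, y_c
        self.sd_at, self.sd_pt = y_at.std(), y_pt.std()
        self.cfg = cfg

    def __call__(self, d_at: np.ndarray, d_pt: np.ndarray, d_c: np.ndarray) -> tuple[float, float, float, float]:
        cfg = self.cfg
        r_at = _pearson0(self.y_at, d_at, self.sd_at)
        r_pt = _pearson0(self.y_pt, d_pt, self.sd_pt)
        t0 = tf0(r_at, r_pt, cfg.tf_cfg)
        iic_val = 0.0
        if cfg.target == "tf1":
            var = d_at.var()
            if var > 0.0:
                c1 = float(np.mean((d_at - d_at.mean()) * (self.y_at - self.y_at.mean()))) / var
                c0 = float(self.y_at.mean()) - c1 * float(d_at.mean())
                calc_c = c0 + c1 * d_c
                if calc_c.std() > 0.0:
                    iic_val = iic(self.y_c, calc_c)
            return tf1(t0, iic_val, cfg.tf_cfg), r_at, r_pt, iic_val
        return t0, r_at, r_pt, iic_val


def optimize(split: SplitDataset, cfg: MonteCarloConfig) -> tuple[SemiCorrModel, TrainingTrace]:
    """Train a semi-correlation model on one split.

    Returns the model (weights plus OLS-fitted latent line) and the
    per-epoch training trace.  Deterministic given the split and seed.
    """
    at, pt, cal = split.active_training, split.passive_training, split.calibration
    freq = count_frequencies((tokenize(r.smiles) for r in at), "active_training")
    active = select_active_tokens(freq, cfg.T)
    if len(active) < 2:
        raise ValueError(
            f"need at least 2 active tokens above threshold T={cfg.T}, got {len(active)}"
        )
    columns = sorted(active)
    x_at = _count_matrix(at, columns)
    x_pt = _count_matrix(pt, columns)
    x_c = _count_matrix(cal, columns)
    y_at = np.array([r.label for r in at], dtype=float)
    y_pt = np.array([r.label for r in pt], dtype=float)
    y_c = np.array([r.label for r in cal], dtype=float)

    objective = _Objective(y_at, y_pt, y_c, cfg)
    rng = np.random.default_rng(cfg.seed)

    lo, hi = cfg.init_range
    w = rng.uniform(lo, hi, size=len(columns))
    d_at, d_pt, d_c = x_at @ w, x_pt @ w, x_c @ w
    cur_tf, r_at, r_pt, iic_val = objective(d_at, d_pt, d_c)

    trace = TrainingTrace()
    trace.records.append(EpochRecord(0, cur_tf, r_at, r_pt, iic_val, 0))

    for epoch in range(1, cfg.N + 1):
        accepted = 0
        for j in rng.permutation(len(columns)):
            tries = fails = 0
            while tries < cfg.proposals_per_token and fails < cfg.patience:
                tries += 1
                mag = cfg.step * 10.0 ** (-cfg.scale_decades * rng.random())
                delta = mag if rng.random() < 0.5 else -mag
                t_at = d_at + delta * x_at[:, j]
                t_pt = d_pt + delta * x_pt[:, j]
                t_c = d_c + delta * x_c[:, j]
                new_tf, n_rat, n_rpt, n_iic = objective(t_at, t_pt, t_c)
                if new_tf > cur_tf:  # strict: ties are rejected
                    w[j] += delta
                    d_at, d_pt, d_c = t_at, t_pt, t_c
                    cur_tf, r_at, r_pt, iic_val = new_tf, n_rat, n_rpt, n_iic
                    accepted += 1
                    fails = 0
                else:
                    fails += 1
        trace.records.append(EpochRecord(epoch, cur_tf, r_at, r_pt, iic_val, accepted))

    var = d_at.var()
    if var == 0.0:
        raise DegenerateFitError("final descriptor is constant on the active training set")
    c1 = float(np.mean((d_at - d_at.mean()) * (y_at - y_at.mean()))) / float(var)
    c0 = float(y_at.mean()) - c1 * float(d_at.mean())

    cw = {t: 0.0 for t in freq.counts}
    cw.update({t: float(wj) for t, wj in zip(columns, w)})
    weights = WeightTable(cw=cw, active_set=frozenset(active), T=cfg.T, N=cfg.N)
    model = SemiCorrModel(weights=weights, c0=c0, c1=c1).validate()
    return model, trace


def count_parameters(model: SemiCorrModel) -> int:
    """Number of optimized parameters: tokens whose weight is free to move."""
    return len(model.weights.active_set)


def probe_runs(
    split: SplitDataset, cfg: MonteCarloConfig, n_probes: int
) -> list[WeightTable]:
    """Independent optimizations differing only in seed (seed+0 .. seed+n-1).

    Repeated probes expose which tokens keep a stable weight sign — the
    basis of the mechanistic interpretation.
    """
    if n_probes < 2:
        raise ValueError("need at least 2 probe runs")
    tables = []
    for i in range(n_probes):
        model, _ = optimize(split, replace(cfg, seed=cfg.seed + i))
        tables.append(model.weights)
    return tables
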