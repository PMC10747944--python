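"""Monte Carlo target functions and the index of ideality of correlation.

Two target functions drive the weight optimization:

    TF0 = r_AT + r_PT - |r_AT - r_PT| * 0.1
    TF1 = TF0 + IIC_C * 0.5

r_AT and r_PT are Pearson correlations between observed and predicted
endpoints on the active and passive training sets.  IIC_C, the index of
ideality of correlation, is computed on the calibration set only:

    IIC_C = r_C * min(MAE-, MAE+) / max(MAE-, MAE+)

where MAE- and MAE+ are mean absolute residuals over the negative
(delta < 0) and non-negative (delta >= 0) sides of delta_k = observed_k -
calculated_k.  IIC rewards residual distributions that are balanced around
zero; by construction |IIC| <= |r_C|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedCorrelationError

logger = logging.getLogger(__name__)


@dataclass
class TargetFunctionConfig:
    """Coefficients of the target functions.

    diff_coeff multiplies |r_AT - r_PT| in TF0 (default 0.1); iic_coeff
    multiplies IIC in TF1 (default 0.5).
    """

    diff_coeff: float = 0.1
    iic_coeff: float = 0.5
    use_iic: bool = True

    def __post_init__(self) -> None:
        if self.diff_coeff < 0 or self.iic_coeff < 0:
            raise ValueError("target-function coefficients must be non-negative")


@dataclass
class ResidualSplit:
    """One-sided mean absolute residuals of delta = observed - calculated."""

    mae_neg: float
    mae_pos: float
    n_neg: int
    n_pos: int


def pearson_r(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Sample Pearson correlation between observed and calculated endpoints.

    Raises :class:`UndefinedCorrelationError` if either vector is constant.
    """
    o = np.asarray(observed, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if o.size != c.size:
        raise ValueError("observed and calculated must have equal length")
    if o.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    so, sc = o.std(), c.std()
    if so == 0.0 or sc == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = float(np.mean((o - o.mean()) * (c - c.mean())) / (so * sc))
    return max(-1.0, min(1.0, r))


def residual_split(
    observed: Sequence[float], calculated: Sequence[float]
) -> ResidualSplit:
    """Split residuals delta = observed - calculated at zero.

    delta < 0 feeds mae_neg, delta >= 0 feeds mae_pos; an empty side has
    MAE defined as 0.
    """
    o = np.asarray(observed, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if o.size != c.size:
        raise ValueError("observed and calculated must have equal length")
    delta = o - c
    neg = delta[delta < 0]
    pos = delta[delta >= 0]
    mae_neg = float(np.mean(np.abs(neg))) if neg.size else 0.0
    mae_pos = float(np.mean(np.abs(pos))) if pos.size else 0.0
    return ResidualSplit(mae_neg=mae_neg, mae_pos=mae_pos, n_neg=int(neg.size), n_pos=int(pos.size))


def iic(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Index of ideality of correlation on the calibration set.

    Returns 0 when the ratio is undefined: one residual side empty, or a
    perfect fit (both MAEs zero).  The optimizer is then not rewarded for a
    one-sided residual distribution it cannot assess.
    """
    rs = residual_split(observed, calculated)
    if rs.n_neg == 0 or rs.n_pos == 0:
        logger.debug("IIC undefined (one-sided residuals, n-=%d n+=%d): 0", rs.n_neg, rs.n_pos)
        return 0.0
    hi = max(rs.mae_neg, rs.mae_pos)
    if hi == 0.0:
        logger.debug("IIC undefined (all residuals zero): 0")
        return 0.0
    r_c = pearson_r(observed, calculated)
    return r_c * min(rs.mae_neg, rs.mae_pos) / hi


def tf0(r_at: float, r_pt: float, cfg: TargetFunctionConfig | None = None) -> float:
    """Balance-of-correlations target: r_AT + r_PT - |r_AT - r_PT| * diff_coeff."""
    cfg = cfg or TargetFunctionConfig()
    return r_at + r_pt - abs(r_at - r_pt) * cfg.diff_coeff


def tf1(tf0_value: float, iic_value: float, cfg: TargetFunctionConfig | None = None) -> float:
    """IIC-augmented target: TF0 + iic_coeff * IIC."""
    cfg = cfg or TargetFunctionConfig()
    return tf0_value + cfg.iic_coeff * iic_value
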