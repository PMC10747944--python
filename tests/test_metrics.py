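"""Target functions, IIC and the one-sided residual split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semicorr.errors import UndefinedCorrelationError
from semicorr.metrics import (
    TargetFunctionConfig,
    iic,
    pearson_r,
    residual_split,
    tf0,
    tf1,
)


def test_pearson_examples():
    # closed form: cov 0.175, sd 0.5 and sqrt(0.125) -> r = 0.98995
    assert pearson_r([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(0.98995, abs=1e-5)
    obs = [0.0, 0.5, 1.0, 2.0]
    assert pearson_r(obs, obs) == pytest.approx(1.0)
    assert pearson_r(obs, [3 - o for o in obs]) == pytest.approx(-1.0)


def test_pearson_constant_vector_is_error():
    with pytest.raises(UndefinedCorrelationError):
        pearson_r([1, 1, 1], [0, 1, 2])


@pytest.mark.parametrize(
    "obs, calc, mneg, mpos, nneg, npos",
    [
        ([0.0, 1.0], [0.2, 0.8], 0.2, 0.2, 1, 1),
        ([1.0, 1.0], [1.0, 1.0], 0.0, 0.0, 0, 2),  # delta=0 counts as >= 0
        ([0.0, 0.0, 1.0], [0.1, 0.3, 0.2], 0.2, 0.8, 2, 1),
    ],
)
def test_residual_split_examples(obs, calc, mneg, mpos, nneg, npos):
    rs = residual_split(obs, calc)
    assert rs.mae_neg == pytest.approx(mneg)
    assert rs.mae_pos == pytest.approx(mpos)
    assert (rs.n_neg, rs.n_pos) == (nneg, npos)


def test_iic_symmetric_residuals_equal_r():
    obs = [0.0, 0.0, 1.0, 1.0]
    calc = [0.2, -0.2, 0.8, 1.2]  # deltas -0.2, +0.2, +0.2, -0.2
    assert iic(obs, calc) == pytest.approx(pearson_r(obs, calc))


def test_iic_ratio_example():
    # r close to 1 scaled by min/max = 0.2/0.8
    obs = [0.0, 0.0, 1.0]
    calc = [0.1, 0.3, 0.2]
    r = pearson_r(obs, calc)
    assert iic(obs, calc) == pytest.approx(r * 0.25)


def test_iic_degenerate_cases_are_zero():
    assert iic([0.0, 1.0, 0.0], [0.0, 1.0, 0.0]) == 0.0  # perfect fit
    assert iic([0.0, 1.0, 2.0], [-1.0, 0.0, 1.0]) == 0.0  # one-sided residuals


@pytest.mark.parametrize(
    "r_at, r_pt, expected",
    [(0.8, 0.8, 1.6), (0.9, 0.7, 1.58), (0.0, 0.0, 0.0)],
)
def test_tf0_examples(r_at, r_pt, expected):
    assert tf0(r_at, r_pt) == pytest.approx(expected)


def test_tf1_examples():
    assert tf1(1.6, 0.8) == pytest.approx(2.0)
    assert tf1(1.2, 0.0) == pytest.approx(1.2)
    assert tf1(0.0, -1.0) == pytest.approx(-0.5)


def test_tf_coefficients_configurable():
    cfg = TargetFunctionConfig(diff_coeff=0.2, iic_coeff=1.0)
    assert tf0(0.9, 0.7, cfg) == pytest.approx(1.56)
    assert tf1(1.0, 0.5, cfg) == pytest.approx(1.5)


@given(st.floats(-1, 1), st.floats(-1, 1))
@settings(derandomize=True, max_examples=100)
def test_tf0_symmetry_and_diagonal(a, b):
    assert tf0(a, b) == pytest.approx(tf0(b, a))
    assert tf0(a, a) == pytest.approx(2 * a)


@given(
    st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=30),
    st.integers(0, 2**31 - 1),
)
@settings(derandomize=True, max_examples=200)
def test_iic_bounded_by_r_and_counts_conserved(obs, seed):
    rng = np.random.default_rng(seed)
    calc = [o + rng.normal(0, 1) for o in obs]
    rs = residual_split(obs, calc)
    assert rs.n_neg + rs.n_pos == len(obs)
    if len(set(obs)) > 1 and len(set(calc)) > 1:
        assert abs(iic(obs, calc)) <= abs(pearson_r(obs, calc)) + 1e-12


@given(st.floats(-3, 3))
@settings(derandomize=True, max_examples=50)
def test_iic_invariant_under_common_shift(shift):
    obs = [0.0, 1.0, 0.0, 1.0, 1.0]
    calc = [0.3, 0.7, -0.1, 1.4, 0.9]
    shifted = iic([o + shift for o in obs], [c + shift for c in calc])
    assert shifted == pytest.approx(iic(obs, calc), abs=1e-9)
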