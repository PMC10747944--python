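"""Descriptor sum, latent line, category rule and model serialization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semicorr.descriptor import (
    SemiCorrModel,
    WeightTable,
    classify,
    dcw,
    fit_linear,
)
from semicorr.errors import DegenerateFitError
from semicorr.reference import worked_example
from semicorr.tokenizer import tokenize


def test_worked_example_descriptor_and_latent_value():
    """2-butyne: four C at -0.8947 plus the triple bond at 2.5018."""
    we = worked_example()
    toks = tokenize(we.smiles)
    d = dcw(toks, we.weights)
    assert d == pytest.approx(-1.0770, abs=1e-4)
    # the published sum (-1.0769) reflects rounding of the printed weights
    assert d == pytest.approx(-1.0769, abs=2e-4)
    y = we.model.predict_y(toks)
    assert y == pytest.approx(1.057, abs=1e-3)
    assert we.model.predict_category(toks) == 1


def test_dcw_empty_and_blocked():
    wt = WeightTable(cw={"C": 1.5, "X": 9.0}, active_set={"C"})
    assert dcw([], wt) == 0.0
    assert dcw(["X", "X"], wt) == 0.0  # blocked contributes nothing
    assert dcw(["C", "X", "C"], wt) == 3.0
    assert dcw(["?"], wt) == 0.0  # unknown token


def test_dcw_additive_over_concatenation():
    wt = WeightTable(cw={"C": 0.3, "#": -1.2}, active_set={"C", "#"})
    a, b = ["C", "#"], ["C", "C"]
    assert dcw(a + b, wt) == pytest.approx(dcw(a, wt) + dcw(b, wt))


@pytest.mark.parametrize(
    "y, expected", [(1.057, 1), (0.5, 1), (0.4999, 0), (-2.0, 0)]
)
def test_category_rule_boundary_inclusive(y, expected):
    assert classify(y) == expected


def test_classify_rejects_non_finite():
    with pytest.raises(ValueError):
        classify(float("nan"))


def test_fit_linear_closed_forms():
    assert fit_linear([0, 1], [0, 1]) == pytest.approx((0.0, 1.0))
    c0, c1 = fit_linear([1, 1, 2, 2], [0, 1, 0, 1])
    assert c1 == pytest.approx(0.0)
    assert c0 == pytest.approx(0.5)


def test_fit_linear_degenerate_descriptor():
    with pytest.raises(DegenerateFitError):
        fit_linear([2.0, 2.0, 2.0], [0, 1, 0])


def test_constant_labels_yield_zero_slope_rejected_at_finalization():
    c0, c1 = fit_linear([0, 2], [1, 1])
    assert (c0, c1) == pytest.approx((1.0, 0.0))
    wt = WeightTable(cw={"C": 1.0}, active_set={"C"})
    with pytest.raises(DegenerateFitError):
        SemiCorrModel(weights=wt, c0=c0, c1=c1).validate()


@given(st.floats(0.1, 10.0))
@settings(derandomize=True, max_examples=50)
def test_classification_invariant_under_weight_rescaling(lam):
    """(c0, c1, cw) -> (c0, c1/lam, lam*cw) leaves the category unchanged."""
    toks = ["C", "C", "#", "N"]
    base = SemiCorrModel(
        weights=WeightTable(cw={"C": -0.9, "#": 2.5, "N": 0.3},
                            active_set={"C", "#", "N"}),
        c0=1.09, c1=0.031,
    )
    scaled = SemiCorrModel(
        weights=WeightTable(cw={t: lam * w for t, w in base.weights.cw.items()},
                            active_set=base.weights.active_set),
        c0=base.c0, c1=base.c1 / lam,
    )
    assert math.isclose(base.predict_y(toks), scaled.predict_y(toks), rel_tol=1e-9)
    assert base.predict_category(toks) == scaled.predict_category(toks)


def test_model_json_round_trip_exact(tmp_path):
    model = SemiCorrModel(
        weights=WeightTable(cw={"C": -0.894712345, "#": 2.5018, "/": 0.0},
                            active_set={"C", "#"}, T=1, N=15),
        c0=1.091, c1=0.03088,
    )
    path = tmp_path / "model.json"
    model.save(path)
    loaded = SemiCorrModel.load(path)
    assert loaded.c0 == model.c0 and loaded.c1 == model.c1
    assert loaded.weights.cw == model.weights.cw
    assert loaded.weights.active_set == model.weights.active_set
    assert (loaded.weights.T, loaded.weights.N) == (1, 15)
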