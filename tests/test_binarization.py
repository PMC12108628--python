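"""Transfer functions and binarization rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metafs.binarization import (
    BinarizationConfig,
    BinarizationRule,
    TransferFunction,
    apply_rule,
    binarize_population,
    transfer_value,
)

S_FUNCS = [TransferFunction.S1, TransferFunction.S2, TransferFunction.S3,
           TransferFunction.S4]
V_FUNCS = [TransferFunction.V1, TransferFunction.V2, TransferFunction.V3,
           TransferFunction.V4]
GRID = np.linspace(-10.0, 10.0, 41)


class _StreamRng:
    """Stand-in generator replaying a fixed uniform stream row-major."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def random(self, shape):
        return self.values.reshape(shape)


def _sympy_reference(tf: TransferFunction, d: float) -> float:
    """High-precision closed forms evaluated independently via sympy."""
    import sympy as sp

    x = sp.Float(d, 30)
    if tf is TransferFunction.S1:
        expr = 1 / (1 + sp.exp(-2 * x))
    elif tf is TransferFunction.S2:
        expr = 1 / (1 + sp.exp(-x))
    elif tf is TransferFunction.S3:
        expr = 1 / (1 + sp.exp(-x / 2))
    elif tf is TransferFunction.S4:
        expr = 1 / (1 + sp.exp(-x / 3))
    elif tf is TransferFunction.V1:
        expr = sp.Abs(sp.erf(sp.sqrt(sp.pi) / 2 * x))
    elif tf is TransferFunction.V2:
        expr = sp.Abs(sp.tanh(x))
    elif tf is TransferFunction.V3:
        expr = sp.Abs(x / sp.sqrt(1 + x**2))
    else:
        expr = sp.Abs(2 / sp.pi * sp.atan(sp.pi / 2 * x))
    return float(sp.N(expr, 30))


@pytest.mark.parametrize("tf", list(TransferFunction))
def test_transfer_matches_high_precision_forms(tf):
    for d in GRID:
        assert transfer_value(tf, d) == pytest.approx(
            _sympy_reference(tf, d), abs=1e-12)


@pytest.mark.parametrize("tf,d,expected", [
    (TransferFunction.S2, 0.0, 0.5),      # logistic at zero
    (TransferFunction.V2, 0.0, 0.0),      # tanh at zero
    (TransferFunction.S4, 3.0, 0.731059),  # 1/(1+e^-1)
])
def test_transfer_reference_points(tf, d, expected):
    assert transfer_value(tf, d) == pytest.approx(expected, abs=1e-6)


def test_transfer_shape_properties():
    for tf in S_FUNCS:
        vals = transfer_value(tf, GRID)
        assert np.all(np.diff(vals) > 0), "S-shaped must strictly increase"
        assert transfer_value(tf, 0.0) == pytest.approx(0.5)
    for tf in V_FUNCS:
        vals = transfer_value(tf, GRID)
        assert transfer_value(tf, 0.0) == 0.0
        assert np.allclose(vals, transfer_value(tf, -GRID)), "V symmetry"
        pos = transfer_value(tf, GRID[GRID >= 0])
        assert np.all(np.diff(pos) >= 0), "V nondecreasing in |d|"


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.sampled_from(list(TransferFunction)),
       st.floats(-1e6, 1e6, allow_nan=False))
def test_transfer_bounded_unit_interval(tf, d):
    assert 0.0 <= transfer_value(tf, d) <= 1.0


def test_transfer_rejects_non_finite():
    with pytest.raises(ValueError):
        transfer_value(TransferFunction.S1, np.nan)


@pytest.mark.parametrize("t_val,rand,expected", [
    (1.0, 0.3, 1), (1.0, 0.99, 1),   # probability one
    (0.0, 0.3, 0), (0.0, 0.0, 1),    # rand <= 0 fires only at t=0 edge
    (0.7, 0.65, 1), (0.7, 0.75, 0),  # direct comparison rand <= T
])
def test_standard_rule(t_val, rand, expected):
    assert apply_rule(BinarizationRule.STANDARD, t_val, rand) == expected


def test_complement_rule_flips_current_bit():
    assert apply_rule(BinarizationRule.COMPLEMENT, 0.8, 0.5, current_bit=1) == 0
    assert apply_rule(BinarizationRule.COMPLEMENT, 0.8, 0.5, current_bit=0) == 1
    assert apply_rule(BinarizationRule.COMPLEMENT, 0.2, 0.5, current_bit=0) == 0


def test_static_probability_bands():
    alpha = 1.0 / 3.0
    upper = 0.5 * (1 + alpha)
    assert apply_rule(BinarizationRule.STATIC_PROBABILITY, alpha - 0.01, 0.9,
                      current_bit=1, static_alpha=alpha) == 0
    assert apply_rule(BinarizationRule.STATIC_PROBABILITY, 0.5, 0.9,
                      current_bit=1, static_alpha=alpha) == 1
    assert apply_rule(BinarizationRule.STATIC_PROBABILITY, 0.5, 0.9,
                      current_bit=0, static_alpha=alpha) == 0
    assert apply_rule(BinarizationRule.STATIC_PROBABILITY, upper + 0.01, 0.1,
                      current_bit=0, static_alpha=alpha) == 1


def test_elitist_rule_copies_best_bit():
    assert apply_rule(BinarizationRule.ELITIST, 0.9, 0.5, best_bit=1) == 1
    assert apply_rule(BinarizationRule.ELITIST, 0.9, 0.5, best_bit=0) == 0
    assert apply_rule(BinarizationRule.ELITIST, 0.1, 0.5, best_bit=1) == 0


def test_roulette_elitist_unsupported():
    with pytest.raises(NotImplementedError):
        apply_rule(BinarizationRule.ROULETTE_ELITIST, 0.5, 0.5)


def test_apply_rule_validates_inputs():
    with pytest.raises(ValueError):
        apply_rule(BinarizationRule.STANDARD, 1.5, 0.5)


def test_binarize_worked_example_recorded_stream():
    # T(S4) of the positions below: (0.5416, 0.3393, 0.5, 0.7311, 0.5, 0.4584)
    # compared element-wise against the recorded draw stream
    positions = np.array([[0.5, -2.0, 0.0], [3.0, 0.0, -0.5]])
    stream = [0.5, 0.9, 0.6, 0.1, 0.4, 0.2]
    out = binarize_population(
        positions, BinarizationConfig(), _StreamRng(stream),
        current_bits=np.zeros((2, 3), dtype=int),
        best_bits=np.zeros(3, dtype=int))
    assert out.tolist() == [[1, 0, 0], [1, 1, 1]]


def test_binarize_saturated_positions():
    # S2 at +10: T ~ 0.99995, so any draw below 0.999 yields a one
    out = binarize_population(
        np.full((3, 4), 10.0),
        BinarizationConfig(transfer=TransferFunction.S2),
        _StreamRng(np.full(12, 0.999)),
        current_bits=np.zeros((3, 4), dtype=int),
        best_bits=np.zeros(4, dtype=int))
    assert out.all()
    # V1 at zero: T = 0, all zeros regardless of draws
    out = binarize_population(
        np.zeros((2, 5)),
        BinarizationConfig(transfer=TransferFunction.V1),
        np.random.default_rng(0),
        current_bits=np.ones((2, 5), dtype=int),
        best_bits=np.ones(5, dtype=int))
    assert not out.any()


def test_binarize_reproducible_and_validates_shapes():
    positions = np.random.default_rng(5).normal(size=(4, 6))
    args = dict(current_bits=np.zeros((4, 6), dtype=int),
                best_bits=np.zeros(6, dtype=int))
    a = binarize_population(positions, BinarizationConfig(),
                            np.random.default_rng(42), **args)
    b = binarize_population(positions, BinarizationConfig(),
                            np.random.default_rng(42), **args)
    assert np.array_equal(a, b)
    assert set(np.unique(a)) <= {0, 1}
    with pytest.raises(ValueError):
        binarize_population(positions, BinarizationConfig(),
                            np.random.default_rng(0),
                            current_bits=np.zeros((3, 6), dtype=int),
                            best_bits=np.zeros(6, dtype=int))


def test_standard_rule_empirical_frequency():
    t_val = 0.3
    n = 10**5
    draws = np.random.default_rng(99).random(n)
    freq = np.mean(draws <= t_val)
    assert abs(freq - t_val) <= 3 * np.sqrt(t_val * (1 - t_val) / n)
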