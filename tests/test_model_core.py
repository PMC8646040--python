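"""Unit and property tests of the pure model functions.

Every function is pinned to an independent direct-formula oracle
written here from scratch (tanh identity for the logistic, plain
``math`` arithmetic for the rest), plus the hand-computed example
values of the published constants.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fdpsim import (
    ConfigurationError,
    DomainError,
    ModelParams,
    double_exp_kernel,
    eta,
    nmda_gate,
    omega,
    sigmoid,
)

# ---------------------------------------------------------------- oracles


def sigmoid_oracle(x, beta):
    # logistic via the tanh identity: exp(bx)/(1+exp(bx)) = (1+tanh(bx/2))/2
    return 0.5 * (1.0 + math.tanh(0.5 * beta * x))


def omega_oracle(ca, p: ModelParams):
    return (1.0 + 4.0 * sigmoid_oracle(ca - p.alpha2, p.beta2)
            - sigmoid_oracle(ca - p.alpha1, p.beta1))


def eta_oracle(ca, p: ModelParams):
    return 1.0 / (p.p1 / (p.p2 + ca ** p.p3) + p.p4)


def gate_oracle(v, p: ModelParams):
    return (p.p0 * abs(p.g_nmda) * (p.v_r - v)
            / (1.0 + (p.mg / 3.57) * math.exp(-0.062 * v)))


def kernel_oracle(t, tau_slow, tau_fast):
    if t <= 0:
        return 0.0
    return math.exp(-t / tau_slow) - math.exp(-t / tau_fast)


def test_all_functions_match_direct_formula_oracles(params):
    """1000 random inputs per function agree with the oracle to 1e-12."""
    rng = np.random.default_rng(2024)
    # sigmoid: keep |beta*x| moderate so the saturated tails (where the
    # oracle degenerates to exactly 0/1) do not dominate
    x = rng.uniform(-0.3, 0.3, 1000)
    b = rng.uniform(1.0, 100.0, 1000)
    for xi, bi in zip(x, b):
        assert sigmoid(xi, bi) == pytest.approx(sigmoid_oracle(xi, bi), rel=1e-12)
    ca = rng.uniform(0.0, 5.0, 1000)
    for c in ca:
        assert omega(c, params) == pytest.approx(omega_oracle(c, params), rel=1e-12)
        assert eta(c, params) == pytest.approx(eta_oracle(c, params), rel=1e-12)
    v = rng.uniform(-100.0, 130.0, 1000)
    for vi in v:
        assert nmda_gate(vi, params) == pytest.approx(gate_oracle(vi, params), rel=1e-12)
    t = rng.uniform(-20.0, 400.0, 1000)
    for ti in t:
        assert double_exp_kernel(ti, 50.0, 5.0) == pytest.approx(
            kernel_oracle(ti, 50.0, 5.0), rel=1e-12, abs=1e-300)


# ---------------------------------------------------------------- sigmoid


@pytest.mark.parametrize("x, beta, expected", [
    (0.0, 80.0, 0.5),
    (0.1, 80.0, 0.9996646498695336),     # e^8/(1+e^8)
    (-0.1, 80.0, 1.0 - 0.9996646498695336),
])
def test_sigmoid_examples(x, beta, expected):
    assert sigmoid(x, beta) == pytest.approx(expected, rel=1e-9)


@given(x=st.floats(-2.0, 2.0), beta=st.floats(1.0, 200.0))
def test_sigmoid_bounded_and_complementary(x, beta):
    s = sigmoid(x, beta)
    assert 0.0 < s < 1.0 or (s in (0.0, 1.0) and abs(beta * x) > 30)
    assert sigmoid(x, beta) + sigmoid(-x, beta) == pytest.approx(1.0, abs=1e-15)


def test_sigmoid_rejects_non_finite():
    with pytest.raises(DomainError):
        sigmoid(float("nan"), 80.0)
    with pytest.raises(DomainError):
        sigmoid(0.1, float("inf"))


# ---------------------------------------------------------------- omega


def test_omega_examples(params):
    assert omega(0.0, params) == pytest.approx(1.0, abs=1e-10)
    assert omega(0.45, params) == pytest.approx(0.001676750652332304, rel=1e-9)
    assert omega(10.0, params) == pytest.approx(4.0, abs=1e-10)


def test_omega_range_and_ltd_dip(params):
    ca = np.linspace(0.0, 100.0, 5000)
    w = omega(ca, params)
    assert np.all(w > -0.01) and np.all(w <= 4.0)
    # the LTD dip: omega < 1 strictly between alpha1+3/beta1 and alpha2-3/beta2
    lo = params.alpha1 + 3.0 / params.beta1
    hi = params.alpha2 - 3.0 / params.beta2
    dip = (ca > lo) & (ca < hi)
    assert dip.any() and np.all(w[dip] < 1.0)


def test_omega_rejects_negative_calcium(params):
    with pytest.raises(DomainError, match="sign bug"):
        omega(-0.1, params)


# ---------------------------------------------------------------- eta


def test_eta_examples_source_learning_rate(source_params):
    # with p2 = p1*1e-4 the rate spans 1e-4 ... 1 s^-1
    assert eta(0.0, source_params) == pytest.approx(1.0 / 10001.0, rel=1e-12)
    assert eta(0.5, source_params) == pytest.approx(0.5555753077640995, rel=1e-12)


@pytest.mark.parametrize("fixture", ["params", "source_params"])
def test_eta_increasing_and_bounded(fixture, request):
    p = request.getfixturevalue(fixture)
    ca = np.linspace(0.0, 5.0, 500)
    e = eta(ca, p)
    assert np.all(np.diff(e) > 0), "eta must be strictly increasing in calcium"
    assert np.all(e > 0) and np.all(e < 1.0 / p.p4)
    assert eta(1e6, p) == pytest.approx(1.0 / p.p4, rel=1e-6)


def test_eta_rejects_negative_calcium(params):
    with pytest.raises(DomainError):
        eta(-1e-9, params)


# ---------------------------------------------------------------- NMDA gate


def test_gate_vanishes_at_reversal_potential(params):
    assert nmda_gate(params.v_r, params) == 0.0


def test_gate_printed_magnitude_examples():
    # audit variant with the conductance magnitude exactly as printed
    p = ModelParams(g_nmda=1.0 / 140.0)
    assert nmda_gate(-65.0, p) == pytest.approx(0.04155460694440536, rel=1e-12)
    assert nmda_gate(0.0, p) == pytest.approx(0.362691466083151, rel=1e-12)


def test_gate_default_conductance_examples(params):
    assert nmda_gate(-65.0, params) == pytest.approx(0.011635289944433502, rel=1e-12)
    assert nmda_gate(0.0, params) == pytest.approx(0.1015536105032823, rel=1e-12)


def test_gate_nonnegative_and_decreasing_near_reversal(params):
    v = np.linspace(-100.0, 130.0, 2000)
    g = nmda_gate(v, params)
    assert np.all(g >= 0.0)
    near = v > 60.0
    assert np.all(np.diff(g[near]) < 0), "gate must fall toward the reversal potential"


def test_gate_literal_sign_flag_negates(params):
    flipped = params.replace(literal_nmda_sign=True)
    v = np.linspace(-90.0, 120.0, 50)
    np.testing.assert_allclose(nmda_gate(v, flipped), -nmda_gate(v, params), rtol=1e-15)


# ---------------------------------------------------------------- PSP kernel


def test_kernel_zero_before_and_at_event():
    assert double_exp_kernel(0.0, 50.0, 5.0) == 0.0
    assert double_exp_kernel(-5.0, 50.0, 5.0) == 0.0


def test_kernel_peak_location_and_value():
    t_star = 50.0 * 5.0 * math.log(10.0) / 45.0  # 12.792 ms
    peak = double_exp_kernel(t_star, 50.0, 5.0)
    assert peak == pytest.approx(0.6968373144130144, rel=1e-12)
    t = np.linspace(0.0, 400.0, 8000)
    k = double_exp_kernel(t, 50.0, 5.0)
    assert k.max() <= peak + 1e-12
    # single interior maximum: derivative changes sign exactly once
    assert np.sum(np.diff(np.sign(np.diff(k))) != 0) == 1


def test_kernel_rejects_bad_time_constants():
    with pytest.raises(ConfigurationError):
        double_exp_kernel(1.0, 5.0, 50.0)
    with pytest.raises(ConfigurationError):
        double_exp_kernel(1.0, 5.0, 5.0)


# ---------------------------------------------------------------- params


def test_default_parameters_are_consistent(params):
    assert params.i_f + params.i_s == 1.0
    assert params.tau2 < params.tau1
    assert params.tau_f < params.tau_s
    assert params.alpha1 < params.alpha2
    assert 0 < params.p0 <= 1
    assert params.tau_ca == 80.0 and params.s == 20.0


@pytest.mark.parametrize("bad", [
    {"tau2": 60.0},            # PSP kernel order violated
    {"tau_f": 300.0},          # NMDA kernel order violated
    {"alpha1": 0.6},           # omega thresholds out of order
    {"p0": 0.0},
    {"tau_ca": -1.0},
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ConfigurationError):
        ModelParams(**bad)


def test_unknown_parameter_named_in_error():
    with pytest.raises(ConfigurationError, match="tua_ca"):
        ModelParams.from_dict({"tua_ca": 80.0})
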