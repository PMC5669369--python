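import numpy as np
import pytest

from tadsim import default_params, find_fixed_points
from tadsim.dynamics import RHS, effective_tau, sensory_rhs_single, sigmoid, struggle_gate
from tadsim.params import CHANNEL_NAMES, N_STATE, mirror_permutation


def test_sigmoid_midpoint_and_saturation():
    # pure logistic: half of maximum at the threshold
    assert sigmoid(3.0, 2.0, 3.0, zero_at_zero=False) == pytest.approx(0.5)
    # saturation approached for large drives
    assert sigmoid(100.0, 2.0, 3.0, zero_at_zero=False) == pytest.approx(1.0)
    # hand-evaluated logistic value before the zero-input shift:
    # 1/(1+exp(-2*(4.2-3))) = 0.91683...
    assert sigmoid(4.2, 2.0, 3.0, zero_at_zero=False) == pytest.approx(0.916827, abs=1e-5)


def test_sigmoid_zero_input_is_zero_and_nonnegative():
    assert sigmoid(0.0, 2.0, 3.0) == 0.0
    assert np.all(sigmoid(np.linspace(-10, 10, 101), 2.0, 3.0) >= 0.0)


@pytest.mark.parametrize(
    "x9,x10,mode,expected",
    [
        (0.4, 0.4, "heaviside_product", 1.0),   # both integrators active
        (0.4, 0.4, "literal_sign", 1.0),
        (0.4, 0.1, "literal_sign", -1.0),
        (0.4, 0.1, "heaviside_product", 0.0),
        (0.1, 0.1, "heaviside_product", 0.0),   # rest: gate off
        (0.1, 0.1, "literal_sign", 1.0),        # rest: literal product is +1
    ],
)
def test_struggle_gate(x9, x10, mode, expected):
    assert struggle_gate(x9, x10, 0.25, mode) == expected


def test_struggle_gate_rejects_unknown_mode():
    with pytest.raises(ValueError):
        struggle_gate(0.1, 0.1, 0.25, "nonsense")


def test_effective_tau_modulation():
    assert effective_tau(2.0, 0.0, 0.5) == pytest.approx(2.0)  # no dimming
    taus = effective_tau(2.0, np.linspace(0, 1, 20), 0.5)
    assert np.all(np.diff(taus) < 0)  # dimming activity shortens tau
    assert np.all(taus > 0)
    with pytest.raises(ValueError):
        effective_tau(2.0, 0.5, -1.0)


def test_sensory_rhs_bistable_operating_point():
    # the 1-D sensory equation at a=6, P=1.2, b=2, theta=3 has a low and a
    # high stable state; the rhs vanishes at the fixed-point-solver roots
    fps = find_fixed_points(6.0, 1.2, 2.0, 3.0, 1.0)
    assert fps.n == 3
    assert fps.stability == ["stable", "unstable", "stable"]
    assert fps.stable_roots[1] == pytest.approx(0.468, abs=0.01)
    for r in fps.roots:
        assert abs(sensory_rhs_single(r, 6.0, 1.2, 2.0, 3.0)) < 1e-10


def test_sensory_rhs_upper_bound_is_repelling():
    # at X = k the shunting term vanishes and the derivative is -k/tau < 0
    assert sensory_rhs_single(1.0, 6.0, 5.0, 2.0, 3.0, k=1.0) == pytest.approx(-1.0)


def test_rest_is_near_equilibrium(params):
    rhs = RHS(params)
    from tadsim.simulate import rest_state

    x = rest_state(params)
    dx = rhs(x, params.baseline_inputs(), np.zeros(10))
    assert np.max(np.abs(dx)) < 1e-4


def test_assemble_rhs_mirror_symmetry(params):
    """Swapping left/right state and input channels commutes with the rhs."""
    rhs = RHS(params)
    perm = mirror_permutation()
    rng = np.random.default_rng(7)
    for _ in range(25):
        x = rng.uniform(0.0, 0.5, N_STATE)
        ext = params.baseline_inputs() + rng.uniform(-0.2, 0.6, N_STATE)
        noise = rng.normal(0.0, 0.1, 10)
        d1 = rhs(x[perm], ext[perm], noise[perm[:10]])
        d2 = rhs(x, ext, noise)[perm]
        np.testing.assert_allclose(d1, d2, atol=1e-12)


def test_rhs_is_deterministic(params):
    rhs = RHS(params)
    x = np.full(N_STATE, 0.2)
    ext = params.baseline_inputs()
    d1 = rhs(x.copy(), ext.copy(), np.zeros(10))
    d2 = rhs(x.copy(), ext.copy(), np.zeros(10))
    np.testing.assert_array_equal(d1, d2)


def test_rhs_flags_nonfinite_input(params):
    rhs = RHS(params)
    x = np.zeros(N_STATE)
    x[3] = np.nan
    with pytest.raises((FloatingPointError, ValueError)):
        rhs(x, params.baseline_inputs(), np.zeros(10))


def test_channel_names_align_with_populations():
    # P channels feed sensory populations, Q swim, R struggle, M motor
    assert CHANNEL_NAMES[0] == "P1" and CHANNEL_NAMES[9] == "P10"
    assert CHANNEL_NAMES[10] == "Q1" and CHANNEL_NAMES[15] == "Q6"
    assert CHANNEL_NAMES[16] == "R1" and CHANNEL_NAMES[21] == "R6"
    assert CHANNEL_NAMES[22] == "M1" and CHANNEL_NAMES[23] == "M2"
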