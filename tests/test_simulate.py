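import numpy as np
import pytest

from tadsim import Scenario, Event, compile_scenario, integrate, rest_state
from tadsim.params import N_STATE
from tadsim.simulate import NoiseProcess, count_switches, simulate_single_pathway

from conftest import zero_noise


def test_noise_zero_sigma_is_identically_zero():
    n = NoiseProcess(np.zeros(3), 1.0, seed=42)
    for t in (0.0, 0.5, 99.9):
        np.testing.assert_array_equal(n(t), np.zeros(3))


def test_noise_is_reproducible_and_piecewise_constant():
    a = NoiseProcess(np.full(4, 0.3), 1.0, seed=11)
    b = NoiseProcess(np.full(4, 0.3), 1.0, seed=11)
    np.testing.assert_array_equal(a(17.2), b(17.2))
    # constant within a resample interval, fresh across intervals
    np.testing.assert_array_equal(a(5.0), a(5.999))
    assert not np.array_equal(a(5.0), a(6.0))


def test_noise_moments_match_specification():
    """Sample mean ~0 and SD ~sigma over 1e5 resample intervals."""
    sigma = 0.2
    n = NoiseProcess(np.array([sigma]), 1.0, seed=3)
    vals = np.array([n(float(i))[0] for i in range(100_000)])
    assert abs(vals.mean()) < 0.01 * sigma * 5
    assert vals.std() == pytest.approx(sigma, rel=0.01)


def test_noise_rejects_negative_sigma():
    with pytest.raises(ValueError):
        NoiseProcess(np.array([-0.1]))


def test_integration_is_deterministic(params):
    sc = Scenario(events=[Event(kind="touch_trunk", side="left",
                                t_start=50.0, t_end=120.0)], duration=400.0)
    stim = compile_scenario(sc, params)
    r1 = integrate(params, stim, dt=0.1, seed=5)
    r2 = integrate(params, stim, dt=0.1, seed=5)
    np.testing.assert_array_equal(r1.y, r2.y)


def test_unstimulated_rest_is_stationary(params):
    stim = compile_scenario(Scenario(events=[], duration=2000.0), params)
    res = integrate(params, stim, dt=0.1, noise=zero_noise(),
                    controllers_enabled=False)
    drift = np.abs(res.y - res.y[0]).max()
    assert drift < 1e-6


def test_forward_invariance_of_activity_box(params):
    """Trajectories started anywhere in [0, k]^24 stay in [0, k]^24."""
    rng = np.random.default_rng(0)
    stim = compile_scenario(Scenario(events=[], duration=120.0), params)
    for trial in range(100):
        x0 = rng.uniform(0.0, 1.0, N_STATE)
        res = integrate(params, stim, dt=0.1, noise=zero_noise(),
                        controllers_enabled=False, initial=x0, record_every=20)
        assert res.y.min() >= -1e-9
        assert res.y.max() <= 1.0 + 1e-9


def test_rejects_too_coarse_step(params):
    stim = compile_scenario(Scenario(events=[], duration=10.0), params)
    with pytest.raises(ValueError):
        integrate(params, stim, dt=1.0)


def test_single_pathway_simulator_matches_fixed_point(params):
    """Without noise the 1-D pathway settles onto its stable root."""
    from tadsim import find_fixed_points

    tr = simulate_single_pathway(6.0, 1.2, 2.0, 3.0, sigma=0.0,
                                 duration=200.0, x0=0.0, seeds=[0])
    low = find_fixed_points(6.0, 1.2, 2.0, 3.0).roots[0]
    assert tr[0, -1] == pytest.approx(low, abs=1e-6)
    tr_hi = simulate_single_pathway(6.0, 1.2, 2.0, 3.0, sigma=0.0,
                                    duration=200.0, x0=0.9, seeds=[0])
    high = find_fixed_points(6.0, 1.2, 2.0, 3.0).roots[2]
    assert tr_hi[0, -1] == pytest.approx(high, abs=1e-6)


def test_count_switches():
    trace = np.array([0.1, 0.1, 0.5, 0.6, 0.1, 0.05, 0.7])
    assert count_switches(trace, 0.3) == 3
    assert count_switches(np.full(10, 0.1), 0.3) == 0


def test_spontaneous_start_after_ramp_delay(params):
    """With an accelerated ramp, rest ends in a spontaneous swim bout whose
    onset delay tracks (threshold distance)/(ramp slope)."""
    p = params
    p.sensory.sigma = np.zeros(10)  # isolate the deterministic ramp mechanism
    # the ramp ignites swimming once the xIN low branch has risen enough to
    # push the dIN drive over its fold: an input distance of about 0.085
    slope = 0.085 / 1500.0  # -> delay on the order of 1.5 s
    p.controller.ramp_slope_range = (slope, slope)
    stim = compile_scenario(Scenario(events=[], duration=4000.0), p)
    onsets = []
    for seed in (1, 2, 3):
        res = integrate(p, stim, dt=0.1, seed=seed, controllers_enabled=True)
        starts = [e["t"] for e in res.controller_log if e["action"] == "swim_start"]
        assert starts, "no spontaneous swim start observed"
        onsets.append(starts[0])
        u = res.trace("mn_L")
        assert np.abs(u - u[0]).max() > 0.05  # the bout actually swims
    for t0 in onsets:
        assert 1000.0 < t0 < 2600.0


def test_no_spontaneous_start_with_zero_ramp(params):
    p = params
    p.controller.ramp_slope_range = (0.0, 0.0)
    stim = compile_scenario(Scenario(events=[], duration=3000.0), p)
    res = integrate(p, stim, dt=0.1, seed=1, controllers_enabled=True)
    assert not [e for e in res.controller_log if e["action"] == "swim_start"]


def test_spontaneous_stop_pulse_ends_the_bout(params):
    """A short maximum-bout duration triggers the stop pulse and a return
    to rest (the model's account of spontaneous swim termination)."""
    p = params
    p.controller.max_swim_range = (1200.0, 1200.0)
    sc = Scenario(events=[Event(kind="touch_trunk", side="left",
                                t_start=200.0, t_end=350.0)], duration=4000.0)
    res = integrate(p, compile_scenario(sc, p), dt=0.1, seed=2,
                    controllers_enabled=True)
    actions = [e["action"] for e in res.controller_log]
    assert "spontaneous_stop_pulse" in actions
    t = res.t
    u = res.trace("mn_L")
    tail = t > 3200.0
    assert np.abs(u[tail] - u[0]).max() < 0.02  # back at rest
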