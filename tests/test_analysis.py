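import numpy as np
import pytest

from tadsim import (
    NoBurstStructure,
    NoOscillation,
    classify,
    envelope_periods,
    estimate_period,
    estimate_period_spectral,
    phase_shift,
    transition_latency,
    antiphase_index,
)
from tadsim.simulate import SimulationResult


def _sine(period_ms, duration_ms=2000.0, dt=0.1, phase=0.0, amp=1.0):
    t = np.arange(0.0, duration_ms, dt)
    return t, amp * np.sin(2 * np.pi * (t / period_ms) + phase)


def test_estimate_period_on_known_sinusoid():
    t, x = _sine(50.0)
    assert estimate_period(t, x) == pytest.approx(50.0, abs=0.5)
    assert estimate_period_spectral(t, x) == pytest.approx(50.0, rel=0.03)


def test_constant_trace_signals_no_oscillation():
    t = np.arange(0, 500.0, 0.1)
    with pytest.raises(NoOscillation):
        estimate_period(t, np.full_like(t, 0.3))


def test_phase_shift_of_identical_and_delayed_traces():
    t, x = _sine(50.0)
    assert phase_shift(t, x, x) == pytest.approx(0.0, abs=0.01)
    _, y = _sine(50.0, phase=np.pi)  # delayed by half a period
    assert phase_shift(t, x, y) == pytest.approx(0.5, abs=0.01)
    _, q = _sine(50.0, phase=-2 * np.pi * 0.1)  # lags by 10% of the period
    assert phase_shift(t, x, q) == pytest.approx(0.1, abs=0.01)


def test_phase_shift_rejects_mismatched_periods():
    t, x = _sine(50.0)
    _, y = _sine(70.0)
    with pytest.raises(ValueError):
        phase_shift(t, x, y)


def test_envelope_periods_on_synthetic_am_signal():
    """200 Hz carrier under a 130 ms envelope -> (5 ms, 130 ms)."""
    t = np.arange(0.0, 2000.0, 0.05)
    carrier = np.sin(2 * np.pi * t / 5.0)
    env = 0.55 + 0.45 * np.sin(2 * np.pi * t / 130.0)
    x = env * (0.5 + 0.5 * carrier)
    s = envelope_periods(t, x)
    assert s.fast_period_ms == pytest.approx(5.0, rel=0.05)
    assert s.slow_period_ms == pytest.approx(130.0, rel=0.05)
    assert s.slow_period_ms > s.fast_period_ms


def test_unmodulated_oscillation_signals_no_burst_structure():
    t, x = _sine(50.0)
    with pytest.raises(NoBurstStructure):
        envelope_periods(t, 0.5 + 0.5 * x)


def test_antiphase_index_sign():
    t, x = _sine(50.0)
    _, y = _sine(50.0, phase=np.pi)
    assert antiphase_index(t, x, y) < -0.9
    assert antiphase_index(t, x, x) > 0.9


def test_transition_latency_of_instantly_regular_signal():
    t, x = _sine(50.0, duration_ms=1000.0)
    assert transition_latency(t, x, 0.0) < 55.0  # first cycle already regular


def _fake_result(t, uL, uR):
    from tadsim import default_params
    from tadsim.params import N_STATE, state_index

    y = np.zeros((len(t), N_STATE))
    y[:, state_index("mn_L")] = uL
    y[:, state_index("mn_R")] = uR
    return SimulationResult(t=t, y=y, params=default_params())


def test_classify_all_zero_trajectory_is_rest():
    t = np.arange(0.0, 2000.0, 0.5)
    eth = classify(_fake_result(t, np.zeros_like(t), np.zeros_like(t)))
    assert eth.labels() == ["rest"]


def test_classify_synthetic_swim_and_struggle_segments():
    t = np.arange(0.0, 3000.0, 0.25)
    u = np.zeros_like(t)
    swim = (t >= 600) & (t < 1800)
    u[swim] = 0.06 * (1 + np.sin(2 * np.pi * t[swim] / 50.0))
    strug = t >= 1800
    u[strug] = 0.2 * (1 + np.sin(2 * np.pi * t[strug] / 5.0)) * \
        (0.55 + 0.45 * np.sin(2 * np.pi * t[strug] / 130.0))
    eth = classify(_fake_result(t, u, u))
    assert eth.label_at(100.0) == "rest"
    assert eth.label_at(1200.0) == "swim"
    assert eth.label_at(2500.0) == "struggle"


def test_classification_invariant_under_amplitude_rescaling():
    """Thresholds are relative: doubling all motor amplitudes changes nothing."""
    t = np.arange(0.0, 3000.0, 0.25)
    u = np.zeros_like(t)
    swim = (t >= 600) & (t < 1800)
    u[swim] = 0.06 * (1 + np.sin(2 * np.pi * t[swim] / 50.0))
    e1 = classify(_fake_result(t, u, u))
    e2 = classify(_fake_result(t, 2 * u, 2 * u), swim_amplitude=2 * 0.115)
    assert e1.intervals == e2.intervals


def test_classify_rejects_too_short_frame():
    t = np.arange(0.0, 1000.0, 0.5)
    with pytest.raises(ValueError):
        classify(_fake_result(t, np.zeros_like(t), np.zeros_like(t)), frame_ms=60.0)
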