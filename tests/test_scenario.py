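import numpy as np
import pytest

from tadsim import (
    Event,
    Scenario,
    builtin_scenario,
    builtin_table2,
    compile_scenario,
    read_scenario,
    struggle_protocol,
    swim_protocol,
    write_scenario,
)
from tadsim.params import CHANNEL_NAMES, mirror_permutation

CH = {name: i for i, name in enumerate(CHANNEL_NAMES)}


def test_event_validation():
    with pytest.raises(ValueError):
        Event(kind="tickle", t_start=0, t_end=10)
    with pytest.raises(ValueError):
        Event(kind="touch_trunk", t_start=10, t_end=10)
    with pytest.raises(ValueError):
        Event(kind="touch_trunk", t_start=0, t_end=10, side="middle")
    with pytest.raises(ValueError):
        Scenario(events=[Event(kind="light_dim", t_start=0, t_end=500)], duration=100)


def test_empty_scenario_compiles_to_baselines(params):
    trace = compile_scenario(Scenario(events=[], duration=1000.0), params)
    base = params.baseline_inputs()
    for t in (0.0, 137.0, 999.0):
        np.testing.assert_array_equal(trace(t), base)


def test_trunk_touch_drives_both_sides_with_delay(params):
    """A left trunk touch over 200-350 ms drives the left TS channel at 0.5
    and the right TS channel at 0.1 from 230 ms (30 ms conduction delay)."""
    sc = Scenario(events=[Event(kind="touch_trunk", side="left",
                                t_start=200.0, t_end=350.0)], duration=1000.0)
    trace = compile_scenario(sc, params)
    base = params.baseline_inputs()
    assert trace(210.0)[CH["P1"]] == pytest.approx(base[CH["P1"]] + 0.5)
    assert trace(210.0)[CH["P2"]] == pytest.approx(base[CH["P2"]])
    assert trace(240.0)[CH["P2"]] == pytest.approx(base[CH["P2"]] + 0.1)
    assert trace(360.0)[CH["P1"]] == pytest.approx(base[CH["P1"]])
    # between-event times are pure baseline
    np.testing.assert_array_equal(trace(500.0), base)


def test_predator_attack_windows(params):
    """Attack over 2000-3000 ms: dIN channels driven for the whole event
    (right staggered by 30 ms), dINr channels from 2150 ms."""
    sc = Scenario(events=[Event(kind="predator_attack", side="both",
                                t_start=2000.0, t_end=3000.0)], duration=3500.0)
    trace = compile_scenario(sc, params)
    base = params.baseline_inputs()
    assert trace(2010.0)[CH["Q1"]] > base[CH["Q1"]]
    assert trace(2010.0)[CH["Q4"]] == pytest.approx(base[CH["Q4"]])
    assert trace(2040.0)[CH["Q4"]] > base[CH["Q4"]]
    assert trace(2100.0)[CH["R1"]] == pytest.approx(base[CH["R1"]])
    assert trace(2160.0)[CH["R1"]] > base[CH["R1"]]
    assert trace(2160.0)[CH["R4"]] > base[CH["R4"]]
    assert trace(3010.0)[CH["R1"]] == pytest.approx(base[CH["R1"]])


def test_short_touch_never_reaches_struggle_channels(params):
    """Stimulation shorter than the dINr delay recruits no struggle input."""
    for dur in (50.0, 100.0, 149.0):
        sc = Scenario(events=[Event(kind="predator_attack", side="left",
                                    t_start=100.0, t_end=100.0 + dur)], duration=1000.0)
        trace = compile_scenario(sc, params)
        assert all(ch not in [s[0] for s in trace.segments]
                   for ch in (CH["R1"], CH["R4"]))
    sc = Scenario(events=[Event(kind="predator_attack", side="left",
                                t_start=100.0, t_end=260.0)], duration=1000.0)
    trace = compile_scenario(sc, params)
    assert CH["R1"] in [s[0] for s in trace.segments]


def test_builtin_table2_timings():
    sc = builtin_table2()
    assert len(sc.events) == 4
    assert sc.duration == 7000.0
    kinds = [e.kind for e in sc.events]
    assert kinds == ["touch_trunk", "light_dim", "predator_attack", "press_head"]
    press = sc.events[-1]
    assert (press.t_start, press.t_end) == (6500.0, 6600.0)
    touch = sc.events[0]
    assert (touch.t_start, touch.t_end, touch.side) == (200.0, 350.0, "left")


def test_swim_protocol_reproduces_reference_drive(params):
    """Left dIN input 1.37 over 100-250 ms, right 1.3 over 130-250 ms,
    both returning to the background value 0.8."""
    trace = compile_scenario(swim_protocol(), params)
    assert trace(150.0)[CH["Q1"]] == pytest.approx(1.37)
    assert trace(120.0)[CH["Q4"]] == pytest.approx(0.8)
    assert trace(150.0)[CH["Q4"]] == pytest.approx(1.3)
    assert trace(300.0)[CH["Q1"]] == pytest.approx(0.8)
    assert trace(300.0)[CH["Q4"]] == pytest.approx(0.8)
    # a 150 ms stimulus never recruits the struggle channels
    assert trace(200.0)[CH["R1"]] == pytest.approx(params.struggle.R[0])


def test_struggle_protocol_windows(params):
    trace = compile_scenario(struggle_protocol(), params)
    base = params.baseline_inputs()
    assert trace(1010.0)[CH["Q1"]] > base[CH["Q1"]]
    assert trace(1010.0)[CH["Q4"]] == pytest.approx(base[CH["Q4"]])
    assert trace(1040.0)[CH["Q4"]] > base[CH["Q4"]]
    assert trace(1100.0)[CH["R1"]] == pytest.approx(base[CH["R1"]])
    assert trace(1200.0)[CH["R1"]] > base[CH["R1"]]
    assert trace(2010.0)[CH["R1"]] == pytest.approx(base[CH["R1"]])


def test_compilation_is_pure(params):
    sc = builtin_table2()
    t1 = compile_scenario(sc, params)
    t2 = compile_scenario(sc, params)
    grid = np.linspace(0, sc.duration - 1, 200)
    np.testing.assert_array_equal(t1.grid(grid), t2.grid(grid))


def test_mirrored_scenario_equals_channel_swapped_trace(params):
    sc = Scenario(
        events=[
            Event(kind="touch_trunk", side="left", t_start=100.0, t_end=250.0),
            Event(kind="touch_head", side="right", t_start=400.0, t_end=500.0),
        ],
        duration=1000.0,
    )
    tm = compile_scenario(sc.mirrored(), params)
    ts = compile_scenario(sc, params)
    perm = mirror_permutation()
    grid = np.linspace(0, 999, 333)
    np.testing.assert_allclose(tm.grid(grid), ts.grid(grid)[:, perm], atol=1e-12)


def test_scenario_file_round_trip(tmp_path):
    sc = builtin_table2()
    path = tmp_path / "sc.yaml"
    write_scenario(sc, path)
    back = read_scenario(path)
    assert back.duration == sc.duration
    assert len(back.events) == len(sc.events)
    for a, b in zip(back.events, sc.events):
        assert (a.kind, a.side, a.t_start, a.t_end) == (b.kind, b.side, b.t_start, b.t_end)


def test_unknown_builtin_raises():
    with pytest.raises(KeyError):
        builtin_scenario("backflip")
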