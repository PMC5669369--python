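"""Environmental scenarios and their compilation into stimulus traces.

A :class:`Scenario` is an ordered list of timed environmental events (trunk
touch, head touch, light dimming, head press, predator attack).  The
compiler turns it into a :class:`StimulusTrace`: a piecewise-constant
external-input function covering every input channel of the model
(P1..P10, Q1..Q6, R1..R6, M1, M2).  Overlapping contributions add.

Event-to-input semantics:

* ``touch_trunk`` / ``touch_head`` drive the TS / TH channel on the
  stimulated side for the whole event, with a weaker contralateral input
  starting after a short conduction delay (defaults 0.5 / 0.1 / 30 ms).
* ``light_dim`` and ``press_head`` drive both LD / PH channels.
* ``predator_attack`` is a prolonged bilateral stimulation: the dIN
  channels are driven for the whole event (contralateral side staggered by
  30 ms) and the dINr channels from 150 ms after dIN onset.  The 150 ms
  dINr delay is what separates swimming from struggling: brief touches
  never reach the struggle network, prolonged attacks always do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .params import CHANNEL_NAMES, ModelParams

__all__ = [
    "Event",
    "Scenario",
    "StimulusTrace",
    "EVENT_KINDS",
    "default_event_magnitudes",
    "compile_scenario",
    "builtin_table2",
    "swim_protocol",
    "struggle_protocol",
    "builtin_scenario",
    "read_scenario",
    "write_scenario",
]

EVENT_KINDS = ("touch_trunk", "touch_head", "light_dim", "press_head", "predator_attack")
SIDES = ("left", "right", "both")

_CHAN = {name: i for i, name in enumerate(CHANNEL_NAMES)}

# dINr stimulation begins this long after dIN stimulation onset; stimulation
# shorter than this never recruits the struggle network.
DINR_DELAY_MS = 150.0
CONTRA_STAGGER_MS = 30.0


def default_event_magnitudes() -> dict:
    """Per-kind default stimulus magnitudes (input units) and delays (ms)."""
    return {
        "touch_trunk": {"primary": 0.5, "contralateral": 0.1, "delay": 30.0},
        "touch_head": {"primary": 0.5, "contralateral": 0.1, "delay": 30.0},
        "light_dim": {"primary": 0.8},
        "press_head": {"primary": 0.8},
        "predator_attack": {
            "dIN_primary": 0.57,
            "dIN_contralateral": 0.5,
            "dINr": 1.4,
        },
    }


@dataclass
class Event:
    """One timed environmental event."""

    kind: str
    t_start: float
    t_end: float
    side: str = "both"
    magnitude_primary: float | None = None
    magnitude_contralateral: float | None = None
    contralateral_delay: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if not (self.t_start < self.t_end):
            raise ValueError(f"event must satisfy t_start < t_end, got [{self.t_start}, {self.t_end}]")


@dataclass
class Scenario:
    """Ordered list of events plus the total simulated duration (ms)."""

    events: list
    duration: float
    name: str = "custom"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.events = [e if isinstance(e, Event) else Event(**e) for e in self.events]
        if self.events and self.duration < max(e.t_end for e in self.events):
            raise ValueError("scenario duration must cover every event")

    def mirrored(self) -> "Scenario":
        """Scenario with every event's side reflected left<->right."""
        flip = {"left": "right", "right": "left", "both": "both"}
        evs = [
            Event(kind=e.kind, t_start=e.t_start, t_end=e.t_end, side=flip[e.side],
                  magnitude_primary=e.magnitude_primary,
                  magnitude_contralateral=e.magnitude_contralateral,
                  contralateral_delay=e.contralateral_delay)
            for e in self.events
        ]
        return Scenario(events=evs, duration=self.duration,
                        name=self.name + "_mirrored", seed=self.seed)


class StimulusTrace:
    """Piecewise-constant external-input function of time.

    Stores the per-channel baselines plus a list of additive segments
    ``(channel index, t0, t1, delta)``.  ``__call__`` evaluates the full
    24-channel input vector at time ``t``; :meth:`grid` pre-evaluates on a
    regular time grid for the integrator.
    """

    def __init__(self, baseline: np.ndarray, duration: float):
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != (len(CHANNEL_NAMES),):
            raise ValueError("baseline must have one entry per input channel")
        self.baseline = baseline
        self.duration = float(duration)
        self.segments: list[tuple[int, float, float, float]] = []

    def add(self, channel: str, t0: float, t1: float, delta: float) -> None:
        if channel not in _CHAN:
            raise KeyError(f"unknown input channel {channel!r}")
        if t1 > self.duration + 1e-9:
            raise ValueError(f"segment on {channel} ends at {t1} ms, beyond duration {self.duration} ms")
        self.segments.append((_CHAN[channel], float(t0), float(t1), float(delta)))

    def __call__(self, t: float) -> np.ndarray:
        out = self.baseline.copy()
        for ch, t0, t1, delta in self.segments:
            if t0 <= t < t1:
                out[ch] += delta
        return out

    def grid(self, t: np.ndarray) -> np.ndarray:
        """Evaluate on a time grid; returns array (len(t), n_channels)."""
        out = np.tile(self.baseline, (len(t), 1))
        for ch, t0, t1, delta in self.segments:
            mask = (t >= t0) & (t < t1)
            out[mask, ch] += delta
        return out

    def mirrored(self) -> "StimulusTrace":
        """Trace with every left/right channel pair swapped."""
        # channels align with populations, so the state mirror permutation applies
        from .params import mirror_permutation

        perm = mirror_permutation()
        tr = StimulusTrace(self.baseline[perm], self.duration)
        inv = np.argsort(perm)
        for ch, t0, t1, delta in self.segments:
            tr.segments.append((int(inv[ch]), t0, t1, delta))
        return tr


def _sides(event: Event) -> tuple[list[str], list[str]]:
    """(primary sides, contralateral sides) for an event."""
    if event.side == "both":
        return ["left", "right"], []
    other = "right" if event.side == "left" else "left"
    return [event.side], [other]


_TOUCH_CHANNEL = {"touch_trunk": {"left": "P1", "right": "P2"},
                  "touch_head": {"left": "P3", "right": "P4"}}


def compile_scenario(scenario: Scenario, params: ModelParams) -> StimulusTrace:
    """Compile a scenario into a stimulus trace over the model's channels.

    Baselines come from the parameter set; per-kind default magnitudes from
    ``params.event_magnitudes`` (falling back to the package defaults) and
    can be overridden per event.  Compilation is pure: the same scenario and
    parameters always produce an identical trace.
    """
    mags = default_event_magnitudes()
    for kind, d in (params.event_magnitudes or {}).items():
        mags.setdefault(kind, {}).update(d)

    trace = StimulusTrace(params.baseline_inputs(), scenario.duration)
    for ev in scenario.events:
        m = mags[ev.kind]
        if ev.kind in ("touch_trunk", "touch_head"):
            prim = ev.magnitude_primary if ev.magnitude_primary is not None else m["primary"]
            contra = (ev.magnitude_contralateral
                      if ev.magnitude_contralateral is not None else m["contralateral"])
            delay = ev.contralateral_delay if ev.contralateral_delay is not None else m["delay"]
            primary, contralateral = _sides(ev)
            for s in primary:
                trace.add(_TOUCH_CHANNEL[ev.kind][s], ev.t_start, ev.t_end, prim)
            for s in contralateral:
                t0 = min(ev.t_start + delay, ev.t_end)
                if t0 < ev.t_end:
                    trace.add(_TOUCH_CHANNEL[ev.kind][s], t0, ev.t_end, contra)
        elif ev.kind == "light_dim":
            amp = ev.magnitude_primary if ev.magnitude_primary is not None else m["primary"]
            trace.add("P5", ev.t_start, ev.t_end, amp)
            trace.add("P6", ev.t_start, ev.t_end, amp)
        elif ev.kind == "press_head":
            amp = ev.magnitude_primary if ev.magnitude_primary is not None else m["primary"]
            trace.add("P7", ev.t_start, ev.t_end, amp)
            trace.add("P8", ev.t_start, ev.t_end, amp)
        elif ev.kind == "predator_attack":
            # direct drive of the CPG input channels, as in the stimulation
            # protocols: dIN channels for the whole event (staggered), dINr
            # channels only from DINR_DELAY_MS after onset.
            d_prim = m["dIN_primary"]
            d_contra = m["dIN_contralateral"]
            r_amp = m["dINr"]
            first, second = ("left", "right") if ev.side != "right" else ("right", "left")
            q = {"left": "Q1", "right": "Q4"}
            r = {"left": "R1", "right": "R4"}
            trace.add(q[first], ev.t_start, ev.t_end, d_prim)
            t_second = min(ev.t_start + CONTRA_STAGGER_MS, ev.t_end)
            if t_second < ev.t_end:
                trace.add(q[second], t_second, ev.t_end, d_contra)
            t_r = ev.t_start + DINR_DELAY_MS
            if t_r < ev.t_end:
                trace.add(r["left"], t_r, ev.t_end, r_amp)
                trace.add(r["right"], t_r, ev.t_end, r_amp)
    return trace


# ---------------------------------------------------------------------------
# Built-in scenarios: the reference behavioural scenario and the direct
# CPG-stimulation protocols used to characterise swimming and struggling.
# ---------------------------------------------------------------------------

def builtin_table2() -> Scenario:
    """The example scenario: rest, trunk touch, light dimming, predator attack, head press.

    Timings (ms): no events until 200; short touch on the left side 200-350;
    light dimming 1200-1500; predator attack 2000-3000; pressure to the head
    (stop signal) 6500-6600; total duration 7000.
    """
    return Scenario(
        name="table2",
        duration=7000.0,
        events=[
            Event(kind="touch_trunk", side="left", t_start=200.0, t_end=350.0),
            Event(kind="light_dim", side="both", t_start=1200.0, t_end=1500.0),
            Event(kind="predator_attack", side="both", t_start=2000.0, t_end=3000.0),
            Event(kind="press_head", side="both", t_start=6500.0, t_end=6600.0),
        ],
    )


def swim_protocol(duration: float = 2500.0) -> Scenario:
    """Direct dIN stimulation initiating swimming.

    Left dIN input raised to 1.37 over 100-250 ms and right dIN input to
    1.3 over 130-250 ms; both return to the background value 0.8 afterwards
    (the baseline Q1 = Q4 = 0.8 lives in the parameter file).
    """
    return Scenario(
        name="swim_protocol",
        duration=duration,
        events=[
            Event(kind="predator_attack", side="left", t_start=100.0, t_end=250.0,
                  magnitude_primary=None),
        ],
    )


def struggle_protocol(duration: float = 3000.0, from_swimming: bool = False) -> Scenario:
    """Prolonged bilateral stimulation producing struggling.

    dIN channels driven over 1000-2000 ms (right side from 1030 ms) and the
    dINr channels over 1150-2000 ms.  With ``from_swimming`` a swim-starting
    stimulus is prepended so struggling is entered from ongoing swimming.
    """
    events = []
    if from_swimming:
        events.append(Event(kind="predator_attack", side="left", t_start=100.0, t_end=250.0))
    events.append(Event(kind="predator_attack", side="left", t_start=1000.0, t_end=2000.0))
    return Scenario(name="struggle_protocol", duration=duration, events=events)


def builtin_scenario(name: str) -> Scenario:
    builtins = {
        "table2": builtin_table2,
        "swim_protocol": swim_protocol,
        "struggle_protocol": struggle_protocol,
    }
    if name not in builtins:
        raise KeyError(f"unknown builtin scenario {name!r}; choices: {sorted(builtins)}")
    return builtins[name]()


# ---------------------------------------------------------------------------
# Scenario file round trip
# ---------------------------------------------------------------------------

def write_scenario(scenario: Scenario, path: str | Path) -> None:
    d = {
        "name": scenario.name,
        "duration": scenario.duration,
        "seed": scenario.seed,
        "events": [
            {k: v for k, v in asdict(e).items() if v is not None}
            for e in scenario.events
        ],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_scenario(path: str | Path) -> Scenario:
    d = yaml.safe_load(Path(path).read_text())
    return Scenario(
        events=[Event(**e) for e in d.get("events", [])],
        duration=d["duration"],
        name=d.get("name", "custom"),
        seed=d.get("seed"),
    )
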