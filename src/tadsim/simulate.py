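"""Time integration of the full model with noise and behaviour controllers.

Integration is fixed-step classical Runge-Kutta (RK4).  The sensory noise
is piecewise constant: a fresh Gaussian value is drawn for every channel on
each resample interval (default 1 ms, the sensory time unit) and held
within it, so holding it constant across the RK4 stages treats the process
exactly rather than approximating a white-noise SDE.

The spontaneous start/stop machinery of the animal lives in
:class:`Controller`: a slowly rising excitatory ramp onto one xIN
integrator while at rest (spontaneous swim starts), a cap on swim-bout
duration implemented as a brief head-press-like inhibitory pulse
(spontaneous stops), and the post-decision reset that returns the xIN
populations to their low state once locomotion is underway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import RHS, IX_XIN_L, IX_XIN_R
from .params import (
    CHANNEL_NAMES,
    ModelParams,
    N_STATE,
    STATE_NAMES,
    state_index,
)
from .scenario import StimulusTrace

__all__ = [
    "NoiseProcess",
    "Controller",
    "SimulationResult",
    "integrate",
    "rest_state",
    "simulate_single_pathway",
    "count_switches",
]


class NoiseProcess:
    """Piecewise-constant Gaussian noise, one channel per sensory population.

    Values are constant within each resample interval and independent
    ``N(0, sigma_j)`` draws across intervals; a fixed seed reproduces the
    realisation exactly.
    """

    def __init__(self, sigma, resample_ms: float = 1.0, seed: int | None = 0):
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma < 0):
            raise ValueError("noise standard deviations must be non-negative")
        if resample_ms <= 0:
            raise ValueError("resample interval must be positive")
        self.sigma = sigma
        self.resample_ms = float(resample_ms)
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._values: list[np.ndarray] = []

    def _ensure(self, idx: int) -> None:
        while len(self._values) <= idx:
            self._values.append(self._rng.normal(0.0, 1.0, size=self.sigma.shape) * self.sigma)

    def __call__(self, t: float) -> np.ndarray:
        if np.all(self.sigma == 0.0):
            return np.zeros_like(self.sigma)
        idx = int(np.floor(t / self.resample_ms + 1e-12))
        self._ensure(idx)
        return self._values[idx]


@dataclass
class ControllerLogEntry:
    t: float
    action: str


@dataclass
class Controller:
    """Spontaneous start/stop controller and online behaviour flag.

    The flag (``rest`` / ``swimming`` / ``struggling``) is estimated from
    decaying envelopes of the motor and struggle-population activity.  The
    controller only ever *adds* external input (ramp, stop pulse) and resets
    the xIN populations after a locomotor decision; with ``enabled=False``
    it does nothing, leaving the bare dynamical system.
    """

    params: ModelParams
    seed: int | None = 0
    enabled: bool = True
    behaviour: str = "rest"
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        cp = self.params.controller
        self.rng = np.random.default_rng(self.seed)
        self.ramp_value = 0.0
        self.ramp_side = int(self.rng.integers(0, 2))  # 0 = left, 1 = right
        self.ramp_slope = float(self.rng.uniform(*cp.ramp_slope_range))
        self.swim_until = np.inf
        self.swim_started_at = None
        self.stop_pulse_until = -np.inf
        self.motor_env = 0.0
        self.struggle_env = 0.0
        self._u_rest = None
        self._ix_u = [state_index("mn_L"), state_index("mn_R")]
        self._ix_z = [state_index("dINr_L"), state_index("dINr_R")]
        self._ix_ph = [CHANNEL_NAMES.index("P7"), CHANNEL_NAMES.index("P8")]
        self._ix_p_xin = [CHANNEL_NAMES.index("P9"), CHANNEL_NAMES.index("P10")]
        self._xin_low = 0.05  # refined from the rest state on first call

    def _log(self, t: float, action: str) -> None:
        self.log.append(ControllerLogEntry(t=float(t), action=action))

    def step(self, t: float, dt: float, x: np.ndarray, ext: np.ndarray) -> None:
        """Update internal state, mutate ``ext`` in place, possibly clamp xIN."""
        if not self.enabled:
            return
        cp = self.params.controller
        if self._u_rest is None:
            self._u_rest = x[self._ix_u].copy()
            self._xin_low = float(min(x[IX_XIN_L], x[IX_XIN_R]))

        decay = np.exp(-dt / cp.env_decay_ms)
        u_dev = float(np.max(np.abs(x[self._ix_u] - self._u_rest)))
        z_dev = float(np.max(x[self._ix_z]))
        self.motor_env = max(self.motor_env * decay, u_dev)
        self.struggle_env = max(self.struggle_env * decay, z_dev)

        # --- behaviour flag -------------------------------------------------
        if self.struggle_env > cp.struggle_amp_threshold:
            if self.behaviour != "struggling":
                self.behaviour = "struggling"
                self.swim_until = np.inf  # struggling supersedes the swim timer
                self._log(t, "struggle_detected")
        elif self.behaviour == "struggling":
            # struggle network has fallen silent; whatever remains is swim or rest
            self.behaviour = "swimming" if self.motor_env > cp.swim_amp_threshold else "rest"
            if self.behaviour == "swimming":
                self.swim_started_at = t
                self.swim_until = t + float(self.rng.uniform(*cp.max_swim_range))
                self._log(t, "swim_resumed_after_struggle")
            else:
                self._enter_rest(t)
        elif self.behaviour == "rest":
            started = (x[IX_XIN_L] > cp.start_threshold or
                       x[IX_XIN_R] > cp.start_threshold or
                       self.motor_env > cp.swim_amp_threshold)
            if started:
                self.behaviour = "swimming"
                self.swim_started_at = t
                self.swim_until = t + float(self.rng.uniform(*cp.max_swim_range))
                self.ramp_value = 0.0
                self._log(t, "swim_start")
        elif self.behaviour == "swimming":
            # grace period: the CPG needs a few cycles before the motor
            # envelope is informative, so rest detection is deferred
            settled = (self.swim_started_at is not None and
                       t > self.swim_started_at + 400.0)
            if settled and self.motor_env < cp.rest_amp_threshold and t > self.stop_pulse_until:
                self._enter_rest(t)
            elif t >= self.swim_until:
                self.stop_pulse_until = t + cp.stop_pulse_ms
                self.swim_until = np.inf
                self._log(t, "spontaneous_stop_pulse")

        # --- controller outputs --------------------------------------------
        if self.behaviour == "rest":
            self.ramp_value += self.ramp_slope * dt
            ext[self._ix_p_xin[self.ramp_side]] += self.ramp_value
        else:
            hold_over = (self.swim_started_at is not None and
                         t >= self.swim_started_at + cp.kick_hold_ms)
            if hold_over:
                # decision made: integrators return to their low state
                x[IX_XIN_L] = self._xin_low
                x[IX_XIN_R] = self._xin_low
        if t < self.stop_pulse_until:
            ext[self._ix_ph[0]] += cp.stop_pulse_magnitude
            ext[self._ix_ph[1]] += cp.stop_pulse_magnitude

    def _enter_rest(self, t: float) -> None:
        self.behaviour = "rest"
        self.swim_started_at = None
        self.swim_until = np.inf
        self.ramp_value = 0.0
        self.ramp_side = int(self.rng.integers(0, 2))
        self.ramp_slope = float(self.rng.uniform(*self.params.controller.ramp_slope_range))
        self._log(t, "rest")


@dataclass
class SimulationResult:
    """Trajectory plus the logs needed to reproduce and interpret a run."""

    t: np.ndarray                 # time grid, ms
    y: np.ndarray                 # (n_steps, 24) state trajectory
    params: ModelParams
    stimulus_log: list = field(default_factory=list)
    controller_log: list = field(default_factory=list)
    seed: int | None = None
    dt: float = 0.1

    def trace(self, name: str) -> np.ndarray:
        """Activity time series of one population, e.g. ``trace("mn_L")``."""
        return self.y[:, state_index(name)]

    def to_tidy_frame(self) -> pd.DataFrame:
        records = []
        for i, name in enumerate(STATE_NAMES):
            pop, side = name.rsplit("_", 1)
            records.append(pd.DataFrame({
                "t_ms": self.t,
                "population": pop,
                "side": "left" if side == "L" else "right",
                "activity": self.y[:, i],
            }))
        return pd.concat(records, ignore_index=True)

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "t_ms", self.t)
        return df


def rest_state(params: ModelParams, settle_ms: float = 400.0, dt: float = 0.1) -> np.ndarray:
    """Rest equilibrium: relax the noiseless, unstimulated system from zero."""
    rhs = RHS(params)
    ext = params.baseline_inputs()
    noise = np.zeros(10)
    x = np.zeros(N_STATE)
    n = int(settle_ms / dt)
    for _ in range(n):
        x = _rk4_step(rhs, x, ext, noise, dt)
    return x


def _rk4_step(rhs: RHS, x: np.ndarray, ext: np.ndarray, noise: np.ndarray, dt: float) -> np.ndarray:
    k1 = rhs(x, ext, noise)
    k2 = rhs(x + 0.5 * dt * k1, ext, noise)
    k3 = rhs(x + 0.5 * dt * k2, ext, noise)
    k4 = rhs(x + dt * k3, ext, noise)
    return x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    params: ModelParams,
    stimulus: StimulusTrace,
    t_span: tuple[float, float] | float | None = None,
    dt: float = 0.1,
    seed: int | None = 0,
    noise: NoiseProcess | None = None,
    controller: Controller | None = None,
    controllers_enabled: bool | None = None,
    initial: np.ndarray | str = "rest",
    record_every: int = 1,
    bound_tol: float = 1e-6,
) -> SimulationResult:
    """Integrate the model over ``t_span`` under a compiled stimulus.

    Parameters
    ----------
    params : ModelParams
        Full parameter set.
    stimulus : StimulusTrace
        External-input function (baselines plus events).
    t_span : (t0, t1) in ms, a bare duration, or None
        Defaults to ``(0, stimulus.duration)``.
    dt : float
        RK4 step in ms.  Must resolve the fastest rhythm (the ~5 ms
        struggle oscillation); values above 0.5 ms are rejected.
    seed : int or None
        Seeds both the noise process (unless one is passed in) and the
        controller's random draws.
    noise : NoiseProcess, optional
        Pass an explicit process; by default one is built from the
        per-pathway sigmas in ``params``.  Use a zero-sigma process for
        deterministic runs.
    controller : Controller, optional
        Explicit controller; by default one is built from ``params`` and
        enabled/disabled via ``controllers_enabled``.
    initial : array or "rest" or "zero"
        Initial state.
    record_every : int
        Store every n-th step (the integration step itself is unchanged).

    Returns
    -------
    SimulationResult
    """
    if dt > 0.5:
        raise ValueError("dt must be <= 0.5 ms to resolve the fast struggle rhythm")
    if t_span is None:
        t_span = (0.0, stimulus.duration)
    elif np.isscalar(t_span):
        t_span = (0.0, float(t_span))
    t0, t1 = t_span

    rhs = RHS(params)
    if noise is None:
        noise = NoiseProcess(params.sensory.sigma, params.sensory.tau_s, seed=seed)
    if controller is None:
        enabled = (params.controller.enabled if controllers_enabled is None
                   else controllers_enabled)
        controller = Controller(params=params, seed=seed, enabled=enabled)
    if isinstance(initial, str):
        if initial == "rest":
            x = rest_state(params, dt=dt)
        elif initial == "zero":
            x = np.zeros(N_STATE)
        else:
            raise ValueError(f"unknown initial condition {initial!r}")
    else:
        x = np.asarray(initial, dtype=float).copy()
        if x.shape != (N_STATE,):
            raise ValueError(f"initial state must have {N_STATE} components")

    n_steps = int(round((t1 - t0) / dt))
    times = t0 + dt * np.arange(n_steps + 1)
    ext_grid = stimulus.grid(times)

    k_max = params.sigmoid_arrays()[2]
    rec_t = [t0]
    rec_y = [x.copy()]
    for i in range(n_steps):
        t = times[i]
        ext = ext_grid[i].copy()
        controller.step(t, dt, x, ext)
        xi = noise(t)
        x = _rk4_step(rhs, x, ext, xi, dt)
        if np.any(x < -bound_tol - 1e-3) or np.any(x > k_max + bound_tol + 1e-3):
            worst = STATE_NAMES[int(np.argmax(np.maximum(-x, x - k_max)))]
            raise FloatingPointError(
                f"state left its invariant box at t={t:.2f} ms (population {worst})"
            )
        # numerical guard: fixed-step integration can graze the box bounds
        np.clip(x, 0.0, k_max, out=x)
        if (i + 1) % record_every == 0:
            rec_t.append(times[i + 1])
            rec_y.append(x.copy())

    stim_log = [
        {"channel": CHANNEL_NAMES[ch], "t_start": s0, "t_end": s1, "delta": d}
        for ch, s0, s1, d in stimulus.segments
    ]
    return SimulationResult(
        t=np.asarray(rec_t),
        y=np.asarray(rec_y),
        params=params,
        stimulus_log=stim_log,
        controller_log=[asdict_entry(e) for e in controller.log],
        seed=seed,
        dt=dt,
    )


def asdict_entry(e: ControllerLogEntry) -> dict:
    return {"t": e.t, "action": e.action}


def simulate_single_pathway(
    a: float,
    P: float,
    b: float,
    theta: float,
    k: float = 1.0,
    sigma: float = 0.0,
    duration: float = 1000.0,
    dt: float = 0.1,
    x0: float = 0.0,
    seeds=(0,),
    resample: float = 1.0,
) -> np.ndarray:
    """Integrate the 1-D sensory equation under piecewise-constant noise.

    ``dX/dt = -X + (k - X) S(a X + P + xi)`` with a fresh Gaussian noise
    value drawn every ``resample`` time units and held in between, exactly
    as in the full model's sensory block.  Runs all ``seeds`` in parallel
    (RK4, fixed step) and returns an array of shape ``(len(seeds), n_steps+1)``.
    """
    from .dynamics import sensory_rhs_single

    seeds = list(seeds)
    n = int(round(duration / dt))
    per = max(int(round(resample / dt)), 1)
    n_intervals = n // per + 2
    rngs = [np.random.default_rng(s) for s in seeds]
    noise = np.stack([r.normal(0.0, 1.0, n_intervals) * sigma for r in rngs])
    x = np.full(len(seeds), float(x0))
    out = np.empty((len(seeds), n + 1))
    out[:, 0] = x
    for i in range(n):
        xi = noise[:, i // per]
        k1 = sensory_rhs_single(x, a, P, b, theta, k, xi)
        k2 = sensory_rhs_single(x + 0.5 * dt * k1, a, P, b, theta, k, xi)
        k3 = sensory_rhs_single(x + 0.5 * dt * k2, a, P, b, theta, k, xi)
        k4 = sensory_rhs_single(x + dt * k3, a, P, b, theta, k, xi)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(x, 0.0, k, out=x)
        out[:, i + 1] = x
    return out


def count_switches(trace: np.ndarray, threshold: float) -> int:
    """Number of crossings of ``threshold`` (e.g. the unstable fixed point).

    A low-to-high and a subsequent high-to-low crossing count as two
    switches; a bistable trajectory that never leaves one basin scores 0.
    """
    trace = np.asarray(trace)
    side = trace > threshold
    return int(np.abs(np.diff(side.astype(int))).sum())
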