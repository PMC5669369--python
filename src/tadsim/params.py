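"""Parameter and state containers for the tadpole population model.

The model describes the average activity of neuronal populations on the two
body sides of a hatchling *Xenopus* tadpole:

* ten sensory-pathway populations (trunk-skin touch TS, head touch TH,
  light dimming LD, head press PH, and the integrating xIN populations,
  left/right each),
* six swimming CPG populations (dIN, aIN, cIN per side),
* six struggling CPG populations (dINr, aINr, eCIN per side),
* two motor-neuron populations.

Every population obeys a Wilson-Cowan rate equation

    tau * dX/dt = -X + (k - X) * S(drive)

where ``S`` is a sigmoid response function and ``drive`` is the weighted sum
of presynaptic activities plus external input.  All activities are
dimensionless; the simulation clock is in milliseconds.  Connection weights
are stored as non-negative magnitudes; the sign with which each weight
enters a drive is fixed by the network wiring, not by configuration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SigmoidSpec",
    "SensoryParams",
    "SwimParams",
    "StruggleParams",
    "MotorParams",
    "ControllerParams",
    "ModelParams",
    "STATE_NAMES",
    "CHANNEL_NAMES",
    "N_STATE",
    "state_index",
    "mirror_permutation",
    "default_params",
]

# Canonical state ordering.  Sensory pathways come in left/right pairs;
# the CPG blocks are (dIN, aIN, cIN) then (dINr, aINr, eCIN), left side
# first, and finally the two motor-neuron populations.
SENSORY_NAMES = (
    "TS_L", "TS_R", "TH_L", "TH_R", "LD_L", "LD_R",
    "PH_L", "PH_R", "xIN_L", "xIN_R",
)
SWIM_NAMES = ("dIN_L", "aIN_L", "cIN_L", "dIN_R", "aIN_R", "cIN_R")
STRUGGLE_NAMES = ("dINr_L", "aINr_L", "eCIN_L", "dINr_R", "aINr_R", "eCIN_R")
MOTOR_NAMES = ("mn_L", "mn_R")

STATE_NAMES: tuple[str, ...] = SENSORY_NAMES + SWIM_NAMES + STRUGGLE_NAMES + MOTOR_NAMES
N_STATE = len(STATE_NAMES)

# External-input channels, aligned one-to-one with the state ordering:
# P1..P10 feed the sensory populations, Q1..Q6 the swim CPG, R1..R6 the
# struggle CPG and M1..M2 the motor neurons.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    [f"P{i}" for i in range(1, 11)]
    + [f"Q{i}" for i in range(1, 7)]
    + [f"R{i}" for i in range(1, 7)]
    + ["M1", "M2"]
)

_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}


def state_index(name: str) -> int:
    """Index of a population (e.g. ``"dIN_L"``) in the canonical state vector."""
    return _INDEX[name]


def mirror_permutation() -> np.ndarray:
    """Permutation that swaps every left population with its right homologue.

    Applying it to a state vector (or to the channel axis of a stimulus)
    reflects the animal about its midline.
    """
    perm = np.arange(N_STATE)
    for i, name in enumerate(STATE_NAMES):
        if name.endswith("_L"):
            perm[i] = _INDEX[name[:-2] + "_R"]
        elif name.endswith("_R"):
            perm[i] = _INDEX[name[:-2] + "_L"]
    return perm


@dataclass
class SigmoidSpec:
    """Sigmoid response function of one population.

    ``S(x) = max(0, 1/(1 + exp(-b (x - theta))) - offset)`` with
    ``offset = 1/(1 + exp(b theta))`` when ``zero_at_zero`` is true, so that
    a population receiving zero (or net inhibitory) drive has zero response
    and the rest state sits at (or very near) zero activity.  The
    rectification keeps the response non-negative, which in turn keeps every
    activity inside ``[0, k]``.  ``k`` is the saturation constant multiplying
    the shunting term ``(k - X)``.
    """

    b: float
    theta: float
    k: float = 1.0
    polarity: str = "excitatory"  # bookkeeping only; signs live in the wiring
    zero_at_zero: bool = True

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise ValueError(f"sigmoid slope b must be positive, got {self.b}")
        if not (self.k > 0):
            raise ValueError(f"sigmoid saturation k must be positive, got {self.k}")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def offset(self) -> float:
        return 1.0 / (1.0 + np.exp(self.b * self.theta)) if self.zero_at_zero else 0.0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to sigmoid")
        return np.maximum(1.0 / (1.0 + np.exp(-self.b * (x - self.theta))) - self.offset, 0.0)

    @property
    def saturation(self) -> float:
        """Value approached by S as the drive grows without bound."""
        return 1.0 - self.offset


def _arr(x, n, name):
    a = np.asarray(x, dtype=float)
    if a.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {a.shape}")
    return a


@dataclass
class SensoryParams:
    """Parameters of the ten sensory-pathway equations.

    ``a`` are self-coupling strengths, ``P`` baseline external inputs,
    ``lam`` the four weights with which the touch pathways feed the xIN
    integrators (TS_L, TH_L -> xIN_L and TS_R, TH_R -> xIN_R), ``sigma``
    per-pathway noise standard deviations, and ``tau_s`` the common time
    constant (ms) of the sensory equations.
    """

    a: np.ndarray
    P: np.ndarray
    lam: np.ndarray
    sigma: np.ndarray
    tau_s: float = 1.0
    b: np.ndarray = field(default_factory=lambda: np.full(10, 2.0))
    theta: np.ndarray = field(default_factory=lambda: np.full(10, 3.0))
    k: np.ndarray = field(default_factory=lambda: np.ones(10))

    def __post_init__(self) -> None:
        self.a = _arr(self.a, 10, "a")
        self.P = _arr(self.P, 10, "P")
        self.lam = _arr(self.lam, 4, "lam")
        self.sigma = _arr(self.sigma, 10, "sigma")
        self.b = _arr(self.b, 10, "b")
        self.theta = _arr(self.theta, 10, "theta")
        self.k = _arr(self.k, 10, "k")
        if np.any(self.sigma < 0):
            raise ValueError("noise standard deviations must be non-negative")
        if np.any(self.lam < 0):
            raise ValueError("integrator weights lambda must be non-negative")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


@dataclass
class SwimParams:
    """Parameters of the six swimming-CPG equations.

    ``w`` are within-side weights, ``alpha`` commissural (cIN-mediated)
    inhibition weights, ``nu`` the sensory-input weights (xIN, LD, PH onto
    dIN), ``Q`` baseline inputs, ``tau`` base time constants in ms and
    ``eta`` the gain with which light-dimming activity shortens the time
    constants (raising swim frequency).
    """

    w: np.ndarray
    alpha: np.ndarray
    nu: np.ndarray
    Q: np.ndarray
    tau: np.ndarray
    eta: float = 0.5
    b: np.ndarray = field(default_factory=lambda: np.array([1.3, 2.0, 2.0] * 2))
    theta: np.ndarray = field(default_factory=lambda: np.array([4.0, 3.7, 3.7] * 2))
    k: np.ndarray = field(default_factory=lambda: np.ones(6))

    def __post_init__(self) -> None:
        self.w = _arr(self.w, 6, "w")
        self.alpha = _arr(self.alpha, 3, "alpha")
        self.nu = _arr(self.nu, 3, "nu")
        self.Q = _arr(self.Q, 6, "Q")
        self.tau = _arr(self.tau, 6, "tau")
        self.b = _arr(self.b, 6, "b")
        self.theta = _arr(self.theta, 6, "theta")
        self.k = _arr(self.k, 6, "k")
        if np.any(self.tau <= 0):
            raise ValueError("swim time constants must be positive")
        if np.any(self.w < 0) or np.any(self.alpha < 0) or np.any(self.nu < 0):
            raise ValueError("swim weights are stored as non-negative magnitudes")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass
class StruggleParams:
    """Parameters of the six struggling-CPG equations.

    ``c`` are within-side weights, ``beta`` commissural (eCIN-mediated)
    excitation weights plus the swim-cIN input to eCIN, ``delta1/delta2``
    the gains with which the bilateral-touch gate drives dINr (+) and aINr
    (-), ``Delta`` the decision threshold on xIN activity, ``R`` baseline
    inputs and ``mu`` time constants in ms.  ``gate_mode`` selects between
    the product-of-signs gate and a Heaviside product (on only when both
    integrators exceed the threshold).
    """

    c: np.ndarray
    beta: np.ndarray
    delta1: float
    delta2: float
    Delta: float
    R: np.ndarray
    mu: np.ndarray
    gate_mode: str = "heaviside_product"
    b: np.ndarray = field(default_factory=lambda: np.array([1.3, 2.0, 1.3] * 2))
    theta: np.ndarray = field(default_factory=lambda: np.array([4.0, 3.7, 4.0] * 2))
    k: np.ndarray = field(default_factory=lambda: np.ones(6))

    def __post_init__(self) -> None:
        self.c = _arr(self.c, 6, "c")
        self.beta = _arr(self.beta, 3, "beta")
        self.R = _arr(self.R, 6, "R")
        self.mu = _arr(self.mu, 6, "mu")
        self.b = _arr(self.b, 6, "b")
        self.theta = _arr(self.theta, 6, "theta")
        self.k = _arr(self.k, 6, "k")
        if np.any(self.mu <= 0):
            raise ValueError("struggle time constants must be positive")
        if self.gate_mode not in ("literal_sign", "heaviside_product"):
            raise ValueError(f"unknown gate mode {self.gate_mode!r}")
        if not (0.0 <= self.Delta <= 1.0):
            raise ValueError("decision threshold Delta must lie in the reachable activity range")


@dataclass
class MotorParams:
    """Parameters of the two motor-neuron equations."""

    gamma: np.ndarray
    kappa: np.ndarray
    M: np.ndarray
    b: np.ndarray = field(default_factory=lambda: np.full(2, 1.3))
    theta: np.ndarray = field(default_factory=lambda: np.full(2, 4.0))
    k: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self) -> None:
        self.gamma = _arr(self.gamma, 7, "gamma")
        self.kappa = _arr(self.kappa, 2, "kappa")
        self.M = _arr(self.M, 2, "M")
        self.b = _arr(self.b, 2, "b")
        self.theta = _arr(self.theta, 2, "theta")
        self.k = _arr(self.k, 2, "k")
        if np.any(self.kappa <= 0):
            raise ValueError("motor time constants must be positive")


@dataclass
class ControllerParams:
    """Settings for the spontaneous start/stop machinery.

    While the animal rests, an excitatory ramp (slope drawn uniformly from
    ``ramp_slope_range``, input units per ms) is applied to the xIN input of
    one randomly chosen side; swimming starts when that xIN crosses
    ``start_threshold``.  Each swim bout lasts at most a duration drawn
    uniformly from ``max_swim_range`` (ms), after which a brief inhibitory
    pulse on the head-press channels returns the system to rest.
    """

    enabled: bool = True
    ramp_slope_range: tuple[float, float] = (9.4e-7, 1.41e-6)
    start_threshold: float = 0.25
    kick_hold_ms: float = 150.0
    max_swim_range: tuple[float, float] = (5000.0, 20000.0)
    stop_pulse_magnitude: float = 0.8
    stop_pulse_ms: float = 300.0
    swim_amp_threshold: float = 0.05
    rest_amp_threshold: float = 0.02
    struggle_amp_threshold: float = 0.05
    env_decay_ms: float = 60.0


@dataclass
class ModelParams:
    """Complete parameter set of the tadpole model."""

    sensory: SensoryParams
    swim: SwimParams
    struggle: StruggleParams
    motor: MotorParams
    controller: ControllerParams = field(default_factory=ControllerParams)
    # per-event-kind stimulus magnitudes used by the scenario compiler
    event_magnitudes: dict = field(default_factory=dict)

    # ---- derived, flattened views used by the dynamics kernel -------------

    def sigmoid_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-population (b, theta, k) arrays in canonical order."""
        b = np.concatenate([self.sensory.b, self.swim.b, self.struggle.b, self.motor.b])
        th = np.concatenate([self.sensory.theta, self.swim.theta, self.struggle.theta, self.motor.theta])
        k = np.concatenate([self.sensory.k, self.swim.k, self.struggle.k, self.motor.k])
        return b, th, k

    def baseline_inputs(self) -> np.ndarray:
        """Baseline external input for every channel, canonical order."""
        return np.concatenate(
            [self.sensory.P, self.swim.Q, self.struggle.R, self.motor.M]
        )

    def base_tau(self) -> np.ndarray:
        return np.concatenate(
            [
                np.full(10, self.sensory.tau_s),
                self.swim.tau,
                self.struggle.mu,
                self.motor.kappa,
            ]
        )

    # ---- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return [float(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return float(obj)
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return {
            "sensory": clean(asdict(self.sensory)),
            "swim": clean(asdict(self.swim)),
            "struggle": clean(asdict(self.struggle)),
            "motor": clean(asdict(self.motor)),
            "controller": clean(asdict(self.controller)),
            "event_magnitudes": clean(self.event_magnitudes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        ctrl = dict(d.get("controller", {}))
        for key in ("ramp_slope_range", "max_swim_range"):
            if key in ctrl:
                ctrl[key] = tuple(ctrl[key])
        return cls(
            sensory=SensoryParams(**d["sensory"]),
            swim=SwimParams(**d["swim"]),
            struggle=StruggleParams(**d["struggle"]),
            motor=MotorParams(**d["motor"]),
            controller=ControllerParams(**ctrl),
            event_magnitudes=dict(d.get("event_magnitudes", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Short stable hash of the parameter set, embedded in outputs."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_params() -> ModelParams:
    """The calibrated default parameter set shipped with the package."""
    with resources.as_file(
        resources.files("tadsim.data").joinpath("default_params.yaml")
    ) as p:
        return ModelParams.from_yaml(p)
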