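"""Right-hand sides of the tadpole population equations.

The full model couples 24 Wilson-Cowan rate equations (12 populations per
body side).  The heavy lifting is done by :class:`RHS`, which precompiles
the connection weights into a single 24x24 matrix so that one derivative
evaluation costs a matrix-vector product plus a vectorised sigmoid.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, N_STATE, state_index

__all__ = [
    "sigmoid",
    "struggle_gate",
    "effective_tau",
    "RHS",
    "sensory_rhs_single",
]

# State-block slices in the canonical ordering.
SENSORY = slice(0, 10)
SWIM = slice(10, 16)
STRUGGLE = slice(16, 22)
MOTOR = slice(22, 24)

IX_LD_L = state_index("LD_L")
IX_LD_R = state_index("LD_R")
IX_XIN_L = state_index("xIN_L")
IX_XIN_R = state_index("xIN_R")


def sigmoid(x, b: float, theta: float, zero_at_zero: bool = True):
    """Sigmoid response ``1/(1+exp(-b(x-theta)))``, optionally shifted so S(0)=0.

    The shift makes the quiescent state an equilibrium at (very nearly) zero
    activity, which is how the rest state of the animal is represented.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to sigmoid")
    s = 1.0 / (1.0 + np.exp(-b * (x - theta)))
    if zero_at_zero:
        # subtract the zero-input response and rectify: the population's
        # response to zero or net-inhibitory drive is zero, keeping every
        # activity inside [0, k]
        s = np.maximum(s - 1.0 / (1.0 + np.exp(b * theta)), 0.0)
    return s


def struggle_gate(x9: float, x10: float, Delta: float, mode: str = "heaviside_product") -> float:
    """Bilateral-touch gate driving the struggle network.

    ``heaviside_product`` returns 1 only when both integrator (xIN)
    activities exceed the decision threshold ``Delta`` — struggling requires
    sustained input on both body sides.  ``literal_sign`` returns the raw
    product ``sign(x9 - Delta) * sign(x10 - Delta)``, which is also +1 when
    both integrators are *below* threshold; it is retained for fidelity
    experiments only.
    """
    if mode == "heaviside_product":
        return 1.0 if (x9 > Delta and x10 > Delta) else 0.0
    if mode == "literal_sign":
        return float(np.sign(x9 - Delta) * np.sign(x10 - Delta))
    raise ValueError(f"unknown gate mode {mode!r}")


def effective_tau(tau0, x_ld, eta: float):
    """Light-dimming modulation of the swim time constants.

    ``tau = tau0 / (1 + eta * x_ld)``: pineal (light-dimming) activity
    shortens the swim-CPG time constants, raising the swim frequency by the
    factor ``1 + eta * x_ld``.  Monotonically decreasing in ``x_ld`` and
    equal to ``tau0`` in normal light.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    x_ld = np.maximum(np.asarray(x_ld, dtype=float), 0.0)
    out = np.asarray(tau0, dtype=float) / (1.0 + eta * x_ld)
    if np.any(out <= 0):
        raise ValueError("effective time constant must stay positive")
    return out


class RHS:
    """Compiled derivative function of the full model.

    Parameters are flattened once at construction; calling the object with a
    state vector, an external-input vector (one entry per channel, already
    including baselines and any stimulus/controller additions) and a
    10-component sensory-noise vector returns the 24-component derivative.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        self.b, self.theta, self.k = params.sigmoid_arrays()
        self.offset = 1.0 / (1.0 + np.exp(self.b * self.theta))
        self.tau0 = params.base_tau()
        self.eta = params.swim.eta

        W = np.zeros((N_STATE, N_STATE))
        sp, sw, st, mo = params.sensory, params.swim, params.struggle, params.motor

        # Sensory self-couplings and the xIN integrator inputs.
        for j in range(10):
            W[j, j] = sp.a[j]
        W[8, 0] += sp.lam[0]   # TS_L -> xIN_L
        W[8, 2] += sp.lam[1]   # TH_L -> xIN_L
        W[9, 1] += sp.lam[2]   # TS_R -> xIN_R
        W[9, 3] += sp.lam[3]   # TH_R -> xIN_R

        # Swim CPG, left side: indices 10=dIN_L, 11=aIN_L, 12=cIN_L.
        w, al, nu = sw.w, sw.alpha, sw.nu
        for off, other in ((10, 15), (13, 12)):  # (side base, contralateral cIN)
            d, a_, c_ = off, off + 1, off + 2
            W[d, d] += w[0];  W[d, a_] -= w[1];  W[d, other] -= al[0]
            W[a_, d] += w[2]; W[a_, a_] -= w[3]; W[a_, other] -= al[1]
            W[c_, d] += w[4]; W[c_, a_] -= w[5]; W[c_, other] -= al[2]
        # Sensory drive onto dINs: xIN and LD excite, PH inhibits (same side).
        W[10, IX_XIN_L] += nu[0]; W[10, IX_LD_L] += nu[1]; W[10, state_index("PH_L")] -= nu[2]
        W[13, IX_XIN_R] += nu[0]; W[13, IX_LD_R] += nu[1]; W[13, state_index("PH_R")] -= nu[2]

        # Struggle CPG, 16=dINr_L, 17=aINr_L, 18=eCIN_L (right at +3).
        c, be = st.c, st.beta
        for off, other_ecin, other_swim_cin in ((16, 21, 15), (19, 18, 12)):
            d, a_, e_ = off, off + 1, off + 2
            W[d, d] += c[0];  W[d, a_] -= c[1];  W[d, other_ecin] += be[0]
            W[a_, d] += c[2]; W[a_, a_] -= c[3]; W[a_, other_ecin] += be[1]
            W[e_, d] += c[4]; W[e_, a_] -= c[5]; W[e_, other_swim_cin] += be[2]

        # Motor neurons read the same-side CPG populations.
        g = mo.gamma
        W[22, 10] += g[0]; W[22, 11] -= g[1]; W[22, 15] -= g[2]
        W[22, 16] += g[3]; W[22, 17] -= g[4]; W[22, 21] += g[5]; W[22, 22] += g[6]
        W[23, 13] += g[0]; W[23, 14] -= g[1]; W[23, 12] -= g[2]
        W[23, 19] += g[3]; W[23, 20] -= g[4]; W[23, 18] += g[5]; W[23, 23] += g[6]
        self.W = W

        # Gate drive vector: +delta1 onto dINr, -delta2 onto aINr, both sides.
        gv = np.zeros(N_STATE)
        gv[16] = gv[19] = st.delta1
        gv[17] = gv[20] = -st.delta2
        self.gate_vec = gv
        self.Delta = st.Delta
        self.gate_mode = st.gate_mode

    def drives(self, x: np.ndarray, ext: np.ndarray, noise: np.ndarray) -> np.ndarray:
        d = self.W @ x + ext
        d[SENSORY] += noise
        g = struggle_gate(x[IX_XIN_L], x[IX_XIN_R], self.Delta, self.gate_mode)
        if g != 0.0:
            d = d + g * self.gate_vec
        return d

    def tau(self, x: np.ndarray) -> np.ndarray:
        """Per-population time constants with light-dimming modulation."""
        tau = self.tau0.copy()
        denom_l = 1.0 + self.eta * max(x[IX_LD_L], 0.0)
        denom_r = 1.0 + self.eta * max(x[IX_LD_R], 0.0)
        tau[10:13] /= denom_l
        tau[13:16] /= denom_r
        return tau

    def __call__(self, x: np.ndarray, ext: np.ndarray, noise: np.ndarray) -> np.ndarray:
        d = self.drives(x, ext, noise)
        s = np.maximum(1.0 / (1.0 + np.exp(-self.b * (d - self.theta))) - self.offset, 0.0)
        dx = (-x + (self.k - x) * s) / self.tau(x)
        if not np.all(np.isfinite(dx)):
            bad = [n for n, v in zip(self._names(), dx) if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite derivative for population(s) {bad}")
        return dx

    @staticmethod
    def _names():
        from .params import STATE_NAMES
        return STATE_NAMES


def sensory_rhs_single(x, a: float, P: float, b: float, theta: float,
                       k: float = 1.0, noise: float = 0.0,
                       zero_at_zero: bool = True):
    """Right-hand side of the one-dimensional sensory-pathway equation.

    ``dX/dt = -X + (k - X) S(a X + P + xi)`` — the building block analysed
    by the bifurcation module and used for noise-switching experiments.
    """
    x = np.asarray(x, dtype=float)
    return -x + (k - x) * sigmoid(a * x + P + noise, b, theta, zero_at_zero)
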