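"""Fixed-point and saddle-node analysis of the 1-D sensory equation.

A single sensory pathway obeys ``dX/dt = f(X) = -X + (k - X) S(a X + P)``.
Depending on ``(a, P)`` this equation has one or three fixed points; the
three-fixed-point (bistable) wedge in the ``(P, a)`` plane is bounded by two
saddle-node branches that meet at a cusp.  The bistable regime is how the
model stores a sensory "decision": a transient input can flip a pathway from
its low to its high stable state.

Two independent routes to the same structure are provided: a brute-force
root count on a parameter grid (:func:`bistable_region_map`) and a
predictor-corrector continuation of the saddle-node conditions
``f = 0, df/dX = 0`` (:func:`sn_continuation`).  The former serves as the
oracle for the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "FixedPointSet",
    "SNCurve",
    "find_fixed_points",
    "sn_continuation",
    "bistable_region_map",
    "cusp_point",
    "hysteresis_sweep",
]

SCAN_POINTS = 2001      # density of the sign-change scan on [0, k]
ROOT_TOL = 1e-12        # bisection/brentq tolerance
SN_TOL = 1e-8           # residual tolerance on the saddle-node conditions


def _sig_parts(u, b, theta, zero_at_zero=True):
    s = 1.0 / (1.0 + np.exp(-b * (u - theta)))
    off = 1.0 / (1.0 + np.exp(b * theta)) if zero_at_zero else 0.0
    return s, off


def _f(X, a, P, b, theta, k, zero_at_zero=True):
    s, off = _sig_parts(a * X + P, b, theta, zero_at_zero)
    return -X + (k - X) * np.maximum(s - off, 0.0)


def _f_X(X, a, P, b, theta, k, zero_at_zero=True):
    s, off = _sig_parts(a * X + P, b, theta, zero_at_zero)
    ds = b * s * (1.0 - s)
    return -1.0 - (s - off) + (k - X) * a * ds


def _f_XX(X, a, P, b, theta, k, zero_at_zero=True):
    s, _ = _sig_parts(a * X + P, b, theta, zero_at_zero)
    ds = b * s * (1.0 - s)
    dds = b * b * s * (1.0 - s) * (1.0 - 2.0 * s)
    return -2.0 * a * ds + (k - X) * a * a * dds


def _f_P(X, a, P, b, theta, k, zero_at_zero=True):
    s, _ = _sig_parts(a * X + P, b, theta, zero_at_zero)
    return (k - X) * b * s * (1.0 - s)


def _f_XP(X, a, P, b, theta, k, zero_at_zero=True):
    s, _ = _sig_parts(a * X + P, b, theta, zero_at_zero)
    ds = b * s * (1.0 - s)
    dds = b * b * s * (1.0 - s) * (1.0 - 2.0 * s)
    return -ds + (k - X) * a * dds


@dataclass
class FixedPointSet:
    """Roots of the 1-D equation at one parameter point, sorted ascending."""

    a: float
    P: float
    b: float
    theta: float
    k: float
    roots: list = field(default_factory=list)
    stability: list = field(default_factory=list)  # "stable" | "unstable"

    @property
    def n(self) -> int:
        return len(self.roots)

    @property
    def stable_roots(self) -> list:
        return [r for r, s in zip(self.roots, self.stability) if s == "stable"]


def find_fixed_points(a, P, b, theta, k=1.0, zero_at_zero=True) -> FixedPointSet:
    """All equilibria of ``-X + (k - X) S(aX + P)`` on ``[0, k]``.

    Dense sign-change scan followed by Brent refinement; stability from the
    sign of ``df/dX``.  By continuity (f(0) >= 0, f(k) < 0) at least one
    root always exists.
    """
    xs = np.linspace(0.0, k, SCAN_POINTS)
    fs = _f(xs, a, P, b, theta, k, zero_at_zero)
    roots: list[float] = []
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(float(xs[i]))
        elif fs[i] * fs[i + 1] < 0.0:
            r = optimize.brentq(
                _f, xs[i], xs[i + 1], args=(a, P, b, theta, k, zero_at_zero),
                xtol=ROOT_TOL,
            )
            roots.append(float(r))
    if fs[-1] == 0.0:
        roots.append(float(xs[-1]))
    # collapse near-duplicates from tangencies
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 1e-9:
            uniq.append(r)
    if not uniq:
        raise AssertionError("no root found on [0, k]; violates continuity argument")
    stab = [
        "stable" if _f_X(r, a, P, b, theta, k, zero_at_zero) < 0 else "unstable"
        for r in uniq
    ]
    return FixedPointSet(a=a, P=P, b=b, theta=theta, k=k, roots=uniq, stability=stab)


@dataclass
class SNCurve:
    """Saddle-node locus in the ``(P, a)`` plane at fixed ``(b, theta, k)``.

    ``lower`` and ``upper`` are the two fold branches (arrays of ``(a, P)``
    rows, ``lower`` having the smaller P at given a); ``cusp`` is the point
    where they meet.
    """

    b: float
    theta: float
    k: float
    lower: np.ndarray
    upper: np.ndarray
    cusp: tuple[float, float]  # (P, a)

    def to_frame(self):
        import pandas as pd

        rows = []
        for branch, pts in (("lower", self.lower), ("upper", self.upper)):
            for a, P in pts:
                rows.append({"a": a, "P": P, "branch": branch})
        return pd.DataFrame(rows)


def _solve_fold(a, P0, X0, b, theta, k, zero_at_zero=True):
    """Newton solve of {f = 0, f_X = 0} for (X, P) at fixed a."""
    X, P = X0, P0
    for _ in range(60):
        F = np.array([
            _f(X, a, P, b, theta, k, zero_at_zero),
            _f_X(X, a, P, b, theta, k, zero_at_zero),
        ])
        if np.max(np.abs(F)) < SN_TOL * 1e-2:
            break
        J = np.array([
            [_f_X(X, a, P, b, theta, k, zero_at_zero), _f_P(X, a, P, b, theta, k, zero_at_zero)],
            [_f_XX(X, a, P, b, theta, k, zero_at_zero), _f_XP(X, a, P, b, theta, k, zero_at_zero)],
        ])
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return None
        X, P = X - step[0], P - step[1]
        if not (np.isfinite(X) and np.isfinite(P)):
            return None
    res = max(abs(_f(X, a, P, b, theta, k, zero_at_zero)),
              abs(_f_X(X, a, P, b, theta, k, zero_at_zero)))
    if res > SN_TOL:
        return None
    return float(X), float(P)


def cusp_point(b, theta, k=1.0, guess=(0.3, 1.0, 4.0), zero_at_zero=True):
    """Cusp ``(P, a)`` where the two fold branches merge.

    Solves the three conditions ``f = f_X = f_XX = 0`` for ``(X, P, a)``.
    """
    def F(v):
        X, P, a = v
        return [
            _f(X, a, P, b, theta, k, zero_at_zero),
            _f_X(X, a, P, b, theta, k, zero_at_zero),
            _f_XX(X, a, P, b, theta, k, zero_at_zero),
        ]

    sol, info, ier, _ = optimize.fsolve(F, guess, full_output=True)
    if ier != 1:
        raise RuntimeError("cusp solve did not converge")
    X, P, a = sol
    return float(P), float(a)


def _fold_seeds(a, b, theta, k, zero_at_zero=True, P_range=(-5.0, 8.0)):
    """Locate both folds at one ``a`` by scanning P for root-count changes."""
    Ps = np.linspace(P_range[0], P_range[1], 400)
    counts = [find_fixed_points(a, P, b, theta, k, zero_at_zero).n for P in Ps]
    seeds = []
    for i in range(len(Ps) - 1):
        if counts[i] != counts[i + 1]:
            Pmid = 0.5 * (Ps[i] + Ps[i + 1])
            # probe on whichever side of the transition has three roots and
            # seed from the midpoint of the pair that merges at the fold
            if counts[i + 1] > counts[i]:      # lower fold: saddle+high born
                fps = find_fixed_points(a, Ps[i + 1], b, theta, k, zero_at_zero)
                pair = fps.roots[1:] if fps.n == 3 else fps.roots
            else:                              # upper fold: low+saddle merge
                fps = find_fixed_points(a, Ps[i], b, theta, k, zero_at_zero)
                pair = fps.roots[:2] if fps.n == 3 else fps.roots
            seeds.append((Pmid, float(np.mean(pair))))
    return seeds


def sn_continuation(b, theta, k=1.0, a_range=(3.0, 10.0), n_steps=120,
                    zero_at_zero=True) -> SNCurve:
    """Trace both saddle-node branches over ``a_range`` by continuation.

    Starts from fold locations found by brute-force scanning at the largest
    ``a`` and follows each branch with a secant predictor and a Newton
    corrector as ``a`` decreases toward the cusp.  Branches are truncated
    (with the cusp closing the wedge) once they merge.
    """
    P_cusp, a_cusp = cusp_point(b, theta, k, zero_at_zero=zero_at_zero)
    a_hi = max(a_range)
    a_lo = max(min(a_range), a_cusp)
    a_grid = np.linspace(a_hi, a_lo, n_steps)

    seeds = _fold_seeds(a_hi, b, theta, k, zero_at_zero)
    if len(seeds) < 2:
        raise RuntimeError(
            f"could not find two folds at a={a_hi}; a_range must start above the cusp"
        )
    # refine seeds
    branches = []
    for P0, X0 in seeds[:2]:
        sol = _solve_fold(a_hi, P0, X0, b, theta, k, zero_at_zero)
        if sol is None:
            raise RuntimeError("fold refinement failed at the starting slice")
        branches.append([(a_hi, sol[1], sol[0])])  # (a, P, X)

    for a in a_grid[1:]:
        for br in branches:
            a_prev, P_prev, X_prev = br[-1]
            # secant predictor when two points are available
            if len(br) >= 2:
                a2, P2, X2 = br[-2]
                slope_P = (P_prev - P2) / (a_prev - a2)
                slope_X = (X_prev - X2) / (a_prev - a2)
                P0, X0 = P_prev + slope_P * (a - a_prev), X_prev + slope_X * (a - a_prev)
            else:
                P0, X0 = P_prev, X_prev
            sol = _solve_fold(a, P0, X0, b, theta, k, zero_at_zero)
            if sol is not None:
                br.append((a, sol[1], sol[0]))

    low, high = branches
    # order by P so "lower" is the small-P fold
    if np.mean([p for _, p, _ in low]) > np.mean([p for _, p, _ in high]):
        low, high = high, low
    lower = np.array([(a, P) for a, P, _ in low])
    upper = np.array([(a, P) for a, P, _ in high])
    return SNCurve(b=b, theta=theta, k=k, lower=lower, upper=upper,
                   cusp=(P_cusp, a_cusp))


def bistable_region_map(b, theta, k, P_grid, a_grid, zero_at_zero=True) -> np.ndarray:
    """Boolean grid (len(a_grid) x len(P_grid)): True where three fixed points exist.

    Brute force over every grid point; the oracle against which the
    continuation curves are checked.
    """
    out = np.zeros((len(a_grid), len(P_grid)), dtype=bool)
    for i, a in enumerate(a_grid):
        for j, P in enumerate(P_grid):
            out[i, j] = find_fixed_points(a, P, b, theta, k, zero_at_zero).n == 3
    return out


def hysteresis_sweep(a, b, theta, k=1.0, P_range=(0.0, 2.5), n=400,
                     settle=60.0, dt=0.05, zero_at_zero=True):
    """Quasi-static sweep of P up then down; returns the two jump points.

    Integrates the 1-D equation while stepping P slowly, recording the P at
    which the state jumps between the low and high branches.  In the
    bistable regime the two transition points differ (hysteresis) and lie on
    the saddle-node branches.
    """
    from .dynamics import sensory_rhs_single

    def sweep(P_values, x0):
        x = x0
        trace = []
        for P in P_values:
            for _ in range(int(settle / dt)):
                x = x + dt * sensory_rhs_single(x, a, P, b, theta, k, 0.0, zero_at_zero)
            trace.append(x)
        return np.array(trace)

    P_up = np.linspace(P_range[0], P_range[1], n)
    x_up = sweep(P_up, 0.0)
    P_dn = P_up[::-1]
    x_dn = sweep(P_dn, float(x_up[-1]))
    jump_up = P_up[int(np.argmax(np.diff(x_up)))] if np.max(np.diff(x_up)) > 0.05 else None
    jump_dn = P_dn[int(np.argmin(np.diff(x_dn)))] if np.min(np.diff(x_dn)) < -0.05 else None
    return jump_up, jump_dn
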