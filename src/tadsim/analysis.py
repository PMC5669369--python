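"""Quantification of simulated dynamics and behaviour classification.

Periods are estimated from inter-peak intervals rather than spectral fits
because the model's traces are strongly non-sinusoidal (plateau-like swim
bursts, bursty struggle activity); a periodogram-based estimate is provided
as an independent cross-check only.

The ethogram classifier works on fixed analysis frames of the motor traces:
a frame is ``rest`` when the motor deviation from its rest level stays below
a threshold, ``struggle`` when high-frequency (intra-burst) oscillation is
present, ``swim`` otherwise, and ``swim_accel`` when the swim frequency
exceeds the calibrated baseline by a configurable factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import SimulationResult

__all__ = [
    "OscillationSummary",
    "EnvelopeSummary",
    "Ethogram",
    "NoOscillation",
    "NoBurstStructure",
    "estimate_period",
    "estimate_period_spectral",
    "phase_shift",
    "envelope_periods",
    "classify",
    "transition_latency",
    "antiphase_index",
]

PEAK_PROMINENCE_FRAC = 0.25   # peak prominence relative to trace amplitude
REGULARITY_TOL = 0.05         # cycle-period tolerance for the transient criterion
ACCEL_FACTOR = 1.15           # swim_accel cut relative to baseline frequency
REST_AMP_FRAC = 0.10          # rest threshold relative to calibrated swim amplitude


class NoOscillation(Exception):
    """Raised when a trace has no sustained oscillation to analyse."""


class NoBurstStructure(Exception):
    """Raised when a trace oscillates but shows no envelope/burst structure."""


@dataclass
class OscillationSummary:
    period_ms: float
    frequency_hz: float
    amplitude: float
    antiphase_index: float | None
    window: tuple[float, float]


@dataclass
class EnvelopeSummary:
    fast_period_ms: float
    slow_period_ms: float
    burst_duration_ms: float
    n_bursts: int


@dataclass
class Ethogram:
    """Time-ordered behaviour intervals labelling the analysed span."""

    intervals: list = field(default_factory=list)  # (t_start, t_end, label)

    def labels(self) -> list:
        return [lab for _, _, lab in self.intervals]

    def label_at(self, t: float) -> str:
        for a, b, lab in self.intervals:
            if a <= t < b:
                return lab
        raise ValueError(f"time {t} outside the analysed span")

    def intervals_with(self, label: str) -> list:
        return [(a, b) for a, b, lab in self.intervals if lab == label]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.intervals, columns=["t_start", "t_end", "label"])


def _window(t, x, window):
    if window is not None:
        m = (t >= window[0]) & (t < window[1])
        return t[m], x[m]
    return t, x


def _peaks(t, x, prominence_frac=PEAK_PROMINENCE_FRAC):
    amp = x.max() - x.min()
    if amp <= 0:
        return np.array([], dtype=int), 0.0
    pk, _ = signal.find_peaks(x, prominence=prominence_frac * amp)
    return pk, amp


def estimate_period(t, x, window=None, prominence_frac=PEAK_PROMINENCE_FRAC) -> float:
    """Oscillation period (ms) as the mean inter-peak interval.

    Raises :class:`NoOscillation` for traces with fewer than three peaks or
    negligible amplitude.
    """
    t, x = _window(np.asarray(t, float), np.asarray(x, float), window)
    pk, amp = _peaks(t, x, prominence_frac)
    if amp < 1e-6 or len(pk) < 3:
        raise NoOscillation(
            f"found {len(pk)} peaks (amplitude {amp:.2e}); need at least 3"
        )
    return float(np.diff(t[pk]).mean())


def estimate_period_spectral(t, x, window=None) -> float:
    """Period from the dominant periodogram frequency (cross-check estimator)."""
    t, x = _window(np.asarray(t, float), np.asarray(x, float), window)
    dt = float(np.median(np.diff(t)))
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise NoOscillation("constant trace")
    f, p = signal.periodogram(x, fs=1000.0 / dt)
    f, p = f[1:], p[1:]
    return float(1000.0 / f[int(np.argmax(p))])


def phase_shift(t, x_a, x_b, window=None, period_tol=0.05) -> float:
    """Phase of ``x_b`` relative to ``x_a`` as a fraction of the period in [0, 1).

    Computed as the circular mean of per-cycle peak-time offsets.  Both
    traces must oscillate with matching periods (within ``period_tol``).
    """
    t = np.asarray(t, float)
    Ta = estimate_period(t, x_a, window)
    Tb = estimate_period(t, x_b, window)
    if abs(Ta - Tb) > period_tol * Ta:
        raise ValueError(f"period mismatch: {Ta:.2f} vs {Tb:.2f} ms")
    tw, xa = _window(t, np.asarray(x_a, float), window)
    _, xb = _window(t, np.asarray(x_b, float), window)
    pa, _ = _peaks(tw, xa)
    pb, _ = _peaks(tw, xb)
    ta, tb = tw[pa], tw[pb]
    offsets = []
    for tpk in tb:
        prev = ta[ta <= tpk]
        if len(prev) and tpk - prev[-1] < 2 * Ta:
            offsets.append((tpk - prev[-1]) / Ta)
    if not offsets:
        raise NoOscillation("no interleaved peaks for phase estimate")
    ang = np.exp(2j * np.pi * np.asarray(offsets))
    return float((np.angle(ang.mean()) / (2 * np.pi)) % 1.0)


def envelope_periods(t, x, window=None, fast_prominence_frac=0.10) -> EnvelopeSummary:
    """Fast and slow (envelope) periods of a burst-modulated oscillation.

    The amplitude envelope is the linear interpolation of peak heights;
    bursts are segments where the envelope exceeds the midpoint of its
    range.  The fast period is the mean within-burst peak interval and the
    slow period the mean interval between successive burst onsets.
    """
    t, x = _window(np.asarray(t, float), np.asarray(x, float), window)
    pk, amp = _peaks(t, x, fast_prominence_frac)
    if amp < 1e-6 or len(pk) < 6:
        raise NoOscillation("too few peaks for envelope analysis")
    tp, e = t[pk], x[pk]
    env = np.interp(t, tp, e)
    thr = 0.5 * (env.max() + env.min())
    depth = (e.max() - e.min()) / max(e.max() - x.min(), 1e-12)
    above = env > thr
    edges = np.diff(above.astype(int))
    onsets = t[1:][edges == 1]
    offsets = t[1:][edges == -1]
    if len(onsets) < 3 or depth < 0.05:
        raise NoBurstStructure(
            f"{len(onsets)} burst onsets, envelope depth {depth:.3f}"
        )
    slow = float(np.diff(onsets).mean())
    # within-burst peak intervals
    fast_iv = []
    for a, b in zip(onsets, offsets[offsets > onsets[0]]):
        sel = (tp >= a) & (tp < b)
        if sel.sum() >= 3:
            fast_iv.extend(np.diff(tp[sel]))
    if not fast_iv:
        fast_iv = np.diff(tp)
    fast = float(np.mean(fast_iv))
    dur = float(np.mean([b - a for a, b in zip(onsets, offsets[offsets > onsets[0]])])) \
        if len(offsets) else float("nan")
    if not slow > fast:
        raise NoBurstStructure("envelope period does not exceed the fast period")
    return EnvelopeSummary(fast_period_ms=fast, slow_period_ms=slow,
                           burst_duration_ms=dur, n_bursts=len(onsets))


def antiphase_index(t, x_left, x_right, window=None) -> float:
    """Zero-lag cross-correlation of the two sides (negative = anti-phase)."""
    _, xl = _window(np.asarray(t, float), np.asarray(x_left, float), window)
    _, xr = _window(np.asarray(t, float), np.asarray(x_right, float), window)
    xl = xl - xl.mean()
    xr = xr - xr.mean()
    denom = np.sqrt((xl ** 2).sum() * (xr ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xl * xr).sum() / denom)


def transition_latency(t, x, stimulus_onset_ms: float,
                       tol=REGULARITY_TOL) -> float:
    """Time from stimulus onset until the oscillation becomes regular.

    Regularity is reached at the first of three consecutive cycles whose
    periods are all within ``tol`` of the asymptotic (late-trace) period.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    m = t >= stimulus_onset_ms
    tw, xw = t[m], x[m]
    pk, amp = _peaks(tw, xw)
    if len(pk) < 6:
        raise NoOscillation("oscillation never becomes analysable")
    tp = tw[pk]
    periods = np.diff(tp)
    asymptotic = periods[-5:].mean()
    for i in range(len(periods) - 2):
        if np.all(np.abs(periods[i:i + 3] - asymptotic) < tol * asymptotic):
            return float(tp[i] - stimulus_onset_ms)
    raise NoOscillation("regularity criterion never satisfied")


# ---------------------------------------------------------------------------
# Ethogram classification
# ---------------------------------------------------------------------------

def classify(result: SimulationResult, frame_ms: float = 200.0,
             swim_period_ms: float = 50.0, swim_amplitude: float = 0.115,
             rest_frac: float = REST_AMP_FRAC,
             accel_factor: float = ACCEL_FACTOR) -> Ethogram:
    """Frame-wise behaviour classification of a simulation into an ethogram.

    Per frame of the motor traces: ``rest`` if the motor amplitude is below
    ``rest_frac`` times the calibrated swim amplitude; ``struggle`` if
    fast (intra-burst) oscillation is present, i.e. the median inter-peak
    interval on either side is below 40% of the swim period; otherwise
    ``swim``, upgraded to ``swim_accel`` when the frame frequency is at
    least ``accel_factor`` times the calibrated swim frequency.  Thresholds
    are relative, so the labels are invariant under a uniform rescaling of
    the motor amplitudes.  Adjacent frames with equal labels are merged.
    """
    if frame_ms < 2 * swim_period_ms:
        raise ValueError("frame must cover at least two swim periods")
    t = result.t
    uL = result.trace("mn_L")
    uR = result.trace("mn_R")
    u_rest = uL[0], uR[0]
    base_freq = 1000.0 / swim_period_ms

    edges = np.arange(t[0], t[-1] + 1e-9, frame_ms)
    if edges[-1] < t[-1]:
        edges = np.append(edges, t[-1])
    labels = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (t >= a) & (t < b)
        if m.sum() < 8:
            continue
        dev = max(np.abs(uL[m] - u_rest[0]).max(), np.abs(uR[m] - u_rest[1]).max())
        if dev < rest_frac * swim_amplitude:
            labels.append((a, b, "rest"))
            continue
        fast = False
        freqs = []
        for x in (uL[m], uR[m]):
            amp = x.max() - x.min()
            if amp < rest_frac * swim_amplitude:
                continue
            pk, _ = signal.find_peaks(x, prominence=0.15 * amp)
            if len(pk) >= 3:
                iv = np.median(np.diff(t[m][pk]))
                if iv < 0.4 * swim_period_ms:
                    fast = True
                freqs.append(1000.0 / iv)
        if fast:
            labels.append((a, b, "struggle"))
        elif freqs and max(freqs) >= accel_factor * base_freq:
            labels.append((a, b, "swim_accel"))
        else:
            labels.append((a, b, "swim"))

    merged: list[tuple[float, float, str]] = []
    for a, b, lab in labels:
        if merged and merged[-1][2] == lab and abs(merged[-1][1] - a) < 1e-9:
            merged[-1] = (merged[-1][0], b, lab)
        else:
            merged.append((a, b, lab))
    return Ethogram(intervals=merged)
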