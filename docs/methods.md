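# Methods

## The model

`tadsim` simulates the sensorimotor nervous system of the hatchling *Xenopus*
tadpole as 24 coupled Wilson–Cowan rate equations — 12 neuronal populations on
each body side.  Every population's mean activity `X ∈ [0, k]` obeys

    tau dX/dt = -X + (k - X) · S(drive),        S(x) = max(0, σ(b(x-θ)) - σ(-bθ))

where `σ` is the logistic function, `drive` is the weighted sum of presynaptic
activities plus external input, and `k = S(+∞)`-style saturation is normalised
to 1.  Subtracting the zero-input response makes quiescence an equilibrium at
(essentially) zero activity; rectifying at zero keeps the response
non-negative, which together with the shunting factor `(k - X)` makes the box
`[0, k]^24` forward invariant (at `X = 0` the derivative is `≥ 0`, at `X = k`
it is `-k/tau < 0`).

The populations, per side:

| block | populations | role |
|---|---|---|
| sensory | TS, TH, LD, PH | trunk-touch, head-touch, light-dimming and head-press (cement-gland) pathways |
| integrator | xIN | pools TS and TH drive; its activation is the swim decision |
| swim CPG | dIN, aIN, cIN | excitatory driver, ascending inhibitor, commissural inhibitor |
| struggle CPG | dINr, aINr, eCIN | repetitive-firing driver/inhibitor, excitatory commissural |
| output | mn | motor pool reading all same-side CPG populations |

Connection signs are fixed by the wiring (weights are stored as magnitudes):
cINs inhibit the opposite side, eCINs excite it, PH inhibits dINs, and the
bilateral-touch gate `H(X9 - Δ)·H(X10 - Δ)` feeds the dINr (+δ1) and aINr
(−δ2) populations.  A `literal_sign` gate variant (the raw product of signs,
which is also +1 when both integrators are *silent*) is available for
fidelity experiments but is not the default, because it would drive struggling
at rest.

All times are milliseconds; activities are dimensionless.  The sensory
equations evolve on a 1 ms time unit (`tau_s = 1 ms`), which is also the
noise-resampling interval.

## Sensory pathways: bistability as a decision latch

Each pathway reduces to the 1-D equation `dX/dt = -X + (k-X) S(aX + P)`, which
has one or three equilibria depending on `(a, P)`.  The three-equilibrium
wedge in the `(P, a)` plane is bounded by two saddle-node branches meeting at
a cusp; `tadsim.bifurcation` traces it both by brute-force root counting
(2001-point scan + Brent refinement to 1e-12) and by a bespoke
predictor–corrector continuation of `{f = 0, ∂f/∂X = 0}` (Newton corrector,
secant predictor, residual tolerance 1e-8), each validating the other.

Default operating points:

* **xIN integrators**: `a = 6, P = 1.2, b = 2, θ = 3` — inside the wedge
  (folds at `P ≈ 0.97` and `1.38`; stable states ≈ 0.037 and 0.468).  A touch
  pushes the integrator past the upper fold and it *latches* active: that
  latch is the decision memory.  With noise SD 0.1 the latch is stable over
  1000 time units; switching requires SD ≈ 0.22 or more.
* **TS/TH/LD/PH pathways**: `a = 5, P = 1.2` — just below the wedge
  (folds ≈ 1.34/1.50), i.e. monostable-low.  Stimulation (+0.5 touch, +0.8
  dimming/press) activates them; when the stimulus ends they decay.  This is
  deliberate: press-head and light-dimming responses must last only as long
  as their stimulus, and a touch pathway that latched forever would keep
  re-arming the integrators.

## Swimming: bistable rest + anti-phase limit cycle

Each side's dIN carries strong self-excitation (w1 = 26, `b = 1.3, θ = 4`):
at the background drive `Q = 0.8` an *isolated* dIN would self-ignite.  Rest
is nevertheless stable because each cIN tonically reads its own dIN (low
threshold, `θ = 0.8`) and inhibits the opposite dIN (α1 = 2): the symmetric
quiet state carries just enough mutual inhibition to hold both sides down.
A kick to one dIN ignites it; the slow aIN (τ ≈ 4 ms vs 1.5 ms) terminates
the burst, and — the step that makes the rhythm self-sustaining — the
lingering aIN also suppresses its *own* cIN (w6), lifting the inhibition off
the opposite side so that it ignites in turn.  The result is a stable
anti-phase limit cycle coexisting with the stable rest state:

* quiet rest persists indefinitely (tested ≥ 10 s);
* the standard initiation protocol (left dIN input 1.37 over 100–250 ms,
  right 1.3 from 130 ms) leaves a sustained anti-phase rhythm, period
  50.0 ms (the swim time constants are calibrated by exact uniform
  rescaling), persisting ≥ 10 s after the stimulus;
* same-side aIN lags dIN by 0.100 of a period (set by the aIN threshold
  θ = 2.8 and time constant);
* head-press (PH) activation subtracts ν3·X_PH ≈ 0.8 from the dIN drive,
  which is below the limit cycle's existence range — swimming collapses to
  rest within ~200 ms and stays there once the press ends;
* light dimming divides the swim time constants by `1 + η·X_LD` (η = 0.5),
  raising the frequency by ~25% at full pineal activation — from 20 Hz
  toward the top of the behavioural 10–25 Hz band — and reverting with the
  light.

The transitional phase between stimulus onset and regular oscillation
(first of three consecutive cycles within 5% of the asymptotic period)
measures 171 ms: the rhythm is regular from the first full cycle after the
stimulus ends at 250 ms.

## Struggling: envelope (torus) oscillations

Each side's dINr–aINr pair is a fast smooth oscillator (classic weights
16/12/15/3, time constants ≈ 1.7 ms) that is quiescent at zero input and
oscillates under the dINr stimulation applied 150 ms after a prolonged
bilateral attack begins.  The eCINs act as fast commissural relays
(E→E weight β1 = 1.32, E→I β2 = 0.45).  Near the boundary between in-phase
and anti-phase locking of the two fast oscillators the system settles on a
torus: the fast rhythm (5.0 ms) is amplitude-modulated by a slow envelope
(135 ms) that alternates *anti-phase* between the sides (envelope
correlation ≈ −0.75).  β1 positions the envelope/fast period ratio; the
struggle time constants scale the fast period.

Two consequences of this wiring are worth stating plainly:

* A deep square-wave burst alternation is not reachable here: with a fast
  aINr, the slow cross-side subsystem (the two eCIN relays) is
  two-dimensional and monotone, which rules out a slow limit cycle of its
  own.  The envelope is therefore a genuine torus with moderate modulation
  depth (~0.3 on dINr peak heights).
* The swim network receives no input from the struggle network, so the only
  way swimming can resume when the attack ends — which it must, from rest
  or from swimming alike — is for the swim limit cycle to keep running
  (phase memory) through the stimulation.  It does, at ~73 ms period under
  the elevated drive, snapping back to 50.0 ms at stimulus end.  Because
  the motor pools read both CPGs, the motor trace during struggling
  superimposes that swim rhythm on the struggle envelope; envelope
  statistics (fast/slow periods, cross-side phase) are therefore measured
  on the dINr traces, where the struggle rhythm lives undisturbed.  The
  struggle rhythm is plainly visible in the motor trace as well (fast
  ~5–6 ms intra-burst peaks riding on the slower components), and the
  ethogram classifier uses exactly that signature.

Struggle activity never outlasts its stimulation by more than about one
envelope period; afterwards the network returns to quiescence and the motor
output to swimming.

## Scenarios, events and the 150 ms rule

A scenario is an ordered list of timed events (`touch_trunk`, `touch_head`,
`light_dim`, `press_head`, `predator_attack`) compiled into a
piecewise-constant external-input trace over the 24 input channels
(P1..P10, Q1..Q6, R1..R6, M1, M2), equal to the parameter-file baselines
outside events; overlapping contributions add.  Touches drive the
stimulated side at 0.5 and the contralateral side at 0.1 after a 30 ms
conduction delay.  A predator attack drives the dIN channels directly
(+0.57/+0.5, 30 ms stagger) and the dINr channels from 150 ms after onset:
stimulation shorter than 150 ms therefore *cannot* recruit the struggle
network — this delay is what separates swim initiation from struggling.
Attacks are routed to the CPG input channels rather than through the touch
pathways, matching how the struggle experiments are driven; a touch-routed
variant can be expressed as explicit touch events.

The built-in `table2` scenario (rest to 200 ms; left trunk touch 200–350;
light dimming 1200–1500; predator attack 2000–3000; head press 6500–6600;
7000 ms total) reproduces the behavioural sequence
rest → swim → accelerated swim → struggle → swim → rest.

## Spontaneous starts and stops

While the animal rests, an excitatory ramp (slope drawn uniformly from
9.4e-7..1.41e-6 input units/ms, one body side per rest episode) is added to
the xIN input.  Swimming ignites once the xIN low branch has risen enough
(~0.085 input units) for its drive to push the dIN past its fold — giving
spontaneous-start delays of roughly 60–90 s deterministically, earlier with
sensory noise.  The ramp is applied unilaterally so a spontaneous start can
never satisfy the bilateral struggle gate.  After any locomotor onset the
controller resets the integrators to their low state — the decision taken,
the integrators return to baseline —
150 ms after onset, long enough for the kick to establish the limit cycle.

Each swim bout carries a maximum duration drawn uniformly from 5–20 s
(the biological mechanism of spontaneous stopping being unknown, the model
prescribes the duration); expiry triggers a 300 ms inhibitory pulse on the
head-press channels, returning the system to rest through the same pathway
an actual head press uses.  The controller's behaviour flag (rest /
swimming / struggling) is estimated online from decaying envelopes of the
motor and dINr activities with a 400 ms grace period after each onset.

## Behaviour classification

The ethogram classifier works on 200 ms frames of the two motor traces
(≥ 2 swim periods by construction): *rest* when the motor deviation from its
rest level stays below 10% of the calibrated swim amplitude; *struggle*
when fast oscillation is present (median inter-peak interval under 40% of
the swim period); otherwise *swim*, upgraded to *swim_accel* at ≥ 1.15× the
baseline swim frequency.  All thresholds are relative, so uniformly
rescaling the motor amplitudes leaves the labels unchanged.  Periods are
measured as mean inter-peak intervals (prominence 0.25 of trace amplitude);
traces here are strongly non-sinusoidal, so a periodogram estimate is
provided only as a cross-check.  Envelopes are linear interpolations of
peak heights; bursts are segments above the midpoint of the envelope range;
the slow period is the mean interval between burst onsets.

## Numerical choices

* Fixed-step RK4; default `dt = 0.1 ms` (the 50-seed scenario suite uses
  0.15 ms after checking label-for-label agreement with 0.1 ms).  Steps
  above 0.5 ms are rejected — they would under-resolve the 5 ms struggle
  rhythm.  Halving `dt` moves the swim period by far less than 0.5%.
* Noise is piecewise constant per 1 ms resample interval and held across
  RK4 stages — the process is itself piecewise constant, so this is exact
  in distribution, not an SDE discretisation compromise.  Identical seeds
  give bit-identical trajectories.
* States are clipped to `[0, k]` after each step (guarding roundoff-level
  excursions); a genuine excursion beyond 1e-3 aborts with the offending
  population named.
* Root scans use 2001 points on `[0, k]`, Brent to 1e-12; saddle-node
  residual tolerance 1e-8; the cusp is solved directly from
  `f = f_X = f_XX = 0`.
* Calibration: the swim period responds exactly to uniform rescaling of the
  swim time constants, so it is matched to 50 ms in one step.  The struggle
  fast period likewise via the struggle time constants, but it is left
  untouched when already within half its tolerance: the slow envelope
  period hops between locking windows under tiny rescalings, and the
  shipped set (fast 5.0 ms, slow 135 ms) sits in a good window.

## What the simulations do and do not show

The model is a population-level (mean-field) description: it contains no
spiking, no axonal conduction delays, and no rostro-caudal structure, so
head-to-tail wave propagation and intra-burst spike timing are outside its
scope.  The environmental events are idealised step inputs; real skin
stimulation is spatially distributed and noisy in amplitude, not only in
the pathway noise term.  Parameter values are a calibrated set that places
each subnetwork in the intended dynamical regime — they are constrained by
the target dynamical signatures (periods, phase relations, thresholds),
not by fits to physiological recordings, and other parameter sets in the
same regimes would reproduce the same behaviour.  Passing tests demonstrate
that the implemented mechanisms produce the intended regimes and behavioural
semantics, not that the tadpole's circuits are quantitatively identical.
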