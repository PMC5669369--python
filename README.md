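# tadsim

A population-level simulator of decision making and locomotor behaviour in
the hatchling *Xenopus* tadpole.

The hatchling tadpole has a small, well-mapped nervous system and a small
behavioural repertoire: it rests, swims (alternating left–right motor
activity at 10–25 Hz), accelerates its swimming when the light dims,
struggles (slow, strong alternating flexions) when grasped, and stops when
its head is pressed.  `tadsim` models the circuits behind this repertoire as
24 coupled Wilson–Cowan rate equations — per body side: four sensory
pathways (trunk touch TS, head touch TH, light dimming LD, head press PH),
an integrator population (xIN) whose activation constitutes the decision to
swim, swimming CPG populations (dIN, aIN, cIN), struggling CPG populations
(dINr, aINr, eCIN) and a motor pool.  Each population obeys

    tau dX/dt = -X + (k - X) S(w·activities + input + noise)

with a rectified logistic response S.  Timed environmental events (touches,
light dimming, head press, predator attack) are compiled into
piecewise-constant input traces; sensory noise is piecewise constant per
1 ms; spontaneous swim starts and stops are generated by a behavioural
controller.  The package is aimed at computational neuroscientists studying
sensorimotor decision making, central pattern generators, and
bistable/quasi-periodic population dynamics.

Key dynamical regimes, all reproduced by the calibrated defaults:

* **sensory bistability** — each pathway is a 1-D bistable unit; the xIN
  integrators latch on suprathreshold input (the decision memory) and noise
  above σ ≈ 0.2 drives spontaneous state switching;
* **swimming** — a stable quiet state coexists with a stable anti-phase
  limit cycle (period 50 ms); a 150 ms asymmetric stimulus switches between
  them, and head-press inhibition switches back;
* **struggling** — under prolonged bilateral stimulation the struggle
  network generates envelope (torus) oscillations: a 5 ms fast rhythm under
  a 135 ms slow envelope alternating between the sides, collapsing back to
  swimming when the stimulation ends.

## Worked example

```python
import tadsim

params = tadsim.default_params()                 # calibrated parameter set
scenario = tadsim.builtin_table2()               # touch, dim, attack, press
stim = tadsim.compile_scenario(scenario, params)
result = tadsim.integrate(params, stim, dt=0.1, seed=1)
for t0, t1, label in tadsim.classify(result).intervals:
    print(f"{t0:7.0f} {t1:7.0f}  {label}")
```

prints the behavioural sequence produced by the event scenario:

```
      0     200  rest
    200    1200  swim
   1200    1400  swim_accel
   1400    2000  swim
   2000    3000  struggle
   3000    6600  swim
   6600    7000  rest
```

Reading it: the tadpole rests until its left trunk is touched at 200 ms,
swims at ~20 Hz, accelerates while the light is dimmed (1200–1500 ms),
struggles exactly for the duration of the predator attack (2000–3000 ms),
resumes swimming, and returns to rest when its head is pressed at 6500 ms.
Repeating with other seeds varies the details (a bout may also stop
spontaneously) but not this grammar.

The same run from the command line:

```bash
tadsim simulate --scenario table2 --seed 1 --out run1     # trajectory + ethogram
tadsim bifurcate --theta 3 --theta 4 --theta 5            # saddle-node curves
tadsim calibrate                                          # regime verification report
tadsim classify run1/trajectory.csv                       # re-analyse a trajectory
```

Quantitative analysis of a single regime:

```python
import tadsim
p = tadsim.default_params()
stim = tadsim.compile_scenario(tadsim.swim_protocol(), p)
res = tadsim.integrate(p, stim, dt=0.1,
                       noise=tadsim.NoiseProcess([0.0]*10),
                       controllers_enabled=False)
T = tadsim.estimate_period(res.t, res.trace("mn_L"), (1500, 3000))
lag = tadsim.phase_shift(res.t, res.trace("dIN_L"), res.trace("aIN_L"), (1500, 3000))
print(f"swim period {T:.1f} ms, aIN lags dIN by {100*lag:.0f}% of a cycle")
# -> swim period 50.0 ms, aIN lags dIN by 10% of a cycle
```

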