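sensory:
  a: [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 6.0, 6.0]
  P: [1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2]
  lam: [0.8, 0.8, 0.8, 0.8]
  sigma: [0.05, 0.05, 0.05, 0.05, 0.1, 0.1, 0.05, 0.05, 0.05, 0.05]
  tau_s: 1.0
  b: [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]
  theta: [3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0]
  k: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
swim:
  w: [26.0, 16.0, 15.0, 0.0, 8.0, 3.0]
  alpha: [2.0, 0.0, 0.0]
  nu: [1.22, 1.15, 1.7]
  Q: [0.8, 0.0, 0.0, 0.8, 0.0, 0.0]
  tau: [1.4755, 3.985, 0.4432, 1.4755, 3.985, 0.4432]
  eta: 0.5
  b: [1.3, 2.0, 2.0, 1.3, 2.0, 2.0]
  theta: [4.0, 2.8, 0.8, 4.0, 2.8, 0.8]
  k: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
struggle:
  c: [16.0, 12.0, 15.0, 3.0, 8.0, 0.0]
  beta: [1.32, 0.45, 0.05]
  delta1: 1.4
  delta2: 0.4
  Delta: 0.25
  R: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  mu: [1.667, 1.667, 1.667, 1.667, 1.667, 1.667]
  gate_mode: heaviside_product
  b: [1.3, 2.0, 2.0, 1.3, 2.0, 2.0]
  theta: [4.0, 3.7, 2.0, 4.0, 3.7, 2.0]
  k: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
motor:
  gamma: [3.0, 1.0, 1.0, 15.0, 4.0, 2.0, 0.3]
  kappa: [0.7, 0.7]
  M: [0.0, 0.0]
  b: [2.0, 2.0]
  theta: [2.0, 2.0]
  k: [1.0, 1.0]
controller:
  enabled: true
  ramp_slope_range: [9.4e-07, 1.41e-06]
  start_threshold: 0.25
  kick_hold_ms: 150.0
  max_swim_range: [5000.0, 20000.0]
  stop_pulse_magnitude: 0.8
  stop_pulse_ms: 300.0
  swim_amp_threshold: 0.05
  rest_amp_threshold: 0.02
  struggle_amp_threshold: 0.05
  env_decay_ms: 60.0
event_magnitudes:
  touch_trunk: {primary: 0.5, contralateral: 0.1, delay: 30.0}
  touch_head: {primary: 0.5, contralateral: 0.1, delay: 30.0}
  light_dim: {primary: 0.8}
  press_head: {primary: 0.8}
  predator_attack: {dIN_primary: 0.57, dIN_contralateral: 0.5, dINr: 1.4}
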