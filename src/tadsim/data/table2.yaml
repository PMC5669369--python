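name: table2
duration: 7000.0
seed: null
events:
- kind: touch_trunk
  t_start: 200.0
  t_end: 350.0
  side: left
- kind: light_dim
  t_start: 1200.0
  t_end: 1500.0
  side: both
- kind: predator_attack
  t_start: 2000.0
  t_end: 3000.0
  side: both
- kind: press_head
  t_start: 6500.0
  t_end: 6600.0
  side: both
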