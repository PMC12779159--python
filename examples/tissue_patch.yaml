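kind: tissue_patch
geometry:
  Dc: 20.0
  density: 0.1
  Lx: 100.0
  Ly: 100.0
  nodes_per_rod: 15
beat:
  omega: 6.283185307179586
  theta_min: 0.8
  theta_max: 2.4
  L_fwd: 7.0
  recovery_coeffs:
  - -0.3235
  - 5.2009
  - -26.665
  - 49.471
  theta_shape: sine
  freq_hz: 18.0
flow:
  mu: 1.0
  forcing_mode: resistive
  gamma: null
  wall: true
  epsilon: 0.1
metachrony:
  phase_increment: 0.0
tracers:
  region: null
  count: 0
  labeling: x_quartile
integrator:
  scheme: rk4
  steps_per_cycle: 100
  duration_cycles: 100
  sample_every: 1
seeds:
- 1
- 2
- 3
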