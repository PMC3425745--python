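# Itinerant arm movement from a winnerless-competition pattern generator,
# plus the proprioception-removed observation replay. Time base: ms.
experiment: handwriting
attractor:
  K: 6
  rho_forward: 0.5
  rho_backward: 1.5
  rate: 0.016666666666666666
  radius: 1.2
arm:
  lengths: [1.0, 1.0]
  inertia: [1.0, 1.0]
  damping: 0.06
  spring_gain: 0.002
params:
  prop_precision: 0.25
  vis_precision: 0.5
  vis_precision_observation: 8.0
  state_precision_theta: 512.0
  state_precision_omega: 512.0
  state_precision_lv: 64.0
  roughness: 0.25
  roughness_out: 1.0
  reflex_lookahead: 2.0
  order: 3
  target_softness: 0.25
  kappa_a: 256.0
  world_damping: 0.002
integrator:
  dt: 2.0
  kappa_mu: 1.0
  kappa_a: 256.0
  scheme: local_linearisation
  action_substeps: 8
  record_uncertainty: false
duration_ms: 4200.0
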