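# Salience-driven saccadic visual search: three face hypotheses, upright
# world, eight saccades of sixteen 12 ms bins. Every free parameter of the
# run is pinned here; see docs/methods.md for rationale.
experiment: visual-search
face:
  size: 33
  contrast: 1.0
rotation_angle: 90.0
true_index: 0
sampler:
  sigma_fov: 0.25
  grid_side: 9
  max_precision: 8.0
schedule:
  n_saccades: 8
  bins_per_saccade: 16
  bin_ms: 12.0
params:
  tau_o: 8.0
  tau_h: 100000.0
  info_rate: 1.0
  prop_precision: 2.0
  state_precision_o: 512.0
  state_precision_h: 64.0
  prior_precision: 16.0
  roughness: 0.03125
  roughness_vis: 1.0
  order: 3
integrator:
  dt: 1.5
  kappa_mu: 2.0
  kappa_a: 1.0
  scheme: local_linearisation
ior:
  beta_fraction: 0.5
  sigma: null
  decay: 0.5
grid_side: 17
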