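# Methods

`actinf` simulates embodied Bayesian agents whose perception and action both
minimise variational free energy. This note records the model, the numerical
scheme, the meaning and defaults of the parameters that matter, what the
synthetic stimuli do and do not emulate, and the design choices made where
the science left the design open.

## The model class

An agent owns a hierarchical dynamic generative model. Each level has hidden
states `x` with equations of motion `f(x, v)`, causes `v`, and an output
mapping `g(x, v)` predicting the level below; the bottom level predicts
sensory data. Everything lives in *generalised coordinates of motion*: a
variable is represented by its value and temporal derivatives to embedding
order `n`, so an instant of the trajectory encodes its local dynamics. The
derivative-shift operator `D` maps each derivative block onto the slot below.

Random fluctuations are smooth: each noise stream has Gaussian
autocorrelation `exp(-γτ²/2)`, so the covariance among its derivative orders
is closed-form (`gencoords.generalised_covariance`) and the full generalised
precision of a stream factors as `kron(temporal_precision(γ, n),
spatial_precision)`. Small `γ` means smooth noise (high precision on
velocity channels); large `γ` means rough noise (derivative channels carry
little weight). Sensory channel groups may have different `γ`
(`ModelLevel.output_groups`) — this is load-bearing, see "Precision
engineering" below.

Under the Laplace (fixed-form Gaussian) assumption the variational free
energy is the precision-weighted sum of squared generalised prediction
errors plus log-normalisers,

    F = ½ Σ ε̃ᵀ Π̃ ε̃ − ½ Σ log|Π̃ / 2π|,

with error streams: sensory `ε̃_z = s̃ − g̃(μ̃)`, dynamical
`ε̃_w = Dμ̃_x − f̃(μ̃)`, and a prior stream on the top-level causes.
Predictions propagate order-by-order by the first-order chain rule
(`g̃ᵏ = ∂g·μ̃ᵏ` for k ≥ 1).

Perception and action integrate the coupled descent

    dμ̃/dt = Dμ̃ − κ_μ ∂F/∂μ̃
    da/dt  =     − κ_a ∂F/∂a .

## Numerics

- **Gradients.** `∂F/∂μ̃ = J_ε̃ᵀ Π̃ ε̃` with the error Jacobian obtained by
  central finite differences (step 1e-6) of the stacked error function;
  user-supplied analytic Jacobians of `f`/`g` accelerate prediction. The
  gradients match independent finite differences of `F` itself to ~1e-9
  relative error on random smooth models (`oracles.check_gradients`).
- **Action gradient.** `∂F/∂a = (∂s̃/∂a)ᵀ Π̃_z ε̃_z`, with the sensitivity
  from the world's action map by central differences.
- **Integration.** Default scheme is local linearisation: the
  matrix-exponential update of the Jacobian-linearised flow per step, with
  the flow Jacobian approximated as `D − κ_μ H` and `H` the Gauss-Newton
  curvature `J_ε̃ᵀ Π̃ J_ε̃`. Forward Euler is retained for testing; it is
  unstable at the default step size because the descent is stiff when
  precisions are high.
- **The reflex loop is sub-stepped.** Action and the physical world it moves
  form a loop much faster than perception (a spinal reflex under a cortical
  estimator). Each perception step of `dt` runs `action_substeps`
  semi-implicit action updates, solving `(I/(dt' κ_a) + G_a)·δa = −∂F/∂a`
  with `G_a = (∂s̃/∂a)ᵀ Π̃_z (∂s̃/∂a)` (positive semi-definite, so the
  update is unconditionally stable), advancing the world by `dt'` after
  each. Perception still updates from the pre-step expectations.
- **Uncertainty.** Conditional covariance is the inverse Gauss-Newton
  curvature at the current expectations — exact for linear-Gaussian models,
  where iterated perception also recovers the conjugate posterior mean to
  <1e-6 (`oracles.check_linear_gaussian`).
- **Descent property.** With static input and frozen action, F is
  non-increasing per step to within 1e-9·|F₀| over 1000 steps at the default
  sub-step (`oracles.check_descent`); the oracle model supplies analytic
  Jacobians because finite-difference rounding (~1e-10) otherwise produces
  spurious increases at exactly that tolerance.

## Precision engineering (why the defaults are what they are)

Active inference only moves when the agent trusts its prior dynamics more
than the sensed stillness of the world. Three choices recur in both
experiments:

- **Prior dynamics precisions high** (state precision 512 on oculomotor and
  arm states) versus **modest sensory precisions** (proprioception 2 and
  0.25, vision 8 and 0.5): expectations roll out the intended trajectory and
  the reflex drags the world along, instead of beliefs being pinned to a
  static world.
- **Rough sensory noise** (γ = 1) versus **smooth state noise** (γ = 1/32 or
  1/4): a smooth stream's velocity channels carry enormous temporal
  precision; if vision were smooth, its optic-flow channel would pin the
  gaze-velocity expectation and saccades would never launch. Rough visual
  noise is also a reading of saccadic suppression.
- **Top-order truncation**: with n = 3 the unrepresented third derivative is
  penalised through the temporal precision's last diagonal entry, which for
  very smooth noise (γ = 1/32, T₂₂ ≈ 512) freezes acceleration
  expectations. The motor model therefore uses γ = 1/4 for its state noise.

## The visual-search experiment

Hidden states: gaze displacement `x_o` (2) and hypothesis log-propensities
`x_h` (K = 3); cause: the 2-D prior gaze attractor `η` selected from the
salience map. `f`: `dx_o/dt = (η − x_o)/τ_o` (τ_o = 8 ms),
`dx_h/dt = −x_h/τ_h` with τ_h = 1e5 ms — the stimulus is constant within a
trial, so the leak is effectively absent and evidence integrates across
saccades. `g`: the softmax-weighted mixture of the templates foveally
sampled at the believed gaze, plus the proprioceptive gaze readout.

The fovea is a 9×9 lattice clipped to a disc of radius 2σ_fov (σ_fov = 0.25
gaze units, ~60 samples); per-offset precision is `8·exp(−e²/2σ_fov²)`. The
world shows one true template; action is a gaze-velocity command.

**Salience** at candidate location `l` is the expected precision-weighted
discriminability of fictive data,
`Σ_k w_k Σ_i ρ_i (m_ki(l) − m̄_i(l))²`, a monotone surrogate of the
posterior-confidence gain fictive sampling would afford. It is computed on a
17×17 grid at saccade boundaries only. Inhibition of return subtracts
Gaussian bumps (amplitude 0.5·map-maximum, width σ_fov, geometric decay 0.5
per saccade) at remembered fixations. The schedule is 8 saccades × 16 bins
× 12 ms, sub-stepped at dt = 1.5 ms with κ_μ = 2.

**Reported confidence.** The 90 % interval about the true stimulus is
±1.645·sd on the log-propensity scale with

    sd_k(t)² = 1/P_k(t) + blur_k(t)² + innovation_k(t)²,

where `P_k` assimilates the instantaneous Fisher information of each
hypothesis recursively (inflow `info_rate`·`Σ_i ρ_i (w_k(m_ki − vis_i))²`,
leak 2/τ_h) — filtering schemes propagate conditional precision over time,
which a memoryless instantaneous curvature cannot reproduce; `blur` is the
gaze-motion marginalisation (a gaze smear of one noise-correlation time,
`|v|·γ_vis^-½`, masquerades as hypothesis evidence through the
hypothesis-gaze cross-information); and `innovation` is adaptive-filtering
inflation by the expectation's own motion over the last bin. At a settled
fixation both transients vanish and the uncertainty collapses to the
accumulated level — hence stepwise shrinkage across saccades with transient
increases during the fast phase, the two signatures the experiment tests.

## The itinerant-motor experiment

A generalised Lotka-Volterra network (K = 6, `dx_i/dt = rate·x_i(1 − Σ_j
A_ij x_j)`, rate = 1/60 ms⁻¹) with cyclic asymmetric competition
(`a_ii = 1`, weak 0.5 from the predecessor, strong 1.5 from the successor)
produces winnerless competition: the trajectory cycles near the single-state
vertices in ascending order. The agent's generative model carries *log*
activities `z = log x`, whose flow `dz/dt = rate(1 − A e^z)` is globally
stable while `e^z` follows the ordinary solution exactly.

The dominant state selects a workspace target on a circle of radius 1.2
(inside the reachable annulus of the two-link arm, L₁ = L₂ = 1); the
generative model believes the endpoint is drawn to it by a spring
(k_s = 2e-3 ms⁻², endpoint damping 0.06 ms⁻¹) whose torques are the
Jacobian-transpose image of the endpoint force, with diagonal inertia and no
Coriolis terms. The target map uses a sharp softmax (temperature 0.25)
rather than a hard argmax so that visual evidence can re-phase the attractor
states during observation — a hard winner has zero gradient and would make
action observation impossible; `target_softness=0` restores the hard switch.

Sensation: muscle spindles report joint angles *and* velocities (the
velocity channel carries a 2 ms reflex look-ahead `ω + la·acc(a)`, giving
torque direct leverage on sensed stretch velocity — without it the reflex
has position and acceleration terms but no velocity term, because odd
cross-order temporal precisions vanish); vision reports the endpoint (red
ball) and the displayed target (green ball). During self-generated action
the green ball tracks the agent's own intention and receives ~0 attention
(precision 1e-2·vision); an observer attends it (precision 8) and can read
the demonstrator's intention from it — this is the channel that makes
mirror entrainment strong (median per-state correlation ≈ 0.99 from a
hypothesis-neutral observer start, versus ≈ +0.015 over a vision-ablated
control when the observer can only see the endpoint).

Observation mode scales proprioceptive precision by 1e-6 (not exactly 0, to
keep precisions positive definite), disables action, and replays the
recorded visual stream. Place-field analysis thresholds each state's
activity at half its maximum and reports the endpoint positions, centroid
and dispersion.

## Synthetic stimuli

The face-like templates are parametric geometry (elliptical outline, two
eyes, a curved mouth, smooth Gaussian-profile strokes), rendered at 33×33,
left-right symmetric, deterministic, with inverted (vertical flip) and
rotated (90° clockwise, exact pixel permutation) variants. They emulate the
role of the original stimuli — three mutually exclusive, partially
overlapping image hypotheses — not face statistics: a green run establishes
that evidence accumulation, salience-driven sampling and inhibition of
return behave as described, not that the model generalises to photographs,
natural scenes, or free viewing.

All simulations are noise-free demonstrations by default; the seed controls
only tiny symmetry-breaking jitter in the motor initial conditions, so runs
are reproducible byte for byte.

## Known limitations

- Salience is our concretisation of a verbally-defined quantity; an
  implementation maximising the expected log-determinant of posterior
  precision could select slightly different fixations.
- The reported hypothesis confidence uses the assimilated-information
  readout described above, not the raw instantaneous curvature (which is
  memoryless and cannot show accumulation); the instantaneous curvature
  remains available via `conditional_std`.
- The arm is a simplified Newtonian model (diagonal, configuration-
  independent inertia); full manipulator dynamics, muscle models, and
  letter-shaped target layouts are out of scope.
- No learning: model parameters, precisions and templates are fixed; there
  is no M-step and no discrete-state machinery.
- Euler integration is provided for testing but is not stable at the
  default precisions and step sizes; use local linearisation.
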