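# actinf — active inference by generalised predictive coding

`actinf` simulates embodied agents that perceive and act by jointly
minimising variational free energy. It is aimed at computational
neuroscientists and students of the free-energy principle who want a
compact, fully-tested reference implementation of generalised predictive
coding — plus two classic embodied demonstrations built on top of it:
salience-driven saccadic visual search, and itinerant arm movements from a
winnerless-competition pattern generator with a mirror-neuron-style
action-observation mode.

## The model in brief

The agent entertains a hierarchical dynamic generative model with hidden
states `x`, causes `v`, equations of motion `f` and sensory mapping `g`,
all in generalised coordinates of motion (values plus temporal derivatives,
tilde notation). Under the Laplace assumption the variational free energy
is a precision-weighted sum of squared generalised prediction errors,

    F = ½ Σ ε̃ᵀ Π̃ ε̃ − ½ Σ log|Π̃/2π| ,
    ε̃_z = s̃ − g̃(μ̃),   ε̃_w = Dμ̃_x − f̃(μ̃),

and both perception (posterior expectations `μ̃`) and action `a` descend
on it:

    dμ̃/dt = Dμ̃ − κ_μ ∂F/∂μ̃ ,        da/dt = − κ_a ∂F/∂a .

Perception is generalised predictive coding (Kalman-Bucy-like filtering);
action is a classical reflex arc that changes sensory input to fulfil the
agent's predictions. *Salience* — the posterior confidence that fictively
sampling a location would afford — enters as a prior on where to look next,
with inhibition of return depleting recently foveated locations.

See `docs/methods.md` for the full model, numerics and parameter rationale.

## Worked example

```bash
python examples/visual_search.py
```

prints (abridged):

```
fixation sequence (gaze units, origin = image centre):
  saccade 0: (-0.56, +0.00)
  saccade 1: (+0.00, -0.57)
  saccade 2: (+0.00, +0.56)
  ...
final posterior weights:
  upright   0.9945
  inverted  0.0023
  rotated   0.0032

uncertainty about the true stimulus (start, then each fixation end):
  297.672  0.818  0.414  0.362  0.356  0.323  0.313  0.289  0.284
```

The agent, shown an upright face-like pattern while entertaining upright /
inverted / rotated hypotheses, fixates the most diagnostic locations (eyes,
mouth), never refixates the same spot twice in a row (inhibition of
return), ends ~99.5 % confident in the true hypothesis, and its 90 %
confidence interval about the true stimulus shrinks at every saccade —
with transient increases only during the fast phase of each saccade.

Other examples, one per capability:

- `examples/exact_inference.py` — perception recovers a conjugate-Gaussian
  posterior exactly (mean to ~1e-12, variance from the free-energy
  curvature).
- `examples/itinerant_arm.py` — the two-joint arm visits six targets in the
  attractor's cyclic order; half-max activity of each state forms a
  place-field-like patch.
- `examples/action_observation.py` — replaying the visual stream with
  proprioception removed entrains the same state units (median per-state
  correlation ≈ 0.99): mirror-neuron-like responses.
- `examples/make_stimuli.py` — renders the stimulus templates and a full
  run's CSV/image artifacts through the scenario runner
  (`actinf.runner.simulate` / `report`), byte-reproducible per seed.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs everything from scratch: the oracle battery (gradients versus
finite differences on 50 random smooth models; exact linear-Gaussian
inference; 1000-step free-energy descent; brute-force salience argmax), the
full eight-saccade visual search, and the motor experiment with its
action-observation replay, printing a one-line summary of each. The source
publication reports its outcomes as figures and behavioural properties
rather than printed numbers, so the JSON target mapping it writes is empty;
the behavioural properties themselves are asserted by
`tests/test_acceptance.py`.
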