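"""Salience maps, inhibition of return, and the saccade scheduler.

Salience at a candidate fixation location is the posterior confidence
about the hidden causes of sensory input that *would* be afforded by
fictively sampling from that location.  Under the Laplace assumption the
expected gain in posterior precision over the hypothesis states is
monotone in the precision-weighted discriminability of the fictive data,
which is what this module computes::

    salience(l) = sum_k w_k sum_i rho_i (m_ki(l) - mbar_i(l))^2

where ``m_ki(l)`` is template k fictively foveal-sampled at l with
retinal offset i, ``rho_i`` the foveal precision profile, ``w`` the
current posterior hypothesis weights and ``mbar`` the w-weighted mean
prediction.  Previously foveated locations are depleted by a Gaussian
inhibition-of-return kernel with geometric decay over saccades.

The scheduler alternates (i) compute salience under the current
posterior, apply inhibition of return, select the peak as the prior gaze
attractor, and (ii) integrate the perception-action dynamics for one
inter-saccadic epoch with that attractor as prior cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .active_inference import AgentState, IntegratorConfig, SimulationTrace, run_epoch
from .exceptions import ConfigurationError, NumericalDomainError
from .hdm import conditional_std
from .visual_world import (
    FovealSampler,
    HypothesisSet,
    SearchParams,
    VisualWorld,
    foveal_sample,
    make_search_model,
    sample_image,
    softmax,
)

__all__ = [
    "SalienceMap",
    "SaccadeSchedule",
    "IORParams",
    "make_grid",
    "raw_salience",
    "apply_inhibition_of_return",
    "select_target",
    "run_visual_search",
    "SearchResult",
]


@dataclass
class SalienceMap:
    """Candidate fixation grid with raw and IOR-depleted salience values."""

    points: np.ndarray                 # (G, 2) gaze-unit locations, row-major
    shape: tuple                       # (rows, cols) of the grid
    raw: np.ndarray                    # (G,)
    effective: np.ndarray              # (G,) after inhibition of return
    ior_memory: list = field(default_factory=list)   # [(location, age), ...]

    def value_at(self, loc) -> float:
        """Effective salience at the grid point nearest ``loc``."""
        i = int(np.argmin(np.linalg.norm(self.points - np.asarray(loc), axis=1)))
        return float(self.effective[i])

    def as_grid(self, which: str = "effective") -> np.ndarray:
        return getattr(self, which).reshape(self.shape)


@dataclass
class SaccadeSchedule:
    """How many saccades, inter-saccadic bins, and bin duration (ms)."""

    n_saccades: int = 8
    bins_per_saccade: int = 16
    bin_ms: float = 12.0

    def __post_init__(self) -> None:
        if self.n_saccades < 1 or self.bins_per_saccade < 1 or self.bin_ms <= 0:
            raise ConfigurationError("schedule entries must be positive")


@dataclass
class IORParams:
    """Inhibition-of-return kernel: amplitude fraction, width, decay.

    ``beta_fraction`` scales the depletion amplitude to the current raw
    map maximum; ``sigma`` is the spatial width (defaults to the foveal
    width downstream); ``decay`` is the geometric factor per saccade.
    """

    beta_fraction: float = 0.5
    sigma: float | None = None
    decay: float = 0.5


def make_grid(extent: float = 1.0, side: int = 17, span: float = 0.9) -> tuple:
    """Row-major candidate-fixation grid over the image extent.

    Row 0 is the top of the image (largest y), matching image layout so
    the row-major tie-break is well defined.
    """
    if side < 1:
        raise ConfigurationError("grid side must be >= 1")
    lin = np.linspace(-span * extent, span * extent, side)
    xs, ys = np.meshgrid(lin, lin[::-1])
    points = np.column_stack([xs.ravel(), ys.ravel()])
    return points, (side, side)


def raw_salience(weights: np.ndarray, hset: HypothesisSet, sampler: FovealSampler,
                 grid_points: np.ndarray, grid_shape: tuple | None = None) -> SalienceMap:
    """Expected precision-weighted discriminability of fictive data.

    ``weights`` are the current posterior hypothesis weights (softmax of
    the hypothesis log-propensities).  With a single hypothesis, or
    identical templates, the map is identically zero: fictive sampling
    cannot disambiguate anything.
    """
    grid_points = np.asarray(grid_points, dtype=float)
    if grid_points.size == 0:
        raise ConfigurationError("salience grid is empty")
    w = np.asarray(weights, dtype=float).reshape(-1)
    if w.size != hset.K:
        raise ConfigurationError(f"expected {hset.K} weights, got {w.size}")
    w = w / w.sum()
    positions = grid_points[:, None, :] + sampler.offsets[None, :, :]  # (G, R, 2)
    m = np.stack([sample_image(t, positions) for t in hset.templates])  # (K, G, R)
    mbar = np.einsum("k,kgr->gr", w, m)
    disp = np.einsum("k,kgr->g", w, (m - mbar[None]) ** 2 * sampler.precision_profile)
    shape = grid_shape or (len(grid_points), 1)
    return SalienceMap(points=grid_points, shape=shape, raw=disp,
                       effective=disp.copy(), ior_memory=[])


def apply_inhibition_of_return(smap: SalienceMap, beta: float, sigma_ior: float,
                               decay: float) -> SalienceMap:
    """Deplete salience around remembered fixations.

    ``effective(l) = raw(l) - sum_j beta * decay**age_j *
    exp(-|l - l_j|^2 / (2 sigma_ior^2))`` over the fixation history.
    """
    if beta < 0 or sigma_ior <= 0 or not (0 <= decay <= 1):
        raise ConfigurationError("require beta >= 0, sigma_ior > 0, 0 <= decay <= 1")
    eff = smap.raw.copy()
    for loc, age in smap.ior_memory:
        d2 = np.sum((smap.points - np.asarray(loc)) ** 2, axis=1)
        eff -= beta * decay**age * np.exp(-d2 / (2 * sigma_ior**2))
    return replace(smap, effective=eff)


def select_target(smap: SalienceMap) -> np.ndarray:
    """Grid location of maximum effective salience; ties -> lowest index."""
    vals = smap.effective
    if np.all(np.isnan(vals)):
        raise NumericalDomainError("salience map is all-NaN")
    return smap.points[int(np.nanargmax(vals))].copy()


# ---------------------------------------------------------------------------
# the full visual-search experiment
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    """Everything a visual-search run produced."""

    trace: SimulationTrace
    salience_maps: list            # per-saccade maps (effective incl. IOR)
    fixations: np.ndarray          # (n_saccades, 2) gaze at each saccade end
    targets: np.ndarray            # (n_saccades, 2) selected prior attractors
    hypothesis_weights: np.ndarray  # (T, K) softmax of hypothesis states
    hypothesis_states: np.ndarray   # (T, K) log-propensity expectations
    state_std: np.ndarray          # (T, K) state-scale conditional std
    epoch_ends: np.ndarray         # indices into the trace of each saccade end
    initial_uncertainty: float     # std of the true hypothesis state at t=0
    true_index: int
    schedule: SaccadeSchedule
    diverged: bool = False

    def posteriors_frame(self):
        """Tidy per-bin posterior table with 90 % credible bands.

        Expectations and intervals are on the hypothesis-state
        (log-propensity) scale the model infers on; the softmax weight is
        carried alongside for categorical reading.
        """
        import pandas as pd

        K = self.hypothesis_states.shape[1]
        rows = []
        for k in range(K):
            x = self.hypothesis_states[:, k]
            sd = self.state_std[:, k]
            rows.append(pd.DataFrame({
                "time_ms": self.trace.times,
                "hypothesis": k,
                "expectation": x,
                "ci_low": x - 1.645 * sd,
                "ci_high": x + 1.645 * sd,
                "weight": self.hypothesis_weights[:, k],
            }))
        return pd.concat(rows, ignore_index=True)

    def fixation_end_uncertainty(self) -> np.ndarray:
        """Uncertainty about the true hypothesis at each saccade end."""
        return self.state_std[self.epoch_ends, self.true_index]


def _hypothesis_information(mu_t: np.ndarray, hset: HypothesisSet,
                            sampler: FovealSampler, grad_step: float = 1e-3):
    """Instantaneous Fisher information of each hypothesis state.

    The sensitivity of the visual prediction to log-propensity k is
    ``w_k (m_k - vis)``; weighting by the foveal precision profile gives
    the information the current (believed) fixation carries about each
    hypothesis per unit time.  Also returned is the hypothesis-gaze
    cross-information (how much a gaze error masquerades as hypothesis
    evidence), needed to marginalise gaze motion out of the reported
    confidence.
    """
    K = hset.K
    x_o, x_h = mu_t[:2], mu_t[2 : 2 + K]
    w = softmax(x_h)
    m = np.stack([foveal_sample(t, x_o, sampler) for t in hset.templates])
    vis = w @ m
    dvis = w[:, None] * (m - vis[None, :])                    # (K, R)
    info = np.einsum("kr,r->k", dvis**2, sampler.precision_profile)
    # mixture-prediction gradient w.r.t. gaze, central differences
    G = np.zeros((sampler.R, 2))
    for d in range(2):
        dx = np.zeros(2)
        dx[d] = grad_step
        mp = np.stack([foveal_sample(t, x_o + dx, sampler) for t in hset.templates])
        mm = np.stack([foveal_sample(t, x_o - dx, sampler) for t in hset.templates])
        G[:, d] = w @ (mp - mm) / (2 * grad_step)
    cross = np.einsum("kr,r,rd->kd", dvis, sampler.precision_profile, G)  # (K, 2)
    return info, cross


def _effective_state_std(P_acc: np.ndarray, cross: np.ndarray,
                         gaze_velocity: np.ndarray, blur_time: float,
                         innovation: np.ndarray) -> np.ndarray:
    """Hypothesis-state uncertainty with transients marginalised in.

    The accumulated conditional variance ``1/P`` is inflated by two
    transient terms.  Motion blur: while the (believed) gaze sweeps at
    velocity v, data assimilated over one noise-correlation time come
    from a smear of width ``|v| blur_time``; a gaze error of that size
    masquerades as hypothesis evidence ``cross @ de``, displacing the
    estimate by ``cross @ de / P``.  Innovation inflation: while the
    expectation itself is still moving (``innovation`` = its change over
    the last time bin), the current value cannot be trusted to better
    than that change — the standard adaptive-filtering inflation.  Both
    vanish at a settled fixation, where the uncertainty collapses back
    to the accumulated level.
    """
    blur = (cross @ (gaze_velocity * blur_time)) / P_acc
    return np.sqrt(1.0 / P_acc + blur**2 + innovation**2)


def run_visual_search(
    hset: HypothesisSet,
    sampler: FovealSampler,
    schedule: SaccadeSchedule | None = None,
    params: SearchParams | None = None,
    integrator: IntegratorConfig | None = None,
    ior: IORParams | None = None,
    grid_side: int = 17,
    seed: int = 0,
) -> SearchResult:
    """Run the full salience-driven visual search.

    The run is deterministic (noise-free world); ``seed`` is accepted for
    interface uniformity and reserved for stochastic extensions.
    """
    schedule = schedule or SaccadeSchedule()
    params = params or SearchParams()
    integrator = integrator or IntegratorConfig(dt=schedule.bin_ms / 8.0, kappa_mu=2.0)
    if not integrator.record_uncertainty:
        integrator = replace(integrator, record_uncertainty=True)
    ior = ior or IORParams()
    sigma_ior = ior.sigma if ior.sigma is not None else sampler.sigma_fov
    K = hset.K

    model = make_search_model(hset, sampler, params)
    world = VisualWorld(hset, sampler, order=params.order, gaze0=(0.0, 0.0))
    extent = hset.templates[0].extent
    grid_points, grid_shape = make_grid(extent=extent, side=grid_side)

    mu0 = np.zeros(model.mu_dim)
    state = AgentState(mu=mu0, action=np.zeros(2), time=0.0)

    steps_per_epoch = max(1, int(round(schedule.bins_per_saccade * schedule.bin_ms
                                       / integrator.dt)))
    bin_steps = max(1, int(round(schedule.bin_ms / integrator.dt)))
    h_idx = [model.coordinate_index(0, "x", 0, 2 + k) for k in range(K)]
    v_idx = [model.coordinate_index(0, "x", 1, i) for i in range(2)]  # gaze velocity
    blur_time = 1.0 / np.sqrt(params.roughness_vis)
    s0 = world.sense(0.0, state.action)
    sd0 = conditional_std(model, s0, state.mu)
    # conditional precision of the hypothesis states is assimilated
    # recursively: instantaneous Fisher information flows in at
    # ``info_rate`` and stale information leaks out with the (slow)
    # hypothesis time constant, mirroring how filtering schemes
    # propagate posterior precision over time
    P_floor = 1.0 / np.maximum(sd0[h_idx], 1e-12) ** 2
    P_acc = P_floor.copy()
    initial_uncertainty = float(1.0 / np.sqrt(P_acc[hset.true_index]))

    maps, fixations, targets, traces = [], [], [], []
    weights_hist, states_hist, wstd_hist, epoch_ends = [], [], [], []
    memory: list = []
    diverged = False
    step_count = 0
    for sac in range(schedule.n_saccades):
        blocks = model.unpack(state.mu)
        w = softmax(blocks[0]["x"][0, 2 : 2 + K])
        smap = raw_salience(w, hset, sampler, grid_points, grid_shape)
        smap.ior_memory = [(loc, age) for loc, age in memory]
        beta = ior.beta_fraction * float(smap.raw.max())
        smap = apply_inhibition_of_return(smap, beta, sigma_ior, ior.decay)
        eta = select_target(smap)
        model.set_prior(eta)
        maps.append(smap)
        targets.append(eta)

        trace, state = run_epoch(state, model, world, integrator, steps_per_epoch)
        traces.append(trace)
        for mu_t in trace.expectations:
            info, cross = _hypothesis_information(mu_t, hset, sampler)
            P_acc = P_acc + integrator.dt * (
                -(2.0 / params.tau_h) * (P_acc - P_floor) + params.info_rate * info
            )
            x_h = mu_t[h_idx].copy()
            # innovation: how far the expectation moved over the last bin
            past = states_hist[-bin_steps] if len(states_hist) >= bin_steps else \
                (states_hist[0] if states_hist else x_h)
            sd_eff = _effective_state_std(P_acc, cross, mu_t[v_idx], blur_time,
                                          np.abs(x_h - past))
            weights_hist.append(softmax(x_h))
            states_hist.append(x_h)
            wstd_hist.append(sd_eff)
        step_count += len(trace)
        epoch_ends.append(step_count - 1)
        fixations.append(world.gaze.copy())
        memory = [(loc, age + 1) for loc, age in memory]
        memory.insert(0, (world.gaze.copy(), 0))
        if trace.diverged:
            diverged = True
            break

    full = SimulationTrace(
        times=np.concatenate([t.times for t in traces]),
        expectations=np.vstack([t.expectations for t in traces]),
        uncertainties=np.vstack([t.uncertainties for t in traces])
        if traces[0].uncertainties.size else np.zeros((0, 0)),
        actions=np.vstack([t.actions for t in traces]),
        free_energies=np.concatenate([t.free_energies for t in traces]),
        sensory=np.vstack([t.sensory for t in traces]),
        diverged=diverged,
    )
    return SearchResult(
        trace=full,
        salience_maps=maps,
        fixations=np.asarray(fixations),
        targets=np.asarray(targets),
        hypothesis_weights=np.asarray(weights_hist),
        hypothesis_states=np.asarray(states_hist),
        state_std=np.asarray(wstd_hist),
        epoch_ends=np.asarray(epoch_ends),
        initial_uncertainty=initial_uncertainty,
        true_index=hset.true_index,
        schedule=schedule,
        diverged=diverged,
    )
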