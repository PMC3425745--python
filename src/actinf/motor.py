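"""Itinerant motor control and action observation.

A generalised Lotka-Volterra attractor with cyclic asymmetric
competition acts as a central pattern generator: its trajectory cycles
sequentially near single-state saddles (winnerless competition), and the
currently dominant state selects a target point in the workspace.  The
agent's generative model predicts that a two-joint arm is drawn to that
target by an imaginary spring; classical reflex arcs (action minimising
proprioceptive prediction error) make the prediction come true.

Removing proprioceptive input (scaling its precision to ~0 and disabling
action) while replaying the visual consequences of a previous run turns
the same model into an observer: the attractor states are then inferred
from vision alone, reproducing mirror-neuron-like activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .active_inference import AgentState, IntegratorConfig, SimulationTrace
from .exceptions import ConfigurationError
from .hdm import HierarchicalModel, ModelLevel

__all__ = [
    "LVAttractor",
    "ArmModel",
    "ObservationMode",
    "MotorParams",
    "MotorResult",
    "default_attractor",
    "lv_flow",
    "winner",
    "forward_kinematics",
    "arm_jacobian",
    "arm_flow",
    "run_motor_simulation",
    "place_field_analysis",
    "PlaceFields",
    "visitation_sequence",
]


@dataclass
class LVAttractor:
    """Competitive Lotka-Volterra network with one workspace target per state.

    ``connectivity`` must carry the cyclic asymmetry (weak competition
    forward along the cycle, strong backward) that produces winnerless
    itinerancy rather than a stable coexistence equilibrium.
    """

    K: int
    connectivity: np.ndarray      # (K, K)
    rate: float                   # 1/ms time constant of the flow
    targets: np.ndarray           # (K, 2) workspace points

    def __post_init__(self) -> None:
        A = np.asarray(self.connectivity, dtype=float)
        if A.shape != (self.K, self.K):
            raise ConfigurationError("connectivity must be K x K")
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")
        self.connectivity = A
        self.targets = np.asarray(self.targets, dtype=float).reshape(self.K, 2)


def default_attractor(K: int = 6, rho_forward: float = 0.5, rho_backward: float = 1.5,
                      rate: float = 1.0 / 60.0, radius: float = 1.2,
                      lengths=(1.0, 1.0)) -> LVAttractor:
    """Cyclic winnerless-competition attractor with targets on a circle.

    ``a_ii = 1``, ``a_{i,i+1} = rho_forward < 1``, ``a_{i,i-1} =
    rho_backward > 1`` (indices mod K) yields a stable heteroclinic
    channel visiting the K single-state vertices in order.  Targets sit
    on a circle of the given radius, inside the arm's reachable annulus.
    """
    lo, hi = abs(lengths[0] - lengths[1]), lengths[0] + lengths[1]
    if not (lo < radius < hi):
        raise ConfigurationError(
            f"target radius {radius} outside reachable annulus ({lo}, {hi})"
        )
    A = np.ones((K, K))
    for i in range(K):
        A[i, i] = 1.0
        # state i+1 feels weak competition from i, so it inherits dominance:
        # the winner sequence ascends 0, 1, ..., K-1 cyclically
        A[(i + 1) % K, i] = rho_forward
        A[(i - 1) % K, i] = rho_backward
    ang = 2 * np.pi * np.arange(K) / K
    targets = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return LVAttractor(K=K, connectivity=A, rate=rate, targets=targets)


def lv_flow(x: np.ndarray, attractor: LVAttractor) -> np.ndarray:
    """Generalised Lotka-Volterra velocity on the positive orthant."""
    x = np.asarray(x, dtype=float).reshape(-1)
    return attractor.rate * x * (1.0 - attractor.connectivity @ x)


def winner(x: np.ndarray) -> int:
    """Index of the currently dominant state; ties go to the lowest index."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size < 1:
        raise ConfigurationError("winner of an empty vector is undefined")
    return int(np.argmax(x))


def _target_weights(z_lv: np.ndarray, softness: float) -> np.ndarray:
    z = np.asarray(z_lv, float) / softness
    e = np.exp(z - z.max())
    return e / e.sum()


def _soft_target(z_lv: np.ndarray, attractor: LVAttractor,
                 softness: float) -> np.ndarray:
    """Workspace target of the current attractor state.

    ``softness > 0`` blends targets with softmax(z / softness) — a sharp
    but differentiable version of "the currently active state"; 0 gives
    the hard winner.
    """
    if softness <= 0:
        return attractor.targets[winner(z_lv)]
    return _target_weights(z_lv, softness) @ attractor.targets


@dataclass
class ArmModel:
    """Planar two-joint arm with diagonal inertia.

    ``theta[0]`` is the absolute shoulder angle, ``theta[1]`` the
    relative elbow angle; the endpoint is drawn to targets by a spring
    of gain ``spring_gain`` with endpoint damping ``damping``.
    """

    lengths: tuple = (1.0, 1.0)
    inertia: tuple = (1.0, 1.0)
    damping: float = 0.06          # endpoint damping per ms (overdamped reach)
    spring_gain: float = 2e-3      # spring stiffness per ms^2 (settles in ~100 ms)
    # default pose bends the elbow: the outstretched arm is a kinematic
    # singularity where radial forces produce no torque
    theta: np.ndarray = field(default_factory=lambda: np.array([0.4, 0.9]))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if min(self.lengths) <= 0 or min(self.inertia) <= 0:
            raise ConfigurationError("lengths and inertia must be positive")
        self.theta = np.asarray(self.theta, dtype=float).reshape(2).copy()
        self.omega = np.asarray(self.omega, dtype=float).reshape(2).copy()


def forward_kinematics(theta: np.ndarray, lengths=(1.0, 1.0)) -> np.ndarray:
    """Endpoint position of the two-joint arm."""
    t1, t2 = np.asarray(theta, dtype=float).reshape(2)
    L1, L2 = lengths
    return np.array([
        L1 * np.cos(t1) + L2 * np.cos(t1 + t2),
        L1 * np.sin(t1) + L2 * np.sin(t1 + t2),
    ])


def arm_jacobian(theta: np.ndarray, lengths=(1.0, 1.0)) -> np.ndarray:
    """d(endpoint)/d(theta), 2 x 2."""
    t1, t2 = np.asarray(theta, dtype=float).reshape(2)
    L1, L2 = lengths
    s1, c1 = np.sin(t1), np.cos(t1)
    s12, c12 = np.sin(t1 + t2), np.cos(t1 + t2)
    return np.array([
        [-L1 * s1 - L2 * s12, -L2 * s12],
        [L1 * c1 + L2 * c12, L2 * c12],
    ])


def arm_flow(arm: ArmModel, target: np.ndarray,
             theta: np.ndarray | None = None,
             omega: np.ndarray | None = None) -> np.ndarray:
    """Angular accelerations from the imaginary spring to ``target``.

    Joint torques are the Jacobian-transpose image of the endpoint force
    ``k_s (p - e) - c e_dot``; accelerations divide by diagonal inertia.
    """
    th = arm.theta if theta is None else np.asarray(theta, float).reshape(2)
    om = arm.omega if omega is None else np.asarray(omega, float).reshape(2)
    J = arm_jacobian(th, arm.lengths)
    e = forward_kinematics(th, arm.lengths)
    e_dot = J @ om
    force = arm.spring_gain * (np.asarray(target, float).reshape(2) - e) \
        - arm.damping * e_dot
    tau = J.T @ force
    return tau / np.asarray(arm.inertia, dtype=float)


@dataclass
class ObservationMode:
    """Action versus observation: proprioceptive precision scale and agency."""

    proprioceptive_precision_scale: float = 1.0
    action_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.proprioceptive_precision_scale <= 1.0):
            raise ConfigurationError("precision scale must lie in [0, 1]")
        if self.proprioceptive_precision_scale < 1e-3 and self.action_enabled:
            raise ConfigurationError("observation mode implies action_enabled = False")

    @classmethod
    def action(cls) -> "ObservationMode":
        return cls(1.0, True)

    @classmethod
    def observation(cls, scale: float = 1e-6) -> "ObservationMode":
        # exactly zero would make the output precision singular
        return cls(scale, False)


@dataclass
class MotorParams:
    """Tunables of the motor generative model (time base: ms)."""

    # prior dynamics must dominate sensory precision, else the agent
    # believes the sensed stillness instead of its itinerant intentions
    prop_precision: float = 0.25
    vis_precision: float = 0.5
    # attention boosts visual precision when merely observing: vision is
    # then the only channel that can entrain the attractor states
    vis_precision_observation: float = 8.0
    state_precision_theta: float = 512.0
    state_precision_omega: float = 512.0
    state_precision_lv: float = 64.0
    roughness: float = 0.25         # state noise roughness
    roughness_out: float = 1.0      # rough sensory noise: prior dynamics,
                                    # not sensed stillness, drive movement
    reflex_lookahead: float = 2.0   # ms of velocity look-ahead in the spindle
    order: int = 3                  # channel, giving torque direct leverage
    target_softness: float = 0.25   # softmax temperature of the winner->target map
    kappa_a: float = 256.0          # reflex gain
    world_damping: float = 2e-3     # viscous joint damping of the physical arm (1/ms)


def make_motor_model(attractor: LVAttractor, arm: ArmModel,
                     params: MotorParams, mode: ObservationMode) -> HierarchicalModel:
    """Generative model: attractor states -> spring target -> arm -> senses.

    Hidden states ``[theta (2), omega (2), z_lv (K)]`` where ``z_lv`` are
    the *log* attractor activities: the Lotka-Volterra flow in log space,
    ``dz/dt = rate (1 - A exp(z))``, is globally stable (no runaway off
    the positive orthant), while ``exp(z)`` follows exactly the ordinary
    LV solution.  The sensory mapping reports joint angles and angular
    velocities (proprioception: muscle spindles signal both length and
    stretch velocity) and two visual objects: the endpoint (the red ball)
    and the displayed target (the green ball), predicted as the
    softmax-weighted mixture of the per-state target points.  The target
    channel is what lets an observer infer the demonstrator's attractor
    state from vision alone; in observation mode the proprioceptive
    precision is scaled toward zero.
    """
    K = attractor.K
    nx = 4 + K
    A = attractor.connectivity
    rate = attractor.rate
    _fd = 1e-6

    def f(x, v):
        th, om, z = x[:2], x[2:4], x[4:]
        p = _soft_target(z, attractor, params.target_softness)
        acc = arm_flow(arm, p, theta=th, omega=om)
        dz = rate * (1.0 - A @ np.exp(np.clip(z, -50.0, 50.0)))
        return np.concatenate([om, acc, dz])

    def g(x, v):
        th, om, z = x[:2], x[2:4], x[4:]
        return np.concatenate([
            th, om,
            forward_kinematics(th, arm.lengths),
            _soft_target(z, attractor, max(params.target_softness, 1e-6)),
        ])

    def jac_g(x, v):
        z = x[4:]
        Jgx = np.zeros((8, nx))
        Jgx[:2, :2] = np.eye(2)
        Jgx[2:4, 2:4] = np.eye(2)
        Jgx[4:6, :2] = arm_jacobian(x[:2], arm.lengths)
        soft = max(params.target_softness, 1e-6)
        w = _target_weights(z, soft)
        dw = (np.diag(w) - np.outer(w, w)) / soft
        Jgx[6:8, 4:] = attractor.targets.T @ dw
        return Jgx, np.zeros((8, 0))

    def jac_f(x, v):
        th, om, z = x[:2], x[2:4], x[4:]
        J = np.zeros((nx, nx))
        J[:2, 2:4] = np.eye(2)
        # arm-acceleration sensitivities to theta/omega by central differences
        p = _soft_target(z, attractor, params.target_softness)
        for i in range(4):
            d = np.zeros(4)
            d[i] = _fd
            ap = arm_flow(arm, p, theta=th + d[:2], omega=om + d[2:])
            am = arm_flow(arm, p, theta=th - d[:2], omega=om - d[2:])
            J[2:4, i] = (ap - am) / (2 * _fd)
        # acceleration sensitivity to the attractor states via the soft target
        if params.target_softness > 0:
            w = _target_weights(z, params.target_softness)
            dw = (np.diag(w) - np.outer(w, w)) / params.target_softness  # (K, K)
            dp_dz = attractor.targets.T @ dw                             # (2, K)
            Jarm = arm_jacobian(th, arm.lengths)
            inertia = np.asarray(arm.inertia, dtype=float)
            J[2:4, 4:] = (Jarm.T @ (arm.spring_gain * dp_dz)) / inertia[:, None]
        # log-space LV flow Jacobian
        J[4:, 4:] = -rate * A * np.exp(np.clip(z, -50.0, 50.0))[None, :]
        return J, np.zeros((nx, 0))

    observing = mode.proprioceptive_precision_scale < 1e-3
    vis_prec = params.vis_precision_observation if observing else params.vis_precision
    # the self-controlled green ball gets almost no attention during action
    # (it carries no news); an observer attends it to read the
    # demonstrator's intention
    tgt_prec = vis_prec if observing else 1e-2 * params.vis_precision
    out_prec = np.concatenate([
        np.full(4, params.prop_precision * max(mode.proprioceptive_precision_scale, 1e-9)),
        np.full(2, vis_prec),
        np.full(2, tgt_prec),
    ])
    state_prec = np.concatenate([
        np.full(2, params.state_precision_theta),
        np.full(2, params.state_precision_omega),
        np.full(K, params.state_precision_lv),
    ])
    level = ModelLevel(
        ny=8, nx=nx, nv=0, g=g, f=f, jac_g=jac_g, jac_f=jac_f,
        output_precision=out_prec,
        state_precision=state_prec,
        roughness_output=params.roughness_out,
        roughness_states=params.roughness,
    )
    return HierarchicalModel([level], order=params.order)


class ArmWorld:
    """Physical two-joint arm driven by torque commands (the action).

    The display also shows the current movement target (the green ball);
    in self-generated action it tracks the agent's own intention, set by
    the simulation loop via ``display_target``.
    """

    def __init__(self, arm: ArmModel, params: MotorParams, order: int = 3):
        self.arm = arm
        self.params = params
        self.order = int(order)
        self.theta = arm.theta.copy()
        self.omega = arm.omega.copy()
        self.display_target = forward_kinematics(arm.theta, arm.lengths)
        self.history: list = []   # (theta, endpoint)

    def _acc(self, a: np.ndarray) -> np.ndarray:
        inertia = np.asarray(self.arm.inertia, dtype=float)
        return (np.asarray(a, float).reshape(2)
                - self.params.world_damping * self.omega) / inertia

    def sense(self, t: float, a: np.ndarray) -> np.ndarray:
        """Generalised data [theta, omega, endpoint, target] + derivatives.

        The spindle velocity channel reports a short look-ahead,
        ``omega + la * acc(a)``, so torque has direct leverage on the
        sensed stretch velocity (the fast spinal reflex loop).
        """
        s = np.zeros((self.order, 8))
        J = arm_jacobian(self.theta, self.arm.lengths)
        acc = self._acc(a)
        la = self.params.reflex_lookahead
        e = forward_kinematics(self.theta, self.arm.lengths)
        s[0] = np.concatenate([self.theta, self.omega + la * acc, e,
                               self.display_target])
        if self.order > 1:
            s[1] = np.concatenate([self.omega, acc, J @ self.omega, np.zeros(2)])
        if self.order > 2:
            s[2] = np.concatenate([acc, np.zeros(2), J @ acc, np.zeros(2)])
        return s

    __call__ = sense

    def advance(self, dt: float, a: np.ndarray) -> None:
        # semi-implicit Euler keeps the oscillatory arm stable
        self.omega = self.omega + dt * self._acc(a)
        self.theta = self.theta + dt * self.omega
        self.history.append((self.theta.copy(),
                             forward_kinematics(self.theta, self.arm.lengths)))


class ReplayWorld:
    """Replays the visual stream of a recorded run; no proprioception.

    ``sense`` returns the recorded generalised visual channels at the
    nearest recorded time with the proprioceptive channels zeroed — the
    model side removes them by scaling their precision to ~0.
    """

    def __init__(self, times: np.ndarray, sensory: np.ndarray, order: int):
        self.times = np.asarray(times, dtype=float)
        self.sensory = np.asarray(sensory, dtype=float)   # (T, order*8)
        self.order = int(order)

    def sense(self, t: float, a: np.ndarray) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.times, t), 0, len(self.times) - 1))
        s = self.sensory[i].reshape(self.order, 8).copy()
        s[:, :4] = 0.0
        return s

    __call__ = sense


@dataclass
class MotorResult:
    """Trace plus endpoint path and per-state attractor activity."""

    trace: SimulationTrace
    endpoint_path: np.ndarray      # (T, 2) physical (or replayed) endpoint
    joint_path: np.ndarray         # (T, 2) physical joint angles
    activity: np.ndarray           # (T, K) posterior attractor-state expectations
    attractor: LVAttractor
    mode: ObservationMode
    diverged: bool = False

    def winner_sequence(self) -> list[int]:
        """Dominant-state index over time, consecutive repeats collapsed."""
        seq = [winner(x) for x in self.activity]
        out = [seq[0]] if seq else []
        for s in seq[1:]:
            if s != out[-1]:
                out.append(s)
        return out


def run_motor_simulation(
    attractor: LVAttractor,
    arm: ArmModel,
    mode: ObservationMode,
    duration_ms: float,
    params: MotorParams | None = None,
    integrator: IntegratorConfig | None = None,
    seed: int = 0,
    replay_from: MotorResult | None = None,
) -> MotorResult:
    """Integrate the motor (or observation) experiment for ``duration_ms``.

    In action mode the agent's reflexes (torque = action) realise the
    itinerant trajectory its attractor prior prescribes.  In observation
    mode action is disabled, proprioceptive precision is scaled to ~0 and
    the world replays the visual stream of ``replay_from`` (an action-mode
    result; if absent, an action run is performed internally first).
    The attractor expectations are then initialised at a state-neutral
    point so any mirroring reflects genuine visual entrainment.
    """
    params = params or MotorParams()
    integrator = integrator or IntegratorConfig(dt=2.0, kappa_mu=1.0,
                                                kappa_a=params.kappa_a,
                                                action_substeps=8)
    n_steps = int(round(duration_ms / integrator.dt))
    if n_steps == 0:
        K = attractor.K
        return MotorResult(
            trace=SimulationTrace(times=np.zeros(0), expectations=np.zeros((0, 0)),
                                  uncertainties=np.zeros((0, 0)), actions=np.zeros((0, 2)),
                                  free_energies=np.zeros(0), sensory=np.zeros((0, 0))),
            endpoint_path=np.zeros((0, 2)), joint_path=np.zeros((0, 2)),
            activity=np.zeros((0, K)), attractor=attractor, mode=mode,
        )

    rng = np.random.default_rng(seed)
    K = attractor.K
    model = make_motor_model(attractor, arm, params, mode)

    observing = mode.proprioceptive_precision_scale < 1e-3
    if observing:
        if replay_from is None:
            replay_from = run_motor_simulation(
                attractor, arm, ObservationMode.action(), duration_ms,
                params=params, integrator=IntegratorConfig(
                    dt=integrator.dt, kappa_mu=integrator.kappa_mu,
                    kappa_a=params.kappa_a,
                    scheme=integrator.scheme,
                    record_uncertainty=integrator.record_uncertainty,
                    action_substeps=integrator.action_substeps),
                seed=seed)
        world = ReplayWorld(replay_from.trace.times, replay_from.trace.sensory,
                            params.order)
        # hypothesis-neutral start: all attractor states equal, so any
        # mirroring of the action run reflects visual entrainment
        x_lv0 = np.full(K, 0.2) * np.exp(1e-3 * rng.standard_normal(K))
        theta0, omega0 = replay_from.joint_path[0], np.zeros(2)
        cfg = IntegratorConfig(dt=integrator.dt, kappa_mu=integrator.kappa_mu,
                               kappa_a=0.0, scheme=integrator.scheme,
                               record_uncertainty=integrator.record_uncertainty)
    else:
        world = ArmWorld(arm, params, order=params.order)
        # start near the first vertex of the heteroclinic cycle
        x_lv0 = np.full(K, 0.05) * np.exp(1e-3 * rng.standard_normal(K))
        x_lv0[0] = 0.9
        theta0, omega0 = world.theta.copy(), world.omega.copy()
        cfg = integrator

    mu0 = np.zeros(model.mu_dim)
    blocks = model.unpack(mu0)
    blocks[0]["x"][0, :2] = theta0
    blocks[0]["x"][0, 2:4] = omega0
    blocks[0]["x"][0, 4:] = np.log(np.abs(x_lv0))   # model carries log-activities
    mu0 = model.pack(blocks)
    state = AgentState(mu=mu0, action=np.zeros(2), time=0.0)

    z_idx = [model.coordinate_index(0, "x", 0, 4 + k) for k in range(K)]
    soft = max(params.target_softness, 1e-6)
    from .active_inference import _step_full

    times, mus, stds, acts, Fs, ss = [], [], [], [], [], []
    diverged_flag, msg = False, ""
    cur = state
    for _ in range(n_steps):
        if isinstance(world, ArmWorld):
            # the display's green ball tracks the agent's current intention
            world.display_target = _soft_target(cur.mu[z_idx], attractor, soft)
        try:
            cur, info = _step_full(cur, model, world, cfg)
        except Exception as exc:  # divergence -> partial result with flag
            diverged_flag, msg = True, str(exc)
            break
        times.append(cur.time)
        mus.append(cur.mu.copy())
        acts.append(cur.action.copy())
        Fs.append(info["free_energy"])
        ss.append(info["s_tilde"].reshape(-1))
        if cfg.record_uncertainty:
            H = info["curvature"]
            Hreg = H + 1e-9 * np.eye(H.shape[0]) * max(1.0, np.trace(H) / H.shape[0])
            stds.append(np.sqrt(np.clip(np.diag(np.linalg.inv(Hreg)), 0.0, None)))
    trace = SimulationTrace(
        times=np.asarray(times),
        expectations=np.asarray(mus) if mus else np.zeros((0, model.mu_dim)),
        uncertainties=np.asarray(stds) if stds else np.zeros((0, 0)),
        actions=np.asarray(acts) if acts else np.zeros((0, 2)),
        free_energies=np.asarray(Fs),
        sensory=np.asarray(ss) if ss else np.zeros((0, 0)),
        diverged=diverged_flag,
        error_message=msg,
    )
    state = cur
    T = len(trace)

    if observing:
        endpoint = np.array([world.sense(t, np.zeros(2))[0, 4:6]
                             for t in trace.times])
        joint = np.array([replay_from.joint_path[min(i, len(replay_from.joint_path) - 1)]
                          for i in range(T)])
    else:
        # the world advances once per reflex substep; keep one sample per
        # perception step (the state at the end of each step)
        ss = max(1, cfg.action_substeps) if cfg.kappa_a > 0 else 1
        hist = world.history[ss - 1 :: ss]
        endpoint = np.array([e for _, e in hist[:T]])
        joint = np.array([th for th, _ in hist[:T]])

    idx = [model.coordinate_index(0, "x", 0, 4 + k) for k in range(K)]
    # activity on the natural (positive) scale: exp of the log-states
    activity = np.exp(np.clip(trace.expectations[:, idx], -50.0, 50.0)) \
        if T else np.zeros((0, K))
    return MotorResult(trace=trace, endpoint_path=endpoint, joint_path=joint,
                       activity=activity, attractor=attractor, mode=mode,
                       diverged=trace.diverged)


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

@dataclass
class PlaceFields:
    """Per-state endpoint positions above the activity threshold."""

    positions: list                 # K arrays of (m_k, 2)
    centroids: np.ndarray           # (K, 2), nan where empty
    dispersions: np.ndarray         # (K,) mean squared distance to centroid
    pooled_dispersion: float

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, pos in enumerate(self.positions):
            for x, y in pos:
                rows.append((k, x, y))
        return pd.DataFrame(rows, columns=["state_index", "x", "y"])


def place_field_analysis(result: MotorResult,
                         threshold_fraction: float = 0.5) -> PlaceFields:
    """Positions where each state's activity exceeded its half-max.

    Reports the spatial centroid and dispersion per state; place-cell-like
    selectivity shows as per-state dispersion below the pooled path's.
    """
    if len(result.activity) == 0:
        raise ConfigurationError("place-field analysis needs a non-empty result")
    K = result.activity.shape[1]
    path = result.endpoint_path
    positions, centroids, dispersions = [], [], []
    for k in range(K):
        act = result.activity[:, k]
        mx = act.max()
        mask = act > threshold_fraction * mx if mx > 0 else np.zeros(len(act), bool)
        pos = path[mask]
        positions.append(pos)
        if len(pos):
            c = pos.mean(axis=0)
            centroids.append(c)
            dispersions.append(float(np.mean(np.sum((pos - c) ** 2, axis=1))))
        else:
            centroids.append(np.full(2, np.nan))
            dispersions.append(np.nan)
    pooled_c = path.mean(axis=0)
    pooled = float(np.mean(np.sum((path - pooled_c) ** 2, axis=1)))
    return PlaceFields(positions=positions, centroids=np.asarray(centroids),
                       dispersions=np.asarray(dispersions), pooled_dispersion=pooled)


def visitation_sequence(path: np.ndarray, targets: np.ndarray,
                        eps: float) -> list[int]:
    """Ordered target indices whose eps-neighbourhood the path enters."""
    seq: list[int] = []
    for p in np.asarray(path, dtype=float):
        d = np.linalg.norm(targets - p, axis=1)
        i = int(np.argmin(d))
        if d[i] <= eps and (not seq or seq[-1] != i):
            seq.append(i)
    return seq
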