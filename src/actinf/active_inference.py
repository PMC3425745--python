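"""Numerical integration of coupled perception-action dynamics.

Perception and action jointly descend on variational free energy::

    dmu~/dt = D mu~ - kappa_mu * dF/dmu~
    da/dt   =       - kappa_a  * dF/da

The first equation is generalised predictive coding: expectations are
carried along the trajectory by the derivative-shift operator ``D`` and
corrected by precision-weighted prediction errors.  The second equation
is a reflex arc: action changes the data to fulfil predictions.  Both
update simultaneously from the same pre-step state (Jacobi scheme),
matching the coupled continuous-time form.

Two integration schemes are provided: forward Euler, and local
linearisation (the matrix-exponential update of the Jacobian-linearised
flow over each step), which is the default because the generalised
descent is stiff when precisions are high.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm

from .exceptions import ConfigurationError, IntegrationDivergenceError
from .hdm import HierarchicalModel, free_energy, grad_free_energy_action, prediction_errors

__all__ = ["AgentState", "IntegratorConfig", "SimulationTrace", "step", "run_epoch"]


@dataclass
class AgentState:
    """Posterior expectations mu~ (flat), action a, and time in ms."""

    mu: np.ndarray
    action: np.ndarray
    time: float = 0.0

    def copy(self) -> "AgentState":
        return AgentState(self.mu.copy(), self.action.copy(), self.time)


@dataclass
class IntegratorConfig:
    """Step size (ms), rate constants and integration scheme.

    ``kappa_mu`` and ``kappa_a`` rescale the speed of perception and
    action relative to the 1/ms time base; ``kappa_a = 0`` freezes
    action.  ``scheme`` is ``"local_linearisation"`` (default; matrix
    exponential of the linearised flow) or ``"euler"``.
    """

    dt: float = 1.5
    kappa_mu: float = 1.0
    kappa_a: float = 1.0
    scheme: str = "local_linearisation"
    record_uncertainty: bool = True
    # sub-steps of the fast reflex loop (action + world) per perception step
    action_substeps: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.action_substeps < 1:
            raise ConfigurationError("action_substeps must be >= 1")
        if self.kappa_mu <= 0:
            raise ConfigurationError("kappa_mu must be positive")
        if self.kappa_a < 0:
            raise ConfigurationError("kappa_a must be non-negative")
        if self.scheme not in ("euler", "local_linearisation"):
            raise ConfigurationError(
                f"unknown scheme {self.scheme!r}; use 'euler' or 'local_linearisation'"
            )


@dataclass
class SimulationTrace:
    """Time-indexed record of a run; all histories share the time axis."""

    times: np.ndarray
    expectations: np.ndarray       # (T, mu_dim)
    uncertainties: np.ndarray      # (T, mu_dim) conditional std, or empty
    actions: np.ndarray            # (T, na)
    free_energies: np.ndarray      # (T,)
    sensory: np.ndarray            # (T, n*ny)
    diverged: bool = False
    error_message: str = ""

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path_prefix, names: dict[str, list[str]] | None = None) -> list[str]:
        """Write tidy CSVs (time_ms, variable_name, value), one per block."""
        import pandas as pd

        written = []
        blocks = {
            "expectations": self.expectations,
            "uncertainties": self.uncertainties,
            "actions": self.actions,
            "free_energy": self.free_energies.reshape(-1, 1),
            "sensory": self.sensory,
        }
        for key, arr in blocks.items():
            if arr.size == 0:
                continue
            cols = (names or {}).get(key) or [f"{key}_{i}" for i in range(arr.shape[1])]
            df = pd.DataFrame(arr, columns=cols)
            df.insert(0, "time_ms", self.times)
            tidy = df.melt(id_vars="time_ms", var_name="variable_name", value_name="value")
            out = f"{path_prefix}_{key}.csv"
            with io.open(out, "w", newline="") as fh:
                tidy.to_csv(fh, index=False, lineterminator="\n", float_format="%.12g")
            written.append(out)
        return written


def _sense(sensory_source, t: float, a: np.ndarray) -> np.ndarray:
    return np.asarray(sensory_source(t, a), dtype=float)


def step(
    state: AgentState,
    model: HierarchicalModel,
    sensory_source: Callable,
    cfg: IntegratorConfig,
) -> AgentState:
    """Advance perception and action by one step of size ``cfg.dt``.

    ``sensory_source(t, a)`` must return generalised sensory data of
    shape (n, ny); if it has an ``advance(dt, a)`` method the world's own
    state is integrated with the pre-step action after the agent update
    (simultaneous/Jacobi coupling).
    """
    new_state, _ = _step_full(state, model, sensory_source, cfg)
    return new_state


def _step_full(
    state: AgentState,
    model: HierarchicalModel,
    sensory_source: Callable,
    cfg: IntegratorConfig,
) -> tuple[AgentState, dict]:
    """One step plus the intermediate quantities (F, data, curvature)."""
    dt = cfg.dt
    s_tilde = _sense(sensory_source, state.time, state.action)
    from .hdm import grad_free_energy_mu, prediction_errors

    eps = prediction_errors(model, s_tilde, state.mu).stacked
    F = float(0.5 * eps @ model.Pi_full @ eps + model._log_norm)
    if not np.isfinite(F):
        raise IntegrationDivergenceError("non-finite free energy")
    grad, H = grad_free_energy_mu(model, s_tilde, state.mu, return_curvature=True)
    D = model.shift_matrix
    flow = D @ state.mu - cfg.kappa_mu * grad
    if cfg.scheme == "euler":
        dmu = dt * flow
    else:
        J = D - cfg.kappa_mu * H
        A = J * dt
        Phi = expm(A)
        # dmu = (expm(J dt) - I) J^{-1} flow, via a least-squares solve that
        # tolerates singular directions (they fall back to Euler locally)
        rhs = (Phi - np.eye(J.shape[0])) @ np.linalg.lstsq(J, flow, rcond=None)[0]
        # singular subspace correction: where J ~ 0 the LL update equals dt*flow
        resid = flow - J @ np.linalg.lstsq(J, flow, rcond=None)[0]
        dmu = rhs + dt * resid
    new_mu = state.mu + dmu

    bad = np.flatnonzero(~np.isfinite(new_mu))
    if bad.size:
        raise IntegrationDivergenceError(
            f"non-finite expectation update at coordinate {bad[0]}", coordinate=int(bad[0])
        )

    # the reflex arc (action and the world it moves) can be much faster
    # than perception, so it is sub-stepped with the expectations frozen
    new_action = state.action.copy()
    can_advance = hasattr(sensory_source, "advance")
    if cfg.kappa_a > 0 and state.action.size > 0:
        dts = dt / cfg.action_substeps
        for _ in range(cfg.action_substeps):
            ga, Ga = grad_free_energy_action(
                model, lambda a: _sense(sensory_source, state.time, a), new_action,
                state.mu, return_curvature=True,
            )
            # semi-implicit update: the reflex loop is stiff when sensory
            # precisions are high, so solve (I/(dts kappa_a) + Ga) da = -ga
            M = np.eye(ga.size) / (dts * cfg.kappa_a) + Ga
            new_action = new_action - np.linalg.solve(M, ga)
            if not np.all(np.isfinite(new_action)):
                raise IntegrationDivergenceError("non-finite action update")
            if can_advance:
                sensory_source.advance(dts, new_action)
    elif can_advance:
        sensory_source.advance(dt, state.action)

    info = {"free_energy": F, "s_tilde": s_tilde, "curvature": H}
    return AgentState(mu=new_mu, action=new_action, time=state.time + dt), info


def run_epoch(
    state: AgentState,
    model: HierarchicalModel,
    sensory_source: Callable,
    cfg: IntegratorConfig,
    n_steps: int,
) -> tuple[SimulationTrace, AgentState]:
    """Run ``n_steps`` sequential steps, recording every step.

    On mid-epoch divergence the partial trace is returned with its
    ``diverged`` flag set rather than raising.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    times, mus, stds, acts, Fs, ss = [], [], [], [], [], []
    diverged, msg = False, ""
    cur = state
    for _ in range(n_steps):
        try:
            nxt, info = _step_full(cur, model, sensory_source, cfg)
        except IntegrationDivergenceError as exc:
            diverged, msg = True, str(exc)
            break
        times.append(nxt.time)
        mus.append(nxt.mu.copy())
        acts.append(nxt.action.copy())
        Fs.append(info["free_energy"])
        ss.append(info["s_tilde"].reshape(-1))
        if cfg.record_uncertainty:
            H = info["curvature"]
            Hreg = H + 1e-9 * np.eye(H.shape[0]) * max(1.0, np.trace(H) / H.shape[0])
            stds.append(np.sqrt(np.clip(np.diag(np.linalg.inv(Hreg)), 0.0, None)))
        cur = nxt
    trace = SimulationTrace(
        times=np.asarray(times),
        expectations=np.asarray(mus) if mus else np.zeros((0, model.mu_dim)),
        uncertainties=np.asarray(stds) if stds else np.zeros((0, 0)),
        actions=np.asarray(acts) if acts else np.zeros((0, state.action.size)),
        free_energies=np.asarray(Fs),
        sensory=np.asarray(ss) if ss else np.zeros((0, 0)),
        diverged=diverged,
        error_message=msg,
    )
    return trace, cur
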