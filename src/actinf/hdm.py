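"""Hierarchical dynamic generative models and variational free energy.

A generative model is a stack of levels.  Each level owns hidden states
``x`` with equations of motion ``f(x, v)``, causes ``v``, and an output
mapping ``g(x, v)`` that predicts the level below: the bottom level
predicts sensory data, higher levels predict the causes of the level
beneath them.  All quantities live in generalised coordinates of motion
(value plus temporal derivatives to embedding order ``n``); random
fluctuations are smooth, with Gaussian autocorrelation of per-stream
roughness ``gamma``, so the generalised precision of every noise stream
factors as ``kron(temporal_precision(gamma, n), spatial_precision)``.

Under the Laplace (fixed-form Gaussian) assumption the variational free
energy reduces to a precision-weighted sum of squared generalised
prediction errors plus log-normalisation terms::

    F = 1/2 sum_streams  eps~' Pi~ eps~  -  1/2 sum_streams log|Pi~ / 2 pi|

which is the negative log joint density of data and expectations.
Conditional uncertainty is read from the (Gauss-Newton) curvature of F
at the current expectations.

Gradients of F with respect to the expectations and with respect to
action drive perception and action respectively; they are computed as
exact quadratic-form gradients ``J' Pi eps`` with the error Jacobian
``J`` obtained by central finite differences of the stacked error
function (analytic Jacobians of f and g, where supplied, accelerate the
order-by-order prediction but the gradient route is the same).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ModelSpecificationError, NumericalDomainError
from .gencoords import generalised_covariance, shift_operator

__all__ = [
    "ModelLevel",
    "HierarchicalModel",
    "PredictionErrors",
    "predict",
    "prediction_errors",
    "free_energy",
    "grad_free_energy_mu",
    "grad_free_energy_action",
    "curvature",
    "conditional_std",
]

_FD_STEP = 1e-6


def _as_spd(p, dim: int, name: str) -> np.ndarray:
    """Coerce a scalar / vector / matrix precision spec to an SPD matrix."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim == 0:
        mat = float(arr) * np.eye(dim)
    elif arr.ndim == 1:
        if arr.size != dim:
            raise ModelSpecificationError(f"{name}: expected length {dim}, got {arr.size}")
        mat = np.diag(arr)
    else:
        if arr.shape != (dim, dim):
            raise ModelSpecificationError(f"{name}: expected shape {(dim, dim)}, got {arr.shape}")
        mat = 0.5 * (arr + arr.T)
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ModelSpecificationError(f"{name}: precision is not positive definite") from exc
    return mat


@dataclass
class ModelLevel:
    """One level of a hierarchical dynamic model.

    Parameters
    ----------
    ny, nx, nv
        Dimensions of the output (predictions for the level below, or
        sensory data at the bottom level), hidden states and causes.
    g
        Output mapping ``g(x, v) -> (ny,)``.
    f
        Equations of motion ``f(x, v) -> (nx,)``; ``None`` for a static
        level without hidden states (then ``nx`` must be 0).
    output_precision, state_precision
        Spatial precisions of the output and state noise; scalar, vector
        (diagonal) or full SPD matrix.
    roughness_output, roughness_states
        Gamma of the Gaussian autocorrelation of each noise stream.
    jac_g, jac_f
        Optional analytic Jacobians ``(x, v) -> (d/dx, d/dv)``; absent
        Jacobians are obtained by central differences.
    """

    ny: int
    nx: int
    nv: int
    g: Callable[[np.ndarray, np.ndarray], np.ndarray]
    f: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    output_precision: object = 1.0
    state_precision: object = 1.0
    roughness_output: float = 1.0
    roughness_states: float = 1.0
    jac_g: Callable | None = None
    jac_f: Callable | None = None
    # optional modality split: list of (channel_indices, precision, roughness)
    # giving each output group its own noise roughness (e.g. smooth
    # proprioceptive noise next to rough visual noise)
    output_groups: list | None = None

    Pi_z: np.ndarray = field(init=False, repr=False)
    Pi_w: np.ndarray = field(init=False, repr=False)
    groups: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.nx > 0 and self.f is None:
            raise ModelSpecificationError("level with hidden states requires f")
        if self.nx == 0 and self.f is not None:
            raise ModelSpecificationError("level without hidden states must not define f")
        self.Pi_w = (
            _as_spd(self.state_precision, self.nx, "state_precision")
            if self.nx > 0
            else np.zeros((0, 0))
        )
        if self.output_groups is None:
            Pi = _as_spd(self.output_precision, self.ny, "output_precision")
            self.groups = [(np.arange(self.ny), Pi, float(self.roughness_output))]
            self.Pi_z = Pi
        else:
            self.groups = []
            seen: list[int] = []
            for gi, (idx, prec, rough) in enumerate(self.output_groups):
                idx = np.asarray(idx, dtype=int)
                Pi = _as_spd(prec, idx.size, f"output_groups[{gi}] precision")
                self.groups.append((idx, Pi, float(rough)))
                seen.extend(idx.tolist())
            if sorted(seen) != list(range(self.ny)):
                raise ModelSpecificationError(
                    "output_groups must partition the output channels exactly"
                )
            Pi_full = np.zeros((self.ny, self.ny))
            for idx, Pi, _ in self.groups:
                Pi_full[np.ix_(idx, idx)] = Pi
            self.Pi_z = Pi_full


class HierarchicalModel:
    """A stack of :class:`ModelLevel` plus a prior over the top causes.

    ``levels[0]`` is the sensory level.  The prior mean over the top
    level's causes (``set_prior``) is the handle through which contextual
    set-points — e.g. a salience-selected gaze target — enter perception
    and hence action.
    """

    def __init__(
        self,
        levels: Sequence[ModelLevel],
        order: int = 4,
        prior_mean: np.ndarray | None = None,
        prior_precision: object = 1.0,
        roughness_prior: float = 1.0,
    ):
        if len(levels) < 1:
            raise ModelSpecificationError("a model needs at least one level")
        if order < 1:
            raise ModelSpecificationError("embedding order must be >= 1")
        for lo, hi in zip(levels[:-1], levels[1:]):
            if hi.ny != lo.nv:
                raise ModelSpecificationError(
                    f"dimension chaining broken: upper level predicts {hi.ny} values "
                    f"but lower level has {lo.nv} causes"
                )
        self.levels = list(levels)
        self.n = int(order)
        nv_top = self.levels[-1].nv
        self.nv_top = nv_top
        if nv_top > 0:
            self.prior_precision = _as_spd(prior_precision, nv_top, "prior_precision")
            self.roughness_prior = float(roughness_prior)
            self.prior_tilde = np.zeros((self.n, nv_top))
            if prior_mean is not None:
                self.set_prior(prior_mean)
        self._build_layout()
        self._build_precisions()

    # ---------------------------------------------------------------- layout
    def _build_layout(self) -> None:
        n = self.n
        slices: list[tuple[int, str, slice, int]] = []
        off = 0
        for li, lev in enumerate(self.levels):
            if lev.nx > 0:
                slices.append((li, "x", slice(off, off + n * lev.nx), lev.nx))
                off += n * lev.nx
            if lev.nv > 0:
                slices.append((li, "v", slice(off, off + n * lev.nv), lev.nv))
                off += n * lev.nv
        self._slices = slices
        self.mu_dim = off
        D = np.zeros((off, off))
        for _, _, sl, d in slices:
            D[sl, sl] = shift_operator(n, d)
        self.shift_matrix = D

    def unpack(self, mu_flat: np.ndarray) -> list[dict[str, np.ndarray]]:
        """Split a flat expectation vector into per-level (n, d) blocks."""
        mu_flat = np.asarray(mu_flat, dtype=float)
        if mu_flat.size != self.mu_dim:
            raise ModelSpecificationError(
                f"expectation vector length {mu_flat.size}, model requires {self.mu_dim}"
            )
        out = [{"x": np.zeros((self.n, lev.nx)), "v": np.zeros((self.n, lev.nv))}
               for lev in self.levels]
        for li, name, sl, d in self._slices:
            out[li][name] = mu_flat[sl].reshape(self.n, d)
        return out

    def pack(self, blocks: list[dict[str, np.ndarray]]) -> np.ndarray:
        mu = np.zeros(self.mu_dim)
        for li, name, sl, d in self._slices:
            mu[sl] = np.asarray(blocks[li][name], dtype=float).reshape(-1)
        return mu

    def coordinate_index(self, level: int, var: str, order: int, i: int) -> int:
        """Flat index of derivative order ``order`` of coordinate ``i``."""
        for li, name, sl, d in self._slices:
            if li == level and name == var:
                return sl.start + order * d + i
        raise KeyError(f"no block ({level!r}, {var!r}) in this model")

    def set_prior(self, mean: np.ndarray, velocity: np.ndarray | None = None) -> None:
        """Set the prior expectation over the top-level causes (order 0/1)."""
        if self.nv_top == 0:
            raise ModelSpecificationError("model has no top-level causes to set a prior on")
        mean = np.asarray(mean, dtype=float).reshape(-1)
        if mean.size != self.nv_top:
            raise ModelSpecificationError(
                f"prior mean length {mean.size}, expected {self.nv_top}"
            )
        self.prior_tilde = np.zeros((self.n, self.nv_top))
        self.prior_tilde[0] = mean
        if velocity is not None and self.n > 1:
            self.prior_tilde[1] = np.asarray(velocity, dtype=float).reshape(-1)

    # ------------------------------------------------------------ precisions
    def _build_precisions(self) -> None:
        """Generalised (kron-composed) precision per error stream.

        Stream order: per-level output errors bottom-up, then per-level
        dynamics errors, then the top-cause prior error.  This order is
        shared by :func:`prediction_errors`.
        """
        n = self.n
        streams: list[tuple[str, np.ndarray]] = []
        for li, lev in enumerate(self.levels):
            if len(lev.groups) == 1:
                _, Pi, rough = lev.groups[0]
                T = generalised_covariance(rough, n).matrix
                streams.append((f"output[{li}]", np.kron(T, Pi)))
            else:
                for gi, (idx, Pi, rough) in enumerate(lev.groups):
                    T = generalised_covariance(rough, n).matrix
                    streams.append((f"output[{li}].{gi}", np.kron(T, Pi)))
        for li, lev in enumerate(self.levels):
            if lev.nx > 0:
                T = generalised_covariance(lev.roughness_states, n).matrix
                streams.append((f"dynamics[{li}]", np.kron(T, lev.Pi_w)))
        if self.nv_top > 0:
            T = generalised_covariance(self.roughness_prior, n).matrix
            streams.append(("prior", np.kron(T, self.prior_precision)))
        self.stream_precisions = streams
        self.error_dim = sum(P.shape[0] for _, P in streams)
        # block-diagonal composite, cached for gradients/curvature
        Pi = np.zeros((self.error_dim, self.error_dim))
        off = 0
        logdet = 0.0
        for _, P in streams:
            d = P.shape[0]
            Pi[off : off + d, off : off + d] = P
            sign, ld = np.linalg.slogdet(P)
            if sign <= 0:
                raise ModelSpecificationError("generalised precision not positive definite")
            logdet += ld
            off += d
        self.Pi_full = Pi
        self._log_norm = -0.5 * (logdet - self.error_dim * np.log(2.0 * np.pi))
        # sensory precision in natural layout (order-major over all channels),
        # used by the action gradient
        lev0 = self.levels[0]
        ny0, n = lev0.ny, self.n
        Pnat = np.zeros((n * ny0, n * ny0))
        for idx, PiG, rough in lev0.groups:
            T = generalised_covariance(rough, n).matrix
            block = np.kron(T, PiG)
            nat = np.array([k * ny0 + c for k in range(n) for c in idx])
            Pnat[np.ix_(nat, nat)] = block
        self.sensory_precision_natural = Pnat


@dataclass
class PredictionErrors:
    """Stacked generalised prediction errors and their per-stream views."""

    stacked: np.ndarray
    streams: dict[str, np.ndarray]

    @property
    def sensory(self) -> np.ndarray:
        if "output[0]" in self.streams:
            return self.streams["output[0]"]
        return np.concatenate(
            [v for k, v in self.streams.items() if k.startswith("output[0].")]
        )

    @property
    def dynamical(self) -> np.ndarray:
        return np.concatenate(
            [v for k, v in self.streams.items() if k.startswith("dynamics")]
        ) if any(k.startswith("dynamics") for k in self.streams) else np.zeros(0)


# ---------------------------------------------------------------------------
# prediction and errors
# ---------------------------------------------------------------------------

def _jacobian_fd(fun, x0, out_dim, h=_FD_STEP):
    x0 = np.asarray(x0, dtype=float)
    J = np.zeros((out_dim, x0.size))
    for i in range(x0.size):
        dx = np.zeros_like(x0)
        dx[i] = h
        J[:, i] = (fun(x0 + dx) - fun(x0 - dx)) / (2.0 * h)
    return J


def _level_jacobians(lev: ModelLevel, x0: np.ndarray, v0: np.ndarray):
    if lev.jac_g is not None:
        Jgx, Jgv = lev.jac_g(x0, v0)
    else:
        Jgx = _jacobian_fd(lambda x: np.asarray(lev.g(x, v0), float).reshape(-1), x0, lev.ny) \
            if lev.nx > 0 else np.zeros((lev.ny, 0))
        Jgv = _jacobian_fd(lambda v: np.asarray(lev.g(x0, v), float).reshape(-1), v0, lev.ny) \
            if lev.nv > 0 else np.zeros((lev.ny, 0))
    if lev.f is None:
        return np.asarray(Jgx, float), np.asarray(Jgv, float), None, None
    if lev.jac_f is not None:
        Jfx, Jfv = lev.jac_f(x0, v0)
    else:
        Jfx = _jacobian_fd(lambda x: np.asarray(lev.f(x, v0), float).reshape(-1), x0, lev.nx)
        Jfv = _jacobian_fd(lambda v: np.asarray(lev.f(x0, v), float).reshape(-1), v0, lev.nx) \
            if lev.nv > 0 else np.zeros((lev.nx, 0))
    return (np.asarray(Jgx, float), np.asarray(Jgv, float),
            np.asarray(Jfx, float), np.asarray(Jfv, float))


def predict(model: HierarchicalModel, mu_flat: np.ndarray):
    """Generalised predictions ``g~`` and ``f~`` per level.

    Order 0 applies the nonlinear mappings; orders k >= 1 propagate by
    the first-order chain rule, ``g~^k = dg/dx mu_x^k + dg/dv mu_v^k``.
    """
    blocks = model.unpack(mu_flat)
    g_tilde, f_tilde = [], []
    for li, lev in enumerate(model.levels):
        x, v = blocks[li]["x"], blocks[li]["v"]
        x0, v0 = x[0], v[0]
        gt = np.zeros((model.n, lev.ny))
        gt[0] = np.asarray(lev.g(x0, v0), dtype=float).reshape(-1)
        if gt[0].size != lev.ny:
            raise ModelSpecificationError(
                f"level {li}: g returned {gt[0].size} values, expected {lev.ny}"
            )
        Jgx, Jgv, Jfx, Jfv = _level_jacobians(lev, x0, v0)
        for k in range(1, model.n):
            gt[k] = Jgx @ x[k] + Jgv @ v[k]
        g_tilde.append(gt)
        if lev.f is not None:
            ft = np.zeros((model.n, lev.nx))
            ft[0] = np.asarray(lev.f(x0, v0), dtype=float).reshape(-1)
            for k in range(1, model.n):
                ft[k] = Jfx @ x[k] + Jfv @ v[k]
            f_tilde.append(ft)
        else:
            f_tilde.append(np.zeros((model.n, 0)))
    return g_tilde, f_tilde


def prediction_errors(
    model: HierarchicalModel, s_tilde: np.ndarray, mu_flat: np.ndarray
) -> PredictionErrors:
    """Generalised prediction errors in the model's canonical stream order."""
    s_tilde = np.asarray(s_tilde, dtype=float)
    ny0 = model.levels[0].ny
    if s_tilde.shape != (model.n, ny0):
        raise ModelSpecificationError(
            f"sensory data shape {s_tilde.shape}, expected {(model.n, ny0)}"
        )
    blocks = model.unpack(mu_flat)
    g_tilde, f_tilde = predict(model, mu_flat)
    streams: dict[str, np.ndarray] = {}
    for li, lev in enumerate(model.levels):
        target = s_tilde if li == 0 else blocks[li - 1]["v"]
        err = target - g_tilde[li]        # (n, ny)
        if len(lev.groups) == 1:
            streams[f"output[{li}]"] = err.reshape(-1)
        else:
            for gi, (idx, _, _) in enumerate(lev.groups):
                streams[f"output[{li}].{gi}"] = err[:, idx].reshape(-1)
    for li, lev in enumerate(model.levels):
        if lev.nx > 0:
            x = blocks[li]["x"]
            Dx = np.zeros_like(x)
            Dx[:-1] = x[1:]
            streams[f"dynamics[{li}]"] = (Dx - f_tilde[li]).reshape(-1)
    if model.nv_top > 0:
        streams["prior"] = (blocks[-1]["v"] - model.prior_tilde).reshape(-1)
    stacked = np.concatenate([streams[k] for k, _ in model.stream_precisions])
    return PredictionErrors(stacked=stacked, streams=streams)


# ---------------------------------------------------------------------------
# free energy and its gradients
# ---------------------------------------------------------------------------

def free_energy(model: HierarchicalModel, s_tilde: np.ndarray, mu_flat: np.ndarray) -> float:
    """Laplace-form variational free energy (negative log joint density)."""
    if not (np.all(np.isfinite(s_tilde)) and np.all(np.isfinite(mu_flat))):
        raise NumericalDomainError("non-finite states passed to free_energy")
    eps = prediction_errors(model, s_tilde, mu_flat).stacked
    F = 0.5 * eps @ model.Pi_full @ eps + model._log_norm
    if not np.isfinite(F):
        raise NumericalDomainError("free energy is not finite")
    return float(F)


def error_jacobian_mu(model, s_tilde, mu_flat, h=_FD_STEP) -> np.ndarray:
    """Jacobian of the stacked errors w.r.t. the flat expectations."""
    def efun(mu):
        return prediction_errors(model, s_tilde, mu).stacked

    return _jacobian_fd(efun, mu_flat, model.error_dim, h=h)


def grad_free_energy_mu(
    model: HierarchicalModel,
    s_tilde: np.ndarray,
    mu_flat: np.ndarray,
    return_curvature: bool = False,
):
    """Gradient dF/dmu~ (and optionally the Gauss-Newton curvature).

    The log-normalisation terms do not depend on the expectations, so
    the gradient is exactly ``J' Pi eps`` for the error Jacobian ``J``.
    """
    eps = prediction_errors(model, s_tilde, mu_flat).stacked
    J = error_jacobian_mu(model, s_tilde, mu_flat)
    PiJ = model.Pi_full @ J
    grad = PiJ.T @ eps
    if return_curvature:
        H = J.T @ PiJ
        return grad, 0.5 * (H + H.T)
    return grad


def grad_free_energy_action(
    model: HierarchicalModel,
    sensory_of_action: Callable[[np.ndarray], np.ndarray],
    action: np.ndarray,
    mu_flat: np.ndarray,
    h: float = _FD_STEP,
    return_curvature: bool = False,
):
    """Gradient dF/da through the sensory dependence on action.

    ``F`` depends on action only through the sensory data entering the
    bottom-level error, so ``dF/da = (ds~/da)' Pi~_z eps~_z``; the
    sensitivity ``ds~/da`` comes from the supplied action map by central
    differences.  With ``return_curvature`` the Gauss-Newton action
    curvature ``(ds~/da)' Pi~_z (ds~/da)`` is returned as well (used for
    the semi-implicit action update when the reflex loop is stiff).
    """
    action = np.asarray(action, dtype=float).reshape(-1)
    s0 = np.asarray(sensory_of_action(action), dtype=float)
    g_tilde, _ = predict(model, mu_flat)
    eps_z = (s0 - g_tilde[0]).reshape(-1)     # natural (order-major) layout
    Pi_z = model.sensory_precision_natural
    na = action.size
    dsda = np.zeros((s0.size, na))
    for i in range(na):
        da = np.zeros(na)
        da[i] = h
        sp = np.asarray(sensory_of_action(action + da), dtype=float).reshape(-1)
        sm = np.asarray(sensory_of_action(action - da), dtype=float).reshape(-1)
        dsda[:, i] = (sp - sm) / (2.0 * h)
    grad = dsda.T @ (Pi_z @ eps_z)
    if return_curvature:
        return grad, dsda.T @ Pi_z @ dsda
    return grad


def curvature(model: HierarchicalModel, s_tilde: np.ndarray, mu_flat: np.ndarray) -> np.ndarray:
    """Gauss-Newton curvature d2F/dmu~2 = J' Pi~ J (exact for linear models)."""
    J = error_jacobian_mu(model, s_tilde, mu_flat)
    H = J.T @ model.Pi_full @ J
    return 0.5 * (H + H.T)


def conditional_std(
    model: HierarchicalModel, s_tilde: np.ndarray, mu_flat: np.ndarray
) -> np.ndarray:
    """Curvature-derived conditional standard deviation of every coordinate.

    Under the Laplace assumption the posterior covariance is the inverse
    curvature of F at the current expectations.
    """
    H = curvature(model, s_tilde, mu_flat)
    # regularise against singular directions (e.g. unconstrained top orders)
    Hreg = H + 1e-9 * np.eye(H.shape[0]) * max(1.0, np.trace(H) / H.shape[0])
    cov = np.linalg.inv(Hreg)
    var = np.clip(np.diag(cov), 0.0, None)
    return np.sqrt(var)
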