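"""Independent oracle battery: analytic and finite-difference checks.

Each check here validates an implementation route against an independent
one — finite differences of the free energy itself, closed-form
conjugate-Gaussian posteriors, or brute-force enumeration — and returns
a small dict of measured errors plus a pass flag.  The checks double as
the ``oracle-suite`` experiment and are reused by the test suite.
"""

from __future__ import annotations

import numpy as np

from .active_inference import AgentState, IntegratorConfig, run_epoch, step
from .hdm import (
    HierarchicalModel,
    ModelLevel,
    curvature,
    free_energy,
    grad_free_energy_action,
    grad_free_energy_mu,
)

__all__ = [
    "random_smooth_model",
    "fd_gradient",
    "check_gradients",
    "check_linear_gaussian",
    "check_descent",
    "check_salience_argmax",
]


def random_smooth_model(rng: np.random.Generator):
    """A random smooth one-level model, its expectations and data.

    g and f are linear maps plus a tanh nonlinearity, so they are smooth
    everywhere with non-trivial curvature; dimensions and precisions are
    drawn at random.
    """
    nx = int(rng.integers(1, 4))
    nv = int(rng.integers(1, 3))
    ny = int(rng.integers(1, 4))
    n = int(rng.integers(2, 4))
    A = rng.normal(size=(ny, nx))
    B = rng.normal(size=(ny, nv))
    C = rng.normal(size=(ny, nx))
    Fx = rng.normal(size=(nx, nx)) * 0.5
    Fv = rng.normal(size=(nx, nv)) * 0.5

    def g(x, v):
        return A @ x + B @ v + 0.3 * np.tanh(C @ x) + 0.2 * np.sin(v).sum()

    def f(x, v):
        return Fx @ np.tanh(x) + Fv @ v

    level = ModelLevel(
        ny=ny, nx=nx, nv=nv, g=g, f=f,
        output_precision=rng.uniform(0.5, 2.0, size=ny),
        state_precision=rng.uniform(0.5, 2.0, size=nx),
        roughness_output=rng.uniform(0.3, 2.0),
        roughness_states=rng.uniform(0.3, 2.0),
    )
    model = HierarchicalModel([level], order=n,
                              prior_mean=rng.normal(size=nv),
                              prior_precision=rng.uniform(0.5, 2.0, size=nv))
    mu = rng.normal(size=model.mu_dim) * 0.7
    s = rng.normal(size=(n, ny)) * 0.7
    return model, s, mu


def fd_gradient(fun, x0: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function."""
    x0 = np.asarray(x0, dtype=float)
    g = np.zeros_like(x0)
    for i in range(x0.size):
        d = np.zeros_like(x0)
        d[i] = h
        g[i] = (fun(x0 + d) - fun(x0 - d)) / (2 * h)
    return g


def _rel(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.linalg.norm(a), np.linalg.norm(b), 1e-12)
    return float(np.linalg.norm(a - b) / denom)


def check_gradients(seed: int = 0, n_models: int = 50, tol: float = 1e-4) -> dict:
    """dF/dmu~ and dF/da versus central finite differences of F."""
    rng = np.random.default_rng(seed)
    worst_mu, worst_a = 0.0, 0.0
    for _ in range(n_models):
        model, s, mu = random_smooth_model(rng)
        g_impl = grad_free_energy_mu(model, s, mu)
        g_fd = fd_gradient(lambda m: free_energy(model, s, m), mu)
        worst_mu = max(worst_mu, _rel(g_impl, g_fd))

        # smooth action map: the data are a smooth function of a 2-D action
        ny, n = s.shape[1], s.shape[0]
        E = rng.normal(size=(n * ny, 2))
        G = rng.normal(size=(n * ny, 2))

        def s_of_a(a, s=s, E=E, G=G, n=n, ny=ny):
            return (s.reshape(-1) + E @ a + 0.1 * np.tanh(G @ a)).reshape(n, ny)

        a0 = rng.normal(size=2) * 0.5
        ga_impl = grad_free_energy_action(model, s_of_a, a0, mu)
        ga_fd = fd_gradient(lambda a: free_energy(model, s_of_a(a), mu), a0)
        worst_a = max(worst_a, _rel(ga_impl, ga_fd))
    return {
        "max_rel_error_mu": worst_mu,
        "max_rel_error_action": worst_a,
        "n_models": n_models,
        "passed": bool(worst_mu <= tol and worst_a <= tol),
    }


def check_linear_gaussian(seed: int = 0, n_steps: int = 64) -> dict:
    """Iterated perception reaches the conjugate-Gaussian posterior."""
    from .fixtures import toy_linear_gaussian_model

    toy = toy_linear_gaussian_model(seed=seed)
    model = toy.model
    state = AgentState(mu=np.zeros(model.mu_dim), action=np.zeros(0), time=0.0)
    cfg = IntegratorConfig(dt=1.0, kappa_a=0.0, record_uncertainty=False)
    source = lambda t, a: toy.s_tilde
    trace, state = run_epoch(state, model, source, cfg, n_steps)
    mean_err = float(np.max(np.abs(state.mu - toy.posterior_mean)))
    H = curvature(model, toy.s_tilde, state.mu)
    var = np.diag(np.linalg.inv(H))
    var_err = float(np.max(np.abs(var - np.diag(toy.posterior_cov))
                           / np.diag(toy.posterior_cov)))
    return {
        "posterior_mean_inf_error": mean_err,
        "posterior_var_rel_error": var_err,
        "passed": bool(mean_err <= 1e-6 and var_err <= 1e-3),
    }


def check_descent(seed: int = 0, n_steps: int = 1000, dt: float = 1.5) -> dict:
    """Free energy is non-increasing with static input and frozen action."""
    rng = np.random.default_rng(seed)
    nx, ny, nv, n = 2, 2, 1, 3
    A = rng.normal(size=(ny, nx))
    Fx = -np.eye(nx) * 0.05 + 0.02 * rng.normal(size=(nx, nx))
    Fv = rng.normal(size=(nx, nv)) * 0.05
    level = ModelLevel(
        ny=ny, nx=nx, nv=nv,
        g=lambda x, v: A @ x,
        f=lambda x, v: Fx @ x + Fv @ v,
        jac_g=lambda x, v: (A, np.zeros((ny, nv))),
        jac_f=lambda x, v: (Fx, Fv),
        output_precision=2.0, state_precision=1.0,
        roughness_output=1.0 / 32.0, roughness_states=1.0 / 32.0,
    )
    model = HierarchicalModel([level], order=n, prior_mean=np.ones(nv),
                              prior_precision=1.0, roughness_prior=1.0 / 32.0)
    s = np.zeros((n, ny))
    s[0] = rng.normal(size=ny)
    state = AgentState(mu=np.zeros(model.mu_dim), action=np.zeros(0), time=0.0)
    cfg = IntegratorConfig(dt=dt, kappa_a=0.0, record_uncertainty=False)
    trace, _ = run_epoch(state, model, lambda t, a: s, cfg, n_steps)
    F = trace.free_energies
    tol = 1e-9 * abs(F[0])
    increases = np.diff(F) > tol
    return {
        "n_steps": int(len(F)),
        "n_increases": int(increases.sum()),
        "max_increase": float(np.max(np.diff(F))) if len(F) > 1 else 0.0,
        "passed": bool(not increases.any() and not trace.diverged),
    }


def check_salience_argmax(grid_side: int = 9) -> dict:
    """Brute-force fictive-sampling check of the salience peak.

    Two templates differ at exactly one pixel; with a narrow fovea the
    most informative fixation is the grid point nearest that pixel.  The
    oracle re-evaluates the salience functional by direct loops.
    """
    from .salience import make_grid, raw_salience, select_target
    from .visual_world import FovealSampler, HypothesisSet, TemplateImage, foveal_sample

    size = 17
    base = np.zeros((size, size))
    px_row, px_col = 4, 12
    other = base.copy()
    other[px_row, px_col] = 1.0
    t0 = TemplateImage(pixels=base, label="blank")
    t1 = TemplateImage(pixels=other, label="dot")
    hset = HypothesisSet(templates=[t0, t1], true_index=1)
    sampler = FovealSampler(sigma_fov=0.08, grid_side=5, max_precision=32.0)
    points, shape = make_grid(extent=1.0, side=grid_side)
    w = np.array([0.5, 0.5])
    smap = raw_salience(w, hset, sampler, points, shape)
    target = select_target(smap)

    # independent brute force: loop over grid points and offsets
    best_val, best_idx = -1.0, -1
    for gi, p in enumerate(points):
        val = 0.0
        m = [foveal_sample(t, p, sampler) for t in (t0, t1)]
        for i in range(sampler.R):
            mbar = w[0] * m[0][i] + w[1] * m[1][i]
            for k in range(2):
                val += w[k] * sampler.precision_profile[i] * (m[k][i] - mbar) ** 2
        if val > best_val:
            best_val, best_idx = val, gi
    brute_target = points[best_idx]

    # pixel centre in gaze units (x rightward, y upward, origin centre)
    half = (size - 1) / 2
    pixel_xy = np.array([(px_col - half) / half, (half - px_row) / half])
    nearest = points[int(np.argmin(np.linalg.norm(points - pixel_xy, axis=1)))]
    return {
        "selected": target.tolist(),
        "brute_force": brute_target.tolist(),
        "nearest_to_pixel": nearest.tolist(),
        "passed": bool(np.allclose(target, brute_target)
                       and np.allclose(target, nearest)),
    }
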