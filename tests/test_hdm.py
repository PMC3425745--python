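"""Hierarchical models: predictions, free energy and its gradients."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from actinf.exceptions import ModelSpecificationError, NumericalDomainError
from actinf.fixtures import toy_linear_gaussian_model
from actinf.hdm import (
    HierarchicalModel,
    ModelLevel,
    conditional_std,
    curvature,
    free_energy,
    grad_free_energy_action,
    grad_free_energy_mu,
    predict,
    prediction_errors,
)
from actinf.oracles import fd_gradient, random_smooth_model


def one_state_model(g, f=lambda x, v: -0.1 * x, order=2, **kw):
    level = ModelLevel(ny=1, nx=1, nv=0, g=g, f=f, **kw)
    return HierarchicalModel([level], order=order)


class TestPredict:
    def test_linear_mapping_propagates_linearly(self):
        model = one_state_model(lambda x, v: 2.0 * x)
        g_tilde, _ = predict(model, np.array([3.0, 1.0]))
        assert np.allclose(g_tilde[0].ravel(), [6.0, 2.0])

    def test_constant_mapping_has_zero_derivatives(self):
        model = one_state_model(lambda x, v: np.array([0.7]))
        g_tilde, _ = predict(model, np.array([3.0, 1.0]))
        assert np.allclose(g_tilde[0].ravel(), [0.7, 0.0])

    def test_chain_rule_on_square(self):
        # g(x) = x^2 at x=2 moving at x'=5: first-order block is 2*2*5
        model = one_state_model(lambda x, v: x**2)
        g_tilde, _ = predict(model, np.array([2.0, 5.0]))
        assert np.allclose(g_tilde[0][1], 20.0, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        model = one_state_model(lambda x, v: 2.0 * x)
        with pytest.raises(ModelSpecificationError):
            predict(model, np.zeros(5))


class TestFreeEnergy:
    def test_zero_errors_leave_normaliser_only(self):
        # static identity model observed at its prior mean: every error
        # stream vanishes, so F is exactly the log-normalisation term
        level = ModelLevel(ny=1, nx=0, nv=1, g=lambda x, v: v,
                           output_precision=2.0)
        model = HierarchicalModel([level], order=1, prior_mean=[0.3],
                                  prior_precision=4.0)
        mu = np.array([0.3])
        F = free_energy(model, np.array([[0.3]]), mu)
        expected = -0.5 * (np.log(2.0) + np.log(4.0) - 2 * np.log(2 * np.pi))
        assert np.isclose(F, expected)
        assert np.allclose(prediction_errors(model, [[0.3]], mu).stacked, 0.0)

    def test_quadratic_scaling_of_errors(self):
        level = ModelLevel(ny=2, nx=0, nv=2, g=lambda x, v: v,
                           output_precision=1.0)
        model = HierarchicalModel([level], order=1, prior_mean=np.zeros(2),
                                  prior_precision=1e-8)
        mu = np.zeros(2)
        F0 = free_energy(model, np.zeros((1, 2)), mu)
        F1 = free_energy(model, np.array([[0.5, -0.2]]), mu)
        F2 = free_energy(model, np.array([[1.0, -0.4]]), mu)
        assert np.isclose(F2 - F0, 4 * (F1 - F0), rtol=1e-6)

    def test_matches_closed_form_gaussian_joint(self):
        # F equals the negative log joint density of data and expectations
        # for a linear-Gaussian static model
        toy = toy_linear_gaussian_model(nv=2, ny=3, seed=7)
        mu = np.array([0.4, -1.1])
        s = toy.s_tilde.ravel()
        model = toy.model
        Pi_z = model.levels[0].Pi_z
        Pi_v = model.prior_precision
        log_lik = multivariate_normal.logpdf(s, mean=toy.A @ mu,
                                             cov=np.linalg.inv(Pi_z))
        log_prior = multivariate_normal.logpdf(mu, mean=toy.prior_mean,
                                               cov=np.linalg.inv(Pi_v))
        assert np.isclose(free_energy(model, toy.s_tilde, mu),
                          -(log_lik + log_prior), rtol=1e-10)

    def test_non_finite_input_rejected(self):
        toy = toy_linear_gaussian_model(seed=0)
        with pytest.raises(NumericalDomainError):
            free_energy(toy.model, toy.s_tilde, np.array([np.nan, 0.0]))

    def test_invariant_under_coordinate_permutation(self, rng):
        # relabelling cause coordinates together with their precisions
        # cannot change the free energy
        A = rng.normal(size=(3, 3))
        prec = rng.uniform(0.5, 2.0, size=3)
        perm = np.array([2, 0, 1])

        def build(Amat, p):
            level = ModelLevel(ny=3, nx=0, nv=3, g=lambda x, v: Amat @ v,
                               output_precision=1.0)
            return HierarchicalModel([level], order=1, prior_mean=np.zeros(3),
                                     prior_precision=p)

        mu = rng.normal(size=3)
        s = rng.normal(size=(1, 3))
        F1 = free_energy(build(A, prec), s, mu)
        F2 = free_energy(build(A[:, perm], prec[perm]), s, mu[perm])
        assert np.isclose(F1, F2, rtol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_finite_differences_of_f(self, seed):
        rng = np.random.default_rng(seed)
        model, s, mu = random_smooth_model(rng)
        g_impl = grad_free_energy_mu(model, s, mu)
        g_fd = fd_gradient(lambda m: free_energy(model, s, m), mu)
        denom = max(np.linalg.norm(g_fd), 1e-12)
        assert np.linalg.norm(g_impl - g_fd) / denom <= 1e-4

    def test_zero_at_posterior_mode(self):
        toy = toy_linear_gaussian_model(seed=3)
        g = grad_free_energy_mu(toy.model, toy.s_tilde, toy.posterior_mean)
        assert np.max(np.abs(g)) <= 1e-8

    def test_gradient_scales_with_precision(self):
        # scaling every precision by c scales the quadratic-part gradient by c
        def build(c):
            level = ModelLevel(ny=2, nx=0, nv=2,
                               g=lambda x, v: np.array([[1.0, 0.5], [0.0, 2.0]]) @ v,
                               output_precision=c * 1.5)
            return HierarchicalModel([level], order=1, prior_mean=np.zeros(2),
                                     prior_precision=c * 0.7)

        mu = np.array([0.3, -0.4])
        s = np.array([[1.0, 0.2]])
        g1 = grad_free_energy_mu(build(1.0), s, mu)
        g3 = grad_free_energy_mu(build(3.0), s, mu)
        assert np.allclose(g3, 3 * g1, rtol=1e-6)

    def test_action_gradient_zero_without_sensory_error(self):
        toy = toy_linear_gaussian_model(seed=1)
        mu = toy.posterior_mean
        s_pred = (toy.A @ mu).reshape(1, -1)
        ga = grad_free_energy_action(toy.model, lambda a: s_pred, np.zeros(2), mu)
        assert np.allclose(ga, 0.0, atol=1e-10)

    def test_identity_action_map_returns_sensory_error(self):
        # with s = a, identity precision, n = 1: dF/da = eps_z exactly
        level = ModelLevel(ny=2, nx=0, nv=2, g=lambda x, v: v,
                           output_precision=1.0)
        model = HierarchicalModel([level], order=1, prior_mean=np.zeros(2),
                                  prior_precision=1e-9)
        mu = np.array([0.2, -0.7])
        a = np.array([1.0, 0.5])
        ga = grad_free_energy_action(model, lambda aa: aa.reshape(1, 2), a, mu)
        assert np.allclose(ga, a - mu, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_action_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(100 + seed)
        model, s, mu = random_smooth_model(rng)
        n, ny = s.shape
        E = rng.normal(size=(n * ny, 2))

        def s_of_a(a):
            return (s.reshape(-1) + E @ a + 0.05 * np.tanh(E @ a)).reshape(n, ny)

        a0 = rng.normal(size=2) * 0.3
        ga = grad_free_energy_action(model, s_of_a, a0, mu)
        ga_fd = fd_gradient(lambda a: free_energy(model, s_of_a(a), mu), a0)
        denom = max(np.linalg.norm(ga_fd), 1e-12)
        assert np.linalg.norm(ga - ga_fd) / denom <= 1e-4


class TestCurvature:
    def test_inverse_curvature_is_posterior_covariance(self):
        toy = toy_linear_gaussian_model(nv=3, ny=4, seed=9)
        H = curvature(toy.model, toy.s_tilde, toy.posterior_mean)
        assert np.allclose(np.linalg.inv(H), toy.posterior_cov, rtol=1e-8)

    def test_conditional_std_matches_marginals(self):
        toy = toy_linear_gaussian_model(seed=4)
        sd = conditional_std(toy.model, toy.s_tilde, toy.posterior_mean)
        assert np.allclose(sd, np.sqrt(np.diag(toy.posterior_cov)), rtol=1e-4)


class TestModelValidation:
    def test_dimension_chaining_enforced(self):
        lower = ModelLevel(ny=2, nx=0, nv=3, g=lambda x, v: v[:2])
        upper = ModelLevel(ny=2, nx=0, nv=1, g=lambda x, v: np.repeat(v, 2))
        with pytest.raises(ModelSpecificationError):
            HierarchicalModel([lower, upper], order=1, prior_mean=[0.0])

    def test_two_level_chaining_accepted_and_errors_stack(self, rng):
        lower = ModelLevel(ny=2, nx=0, nv=3, g=lambda x, v: v[:2])
        upper = ModelLevel(ny=3, nx=0, nv=1,
                           g=lambda x, v: np.concatenate([v, v, v]))
        model = HierarchicalModel([lower, upper], order=1, prior_mean=[0.5])
        mu = rng.normal(size=model.mu_dim)
        errs = prediction_errors(model, rng.normal(size=(1, 2)), mu)
        assert errs.stacked.size == model.error_dim

    def test_indefinite_precision_rejected(self):
        with pytest.raises(ModelSpecificationError):
            ModelLevel(ny=2, nx=0, nv=1, g=lambda x, v: np.repeat(v, 2),
                       output_precision=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_output_groups_must_partition(self):
        with pytest.raises(ModelSpecificationError):
            ModelLevel(ny=3, nx=0, nv=1, g=lambda x, v: np.repeat(v, 3),
                       output_groups=[(np.array([0, 1]), 1.0, 1.0)])

    def test_grouped_and_uniform_precisions_agree(self, rng):
        # one group with the same roughness must reproduce the ungrouped model
        def g(x, v):
            return np.concatenate([v, v[:1]])

        kw = dict(ny=3, nx=0, nv=2, g=g)
        plain = HierarchicalModel(
            [ModelLevel(output_precision=2.0, roughness_output=0.5, **kw)],
            order=2, prior_mean=np.zeros(2), prior_precision=1.0)
        grouped = HierarchicalModel(
            [ModelLevel(output_groups=[(np.arange(3), 2.0, 0.5)], **kw)],
            order=2, prior_mean=np.zeros(2), prior_precision=1.0)
        mu = rng.normal(size=plain.mu_dim)
        s = rng.normal(size=(2, 3))
        assert np.isclose(free_energy(plain, s, mu), free_energy(grouped, s, mu))
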