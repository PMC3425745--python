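"""Foveated sampling, the search generative model, and the visual world."""

import numpy as np
import pytest

from actinf.exceptions import ConfigurationError, ModelSpecificationError
from actinf.hdm import free_energy, grad_free_energy_mu
from actinf.oracles import fd_gradient
from actinf.visual_world import (
    FovealSampler,
    HypothesisSet,
    SearchParams,
    TemplateImage,
    VisualWorld,
    foveal_sample,
    hidden_dynamics_f,
    make_search_model,
    sensory_mapping_g,
    softmax,
)


def centre_sampler():
    """A sampler with a single offset at the fovea."""
    s = FovealSampler(sigma_fov=0.2, grid_side=3, max_precision=4.0)
    s.offsets = np.zeros((1, 2))
    s.eccentricity = np.zeros(1)
    s.precision_profile = np.array([4.0])
    return s


class TestFovealSample:
    def test_constant_image_samples_constant(self, tiny_sampler):
        img = TemplateImage(np.full((7, 7), 0.4))
        for gaze in ([0, 0], [0.3, -0.2], [-0.5, 0.5]):
            assert np.allclose(foveal_sample(img, gaze, tiny_sampler), 0.4)

    def test_far_outside_returns_background(self, tiny_sampler):
        img = TemplateImage(np.ones((7, 7)))
        assert np.allclose(foveal_sample(img, [5.0, 5.0], tiny_sampler), 0.0)

    def test_bilinear_centre_of_two_by_two(self):
        # [[0,1],[0,1]] sampled at the exact centre averages to 0.5
        img = TemplateImage(np.array([[0.0, 1.0], [0.0, 1.0]]))
        val = foveal_sample(img, [0.0, 0.0], centre_sampler())
        assert np.allclose(val, 0.5)

    def test_non_finite_gaze_rejected(self, tiny_sampler):
        img = TemplateImage(np.zeros((5, 5)))
        with pytest.raises(ConfigurationError):
            foveal_sample(img, [np.nan, 0.0], tiny_sampler)


class TestFovealSamplerProfile:
    def test_peak_precision_at_fovea(self):
        s = FovealSampler(sigma_fov=0.3, grid_side=9, max_precision=16.0)
        assert s.precision_profile.max() == pytest.approx(16.0)
        centre = np.argmin(s.eccentricity)
        assert s.precision_profile[centre] == s.precision_profile.max()

    def test_precision_decreases_with_eccentricity(self):
        s = FovealSampler(sigma_fov=0.3, grid_side=9, max_precision=16.0)
        order = np.argsort(s.eccentricity)
        p = s.precision_profile[order]
        assert np.all(np.diff(p) <= 1e-12)
        assert p.min() > 0


class TestSensoryMapping:
    def test_one_hot_mixture_returns_that_template(self, dot_hypotheses, tiny_sampler):
        x = np.concatenate([[0.1, -0.2], [-20.0, 20.0]])  # near one-hot on 1
        out = sensory_mapping_g(x, dot_hypotheses, tiny_sampler)
        direct = foveal_sample(dot_hypotheses.templates[1], x[:2], tiny_sampler)
        assert np.allclose(out[: tiny_sampler.R], direct, atol=1e-8)
        assert np.allclose(out[tiny_sampler.R:], x[:2])

    def test_identical_templates_make_mixture_independent(self, tiny_sampler, rng):
        img = TemplateImage(rng.uniform(size=(9, 9)))
        hset = HypothesisSet(templates=[img, TemplateImage(img.pixels.copy())])
        for x_h in ([0.0, 0.0], [3.0, -1.0]):
            out = sensory_mapping_g(np.concatenate([[0.1, 0.1], x_h]), hset,
                                    tiny_sampler)
            base = foveal_sample(img, [0.1, 0.1], tiny_sampler)
            assert np.allclose(out[: tiny_sampler.R], base)

    def test_equal_propensities_average_two_templates(self, dot_hypotheses, tiny_sampler):
        x = np.array([0.0, 0.0, 0.7, 0.7])
        out = sensory_mapping_g(x, dot_hypotheses, tiny_sampler)
        m = [foveal_sample(t, x[:2], tiny_sampler) for t in dot_hypotheses.templates]
        assert np.allclose(out[: tiny_sampler.R], 0.5 * (m[0] + m[1]))

    def test_mixture_stays_within_template_bounds(self, dot_hypotheses,
                                                  tiny_sampler, rng):
        # convexity: the prediction lies within the per-offset min/max
        for _ in range(20):
            x = np.concatenate([rng.uniform(-0.5, 0.5, 2), rng.normal(size=2)])
            out = sensory_mapping_g(x, dot_hypotheses, tiny_sampler)
            m = np.stack([foveal_sample(t, x[:2], tiny_sampler)
                          for t in dot_hypotheses.templates])
            assert np.all(out[: tiny_sampler.R] >= m.min(0) - 1e-12)
            assert np.all(out[: tiny_sampler.R] <= m.max(0) + 1e-12)

    def test_wrong_dimension_rejected(self, dot_hypotheses, tiny_sampler):
        with pytest.raises(ModelSpecificationError):
            sensory_mapping_g(np.zeros(3), dot_hypotheses, tiny_sampler)


class TestHiddenDynamics:
    def test_fixed_point_at_target(self):
        x = np.array([0.4, -0.1, 0.0, 0.0])
        vel = hidden_dynamics_f(x, eta=[0.4, -0.1], tau_o=8.0, tau_h=100.0, K=2)
        assert np.allclose(vel[:2], 0.0)

    def test_zero_hypothesis_states_do_not_leak(self):
        vel = hidden_dynamics_f(np.zeros(4), eta=[0, 0], tau_o=8.0, tau_h=100.0, K=2)
        assert np.allclose(vel[2:], 0.0)

    def test_linear_attraction_law(self):
        vel = hidden_dynamics_f(np.zeros(4), eta=[1.0, 0.0], tau_o=2.0,
                                tau_h=100.0, K=2)
        assert np.allclose(vel[:2], [0.5, 0.0])

    @pytest.mark.parametrize("tau_o,tau_h", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_time_constants_rejected(self, tau_o, tau_h):
        with pytest.raises(ConfigurationError):
            hidden_dynamics_f(np.zeros(4), [0, 0], tau_o, tau_h, 2)


class TestVisualWorld:
    def test_self_consistency_zero_error(self, dot_hypotheses, tiny_sampler):
        # true hypothesis dominant and gaze matched: prediction equals data
        world = VisualWorld(dot_hypotheses, tiny_sampler, order=2, gaze0=(0.2, -0.1))
        x = np.concatenate([world.gaze, [-30.0, 30.0]])
        pred = sensory_mapping_g(x, dot_hypotheses, tiny_sampler)
        sensed = world.sense(0.0, np.zeros(2))
        assert np.allclose(sensed[0], pred, atol=1e-8)

    def test_static_world_has_zero_derivative_orders(self, dot_hypotheses,
                                                     tiny_sampler):
        world = VisualWorld(dot_hypotheses, tiny_sampler, order=3)
        s = world.sense(0.0, np.zeros(2))
        assert np.allclose(s[1:], 0.0)

    def test_action_shift_consistency(self, dot_hypotheses, tiny_sampler):
        # advancing the gaze by delta equals sampling at gaze + delta
        world = VisualWorld(dot_hypotheses, tiny_sampler, order=2)
        a = np.array([0.3, -0.1])
        world.advance(1.0, a)
        moved = world.sense(1.0, np.zeros(2))[0, : tiny_sampler.R]
        direct = foveal_sample(dot_hypotheses.templates[1], a, tiny_sampler)
        assert np.allclose(moved, direct)

    def test_proprioception_reports_physical_gaze(self, dot_hypotheses,
                                                  tiny_sampler):
        world = VisualWorld(dot_hypotheses, tiny_sampler, order=2, gaze0=(0.4, 0.6))
        s = world.sense(0.0, np.array([0.1, 0.2]))
        assert np.allclose(s[0, tiny_sampler.R:], [0.4, 0.6])
        assert np.allclose(s[1, tiny_sampler.R:], [0.1, 0.2])


class TestSearchModel:
    def test_gradient_matches_finite_differences(self, dot_hypotheses,
                                                 tiny_sampler, rng):
        # regression for the analytic mixture/softmax Jacobians
        model = make_search_model(dot_hypotheses, tiny_sampler,
                                  SearchParams(order=2))
        mu = rng.normal(size=model.mu_dim) * 0.2
        s = rng.uniform(0, 1, size=(2, tiny_sampler.R + 2))
        g1 = grad_free_energy_mu(model, s, mu)
        g2 = fd_gradient(lambda m: free_energy(model, s, m), mu)
        assert np.linalg.norm(g1 - g2) / max(np.linalg.norm(g2), 1e-9) < 1e-4

    def test_dimensions(self, dot_hypotheses, tiny_sampler):
        model = make_search_model(dot_hypotheses, tiny_sampler, SearchParams())
        K, R = dot_hypotheses.K, tiny_sampler.R
        assert model.levels[0].ny == R + 2
        assert model.levels[0].nx == 2 + K
        assert model.mu_dim == SearchParams().order * (2 + K + 2)


class TestTemplateImage:
    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            TemplateImage(np.array([[0.0, 1.5]]))

    def test_pgm_png_roundtrip(self, tmp_path, rng):
        img = TemplateImage(np.round(rng.uniform(size=(8, 8)) * 255) / 255)
        img.save_pgm(tmp_path / "t.pgm")
        img.save_png(tmp_path / "t.png")
        back = TemplateImage.load(tmp_path / "t.png")
        assert np.allclose(back.pixels, img.pixels, atol=1 / 255)

    def test_hypothesis_set_requires_matching_shapes(self):
        a = TemplateImage(np.zeros((4, 4)))
        b = TemplateImage(np.zeros((5, 5)))
        with pytest.raises(ConfigurationError):
            HypothesisSet(templates=[a, b])


def test_softmax_normalises_and_is_shift_invariant(rng):
    z = rng.normal(size=5)
    w = softmax(z)
    assert w.sum() == pytest.approx(1.0)
    assert np.allclose(softmax(z + 10.0), w)
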