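"""Winnerless competition, arm mechanics and the motor simulations."""

import numpy as np
import pytest

from actinf.exceptions import ConfigurationError
from actinf.hdm import free_energy, grad_free_energy_mu
from actinf.motor import (
    ArmModel,
    LVAttractor,
    MotorParams,
    MotorResult,
    ObservationMode,
    arm_flow,
    arm_jacobian,
    default_attractor,
    forward_kinematics,
    lv_flow,
    make_motor_model,
    place_field_analysis,
    run_motor_simulation,
    visitation_sequence,
    winner,
)
from actinf.oracles import fd_gradient


class TestLVFlow:
    def test_extinction_fixed_point(self):
        att = default_attractor()
        assert np.allclose(lv_flow(np.zeros(6), att), 0.0)

    def test_logistic_limit_single_state(self):
        att = LVAttractor(K=1, connectivity=[[1.0]], rate=0.5,
                          targets=[[1.2, 0.0]])
        assert lv_flow(np.array([1.0]), att)[0] == pytest.approx(0.0)
        assert lv_flow(np.array([0.5]), att)[0] > 0
        assert lv_flow(np.array([1.5]), att)[0] < 0

    def test_cyclic_itinerancy_of_default_network(self):
        # numerical integration visits each vertex in ascending cyclic order
        att = default_attractor()
        x = np.full(6, 0.05)
        x[0] = 0.9
        seq = []
        for _ in range(12000):
            x = x + 1.0 * lv_flow(x, att)
            w = winner(x)
            if not seq or seq[-1] != w:
                seq.append(w)
        assert len(seq) >= 7
        for i in range(1, len(seq)):
            assert seq[i] == (seq[i - 1] + 1) % 6

    def test_boundedness_over_long_run(self):
        att = default_attractor()
        x = np.full(6, 0.1)
        lo, hi = np.inf, -np.inf
        for _ in range(100_000):
            x = x + 1.0 * lv_flow(x, att)
            lo, hi = min(lo, x.min()), max(hi, x.max())
        assert lo > 0.0
        assert hi < 10.0


class TestWinner:
    def test_one_hot(self):
        assert winner([0.0, 1.0, 0.0]) == 1

    def test_tie_goes_to_lowest_index(self):
        assert winner([0.3, 0.3, 0.3]) == 0

    def test_increasing_vector_picks_last(self):
        assert winner([0.1, 0.2, 0.3, 0.4]) == 3

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            winner([])


class TestForwardKinematics:
    @pytest.mark.parametrize("theta,expected", [
        ((0.0, 0.0), (2.0, 0.0)),
        ((np.pi / 2, 0.0), (0.0, 2.0)),
        ((0.0, np.pi / 2), (1.0, 1.0)),
    ])
    def test_textbook_poses(self, theta, expected):
        assert np.allclose(forward_kinematics(theta, (1.0, 1.0)), expected,
                           atol=1e-12)

    def test_jacobian_matches_finite_differences(self, rng):
        th = rng.uniform(-np.pi, np.pi, 2)
        J = arm_jacobian(th, (1.0, 0.7))
        Jfd = np.column_stack([
            (forward_kinematics(th + d, (1.0, 0.7))
             - forward_kinematics(th - d, (1.0, 0.7))) / 2e-6
            for d in (np.array([1e-6, 0]), np.array([0, 1e-6]))])
        assert np.allclose(J, Jfd, atol=1e-6)


class TestArmFlow:
    def test_equilibrium_at_target(self):
        arm = ArmModel(theta=[0.4, 0.9], omega=[0.0, 0.0])
        target = forward_kinematics(arm.theta, arm.lengths)
        assert np.allclose(arm_flow(arm, target), 0.0, atol=1e-15)

    def test_doubling_stiffness_doubles_acceleration(self):
        a1 = ArmModel(theta=[0.4, 0.9], spring_gain=1e-3)
        a2 = ArmModel(theta=[0.4, 0.9], spring_gain=2e-3)
        acc1 = arm_flow(a1, [0.0, 1.0])
        acc2 = arm_flow(a2, [0.0, 1.0])
        assert np.allclose(acc2, 2 * acc1)

    def test_radial_force_in_null_space_of_outstretched_arm(self):
        # theta2 = 0 is singular: a force along the arm produces no torque
        arm = ArmModel(theta=[0.3, 0.0], omega=[0.0, 0.0])
        e = forward_kinematics(arm.theta, arm.lengths)
        target = 1.5 * e  # radially outward
        assert np.allclose(arm_flow(arm, target), 0.0, atol=1e-12)


class TestObservationMode:
    def test_observation_implies_no_action(self):
        with pytest.raises(ConfigurationError):
            ObservationMode(proprioceptive_precision_scale=1e-6,
                            action_enabled=True)

    def test_factories(self):
        assert ObservationMode.action().action_enabled
        obs = ObservationMode.observation()
        assert not obs.action_enabled
        assert 0 < obs.proprioceptive_precision_scale < 1e-3


class TestMotorModel:
    def test_gradient_matches_finite_differences(self, rng):
        # regression for the analytic kinematic and LV Jacobians
        att = default_attractor()
        arm = ArmModel()
        model = make_motor_model(att, arm, MotorParams(order=2),
                                 ObservationMode.action())
        mu = rng.normal(size=model.mu_dim) * 0.3
        s = rng.normal(size=(2, 8)) * 0.3
        g1 = grad_free_energy_mu(model, s, mu)
        g2 = fd_gradient(lambda m: free_energy(model, s, m), mu)
        assert np.linalg.norm(g1 - g2) / max(np.linalg.norm(g2), 1e-9) < 1e-4

    def test_target_radius_outside_annulus_rejected(self):
        with pytest.raises(ConfigurationError):
            default_attractor(radius=2.5)
        with pytest.raises(ConfigurationError):
            default_attractor(radius=0.0, lengths=(1.0, 0.4))


class TestRunMotorSimulation:
    def test_zero_duration_returns_empty_result(self):
        att = default_attractor()
        res = run_motor_simulation(att, ArmModel(), ObservationMode.action(),
                                   duration_ms=0.0)
        assert len(res.trace) == 0
        assert res.activity.shape == (0, att.K)
        assert not res.diverged

    def test_short_action_run_tracks_world(self):
        att = default_attractor()
        res = run_motor_simulation(att, ArmModel(), ObservationMode.action(),
                                   duration_ms=300.0, seed=1)
        assert not res.diverged
        assert len(res.endpoint_path) == len(res.trace)
        # the believed and physical arms stay glued together
        believed = np.array([forward_kinematics(mu[:2])
                             for mu in res.trace.expectations])
        assert np.max(np.linalg.norm(believed - res.endpoint_path, axis=1)) < 0.05
        # kinematic consistency of the recorded joint/endpoint paths
        rebuilt = np.array([forward_kinematics(th) for th in res.joint_path])
        assert np.allclose(rebuilt, res.endpoint_path, atol=1e-9)


class TestPlaceFields:
    def _result(self, activity, path):
        from actinf.active_inference import SimulationTrace

        T = len(activity)
        trace = SimulationTrace(
            times=np.arange(T, dtype=float), expectations=np.zeros((T, 1)),
            uncertainties=np.zeros((0, 0)), actions=np.zeros((T, 2)),
            free_energies=np.zeros(T), sensory=np.zeros((T, 1)))
        return MotorResult(trace=trace, endpoint_path=np.asarray(path),
                           joint_path=np.zeros((T, 2)),
                           activity=np.asarray(activity),
                           attractor=default_attractor(),
                           mode=ObservationMode.action())

    def test_constant_activity_keeps_every_position(self, rng):
        path = rng.normal(size=(50, 2))
        res = self._result(np.ones((50, 1)), path)
        pf = place_field_analysis(res)
        assert len(pf.positions[0]) == 50

    def test_one_hot_activity_keeps_single_position(self, rng):
        act = np.zeros((50, 1))
        act[17] = 1.0
        path = rng.normal(size=(50, 2))
        pf = place_field_analysis(self._result(act, path))
        assert len(pf.positions[0]) == 1
        assert np.allclose(pf.positions[0][0], path[17])

    def test_all_zero_activity_gives_empty_set(self, rng):
        pf = place_field_analysis(self._result(np.zeros((20, 1)),
                                               rng.normal(size=(20, 2))))
        assert len(pf.positions[0]) == 0
        assert np.isnan(pf.dispersions[0])


def test_visitation_sequence_collapses_repeats():
    targets = np.array([[0.0, 0.0], [10.0, 0.0]])
    path = np.array([[0.1, 0.0], [0.05, 0.0], [10.0, 0.1], [0.0, 0.0]])
    assert visitation_sequence(path, targets, eps=0.5) == [0, 1, 0]
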