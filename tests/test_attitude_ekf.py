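"""Quaternion algebra and attitude-EKF behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baroimu import attitude_ekf as ekf
from baroimu import quaternion as quat
from baroimu.sensor_model import DEG, MG, FusionConfig, RestStatistics

G = 9.81


def random_unit_quaternion(rng):
    return quat.normalize(rng.standard_normal(4))


class TestSkew:
    def test_zero_vector_gives_zero_matrix(self):
        assert np.all(ekf.skew(np.zeros(3)) == 0.0)

    def test_printed_layout(self):
        # (p, q, r) = (1, 2, 3): first row (0, -r, q).
        S = ekf.skew(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(S[0], [0.0, -3.0, 2.0])
        np.testing.assert_array_equal(S, -S.T)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_matches_cross_product_and_annihilates_self(self, seed):
        rng = np.random.default_rng(seed)
        v, u = rng.standard_normal((2, 3))
        np.testing.assert_allclose(ekf.skew(v) @ u, np.cross(v, u), atol=1e-12)
        np.testing.assert_allclose(ekf.skew(v) @ v, 0.0, atol=1e-12)


class TestPropagateQuaternion:
    def test_zero_rate_is_identity(self):
        q = quat.normalize(np.array([0.1, -0.2, 0.3, 0.9]))
        np.testing.assert_array_equal(ekf.propagate_quaternion(q, np.zeros(3), 0.02), q)

    def test_quarter_turn_about_x_closed_form(self):
        # omega = (pi, 0, 0), Ts = 0.5: rotation of pi/2 about x.
        q = ekf.propagate_quaternion(quat.identity(), np.array([np.pi, 0, 0]), 0.5)
        s = np.sin(np.pi / 4)
        np.testing.assert_allclose(q, [s, 0.0, 0.0, s], atol=1e-12)

    def test_norm_preserved_for_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            q = random_unit_quaternion(rng)
            omega = 10.0 * rng.standard_normal(3)
            out = ekf.propagate_quaternion(q, omega, 0.02)
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12

    def test_constant_rate_compounding_matches_single_rotation(self):
        # 100 steps at omega = (pi/5, 0, 0), Ts = 0.02 == one rotation of
        # angle 100 * |omega| * Ts about x.
        omega = np.array([np.pi / 5, 0.0, 0.0])
        q = quat.identity()
        for _ in range(100):
            q = ekf.propagate_quaternion(q, omega, 0.02)
        expected = quat.from_axis_angle([1, 0, 0], 100 * omega[0] * 0.02)
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestRotationMatrices:
    def test_identity_quaternion_gives_identity(self):
        np.testing.assert_allclose(ekf.quaternion_to_Cbn(quat.identity()), np.eye(3))

    def test_right_hand_rule_quarter_turn(self):
        # pi/2 about x maps body y to nav z (right-hand rule) through C_nb.
        q = quat.from_axis_angle([1, 0, 0], np.pi / 2)
        C_nb = ekf.quaternion_to_Cnb(q)
        np.testing.assert_allclose(C_nb @ [0, 1, 0], [0, 0, 1], atol=1e-12)
        C = ekf.quaternion_to_Cbn(q)
        np.testing.assert_allclose(C @ C.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(C) == pytest.approx(1.0, abs=1e-12)

    def test_Cbn_Cnb_are_transpose_pair(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = random_unit_quaternion(rng)
            prod = ekf.quaternion_to_Cbn(q) @ ekf.quaternion_to_Cnb(q)
            np.testing.assert_allclose(prod, np.eye(3), atol=1e-12)

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError):
            ekf.quaternion_to_Cbn(np.array([0.0, 0.0, 0.0, 1.1]))


class TestBiasTransition:
    def test_random_walk_limit_at_alpha_zero(self):
        b, Qa = ekf.bias_transition(np.array([1.0, 2.0, 3.0]), 0.0, 0.02, 5e-4)
        np.testing.assert_array_equal(b, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(np.diag(Qa), 0.02 * (5e-4) ** 2)

    def test_gauss_markov_covariance(self):
        _, Qa = ekf.bias_transition(np.zeros(3), 1.0, 0.02, 1.0)
        np.testing.assert_allclose(np.diag(Qa), (1 - np.exp(-0.04)) / 2.0)

    def test_fast_correlation_limit(self):
        b, Qa = ekf.bias_transition(np.ones(3), 1e9, 0.02, 1.0)
        assert np.all(np.abs(b) < 1e-12)
        assert np.all(np.diag(Qa) < 1e-8)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            ekf.bias_transition(np.zeros(3), -1.0, 0.02, 1e-4)


class TestProcessNoise:
    def test_identity_quaternion_zero_covariance(self):
        sigma_g, Ts = 0.02, 0.02
        Q = ekf.process_noise(quat.identity(), np.zeros((4, 4)), sigma_g, Ts,
                              np.zeros((3, 3)))
        expected = np.diag([1.0, 1.0, 1.0, 0.0]) * sigma_g ** 2 * (Ts / 2) ** 2
        np.testing.assert_allclose(Q[:4, :4], expected, atol=1e-18)

    def test_zero_gyro_noise_gives_zero_block(self):
        Q = ekf.process_noise(quat.identity(), 1e-3 * np.eye(4), 0.0, 0.02,
                              np.eye(3))
        assert np.all(Q[:4, :4] == 0.0)

    def test_symmetric_psd_for_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q = random_unit_quaternion(rng)
            A = 1e-3 * rng.standard_normal((4, 4))
            Q = ekf.process_noise(q, A @ A.T, 0.02, 0.02, 1e-8 * np.eye(3))
            np.testing.assert_allclose(Q, Q.T, atol=1e-15)
            assert np.linalg.eigvalsh(Q).min() > -1e-12


class TestPredict:
    def test_noop_with_zero_rate_and_zero_noise(self, cfg_a):
        cfg = cfg_a.replace(sigma_g=0.0, sigma_ab=0.0)
        state = ekf.initial_state(quat.identity(), cfg)
        out = ekf.predict(state, np.zeros(3), cfg)
        np.testing.assert_array_equal(out.q, state.q)
        np.testing.assert_allclose(out.P, state.P, atol=1e-18)

    def test_covariance_trace_grows(self, cfg_a):
        state = ekf.initial_state(quat.identity(), cfg_a)
        for _ in range(10):
            new = ekf.predict(state, np.array([0.5, -0.2, 0.1]), cfg_a)
            assert np.trace(new.P) >= np.trace(state.P) - 1e-15
            state = new


class TestMeasurementUpdate:
    def test_zero_innovation_leaves_state(self, cfg_a):
        state = ekf.initial_state(quat.identity(), cfg_a)
        new, diag = ekf.measurement_update(state, np.array([0, 0, -G]), cfg_a)
        assert diag.updated
        np.testing.assert_allclose(diag.innovation, 0.0, atol=1e-12)
        np.testing.assert_allclose(new.q, state.q, atol=1e-12)
        np.testing.assert_allclose(new.bias, 0.0, atol=1e-12)
        # covariance contracts
        assert np.trace(new.P) < np.trace(state.P)

    def test_free_fall_rejects_all_rows_when_tilted(self, cfg_a):
        # Generic tilt spreads gravity over all body axes; with f = 0 every
        # innovation component exceeds the 150 mg gate.
        q0 = quat.from_axis_angle([1, 1, 0], np.deg2rad(30))
        state = ekf.initial_state(q0, cfg_a)
        new, diag = ekf.measurement_update(state, np.zeros(3), cfg_a)
        assert not diag.updated
        assert diag.accepted_axes == ()
        np.testing.assert_array_equal(new.q, state.q)

    def test_partial_axis_acceptance(self, cfg_a):
        # Force innovation (0.05g, 0.20g, 0.01g): only x and z survive.
        state = ekf.initial_state(quat.identity(), cfg_a)
        f = np.array([0.05 * G, 0.20 * G, -G + 0.01 * G])
        _, diag = ekf.measurement_update(state, f, cfg_a)
        assert diag.accepted_axes == ("x", "z")
        assert diag.updated

    def test_gyro_only_coasting_is_pure_propagation(self, cfg_a):
        # With every row rejected the posterior quaternion equals the
        # propagated quaternion bitwise.
        q0 = quat.from_axis_angle([1, 1, 0], np.deg2rad(30))
        state = ekf.initial_state(q0, cfg_a)
        omega = np.array([0.3, -0.1, 0.2])
        reference = state.q.copy()
        for _ in range(25):
            state = ekf.predict(state, omega, cfg_a)
            reference = ekf.propagate_quaternion(reference, omega, cfg_a.Ts)
            state, diag = ekf.measurement_update(state, np.zeros(3), cfg_a)
            assert not diag.updated
            assert np.array_equal(state.q, reference)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(17)
        eps = 1e-7
        for _ in range(25):
            q = random_unit_quaternion(rng)
            b = 0.05 * rng.standard_normal(3)
            x0 = np.concatenate([q, b])

            def z(x):
                qv, q4 = x[:3], x[3]
                s = quat.skew(qv)
                C_bn = np.eye(3) - 2 * q4 * s + 2 * (s @ s)
                return C_bn @ np.array([0, 0, -G]) + x[4:]

            H = ekf.measurement_jacobian(q, G)
            Hfd = np.column_stack([
                (z(x0 + eps * np.eye(7)[i]) - z(x0 - eps * np.eye(7)[i])) / (2 * eps)
                for i in range(7)])
            np.testing.assert_allclose(H, Hfd, atol=1e-6)


class TestFilterRuns:
    def _static_rest(self, q0=None):
        return RestStatistics(gyro_bias=np.zeros(3), baro_baseline=0.0,
                              initial_quaternion=q0 if q0 is not None
                              else quat.identity(),
                              mean_accel=np.array([0.0, 0.0, -G]))

    def test_static_convergence_from_tilt_error(self, cfg_a):
        # Noise-free level data, 5 deg initial tilt error: inclination error
        # below 0.1 deg after 10 s.
        n = 500
        rest = self._static_rest(quat.from_axis_angle([1, 0, 0], np.deg2rad(5)))
        qs, _, _, _, _ = ekf.run_attitude_filter(
            np.zeros((n, 3)), np.tile([0.0, 0.0, -G], (n, 1)), rest, cfg_a)
        fhat = quat.to_C_bn(qs[-1]) @ np.array([0.0, 0.0, -G])
        incl = np.degrees(np.arccos(np.clip(np.dot(fhat, [0, 0, -G]) / G ** 2,
                                            -1, 1)))
        assert incl < 0.1

    def test_vertical_bias_recovery_within_60s(self, cfg_a):
        # 20 mg bias on the gravity axis (the observable component at rest)
        # recovered to within 5 mg in <= 60 s under nominal sensor noise.
        rng = np.random.default_rng(7)
        n = 3000
        bias_true = np.array([0.0, 0.0, 20 * MG])
        accel = (np.tile([0.0, 0.0, -G], (n, 1)) + bias_true
                 + 10 * MG * rng.standard_normal((n, 3)))
        gyro = 1.0 * DEG * rng.standard_normal((n, 3))
        _, bs, _, _, _ = ekf.run_attitude_filter(gyro, accel,
                                                 self._static_rest(), cfg_a)
        assert abs(bs[-1, 2] - bias_true[2]) < 5 * MG

    def test_quaternion_norm_and_covariance_health(self, cfg_a):
        # Along a noisy run: unit quaternion norm to 1e-9, covariance
        # symmetric to 1e-10 and PSD at every step.
        rng = np.random.default_rng(5)
        state = ekf.initial_state(quat.identity(), cfg_a)
        for _ in range(300):
            omega = 0.5 * rng.standard_normal(3)
            f = np.array([0.0, 0.0, -G]) + 10 * MG * rng.standard_normal(3)
            state = ekf.predict(state, omega, cfg_a)
            state, _ = ekf.measurement_update(state, f, cfg_a)
            assert abs(np.linalg.norm(state.q) - 1.0) < 1e-9
            assert np.abs(state.P - state.P.T).max() < 1e-10
            assert np.linalg.eigvalsh(state.P).min() > -1e-10
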