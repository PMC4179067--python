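"""Quaternion EKF for attitude and accelerometer-bias estimation.

State ``x = [q, b]`` (7 elements): the body-to-navigation quaternion in
vector-first layout and a 3-vector accelerometer bias modeled as a first-order
Gauss-Markov process (random walk at correlation rate ``alpha = 0``).

Per sample the filter

1. propagates the quaternion with the exact closed-form exponential of the
   gyro rate, the bias with its exponential decay, and the 7x7 covariance with
   the block-diagonal transition plus process noise built from the propagated
   quaternion second moment;
2. forms the accelerometer-leveling innovation
   ``nu = f^b - C_bn(q)(-g^n) - b`` and gates it per axis: any component with
   ``|nu_i| > lambda_g`` has the corresponding measurement-matrix row zeroed
   (vector selection), protecting the update against dynamic acceleration; if
   every row is zeroed the update is skipped entirely and the filter coasts on
   the gyro;
3. applies the standard Kalman update with ``R = sigma_a^2 I``, symmetrizes
   the covariance and renormalizes the quaternion.

The measurement Jacobian is derived analytically from the leveling model and
is checked against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quaternion as quat
from .quaternion import skew
from .sensor_model import MG, FusionConfig, RestStatistics

__all__ = [
    "AttitudeState",
    "UpdateDiagnostics",
    "skew",
    "propagate_quaternion",
    "quaternion_to_Cbn",
    "quaternion_to_Cnb",
    "bias_transition",
    "process_noise",
    "predict",
    "measurement_jacobian",
    "measurement_update",
    "initial_state",
    "run_attitude_filter",
]

AXES = ("x", "y", "z")

# Initial 1-sigma uncertainties after a rest-period initialization: small
# quaternion uncertainty from accelerometer leveling; bias uncertainty of an
# in-field-calibrated accelerometer (1 mg).
P0_QUAT = 1e-4
P0_BIAS_SD = 1.0 * MG


@dataclass
class AttitudeState:
    """EKF state: quaternion, accelerometer bias and 7x7 error covariance."""

    q: np.ndarray
    bias: np.ndarray
    P: np.ndarray

    def copy(self) -> "AttitudeState":
        return AttitudeState(self.q.copy(), self.bias.copy(), self.P.copy())


@dataclass
class UpdateDiagnostics:
    """Per-step vector-selection outcome."""

    innovation: np.ndarray
    accepted_axes: tuple
    updated: bool


def propagate_quaternion(q: np.ndarray, omega: np.ndarray, Ts: float) -> np.ndarray:
    """One-step quaternion propagation ``Phi(omega) q`` (exact exponential)."""
    return quat.propagate(q, omega, Ts)


def quaternion_to_Cbn(q: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping {n} vectors into {b} for a unit quaternion."""
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm deviates from 1 by {abs(norm - 1.0):.2e}")
    return quat.to_C_bn(q)


def quaternion_to_Cnb(q: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping {b} vectors into {n} (transpose of C_bn)."""
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm deviates from 1 by {abs(norm - 1.0):.2e}")
    return quat.to_C_nb(q)


def bias_transition(bias: np.ndarray, alpha: float, Ts: float,
                    sigma_ab: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Markov bias propagation and its process covariance.

    Returns ``(exp(-alpha Ts) * bias, Qa)`` with
    ``Qa = I (1 - exp(-2 alpha Ts)) / (2 alpha) * sigma_ab^2``; at
    ``alpha = 0`` the analytic limit ``Qa = I Ts sigma_ab^2`` (random walk)
    is used.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0.0:
        decay = 1.0
        var = Ts * sigma_ab ** 2
    else:
        decay = float(np.exp(-alpha * Ts))
        var = (1.0 - np.exp(-2.0 * alpha * Ts)) / (2.0 * alpha) * sigma_ab ** 2
    return decay * np.asarray(bias, dtype=float), np.eye(3) * var


def process_noise(q_pred: np.ndarray, Pq_pred: np.ndarray, sigma_g: float,
                  Ts: float, Qa: np.ndarray) -> np.ndarray:
    """Block-diagonal 7x7 process noise.

    The quaternion block is ``(I tr(M) - M) sigma_g^2 (Ts/2)^2`` with
    ``M = q q^T + P^q`` evaluated at the propagated state: this is the exact
    second moment of the gyro noise mapped through the quaternion kinematics,
    and is symmetric positive semidefinite by construction.
    """
    M = np.outer(q_pred, q_pred) + Pq_pred
    Qq = (np.eye(4) * np.trace(M) - M) * (sigma_g * Ts / 2.0) ** 2
    Q = np.zeros((7, 7))
    Q[:4, :4] = 0.5 * (Qq + Qq.T)
    Q[4:, 4:] = Qa
    return Q


def predict(state: AttitudeState, omega: np.ndarray,
            cfg: FusionConfig) -> AttitudeState:
    """Time-propagation step: quaternion, bias and covariance."""
    Phi = quat.propagation_matrix(omega, cfg.Ts)
    q_pred = Phi @ state.q
    bias_pred, Qa = bias_transition(state.bias, cfg.alpha, cfg.Ts, cfg.sigma_ab)
    decay = 1.0 if cfg.alpha == 0.0 else float(np.exp(-cfg.alpha * cfg.Ts))

    P = state.P
    P1 = np.zeros((7, 7))
    P1[:4, :4] = Phi @ P[:4, :4] @ Phi.T
    P1[:4, 4:] = Phi @ P[:4, 4:] * decay
    P1[4:, :4] = P1[:4, 4:].T
    P1[4:, 4:] = P[4:, 4:] * decay ** 2

    Q = process_noise(q_pred, P1[:4, :4], cfg.sigma_g, cfg.Ts, Qa)
    return AttitudeState(q_pred, bias_pred, P1 + Q)


def measurement_jacobian(q: np.ndarray, g: float) -> np.ndarray:
    """3x7 Jacobian of the leveling model ``z = C_bn(q)(-g^n) + b``.

    With ``u = -g^n`` and ``z = u - 2 q4 (q x u) + 2 q x (q x u)``:

    * ``dz/dq  =  2 q4 [u x] - 2 [(q x u) x] - 2 [q x][u x]``,
    * ``dz/dq4 = -2 (q x u)``,
    * ``dz/db  =  I``.
    """
    u = np.array([0.0, 0.0, -g])
    qv = q[:3]
    q4 = q[3]
    su = skew(u)
    qxu = np.cross(qv, u)
    H = np.zeros((3, 7))
    H[:, :3] = 2.0 * q4 * su - 2.0 * skew(qxu) - 2.0 * skew(qv) @ su
    H[:, 3] = -2.0 * qxu
    H[:, 4:] = np.eye(3)
    return H


def measurement_update(state: AttitudeState, f_b: np.ndarray,
                       cfg: FusionConfig) -> tuple[AttitudeState, UpdateDiagnostics]:
    """Accelerometer-leveling update with per-axis vector selection.

    Rows of H whose innovation component exceeds ``lambda_g`` in magnitude are
    zeroed (keeping the full 3x3 R); if no rows survive the predicted state is
    returned unchanged with ``updated=False``.
    """
    f_b = np.asarray(f_b, dtype=float)
    nu = f_b - quat.to_C_bn(state.q) @ np.array([0.0, 0.0, -cfg.g]) - state.bias
    accept = np.abs(nu) <= cfg.lambda_g
    accepted_axes = tuple(a for a, ok in zip(AXES, accept) if ok)
    if not accept.any():
        return state, UpdateDiagnostics(nu, accepted_axes, False)

    Ha = measurement_jacobian(state.q, cfg.g)
    Ha[~accept, :] = 0.0
    P = state.P
    R = np.eye(3) * cfg.sigma_a_meas ** 2
    S = Ha @ P @ Ha.T + R
    K = P @ Ha.T @ np.linalg.inv(S)
    dx = K @ nu
    q_new = quat.normalize(state.q + dx[:4])
    bias_new = state.bias + dx[4:]
    P_new = (np.eye(7) - K @ Ha) @ P
    P_new = 0.5 * (P_new + P_new.T)
    return (AttitudeState(q_new, bias_new, P_new),
            UpdateDiagnostics(nu, accepted_axes, True))


def initial_state(q0: np.ndarray, cfg: FusionConfig) -> AttitudeState:
    """Fresh state from the rest-period leveling quaternion, zero bias."""
    P = np.zeros((7, 7))
    P[:4, :4] = np.eye(4) * P0_QUAT
    P[4:, 4:] = np.eye(3) * P0_BIAS_SD ** 2
    return AttitudeState(np.asarray(q0, dtype=float).copy(), np.zeros(3), P)


def run_attitude_filter(gyro: np.ndarray, accel: np.ndarray,
                        rest: RestStatistics, cfg: FusionConfig):
    """Stream the EKF over a whole log.  The captured rest-period gyro bias
    is subtracted from every gyro sample before propagation; there is no
    gyro-bias state.

    Returns ``(quaternions (n,4), biases (n,3), innovations (n,3),
    accepted (n,3) bool, updated (n,) bool)``; entry ``k`` is the posterior
    at sample ``k``.
    """
    n = len(gyro)
    state = initial_state(rest.initial_quaternion, cfg)
    qs = np.empty((n, 4))
    bs = np.empty((n, 3))
    innov = np.empty((n, 3))
    updated = np.zeros(n, dtype=bool)
    gbias = rest.gyro_bias
    for k in range(n):
        state = predict(state, gyro[k] - gbias, cfg)
        state, diag = measurement_update(state, accel[k], cfg)
        qs[k] = state.q
        bs[k] = state.bias
        innov[k] = diag.innovation
        updated[k] = diag.updated
    accepted = np.abs(innov) <= cfg.lambda_g
    return qs, bs, innov, accepted, updated
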