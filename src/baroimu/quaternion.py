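"""Unit-quaternion utilities (vector-first layout).

A quaternion is a length-4 :class:`numpy.ndarray` ``[qx, qy, qz, q4]`` with the
vector part first and the scalar part last.  ``q`` always denotes the rotation
from the body frame {b} to the navigation frame {n}; the associated rotation
matrices are

* ``C_nb = I + 2*q4*[qx] + 2*[qx]^2``  (maps {b} vectors into {n}),
* ``C_bn = C_nb.T``                    (maps {n} vectors into {b}),

where ``[qx]`` is the skew-symmetric cross-product matrix of the vector part.
With this assignment the quaternion kinematics ``dq/dt = 1/2 Omega(w) q``
(see :func:`omega_matrix`) follow the right-hand rule: a positive gyro rate
about body x rotates the body by a positive angle about the navigation x
axis, ``dC_nb/dt = C_nb [w x]``.
All functions are pure and operate on plain arrays so they can be used inside
tight filter loops without wrapper overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity",
    "skew",
    "omega_matrix",
    "propagation_matrix",
    "propagate",
    "to_C_bn",
    "to_C_nb",
    "from_axis_angle",
    "between_vectors",
    "normalize",
]


def identity() -> np.ndarray:
    """The identity quaternion (no rotation)."""
    return np.array([0.0, 0.0, 0.0, 1.0])


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix ``[v x]`` such that ``skew(v) @ u == np.cross(v, u)``."""
    v = np.asarray(v, dtype=float)
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def omega_matrix(omega: np.ndarray) -> np.ndarray:
    """4x4 quaternion-rate matrix of the angular velocity ``omega`` (rad/s).

    Layout matches the vector-first quaternion: the top-left 3x3 block is
    ``-[omega x]``, the last column holds ``omega`` and the last row ``-omega^T``.
    """
    o = np.asarray(omega, dtype=float)
    out = np.zeros((4, 4))
    out[:3, :3] = -skew(o)
    out[:3, 3] = o
    out[3, :3] = -o
    return out


def propagation_matrix(omega: np.ndarray, Ts: float) -> np.ndarray:
    """Exact one-step transition matrix ``exp(Ts/2 * Omega(omega))``.

    Because ``Omega(w)^2 = -|w|^2 I`` the matrix exponential has the closed form
    ``cos(theta/2) I + sin(theta/2)/|w| * Omega(w)`` with ``theta = |w| Ts``.
    The matrix is orthogonal, so propagation preserves the quaternion norm.
    """
    o = np.asarray(omega, dtype=float)
    norm = float(np.linalg.norm(o))
    half = 0.5 * norm * Ts
    eye = np.eye(4)
    if norm < 1e-300:
        return eye
    return np.cos(half) * eye + (np.sin(half) / norm) * omega_matrix(o)


def propagate(q: np.ndarray, omega: np.ndarray, Ts: float) -> np.ndarray:
    """Propagate ``q`` through one sampling interval at constant rate ``omega``."""
    return propagation_matrix(omega, Ts) @ q


def to_C_nb(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from {b} to {n}: ``I + 2 q4 [q x] + 2 [q x]^2``."""
    qv = np.asarray(q[:3], dtype=float)
    q4 = float(q[3])
    s = skew(qv)
    return np.eye(3) + 2.0 * q4 * s + 2.0 * (s @ s)


def to_C_bn(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from {n} to {b}: ``I - 2 q4 [q x] + 2 [q x]^2`` (= C_nb^T)."""
    qv = np.asarray(q[:3], dtype=float)
    q4 = float(q[3])
    s = skew(qv)
    return np.eye(3) - 2.0 * q4 * s + 2.0 * (s @ s)


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Quaternion for a rotation of ``angle`` radians about the unit ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle
    return np.concatenate([np.sin(half) * axis, [np.cos(half)]])


def between_vectors(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Shortest-arc quaternion whose ``C_nb`` rotates direction ``u`` onto ``v``.

    The rotation has no component about the target direction, which is the
    zero-yaw convention used for accelerometer leveling.  The scalar part of
    the result is non-negative.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-14:
        return identity()
    if c < -1.0 + 1e-12:
        # Antiparallel: rotate pi about any axis orthogonal to u.
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        return from_axis_angle(axis, np.pi)
    # C_nb(from_axis_angle(a, t)) rotates by +t about a (right-hand rule),
    # so the axis u x v carries u onto v.
    axis = np.cross(u, v)
    axis = axis / np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    return from_axis_angle(axis, angle)


def normalize(q: np.ndarray) -> np.ndarray:
    """Brute-force renormalization to unit norm."""
    return q / np.linalg.norm(q)
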