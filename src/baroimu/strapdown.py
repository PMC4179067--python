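"""Strap-down rotation and gravity cancellation.

The measured specific force is rotated from the body frame into NED with the
estimated attitude and gravity is added back, yielding the linear
acceleration ``a^n = C_nb f^b + g^n``.  Only the vertical component is used
downstream; the up-positive sign conversion (``a_up = -a^n_z``) happens here
and nowhere else.  Lever-arm (tangential/centripetal) terms are a property of
the simulated trajectories only: the estimator never subtracts them — the
vector-selection gate in the EKF absorbs their effect on leveling.
"""

from __future__ import annotations

import numpy as np

from . import quaternion as quat

__all__ = ["linear_acceleration", "a_up", "vertical_acceleration"]


def linear_acceleration(f_b: np.ndarray, q: np.ndarray, g: float = 9.81) -> np.ndarray:
    """Linear acceleration in NED: ``C_nb f^b + g^n`` with ``g^n = (0,0,g)``."""
    return quat.to_C_nb(q) @ np.asarray(f_b, dtype=float) + np.array([0.0, 0.0, g])


def a_up(f_b: np.ndarray, q: np.ndarray, g: float = 9.81) -> float:
    """Up-positive vertical linear acceleration, m/s^2."""
    return -float(linear_acceleration(f_b, q, g)[2])


def vertical_acceleration(f_b: np.ndarray, qs: np.ndarray, g: float = 9.81) -> np.ndarray:
    """Vectorized up-positive vertical linear acceleration for a whole log.

    Parameters
    ----------
    f_b : (n, 3) specific force series in {b}.
    qs : (n, 4) unit quaternion series (vector-first).
    """
    f_b = np.asarray(f_b, dtype=float)
    qs = np.asarray(qs, dtype=float)
    qv = qs[:, :3]
    q4 = qs[:, 3:4]
    # C_nb f = f + 2 q4 (qv x f) + 2 qv x (qv x f), row-wise.
    qxf = np.cross(qv, f_b)
    rotated = f_b + 2.0 * q4 * qxf + 2.0 * np.cross(qv, qxf)
    # a^n_z = (C_nb f)_z + g (down-positive); negate for up-positive output.
    return -(rotated[:, 2] + g)
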