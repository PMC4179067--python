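"""Scenario simulator: ground-truth trajectories and synthetic baro-IMU logs.

Four validation scenarios mirror bench experiments with a 50 Hz wearable
baro-IMU:

* **no-motion** — device at rest for three minutes; exercises the baro noise
  floor and drift-freedom of the vertical channel;
* **free-fall** — drop from a known height onto a mattress, with ballistic
  phases (zero specific force), a restitution bounce and a long final rest;
* **circular** — forced uniform circular motion of the sensor on a lever arm
  in a vertical plane (sinusoidal height, strong centripetal specific force);
* **squat** — a smooth minimum-jerk down-and-up vertical excursion with a
  small trunk-pitch oscillation.

Truth trajectories are kinematically self-consistent: the stored specific
force equals ``C_bn (b_dd^n - g^n) + [omega_dot x] s^b + [omega x][omega x] s^b``
at every sample, including the impulse-matched half-sine contact acceleration
of the free-fall impacts.  The *sensor* model then adds Gaussian gyro/accel
noise, a constant accelerometer bias, clipping at the accelerometer range
(the mechanism behind the under-measured impact humps seen in practice),
colored barometric noise (white noise through the inverse of the whitening
filter) and 1 Pa pressure quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import quaternion as quat
from .baro_conditioning import (WhiteningFilterSpec, altitude_to_pressure,
                                design_whitening_filter)
from .sensor_model import DEG, MG, ImuLog

G = 9.81

__all__ = [
    "SensorErrorModel",
    "ScenarioTruth",
    "colored_baro_noise",
    "make_log",
    "simulate_no_motion",
    "simulate_free_fall",
    "simulate_circular",
    "simulate_squat",
    "simulate",
]


@dataclass
class SensorErrorModel:
    """Sensor error parameters.

    Defaults are the study noise conditions: gyro noise 1 deg/s, accelerometer
    noise 10 mg, colored barometric noise with 0.30 m sample SD, 1 Pa pressure
    quantization and a +/-8 g accelerometer range.
    """

    gyro_noise_sd: float = 1.0 * DEG
    accel_noise_sd: float = 10.0 * MG
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    baro_colored_sd: float = 0.30
    baro_quantum: float = 1.0
    accel_range: float = 8.0 * G
    seed: int = 0

    @classmethod
    def noiseless(cls, seed: int = 0) -> "SensorErrorModel":
        """All noise off; quantization made negligible (1e-9 Pa)."""
        return cls(gyro_noise_sd=0.0, accel_noise_sd=0.0,
                   baro_colored_sd=0.0, baro_quantum=1e-9, seed=seed)

    @classmethod
    def low_noise(cls, seed: int = 0, scale: float = 0.1) -> "SensorErrorModel":
        """Noise scaled down by ``scale`` (used for settling-time measurement)."""
        base = cls(seed=seed)
        return cls(gyro_noise_sd=base.gyro_noise_sd * scale,
                   accel_noise_sd=base.accel_noise_sd * scale,
                   baro_colored_sd=base.baro_colored_sd * scale,
                   baro_quantum=base.baro_quantum, seed=seed)


@dataclass
class ScenarioTruth:
    """Ground truth on the sampling grid.

    ``height``/``velocity`` are up-positive (m, m/s) for the *sensor* origin;
    ``attitude`` is the body-to-navigation quaternion series; ``a_up`` the
    true up-positive linear acceleration; ``specific_force``/``angular_rate``
    the noise-free sensor-frame signals.  ``lever_b`` and ``omega_dot`` allow
    independent reconstruction of the specific force from the kinematics.
    ``theta`` holds the encoder-style rotation angle of the circular scenario.
    """

    t: np.ndarray
    height: np.ndarray
    velocity: np.ndarray
    a_up: np.ndarray
    attitude: np.ndarray
    specific_force: np.ndarray
    angular_rate: np.ndarray
    lever_b: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega_dot: np.ndarray | None = None
    theta: np.ndarray | None = None
    scenario: str = ""
    impact_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)


def colored_baro_noise(n: int, spec: WhiteningFilterSpec, target_sd: float,
                       rng) -> np.ndarray:
    """Serially correlated altitude noise, m.

    White Gaussian noise is passed through the inverse of the whitening filter
    (pole and zero swapped, gain inverted) and rescaled so its sample SD equals
    ``target_sd``.  Passing the result back through the forward whitening
    filter therefore recovers (scaled) white noise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if target_sd == 0.0 or n == 0:
        return np.zeros(n)
    if not spec.designed:
        spec = design_whitening_filter(spec)
    b, a = spec.inverse_ba()
    white = rng.standard_normal(n)
    colored = signal.lfilter(b, a, white)
    sd = colored.std()
    return colored * (target_sd / sd) if sd > 0 else colored


def make_log(truth: ScenarioTruth, errors: SensorErrorModel,
             whitening: WhiteningFilterSpec | None = None,
             baseline_height: float = 0.0) -> ImuLog:
    """Corrupt a truth trajectory with the sensor error model, yielding a log."""
    rng = np.random.default_rng(errors.seed)
    n = len(truth)
    gyro = truth.angular_rate + errors.gyro_noise_sd * rng.standard_normal((n, 3))
    accel = (truth.specific_force + np.asarray(errors.accel_bias)
             + errors.accel_noise_sd * rng.standard_normal((n, 3)))
    accel = np.clip(accel, -errors.accel_range, errors.accel_range)
    spec = design_whitening_filter(whitening)
    noise = colored_baro_noise(n, spec, errors.baro_colored_sd, rng)
    altitude = baseline_height + truth.height + noise
    pressure = altitude_to_pressure(altitude)
    q = errors.baro_quantum
    pressure = np.round(pressure / q) * q
    return ImuLog(truth.t.copy(), gyro, accel, pressure)


def _constant_attitude_truth(t, height, velocity, a_up, q0, scenario,
                             impact_mask=None) -> ScenarioTruth:
    """Truth for purely vertical motion at constant attitude ``q0``."""
    n = len(t)
    attitude = np.tile(q0, (n, 1))
    C_bn = quat.to_C_bn(q0)
    # f^b = C_bn (b_dd^n - g^n) with b_dd^n = (0, 0, -a_up), g^n = (0, 0, +g).
    down = -(np.asarray(a_up) + G)
    specific = down[:, None] * C_bn[:, 2][None, :]
    return ScenarioTruth(t=t, height=np.asarray(height), velocity=np.asarray(velocity),
                         a_up=np.asarray(a_up), attitude=attitude,
                         specific_force=specific, angular_rate=np.zeros((n, 3)),
                         scenario=scenario, impact_mask=impact_mask)


def simulate_no_motion(duration: float = 180.0,
                       errors: SensorErrorModel | None = None,
                       Ts: float = 0.02) -> tuple[ScenarioTruth, ImuLog]:
    """Device at rest, level, for ``duration`` seconds (default 3 min)."""
    errors = errors or SensorErrorModel()
    n = int(round(duration / Ts))
    t = np.arange(n) * Ts
    zeros = np.zeros(n)
    truth = _constant_attitude_truth(t, zeros, zeros, zeros, quat.identity(),
                                     "no-motion")
    return truth, make_log(truth, errors)


def _half_sine_segment(tau, v0, h0, peak, Th):
    """Closed-form kinematics inside a half-sine contact-acceleration pulse.

    Total vertical acceleration ``a(tau) = peak sin(pi tau / Th) - g``.
    """
    w = np.pi / Th
    v = v0 + peak / w * (1.0 - np.cos(w * tau)) - G * tau
    h = h0 + v0 * tau + peak / w * (tau - np.sin(w * tau) / w) - 0.5 * G * tau ** 2
    a = peak * np.sin(w * tau) - G
    return h, v, a


def simulate_free_fall(H: float = 1.53, errors: SensorErrorModel | None = None,
                       Ts: float = 0.02, rest_before: float = 2.0,
                       rest_after: float = 25.0, restitution: float = 0.3,
                       impact_duration: float = 0.04,
                       tilt_axis=(1.0, 1.0, 0.0), tilt_deg: float = 30.0,
                       tumble_rate: float = 0.0) -> tuple[ScenarioTruth, ImuLog]:
    """Drop from height ``H`` onto a mattress.

    Phases: rest I, ballistic fall (``T_fall = sqrt(2H/g)``, specific force
    zero), first impact (impulse-matched half-sine contact acceleration over
    ``impact_duration``), rebound ballistic flight at restitution
    ``restitution``, second impact (restitution zero) and rest III.  The case
    orientation is an arbitrary constant tilt (all gravity components well
    above the vector-selection threshold, so every accelerometer row is
    rejected during the ballistic phases); ``tumble_rate`` (rad/s, about body
    x) optionally spins the case during flight to exercise gyro-only coasting.
    """
    errors = errors or SensorErrorModel()
    e = restitution
    Th = impact_duration
    T_fall = np.sqrt(2.0 * H / G)
    v1 = -G * T_fall                       # velocity at first contact (down)
    A1 = np.pi * (abs(v1) * (1.0 + e) + G * Th) / (2.0 * Th)
    v2 = e * abs(v1)                       # rebound velocity (up)
    h2 = -H + v1 * Th + A1 * Th ** 2 / np.pi - 0.5 * G * Th ** 2
    T_flight = 2.0 * v2 / G
    A2 = np.pi * (v2 + G * Th) / (2.0 * Th)
    h4 = h2 + (-v2) * Th + A2 * Th ** 2 / np.pi - 0.5 * G * Th ** 2

    t0 = rest_before
    t1 = t0 + T_fall
    t2 = t1 + Th
    t3 = t2 + T_flight
    t4 = t3 + Th
    total = t4 + rest_after
    n = int(round(total / Ts))
    t = np.arange(n) * Ts

    h = np.zeros(n)
    v = np.zeros(n)
    a = np.zeros(n)

    fall = (t >= t0) & (t < t1)
    tau = t[fall] - t0
    h[fall] = -0.5 * G * tau ** 2
    v[fall] = -G * tau
    a[fall] = -G

    imp1 = (t >= t1) & (t < t2)
    h[imp1], v[imp1], a[imp1] = _half_sine_segment(t[imp1] - t1, v1, -H, A1, Th)

    flight = (t >= t2) & (t < t3)
    tau = t[flight] - t2
    h[flight] = h2 + v2 * tau - 0.5 * G * tau ** 2
    v[flight] = v2 - G * tau
    a[flight] = -G

    imp2 = (t >= t3) & (t < t4)
    h[imp2], v[imp2], a[imp2] = _half_sine_segment(t[imp2] - t3, -v2, h2, A2, Th)

    rest3 = t >= t4
    h[rest3] = h4

    q0 = quat.from_axis_angle(np.asarray(tilt_axis, dtype=float),
                              np.deg2rad(tilt_deg))
    truth = _constant_attitude_truth(t, h, v, a, q0, "free-fall",
                                     impact_mask=imp1 | imp2)
    if tumble_rate != 0.0:
        # Spin about body x from release until the end of the second impact.
        spinning = (t >= t0) & (t < t4)
        truth.angular_rate[spinning, 0] = tumble_rate
        qk = q0.copy()
        down = -(a + G)
        for k in np.flatnonzero(spinning):
            qk = quat.propagate(qk, truth.angular_rate[k], Ts)
            truth.attitude[k] = qk
            truth.specific_force[k] = quat.to_C_bn(qk) @ np.array([0.0, 0.0, down[k]])
        last = int(np.flatnonzero(spinning)[-1])
        truth.attitude[last + 1:] = qk
        truth.specific_force[last + 1:] = (quat.to_C_bn(qk)
                                           @ np.array([0.0, 0.0, -G]))
    return truth, make_log(truth, errors)


def simulate_circular(f0: float = 0.5, L: float = 0.30, duration: float = 180.0,
                      errors: SensorErrorModel | None = None, Ts: float = 0.02,
                      rest_before: float = 2.0,
                      ramp: float = 2.0) -> tuple[ScenarioTruth, ImuLog]:
    """Forced circular motion of the sensor on a lever arm ``L`` in a vertical
    plane at frequency ``f0`` (Hz).

    The body rotates about its x axis (horizontal, along north); the sensor
    origin is displaced by ``s^b = (0, L, 0)``, so the sensed specific force
    carries the centripetal term ``-w0^2 L`` on y plus the rotating gravity
    tilt, and the sensor height is ``L sin(theta)``.  The motor spins up
    linearly over ``ramp`` seconds (an instantaneous velocity step would be
    unphysical); ``duration`` seconds of steady rotation follow.
    """
    errors = errors or SensorErrorModel()
    w0 = 2.0 * np.pi * f0
    total = rest_before + ramp + duration
    n = int(round(total / Ts))
    t = np.arange(n) * Ts

    tm = t - rest_before
    if ramp > 0.0:
        w = np.where(tm < 0, 0.0, np.where(tm < ramp, w0 * tm / ramp, w0))
        wdot = np.where((tm >= 0) & (tm < ramp), w0 / ramp, 0.0)
        theta = np.where(
            tm < 0, 0.0,
            np.where(tm < ramp, 0.5 * w0 * tm ** 2 / ramp,
                     0.5 * w0 * ramp + w0 * (tm - ramp)))
    else:
        w = np.where(tm < 0, 0.0, w0)
        wdot = np.zeros(n)
        theta = np.where(tm < 0, 0.0, w0 * tm)

    # The body spins about its x axis at -w (the encoder angle theta is the
    # magnitude of the rotation); this sign puts the sensor height at
    # +L sin(theta) with the conventions of this package.
    half = 0.5 * theta
    attitude = np.column_stack([-np.sin(half), np.zeros(n), np.zeros(n),
                                np.cos(half)])
    angular_rate = np.column_stack([-w, np.zeros(n), np.zeros(n)])
    omega_dot = np.column_stack([-wdot, np.zeros(n), np.zeros(n)])

    height = L * np.sin(theta)
    velocity = L * w * np.cos(theta)
    a_up = L * (wdot * np.cos(theta) - w ** 2 * np.sin(theta))

    # f^b = C_bn(-g^n) + [wdot x] s^b + [w x][w x] s^b  (center is fixed).
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    specific = np.column_stack([
        np.zeros(n),
        G * sin_t - w ** 2 * L,
        -wdot * L - G * cos_t,
    ])
    truth = ScenarioTruth(t=t, height=height, velocity=velocity, a_up=a_up,
                          attitude=attitude, specific_force=specific,
                          angular_rate=angular_rate,
                          lever_b=np.array([0.0, L, 0.0]), omega_dot=omega_dot,
                          theta=theta, scenario="circular")
    return truth, make_log(truth, errors)


def _min_jerk(x):
    """Minimum-jerk position profile s(x) on [0, 1] with s(0)=0, s(1)=1."""
    return 10.0 * x ** 3 - 15.0 * x ** 4 + 6.0 * x ** 5


def _min_jerk_d1(x):
    return 30.0 * x ** 2 - 60.0 * x ** 3 + 30.0 * x ** 4


def _min_jerk_d2(x):
    return 60.0 * x - 180.0 * x ** 2 + 120.0 * x ** 3


def simulate_squat(depth: float = 0.60, cycle_s: float = 4.0,
                   errors: SensorErrorModel | None = None, Ts: float = 0.02,
                   rest_pad: float = 2.0,
                   pitch_deg: float = 5.0) -> tuple[ScenarioTruth, ImuLog]:
    """Squat of given ``depth``: minimum-jerk descent and ascent over
    ``cycle_s`` seconds with rest padding on both sides, plus a small smooth
    trunk-pitch oscillation (``pitch_deg`` peak, about body y)."""
    errors = errors or SensorErrorModel()
    T_half = cycle_s / 2.0
    total = 2.0 * rest_pad + cycle_s
    n = int(round(total / Ts))
    t = np.arange(n) * Ts

    h = np.zeros(n)
    v = np.zeros(n)
    a = np.zeros(n)
    tm = t - rest_pad

    down = (tm >= 0) & (tm < T_half)
    x = tm[down] / T_half
    h[down] = -depth * _min_jerk(x)
    v[down] = -depth * _min_jerk_d1(x) / T_half
    a[down] = -depth * _min_jerk_d2(x) / T_half ** 2

    up = (tm >= T_half) & (tm < cycle_s)
    x = (tm[up] - T_half) / T_half
    h[up] = -depth * (1.0 - _min_jerk(x))
    v[up] = depth * _min_jerk_d1(x) / T_half
    a[up] = depth * _min_jerk_d2(x) / T_half ** 2

    # Trunk pitch: zero value and rate at the movement boundaries.
    phi = np.zeros(n)
    phid = np.zeros(n)
    moving = (tm >= 0) & (tm < cycle_s)
    u = tm[moving] / cycle_s
    amp = np.deg2rad(pitch_deg)
    phi[moving] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    phid[moving] = amp * np.pi * np.sin(2.0 * np.pi * u) / cycle_s

    half = 0.5 * phi
    attitude = np.column_stack([np.zeros(n), np.sin(half), np.zeros(n),
                                np.cos(half)])
    angular_rate = np.column_stack([np.zeros(n), phid, np.zeros(n)])

    # f^b = C_bn(q) (0, 0, -(a_up + g)) row-wise; C_bn for a pitch phi about y
    # maps (0, 0, d) to (-d sin(phi), 0, d cos(phi)).
    down_f = -(a + G)
    sin_p, cos_p = np.sin(phi), np.cos(phi)
    specific = np.column_stack([-sin_p * down_f, np.zeros(n), cos_p * down_f])
    truth = ScenarioTruth(t=t, height=h, velocity=v, a_up=a, attitude=attitude,
                          specific_force=specific, angular_rate=angular_rate,
                          scenario="squat")
    return truth, make_log(truth, errors)


SCENARIOS = ("no-motion", "free-fall", "circular", "squat")


def simulate(scenario: str, errors: SensorErrorModel | None = None,
             **params) -> tuple[ScenarioTruth, ImuLog]:
    """Dispatch by scenario name (``no-motion``, ``free-fall``, ``circular``,
    ``squat``)."""
    fns = {
        "no-motion": simulate_no_motion,
        "free-fall": simulate_free_fall,
        "circular": simulate_circular,
        "squat": simulate_squat,
    }
    if scenario not in fns:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return fns[scenario](errors=errors, **params)
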