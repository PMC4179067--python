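"""Data model, units, file I/O, configuration and rest-period bias capture.

The package works on 50 Hz baro-IMU logs: tri-axial angular rate (rad/s),
tri-axial specific force (m/s^2) and absolute barometric pressure (Pa).  The
navigation frame is North-East-Down (NED) with gravity ``g^n = (0, 0, +g)``;
reported heights and vertical velocities are up-positive.

Unit conventions: accelerations quoted in milli-g use 1 mg = 9.81e-3 m/s^2;
angular rates quoted in deg/s are converted to rad/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from . import quaternion as quat
from .baro_conditioning import pressure_to_altitude

MG = 9.81e-3
"""One milli-g in m/s^2."""

DEG = np.pi / 180.0
"""One degree in radians."""

LOG_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "p"]


@dataclass(frozen=True)
class ImuSample:
    """One 50 Hz baro-IMU record.

    Attributes
    ----------
    t : float
        Timestamp, s; strictly increasing across a log.
    gyro : ndarray, shape (3,)
        Angular rate of {b} relative to {n}, resolved in {b}, rad/s.
    accel : ndarray, shape (3,)
        Specific force measured by the accelerometer, m/s^2.
    pressure : float
        Absolute barometric pressure, Pa (> 0).
    """

    t: float
    gyro: np.ndarray
    accel: np.ndarray
    pressure: float


class ImuLog(Sequence):
    """Column-oriented sequence of :class:`ImuSample`.

    Stores the log as contiguous arrays (fast filtering) while behaving as a
    sequence of samples for inspection and round-trip tests.
    """

    def __init__(self, t: np.ndarray, gyro: np.ndarray, accel: np.ndarray,
                 pressure: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.gyro = np.asarray(gyro, dtype=float)
        self.accel = np.asarray(accel, dtype=float)
        self.pressure = np.asarray(pressure, dtype=float)
        n = len(self.t)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3) \
                or self.pressure.shape != (n,):
            raise ValueError("inconsistent log array shapes")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ImuLog(self.t[i], self.gyro[i], self.accel[i], self.pressure[i])
        return ImuSample(float(self.t[i]), self.gyro[i].copy(),
                         self.accel[i].copy(), float(self.pressure[i]))

    def __iter__(self) -> Iterator[ImuSample]:
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "gx": self.gyro[:, 0], "gy": self.gyro[:, 1], "gz": self.gyro[:, 2],
            "ax": self.accel[:, 0], "ay": self.accel[:, 1], "az": self.accel[:, 2],
            "p": self.pressure,
        })


@dataclass
class FusionConfig:
    """Tuning parameters of the fusion pipeline (SI units).

    Defaults follow the published tuning for a 50 Hz wearable baro-IMU:
    gyro noise 1 deg/s, accelerometer measurement noise 10 mg, accelerometer
    bias driving noise 5e-4 m/s^3 with correlation rate alpha = 0 (random
    walk), vector-selection threshold 150 mg, linear-acceleration noise 15 mg
    and pressure-altitude noise 0.30 m (Method A) / 0.15 m (Method B).
    """

    Ts: float = 0.02
    g: float = 9.81
    sigma_g: float = 1.0 * DEG
    sigma_a_meas: float = 10.0 * MG
    sigma_ab: float = 5e-4
    alpha: float = 0.0
    lambda_g: float = 150.0 * MG
    sigma_w: float = 15.0 * MG
    sigma_v: float = 0.30
    method: str = "A"
    rest_window: float = 1.0

    @classmethod
    def for_method(cls, method: str, **overrides) -> "FusionConfig":
        """Config for conditioning Method ``"A"`` (sigma_v = 0.30 m) or
        ``"B"`` (moving average + whitening filter, sigma_v = 0.15 m)."""
        method = method.upper()
        if method not in ("A", "B"):
            raise ValueError(f"unknown conditioning method {method!r}")
        sigma_v = overrides.pop("sigma_v", 0.30 if method == "A" else 0.15)
        return cls(method=method, sigma_v=sigma_v, **overrides)

    def validate(self) -> "FusionConfig":
        if self.Ts <= 0:
            raise ValueError("Ts must be > 0")
        for name in ("sigma_g", "sigma_a_meas", "sigma_ab", "sigma_w", "sigma_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.method not in ("A", "B"):
            raise ValueError(f"method must be 'A' or 'B', got {self.method!r}")
        return self

    def replace(self, **changes) -> "FusionConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class RestStatistics:
    """Sensor statistics captured during the initial rest period.

    ``initial_quaternion`` is the zero-yaw leveling quaternion whose rotation
    maps the mean measured specific force onto the vertical; ``baro_baseline``
    is the mean absolute pressure altitude (m) subtracted from all subsequent
    altitude samples.
    """

    gyro_bias: np.ndarray
    baro_baseline: float
    initial_quaternion: np.ndarray
    mean_accel: np.ndarray
    n_samples: int = 0


class FormatError(ValueError):
    """Malformed input file (missing column, bad value, non-monotone time)."""


class InsufficientRestError(ValueError):
    """Fewer rest samples than the configured bias-capture window."""


def read_log(path) -> ImuLog:
    """Read a sensor-log CSV with header columns t,gx,gy,gz,ax,ay,az,p.

    Units: s, rad/s, m/s^2, Pa.  Raises :class:`FormatError` on a missing
    column, a non-finite value (reported with its row index) or non-monotone
    timestamps.
    """
    df = pd.read_csv(path)
    for col in LOG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    values = df[LOG_COLUMNS].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        raise FormatError(f"non-finite value at row {row} of {path}")
    t = values[:, 0]
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"timestamps not strictly increasing in {path}")
    if np.any(values[:, 7] <= 0):
        raise FormatError(f"non-positive pressure in {path}")
    return ImuLog(t, values[:, 1:4], values[:, 4:7], values[:, 7])


def write_log(path, log: ImuLog) -> None:
    """Write a log as CSV, column schema identical to :func:`read_log`."""
    log.to_frame().to_csv(path, index=False, float_format="%.10g")


def save_config(path, cfg: FusionConfig) -> None:
    """Persist a config as a flat key/value text file (field names as keys)."""
    data = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> FusionConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} is not a flat key/value mapping")
    unknown = set(data) - {f.name for f in dataclasses.fields(FusionConfig)}
    if unknown:
        raise FormatError(f"unknown config keys {sorted(unknown)} in {path}")
    return FusionConfig(**data).validate()


def capture_rest(samples: ImuLog, cfg: FusionConfig) -> RestStatistics:
    """Estimate gyro bias, baro baseline and initial attitude from rest data.

    Uses the first ``rest_window / Ts`` samples: gyro bias is the component-wise
    mean of the angular rate, the baro baseline the mean absolute pressure
    altitude, and the initial quaternion levels the window-mean specific force
    onto the vertical (yaw fixed to zero; heading is unobservable without a
    magnetometer).
    """
    n_req = int(round(cfg.rest_window / cfg.Ts))
    if len(samples) < n_req:
        raise InsufficientRestError(
            f"need {n_req} rest samples ({cfg.rest_window} s at Ts={cfg.Ts}), "
            f"got {len(samples)}")
    window = samples[:n_req] if isinstance(samples, ImuLog) else samples
    if isinstance(window, ImuLog):
        gyro = window.gyro
        accel = window.accel
        pressure = window.pressure
    else:  # generic sequence of ImuSample
        gyro = np.array([s.gyro for s in window][:n_req])
        accel = np.array([s.accel for s in window][:n_req])
        pressure = np.array([s.pressure for s in window][:n_req])
    gyro_bias = gyro.mean(axis=0)
    mean_accel = accel.mean(axis=0)
    baseline = float(np.mean(pressure_to_altitude(pressure)))
    # At rest f^b = C_bn (-g^n): the measured mean points "up" in body axes.
    # Level it onto the NED up direction (0, 0, -1) with a zero-yaw rotation.
    q0 = quat.between_vectors(mean_accel, np.array([0.0, 0.0, -1.0]))
    return RestStatistics(gyro_bias=gyro_bias, baro_baseline=baseline,
                          initial_quaternion=q0, mean_accel=mean_accel,
                          n_samples=n_req)
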