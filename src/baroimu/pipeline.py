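"""End-to-end tracker: rest capture -> EKF -> strap-down -> conditioning ->
complementary filter, streaming and causal (output at time t depends only on
inputs up to t).

The attitude pass (EKF + strap-down) is independent of the conditioning
method, so it can be run once per log and combined with several vertical
passes (Method A / Method B) cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import attitude_ekf, complementary_filter, strapdown
from .baro_conditioning import ConditioningChain
from .sensor_model import FusionConfig, ImuLog, RestStatistics, capture_rest

__all__ = ["AttitudeResult", "attitude_pass", "vertical_pass", "track"]


@dataclass
class AttitudeResult:
    """Output of the attitude stage for a whole log."""

    rest: RestStatistics
    quaternions: np.ndarray
    biases: np.ndarray
    innovations: np.ndarray
    accepted: np.ndarray
    updated: np.ndarray
    a_up: np.ndarray


def attitude_pass(log: ImuLog, cfg: FusionConfig,
                  rest: RestStatistics | None = None) -> AttitudeResult:
    """Run bias capture, the attitude EKF and strap-down gravity cancellation."""
    if rest is None:
        rest = capture_rest(log, cfg)
    qs, bs, innov, accepted, updated = attitude_ekf.run_attitude_filter(
        log.gyro, log.accel, rest, cfg)
    a_up = strapdown.vertical_acceleration(log.accel, qs, cfg.g)
    return AttitudeResult(rest, qs, bs, innov, accepted, updated, a_up)


def vertical_pass(pressure: np.ndarray, a_up: np.ndarray,
                  rest: RestStatistics, cfg: FusionConfig):
    """Condition the pressure stream and run the complementary filter.

    Returns ``(height, velocity, x_p)`` arrays.
    """
    chain = ConditioningChain(rest, cfg)
    x_p = chain.process(np.asarray(pressure, dtype=float))
    g = complementary_filter.gain(cfg.sigma_w, cfg.sigma_v)
    height, velocity = complementary_filter.run(x_p, a_up, g, cfg.Ts)
    return height, velocity, x_p


def track(log: ImuLog, cfg: FusionConfig,
          rest: RestStatistics | None = None,
          attitude: AttitudeResult | None = None) -> pd.DataFrame:
    """Full pipeline over a log; one row per sample.

    Columns: t, height_m, velocity_mps, a_up, x_p, innovation and
    vector-selection diagnostics, and the conditioning method tag.
    """
    cfg.validate()
    if attitude is None:
        attitude = attitude_pass(log, cfg, rest)
    height, velocity, x_p = vertical_pass(log.pressure, attitude.a_up,
                                          attitude.rest, cfg)
    out = pd.DataFrame({
        "t": log.t,
        "height_m": height,
        "velocity_mps": velocity,
        "a_up": attitude.a_up,
        "x_p": x_p,
        "innov_x": attitude.innovations[:, 0],
        "innov_y": attitude.innovations[:, 1],
        "innov_z": attitude.innovations[:, 2],
        "accepted_x": attitude.accepted[:, 0],
        "accepted_y": attitude.accepted[:, 1],
        "accepted_z": attitude.accepted[:, 2],
        "updated": attitude.updated,
    })
    out["method"] = cfg.method
    return out
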