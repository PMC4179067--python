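"""Two-state complementary filter for height and vertical velocity.

The filter blends the conditioned pressure altitude ``x_p`` (reliable at low
frequency) with the strap-down vertical linear acceleration ``a_up``
(reliable at high frequency).  In continuous time it is

    dx/dt = v + k1 (x_p - x),      dv/dt = a_up + k2 (x_p - x),

the steady-state two-state Kalman filter for a double-integrator driven by
white acceleration noise (SD ``sigma_w``) observed through white altitude
noise (SD ``sigma_v``).  The optimal gains give a critically damped loop with
a double pole at ``-1/tau``:

    k2 = sigma_w / sigma_v,   k1 = 2 sqrt(k2),   tau = sqrt(sigma_v / sigma_w).

The discrete recursion advances the state with the constant-acceleration
transition and applies the gain on the previous step's altitude residual
``Dx = x_p - x`` and acceleration increment ``Dv = Ts a_up`` (strict one-step
indexing, no iterated correction).  The transfer function from ``x_p`` to the
height estimate has unit DC gain, so any DC distortion of the conditioning
chain (Method B's 0.21 gain) appears one-for-one in the height estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VerticalState", "ComplementaryGain", "gain", "step", "run"]


@dataclass
class VerticalState:
    """Height (m, up-positive, relative to start) and vertical velocity (m/s).

    Initialized to (0, 0): the device starts at rest at its reference height.
    """

    x: float = 0.0
    v: float = 0.0


@dataclass(frozen=True)
class ComplementaryGain:
    """Complementary-filter gains: k1 (1/s), k2 (1/s^2), time constant tau (s)."""

    k1: float
    k2: float
    tau: float


def gain(sigma_w: float, sigma_v: float) -> ComplementaryGain:
    """Critically damped gains from the two noise standard deviations."""
    if sigma_w <= 0 or sigma_v <= 0:
        raise ValueError("noise standard deviations must be > 0")
    k2 = sigma_w / sigma_v
    return ComplementaryGain(k1=2.0 * np.sqrt(k2), k2=k2, tau=1.0 / np.sqrt(k2))


def step(state: VerticalState, x_p: float, a_up: float,
         g: ComplementaryGain, Ts: float) -> VerticalState:
    """One filter step using the inputs at the previous sample time.

    ``new = A state + B K Ts Dx + c Dv`` with ``A = [[1, Ts], [0, 1]]``,
    ``B = [[1, Ts/2], [0, 1]]``, ``K = (k1, k2)``, ``c = (Ts/2, 1)``,
    ``Dx = x_p - x`` and ``Dv = Ts a_up``.
    """
    dx = x_p - state.x
    dv = Ts * a_up
    u1 = g.k1 * Ts * dx
    u2 = g.k2 * Ts * dx
    return VerticalState(
        x=state.x + Ts * state.v + u1 + 0.5 * Ts * u2 + 0.5 * Ts * dv,
        v=state.v + u2 + dv,
    )


def run(x_p: np.ndarray, a_up: np.ndarray, g: ComplementaryGain, Ts: float,
        state: VerticalState | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Stream the filter over whole series; returns (height, velocity) arrays.

    Output sample ``k`` is the state *before* consuming input ``k`` (causal:
    the estimate at ``t_k`` depends on inputs strictly before ``t_k``).
    """
    x_p = np.asarray(x_p, dtype=float)
    a_up = np.asarray(a_up, dtype=float)
    n = len(x_p)
    if len(a_up) != n:
        raise ValueError("input series must have equal length")
    heights = np.empty(n)
    velocities = np.empty(n)
    x = state.x if state is not None else 0.0
    v = state.v if state is not None else 0.0
    k1Ts = g.k1 * Ts
    k2Ts = g.k2 * Ts
    halfTs = 0.5 * Ts
    for k in range(n):
        heights[k] = x
        velocities[k] = v
        dx = x_p[k] - x
        dv = Ts * a_up[k]
        u2 = k2Ts * dx
        x = x + Ts * v + k1Ts * dx + halfTs * u2 + halfTs * dv
        v = v + u2 + dv
    return heights, velocities
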