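"""Pressure-altitude conversion and conditioning (moving average / whitening).

Raw barometric pressure is converted to altitude with the international
barometric formula, detrended by the rest-period baseline, and smoothed by
either

* **Method A** — a causal 4-point moving average, or
* **Method B** — the same moving average cascaded with a first-order
  whitening filter that removes the serial correlation of the
  environment-dependent pressure fluctuations.

The whitening filter ``H(z) = g0 (z - b) / (z - a)`` is fully determined by
four printed constraints: sampling rate 50 Hz, one pole at about 1 Hz
(``a = exp(-2 pi f_pole Ts)``), DC gain 0.21 and unity gain at 25 Hz (the
Nyquist frequency of the stream).  The implied zero lands at about 0.21 Hz,
roughly two octaves below the pole.  Because of the 0.21 DC gain, Method B
attenuates genuinely low-frequency height changes by a factor ~5 — the price
paid for whitened noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .sensor_model import FusionConfig, RestStatistics

P0 = 101325.0
"""Standard sea-level pressure, Pa."""

BARO_SCALE = 44300.0
BARO_EXP = 0.19


def pressure_to_altitude(p):
    """Barometric formula ``h = 44300 (1 - (p/p0)^0.19)``, h in m, p in Pa.

    Monotone decreasing in p; raises on non-positive pressure.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be > 0")
    h = BARO_SCALE * (1.0 - (p / P0) ** BARO_EXP)
    return float(h) if h.ndim == 0 else h


def altitude_to_pressure(h):
    """Inverse of :func:`pressure_to_altitude` (used by the simulator)."""
    h = np.asarray(h, dtype=float)
    p = P0 * (1.0 - h / BARO_SCALE) ** (1.0 / BARO_EXP)
    return float(p) if p.ndim == 0 else p


@dataclass
class WhiteningFilterSpec:
    """First-order whitening filter specification and coefficients.

    ``H(z) = g0 (z - b)/(z - a)`` with pole ``a`` fixed by ``pole_hz`` and
    ``(b, g0)`` solved from the DC-gain and Nyquist-unity-gain constraints.
    Coefficients are ``None`` until :func:`design_whitening_filter` runs.
    """

    fs: float = 50.0
    pole_hz: float = 1.0
    dc_gain: float = 0.21
    unity_hz: float = 25.0
    a: float | None = None
    b: float | None = None
    g0: float | None = None

    @property
    def designed(self) -> bool:
        return self.a is not None

    @property
    def zero_hz(self) -> float:
        """Frequency implied by the zero location, ``-ln(b) fs / (2 pi)``."""
        if not self.designed:
            raise ValueError("filter not designed yet")
        return -np.log(self.b) * self.fs / (2.0 * np.pi)

    def response(self, f_hz):
        """Complex frequency response at ``f_hz`` (Hz)."""
        if not self.designed:
            raise ValueError("filter not designed yet")
        z = np.exp(2j * np.pi * np.asarray(f_hz, dtype=float) / self.fs)
        return self.g0 * (z - self.b) / (z - self.a)

    def ba(self):
        """(b, a) coefficient arrays for :func:`scipy.signal.lfilter`."""
        if not self.designed:
            raise ValueError("filter not designed yet")
        return self.g0 * np.array([1.0, -self.b]), np.array([1.0, -self.a])

    def inverse_ba(self):
        """Coefficients of the inverse (coloring) filter ``1/H(z)``."""
        if not self.designed:
            raise ValueError("filter not designed yet")
        if abs(self.b) >= 1.0:
            raise ValueError("inverse filter unstable: |b| >= 1")
        return np.array([1.0, -self.a]) / self.g0, np.array([1.0, -self.b])

    def report(self) -> str:
        """Plain-text coefficient report."""
        return (
            f"whitening filter: fs = {self.fs} Hz\n"
            f"pole a = {self.a:.6f} ({self.pole_hz} Hz)\n"
            f"zero b = {self.b:.6f} ({self.zero_hz:.4f} Hz)\n"
            f"gain g0 = {self.g0:.6f}\n"
            f"DC gain = {abs(self.response(0.0)):.6f}, "
            f"gain at {self.unity_hz} Hz = {abs(self.response(self.unity_hz)):.6f}\n"
        )


class FilterDesignError(ValueError):
    """The printed constraints admit no stable first-order filter."""


def design_whitening_filter(spec: WhiteningFilterSpec | None = None) -> WhiteningFilterSpec:
    """Solve the whitening-filter coefficients from the printed constraints.

    The pole is placed at ``a = exp(-2 pi pole_hz / fs)``.  The two magnitude
    constraints ``|H(1)| = dc_gain`` and ``|H(e^{j w1})| = 1`` (``w1`` from
    ``unity_hz``) reduce to a quadratic in ``b`` whose roots are a reciprocal
    pair; the root inside the unit circle is the stable zero.  With the default
    specification the solution is ``a ~ 0.8819, b ~ 0.9740, g0 ~ 0.9534`` and
    the implied zero sits at ~0.21 Hz.
    """
    spec = WhiteningFilterSpec() if spec is None else spec
    if not (0.0 < spec.pole_hz < spec.unity_hz <= spec.fs / 2.0):
        raise FilterDesignError("need 0 < pole_hz < unity_hz <= fs/2")
    a = float(np.exp(-2.0 * np.pi * spec.pole_hz / spec.fs))
    w1 = 2.0 * np.pi * spec.unity_hz / spec.fs
    cw = np.cos(w1)
    D = spec.dc_gain ** 2 * (1.0 - a) ** 2
    E = 1.0 - 2.0 * a * cw + a * a
    A = D - E
    B = 2.0 * (E - D * cw)
    if abs(A) < 1e-15:  # degenerate: dc_gain = 1 with unity at Nyquist -> all-pass
        b = a
    else:
        disc = B * B - 4.0 * A * A
        if disc < 0:
            raise FilterDesignError("constraints infeasible (negative discriminant)")
        roots = np.array([(-B + np.sqrt(disc)) / (2.0 * A),
                          (-B - np.sqrt(disc)) / (2.0 * A)])
        inside = roots[np.abs(roots) < 1.0]
        if inside.size == 0:
            raise FilterDesignError("constraints infeasible (|b| >= 1)")
        b = float(inside[0])
    g0 = spec.dc_gain * (1.0 - a) / (1.0 - b)
    spec.a, spec.b, spec.g0 = a, b, float(g0)
    return spec


MA_ORDER = 4
"""Length of the moving-average stage (a ``4-point`` causal filter)."""

MA_GROUP_DELAY = (MA_ORDER - 1) / 2.0
"""Group delay of the moving-average stage, in samples (1.5)."""


class ConditioningChain:
    """Causal streaming conditioning of raw pressure into relative altitude.

    Carries filter state across :meth:`process` calls, so a log may be
    conditioned sample by sample or in arbitrary chunks with identical output.
    """

    def __init__(self, rest: "RestStatistics", cfg: "FusionConfig",
                 whitening: WhiteningFilterSpec | None = None):
        if cfg.method not in ("A", "B"):
            raise ValueError(f"unknown conditioning method {cfg.method!r}")
        self.baseline = float(rest.baro_baseline)
        self.method = cfg.method
        self._ma_b = np.full(MA_ORDER, 1.0 / MA_ORDER)
        self._ma_a = np.array([1.0])
        self._ma_zi = np.zeros(MA_ORDER - 1)
        if self.method == "B":
            self.whitening = design_whitening_filter(whitening)
            self._wh_b, self._wh_a = self.whitening.ba()
            self._wh_zi = np.zeros(1)
        else:
            self.whitening = None

    def process(self, pressure: np.ndarray) -> np.ndarray:
        """Condition a chunk of raw pressure samples (Pa) into altitude (m)."""
        x = pressure_to_altitude(np.atleast_1d(pressure)) - self.baseline
        y, self._ma_zi = signal.lfilter(self._ma_b, self._ma_a, x, zi=self._ma_zi)
        if self.method == "B":
            y, self._wh_zi = signal.lfilter(self._wh_b, self._wh_a, y, zi=self._wh_zi)
        return y


def condition(pressure: np.ndarray, rest: "RestStatistics",
              cfg: "FusionConfig") -> np.ndarray:
    """One-shot conditioning of a full pressure series (see ConditioningChain)."""
    return ConditioningChain(rest, cfg).process(np.asarray(pressure, dtype=float))
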