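"""Reference models, RMSE computation and Method A/B statistical comparison.

Tracking accuracy is summarized as the root mean square of the pointwise
difference between an estimated and a reference series.  Reference series
come from the scenario itself: zero for no-motion, the analytic ballistic
model ``v = g t``, ``h = g t^2 / 2`` on the detected fall window for
free-fall, and ``h = L sin(theta)`` with a central-difference velocity for
circular motion (squat trials are scored against the simulator truth).

Method comparison follows the study protocol: Bartlett's test for equal RMSE
variance and the paired-sample Wilcoxon signed-rank test at the 5% level;
signed-rank p-values are computed from an explicitly constructed exact null
distribution (valid for the small trial counts used here, N = 10).

Estimates are compared to references without any time realignment; the
conditioning chain's group delay (1.5 samples for the 4-point moving
average) is left in, since the accelerometer path of the complementary
filter is undelayed.  The alignment choice is recorded in suite output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import attitude_pass, vertical_pass
from .sensor_model import FusionConfig, ImuLog
from .simulator import (G, SensorErrorModel, simulate_circular,
                        simulate_free_fall, simulate_no_motion, simulate_squat)

__all__ = [
    "TrialResult",
    "rmse",
    "free_fall_window",
    "circular_reference",
    "signed_rank_null",
    "signed_rank_test",
    "compare_methods",
    "run_validation_suite",
    "summarize_suite",
    "settling_time",
]

ALIGNMENT = "none"
"""Time alignment applied between estimates and references."""


@dataclass
class TrialResult:
    """Per-trial accuracy summary."""

    scenario: str
    method: str
    height_rmse: float
    velocity_rmse: float
    velocity_bias: float
    n_samples: int
    f0: float | None = None
    seed: int | None = None


def rmse(est: np.ndarray, ref: np.ndarray) -> float:
    """Root mean square of the pointwise difference of two equal-length series."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def free_fall_window(log: ImuLog, cfg: FusionConfig, H: float):
    """Detect the ballistic fall window and build its analytic reference.

    ``T_start`` is the first downward crossing of the specific-force norm
    through g/2; ``T_end = T_start + sqrt(2 H / g)``.  Returns
    ``(i_start, i_end, t_start, h_ref, v_ref)`` where the reference series are
    the *downward* displacement ``g t^2 / 2`` (m) and speed ``g t`` (m/s) on
    ``[i_start, i_end)``.
    """
    norm = np.linalg.norm(log.accel, axis=1)
    below = norm < cfg.g / 2.0
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    if crossings.size == 0:
        raise ValueError("no ballistic phase found (no specific-force-norm "
                         "crossing through g/2)")
    i0 = int(crossings[0])
    t_start = float(log.t[i0])
    t_end = t_start + float(np.sqrt(2.0 * H / G))
    i1 = int(np.searchsorted(log.t, t_end, side="right"))
    tau = log.t[i0:i1] - t_start
    return i0, i1, t_start, 0.5 * G * tau ** 2, G * tau


def fall_window_metrics(height: np.ndarray, velocity: np.ndarray,
                        log: ImuLog, cfg: FusionConfig, H: float):
    """Fall-relative displacement and velocity RMSE on the ballistic window.

    The estimate's values at ``T_start`` are subtracted before comparison, so
    the metric scores the tracked *change* during the fall.
    """
    i0, i1, _, h_ref, v_ref = free_fall_window(log, cfg, H)
    disp_down = -(height[i0:i1] - height[i0])
    vel_down = -(velocity[i0:i1] - velocity[i0])
    return rmse(disp_down, h_ref), rmse(vel_down, v_ref), i1 - i0


def circular_reference(theta: np.ndarray, L: float, Ts: float):
    """Encoder-style reference: ``h = L sin(theta)`` and its central-difference
    velocity (one-sided at the endpoints)."""
    theta = np.asarray(theta, dtype=float)
    h = L * np.sin(theta)
    v = np.empty_like(h)
    if len(h) > 2:
        v[1:-1] = (h[2:] - h[:-2]) / (2.0 * Ts)
    if len(h) >= 2:
        v[0] = (h[1] - h[0]) / Ts
        v[-1] = (h[-1] - h[-2]) / Ts
    elif len(h) == 1:
        v[0] = 0.0
    return h, v


def signed_rank_null(n: int) -> np.ndarray:
    """Exact null pmf of the Wilcoxon signed-rank statistic W+ for ``n`` pairs.

    Built by convolving the generating polynomial prod_r (1 + x^r) / 2; the
    returned array has length n(n+1)/2 + 1 and sums to 1.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    pmf = np.array([1.0])
    for r in range(1, n + 1):
        new = np.zeros(len(pmf) + r)
        new[:len(pmf)] += pmf
        new[r:] += pmf
        pmf = 0.5 * new
    return pmf


def signed_rank_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test with exact null p-value.

    Zero differences are discarded (standard practice); if all differences are
    zero the methods are indistinguishable and p = 1.  Ties among the absolute
    differences receive average ranks.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    pmf = signed_rank_null(n)
    w = int(round(w_plus))
    p_low = float(pmf[:w + 1].sum())
    p_high = float(pmf[w:].sum())
    p = min(1.0, 2.0 * min(p_low, p_high))
    return w_plus, p


def compare_methods(results_A: list, results_B: list, alpha: float = 0.05) -> dict:
    """Study-protocol comparison of paired Method A and Method B trials.

    For each metric (height RMSE, velocity RMSE): Bartlett's equal-variance
    statistic and p-value, exact paired signed-rank statistic and p-value,
    and the decisions at the given significance level.
    """
    if len(results_A) != len(results_B):
        raise ValueError("paired trial lists must have equal length")
    if len(results_A) < 5:
        raise ValueError("need at least 5 paired trials")
    report = {"n_trials": len(results_A), "alpha": alpha,
              "alignment": ALIGNMENT}
    for metric in ("height_rmse", "velocity_rmse"):
        a = np.array([getattr(r, metric) for r in results_A])
        b = np.array([getattr(r, metric) for r in results_B])
        bart_stat, bart_p = stats.bartlett(a, b)
        w, p = signed_rank_test(a, b)
        report[metric] = {
            "mean_A": float(a.mean()), "sd_A": float(a.std(ddof=1)),
            "mean_B": float(b.mean()), "sd_B": float(b.std(ddof=1)),
            "bartlett_stat": float(bart_stat), "bartlett_p": float(bart_p),
            "signed_rank_W": w, "signed_rank_p": p,
            "variance_differs": bool(bart_p < alpha),
            "methods_differ": bool(p < alpha),
        }
    return report


def velocity_bias(velocity: np.ndarray) -> float:
    """Time-mean of the velocity estimate (m/s); ~0 for an unbiased tracker."""
    return float(np.mean(velocity))


# ---------------------------------------------------------------------------
# Simulated validation suite
# ---------------------------------------------------------------------------

CIRCULAR_FREQS = (0.25, 0.5, 0.75, 1.0, 1.25)


def _trial_seed(base_seed: int, index: int) -> int:
    return int((1000 * base_seed + index) % 2 ** 31)


def run_validation_suite(base_seed: int = 1, n_trials: int = 10,
                         duration: float = 180.0,
                         freqs=CIRCULAR_FREQS) -> pd.DataFrame:
    """Run the full simulated validation campaign.

    Scenarios: no-motion (``duration``), free-fall from 1.53 m, circular
    motion at each frequency in ``freqs`` with L = 0.30 m (``duration`` of
    steady rotation), and a 0.60 m squat; ``n_trials`` seeds each, tracked
    with both conditioning methods.  Free-fall trials are scored on the
    ballistic fall window (fall-relative displacement against the analytic
    model), the others against their full-trial references.

    Returns one row per (scenario, trial, method).
    """
    cfg_by_method = {m: FusionConfig.for_method(m) for m in ("A", "B")}
    rows = []

    def add(scenario, f0, seed, log, truth, score):
        att = attitude_pass(log, cfg_by_method["A"])
        for method, cfg in cfg_by_method.items():
            h, v, _ = vertical_pass(log.pressure, att.a_up, att.rest, cfg)
            h_rmse, v_rmse, n_used = score(h, v, cfg)
            rows.append({
                "scenario": scenario, "f0": f0, "seed": seed, "method": method,
                "height_rmse": h_rmse, "velocity_rmse": v_rmse,
                "velocity_bias": velocity_bias(v), "n_samples": n_used,
            })

    for i in range(1, n_trials + 1):
        seed = _trial_seed(base_seed, i)
        errors = SensorErrorModel(seed=seed)

        truth, log = simulate_no_motion(duration=duration, errors=errors)
        add("no-motion", None, seed, log, truth,
            lambda h, v, cfg, tr=truth: (rmse(h, tr.height),
                                         rmse(v, tr.velocity), len(tr)))

        truth, log = simulate_free_fall(errors=errors)
        add("free-fall", None, seed, log, truth,
            lambda h, v, cfg, lg=log: fall_window_metrics(h, v, lg, cfg, 1.53))

        for f0 in freqs:
            truth, log = simulate_circular(f0=f0, duration=duration,
                                           errors=errors)
            steady = len(truth) - int(round(duration / 0.02))
            h_ref, v_ref = circular_reference(truth.theta, 0.30, 0.02)

            def score_circ(h, v, cfg, s=steady, hr=h_ref, vr=v_ref):
                return (rmse(h[s:], hr[s:]), rmse(v[s:], vr[s:]),
                        len(hr) - s)

            add("circular", f0, seed, log, truth, score_circ)

        truth, log = simulate_squat(errors=errors)
        add("squat", None, seed, log, truth,
            lambda h, v, cfg, tr=truth: (rmse(h, tr.height),
                                         rmse(v, tr.velocity), len(tr)))

    return pd.DataFrame(rows)


def summarize_suite(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD table across trials, one row per condition and method."""
    grouped = results.groupby(["scenario", "f0", "method"], dropna=False)
    summary = grouped.agg(
        height_rmse_mean=("height_rmse", "mean"),
        height_rmse_sd=("height_rmse", "std"),
        velocity_rmse_mean=("velocity_rmse", "mean"),
        velocity_rmse_sd=("velocity_rmse", "std"),
        n_trials=("seed", "count"),
    ).reset_index()
    summary["alignment"] = ALIGNMENT
    return summary


def settling_time(t: np.ndarray, height: np.ndarray, accel_norm: np.ndarray,
                  band: float = 0.05, tail: float = 2.0,
                  impact_level: float = 2.0 * G) -> float:
    """Recovery time of the height estimate after the first impact.

    The impact instant is the first sample where the specific-force norm
    exceeds ``impact_level``; the asymptote is the mean estimate over the last
    ``tail`` seconds; the settling time is the elapsed time until the estimate
    stays within ``band`` of the asymptote for good.
    """
    hits = np.flatnonzero(accel_norm > impact_level)
    if hits.size == 0:
        raise ValueError("no impact found in the log")
    i_imp = int(hits[0])
    Ts = float(np.median(np.diff(t)))
    n_tail = max(1, int(round(tail / Ts)))
    asymptote = float(np.mean(height[-n_tail:]))
    outside = np.flatnonzero(np.abs(height - asymptote) > band)
    outside = outside[outside >= i_imp]
    if outside.size == 0:
        return 0.0
    i_settle = int(outside[-1]) + 1
    return float(t[i_settle] - t[i_imp])
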