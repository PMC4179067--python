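# baroimu

Baro-inertial sensor fusion for tracking the **height and vertical velocity**
of a moving body at 50 Hz — the vertical channel of human movement analysis
(sit-to-stand transitions, squats, falls and pre-impact fall detection),
where stand-alone inertial integration drifts within seconds and a barometric
altimeter alone is far too noisy.

The estimator is a loosely coupled two-stage cascade:

1. **Attitude stage** — a quaternion EKF with state `x = [q̄, ᵃb]` (attitude
   quaternion + accelerometer bias) propagates the gyro rates through the
   exact exponential `q̄_k = exp(Ts/2 Ω(ω)) q̄_{k-1}` and corrects with
   accelerometer leveling, `z = C_bn(q̄)(-gⁿ) + ᵃb + v`.  Per-axis *vector
   selection* rejects any innovation component above `λ_g = 150 mg`, so
   ballistic flight, centripetal accelerations and impacts cannot corrupt
   the attitude.
2. **Vertical stage** — the specific force is rotated into the navigation
   frame and gravity-compensated (`ẍ = C_nb f^b + gⁿ`); its vertical
   component and the conditioned pressure altitude
   (`h = 44300 (1 - (p/p₀)^0.19)`, baseline-subtracted, then a 4-point
   moving average — *Method A* — optionally cascaded with a whitening filter
   — *Method B*) drive a critically damped complementary filter with gains
   `k₂ = σ_w/σ_v`, `k₁ = 2√k₂` and time constant `τ = √(σ_v/σ_w)`.

The whitening filter (DC gain 0.21, pole at 1 Hz, unity gain at the 25 Hz
Nyquist) removes the serial correlation of environment-driven pressure
fluctuations, for which the complementary filter is then optimal — at the
price of attenuating genuinely slow height changes.

A built-in scenario simulator stands in for the hardware: it generates
kinematically self-consistent ground truth and synthetic logs (correlated
barometric noise, 1 Pa quantization, accelerometer range clipping) for
no-motion, free-fall, forced circular motion and squat trials, so the whole
pipeline is testable offline.  See `docs/methods.md` for the model details.

## Worked example

Simulate a forced circular motion trial (sensor on a 0.30 m lever arm at
0.5 Hz), track it with the whitening-filter method, and score it:

```sh
baroimu simulate --scenario circular --f0 0.5 --duration 60 --seed 1 --out run/sim
baroimu track --input run/sim/log.csv --method B --out run/trk
baroimu evaluate --est run/trk/estimate.csv --truth run/sim/truth.csv --out run/ev
```

The last command prints:

```json
{
  "height_rmse": 0.0901245417249306,
  "velocity_rmse": 0.052815227403221,
  "velocity_bias": 0.010967001906698968,
  "n_samples": 3200,
  "alignment": "none"
}
```

i.e. the 0.60 m peak-to-peak oscillation is tracked to ~9 cm in height and
~0.05 m/s in velocity over the whole trial, including the motor spin-up
transient (Method A scores 0.127 m in height on the same log — at 0.5 Hz
the whitened barometric path already pays off).  Each command also
writes a JSON manifest with its parameters and seed for reproducibility.

The same pipeline is available as a library:

```python
from baroimu import FusionConfig, simulate, track
from baroimu.simulator import SensorErrorModel

truth, log = simulate("squat", errors=SensorErrorModel(seed=1))
est = track(log, FusionConfig.for_method("A"))
print(est[["t", "height_m", "velocity_mps"]].tail())
```

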