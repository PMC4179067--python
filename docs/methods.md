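# Methods

`baroimu` estimates the height and vertical velocity of a rigid body carrying
a 50 Hz baro-IMU (tri-axial gyroscope, tri-axial accelerometer, barometric
pressure sensor).  The estimator is loosely coupled: an attitude stage feeds
a vertical-channel stage, and the two can be reasoned about independently.

## Frames, units and conventions

The navigation frame {n} is North-East-Down; gravity is `g^n = (0, 0, +g)`
with `g = 9.81 m/s^2`.  Reported heights and velocities are up-positive and
relative to the starting position.  Quaternions are vector-first,
`q = [q1, q2, q3, q4]`, and represent the body-to-navigation rotation with
`C_nb = I + 2 q4 [q x] + 2 [q x]^2` (so `dC_nb/dt = C_nb [w x]` for a
body-frame angular rate `w` — the right-hand rule; the transpose `C_bn` maps
navigation vectors into the body frame).  Internally everything is SI;
parameters quoted in milli-g use 1 mg = 9.81e-3 m/s^2.

Heading is deliberately not estimated: projecting the specific force onto
the vertical requires only roll and pitch, so no magnetometer is used and
the initial yaw is fixed to zero.

## Attitude EKF

State: the quaternion plus a 3-vector accelerometer bias, with a 7x7 error
covariance.  The bias follows a first-order Gauss-Markov model with
correlation rate `alpha` (1/s) and driving-noise SD `sigma_ab` (m/s^3);
the default `alpha = 0` reduces it to a random walk with per-step covariance
`Ts * sigma_ab^2 I` (the analytic limit of the Gauss-Markov expression).

Prediction propagates the quaternion with the exact matrix exponential of
the gyro rate — `cos(|w| Ts / 2) I + sin(|w| Ts / 2)/|w| * Omega(w)`, which
is orthogonal and therefore norm-preserving — and builds the quaternion
process noise from the propagated second moment
`M = q q^T + P^q`: the quaternion block is
`(I tr(M) - M) sigma_g^2 (Ts/2)^2`, symmetric PSD by construction.

The measurement is accelerometer leveling: at quasi-static instants the
specific force should equal `C_bn(q)(-g^n) + b`.  The innovation
`nu = f^b - C_bn(q)(-g^n) - b` is gated per axis (vector selection): any
component with `|nu_i| > lambda_g` (default 150 mg) has its measurement-matrix
row zeroed, so dynamic accelerations — ballistic flight, centripetal terms on
a lever arm, impacts — cannot corrupt the attitude.  If all three rows are
zeroed the update is skipped and the filter coasts on the gyro alone (during
simulated free fall with a generically tilted case this happens at every
sample of the ballistic phase).  The update keeps the full `R = sigma_a^2 I`,
symmetrizes the covariance, and renormalizes the quaternion.

The measurement Jacobian is derived analytically from the leveling model and
is verified against central finite differences (tolerance 1e-6) in the test
suite rather than trusted from a printed matrix.

Observability: at rest, only the gravity-parallel bias component is
observable; horizontal bias is indistinguishable from a small tilt.  The
filter's split of a persistent innovation between tilt and bias follows the
ratio of the two initial covariances.  We initialize the quaternion block at
1e-4 and the bias block at (1 mg)^2 — the accelerometer is assumed
field-calibrated — so residual innovations are attributed to tilt, keeping
static inclination errors below 0.1 deg while the vertical bias component is
still recovered (20 mg injected on the gravity axis converges to within 5 mg
in under 60 s through the bias random walk).

Gyro bias is captured during a 1 s rest window (mean of the gyro output) and
subtracted from every sample; there is no gyro-bias state.  The initial
quaternion levels the window-mean specific force onto the vertical by the
shortest arc (zero yaw).

## Strap-down stage

`a^n = C_nb f^b + g^n`; only the vertical component is kept, converted once
to up-positive (`a_up = -a^n_z`).  Lever-arm (tangential/centripetal) terms
are never subtracted by the estimator — the vector-selection gate absorbs
their effect on leveling, and their projection on the vertical is part of
the true motion.

## Barometric conditioning

Pressure converts to altitude through the international barometric formula
`h = 44300 (1 - (p/p0)^0.19)` with `p0 = 1013.25 hPa`; the mean altitude of
the rest window is subtracted (bias capture), yielding height relative to
the start.  Two conditioning methods follow:

* **Method A** — causal 4-point moving average (unit DC gain, 1.5-sample
  group delay).
* **Method B** — Method A cascaded with a first-order whitening filter
  `H(z) = g0 (z - b)/(z - a)`.

Indoor pressure fluctuations are serially correlated; the whitening filter
inverts that coloration so the complementary filter's white-noise assumption
holds.  Its design is fully determined by four constraints: 50 Hz sampling,
pole at 1 Hz (`a = exp(-2 pi f_pole Ts) ~ 0.8819`), DC gain 0.21, unity gain
at the 25 Hz Nyquist frequency.  The two magnitude constraints reduce to a
quadratic in `b` whose roots are a reciprocal pair; the stable root gives
`b ~ 0.9740` (zero at ~0.21 Hz, about two octaves below the pole) and
`g0 ~ 0.9534`.  The 0.21 DC gain is a known price: genuinely slow height
changes passing through the barometric path are attenuated five-fold, which
is why Method B under-reports step-like and very-low-frequency displacements
while Method A does not.

## Complementary filter

Two states (height, vertical velocity), driven by `a_up` and the conditioned
altitude `x_p`.  Gains come from the steady-state Kalman filter of a double
integrator with white acceleration noise `sigma_w` observed through white
altitude noise `sigma_v`:

    k2 = sigma_w / sigma_v,  k1 = 2 sqrt(k2),  tau = sqrt(sigma_v / sigma_w)

— a critically damped loop with a double pole at `-1/tau` (Method A tuning:
`sigma_w = 15 mg`, `sigma_v = 0.30 m`, `tau ~ 1.43 s`; Method B uses
`sigma_v = 0.15 m`).  The feedback enters with positive sign on the residual
`x_p - x` (the sign that stabilizes the loop; the equivalent "minus" form
merely folds the sign into the gain vector).  The discrete recursion applies
the previous step's residual and acceleration increment (strict one-step
indexing); the estimate at `t_k` therefore depends only on inputs before
`t_k`, and the whole pipeline is causal and streamable.

Because the filter's altitude-to-height transfer has unit DC gain, its
height output inherits any DC distortion of the conditioning chain.  After a
velocity disturbance (e.g. an under-measured impact) the height estimate
recovers along `dv * t * exp(-t/tau)`, reaching a 5 cm band in roughly
6-7 tau — about 9 s with Method A tuning.

## Scenario simulator

The simulator generates kinematically self-consistent ground truth plus a
sensor log for four validation scenarios:

* **no-motion** (default 180 s): rest at level attitude; exercises the noise
  floor and drift-freedom.
* **free-fall** (default H = 1.53 m): rest, ballistic fall
  (`T_fall = sqrt(2H/g) ~ 0.56 s`, specific force identically zero), a
  restitution bounce (e = 0.3) on a mattress, and a long final rest
  (default 25 s).  The contact acceleration is an impulse-matched half-sine:
  with a 40 ms contact the true peak is ~30 g.  The case is tilted by 30 deg
  about (1,1,0) so gravity projects onto all three axes (every accelerometer
  row is then rejected during flight); an optional tumble mode spins the
  case during the fall.
* **circular** (L = 0.30 m, f0 in 0.25-1.25 Hz): the sensor rides a lever
  arm in a vertical plane; height `L sin(theta)`, specific force carries the
  rotating gravity tilt plus the centripetal `-w0^2 L` term.  The motor
  spins up linearly over 2 s (an instantaneous velocity step would put an
  unphysical transient into every error metric); the error metrics use the
  180 s steady-rotation window.
* **squat** (depth 0.60 m over 4 s): minimum-jerk descent and ascent with a
  small (5 deg) smooth trunk-pitch oscillation and 2 s rest pads.

Sensor model: white Gaussian gyro noise (1 deg/s) and accelerometer noise
(10 mg), optional constant accelerometer bias, clipping at the accelerometer
range (default +/-8 g), colored barometric noise and 1 Pa pressure
quantization (~8.4 cm of altitude).  The colored noise is white noise passed
through the *inverse* of the whitening filter — the model under which the
whitening filter is exactly the right conditioner — scaled to a 0.30 m
sample SD.  After the 4-point moving average about 0.19 m remains (the
moving average removes the broadband part of the inverse-whitening
spectrum).

The accelerometer range limit is what reproduces the post-impact behavior
seen on real hardware: the true ~30 g contact pulse is sensed as a clipped
~8 g hump, the complementary filter misses most of the velocity reversal,
and the height estimate dives and then recovers over ~6-7 tau (~9 s).

What the simulator does not emulate: temperature-dependent barometer drift,
non-stationary weather/building pressure trends, accelerometer scale-factor
and cross-axis errors, sensor timing jitter, and transport losses.  Passing
the simulated suite therefore demonstrates the correctness and calibration
of the method under its own noise assumptions, not field performance in an
uncontrolled pressure environment (where height errors are known to be
several times larger).

## Evaluation

RMSE between estimate and reference, per trial.  References: zero series
(no-motion), the analytic ballistic model `v = g t`, `h = g t^2/2` on the
detected fall window (start: first downward crossing of the specific-force
norm through g/2; length `sqrt(2H/g)`; the estimate's values at the window
start are subtracted, scoring the tracked change), the encoder-style
`h = L sin(theta)` with central-difference velocity (circular), and the
simulator truth (squat).  No time realignment is applied: the moving
average delays only the barometric path, and the accelerometer path — which
dominates wherever a 30 ms shift would matter — is undelayed; the choice is
recorded in the evaluation output.

Method comparison follows the study protocol: Bartlett's test for equal
RMSE variance and the paired two-sided Wilcoxon signed-rank test at the 5%
level.  Signed-rank p-values come from an explicitly constructed exact null
distribution (generating-polynomial convolution; exact for the N = 10 trial
counts used here), with zero differences dropped and average ranks for ties.

## Numerical choices and degenerate inputs

* Quaternion renormalized after every update; covariance symmetrized
  (`(P + P^T)/2`) after the plain-form update, which is otherwise
  numerically asymmetric.
* `alpha = 0` handled by the analytic limit, not by dividing by alpha.
* A fully-rejected measurement skips the update entirely (no 0x0 algebra).
* Whitening-filter design rejects configurations whose stable zero would
  leave the unit circle; the degenerate all-pass (DC gain 1) is exact.
* Filters are implemented with `scipy.signal.lfilter` carrying explicit
  state, so sample-by-sample and batch processing are bit-identical.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  (scenario, seed) pairs produce byte-identical logs.

## Problem sizes

The validation campaign used by the acceptance script runs the full study
design — 8 conditions x 10 seeds x 2 conditioning methods, 180 s trials
(9000 samples) for no-motion and circular motion, scenario-natural durations
for free-fall (~29 s) and squat (8 s) — about 1.1 M filter steps in roughly
a minute on one core.

## Known limitations

* Horizontal position and heading are out of scope by design.
* The whitening filter is a first-order approximation pinned by four design
  constants; a filter identified from real ARMA noise modeling would differ
  in detail, and with it the exact low-frequency distortion of Method B
  (the height RMSE of Method B on 0.25 Hz circular motion sits at ~0.16 m,
  of which 0.15 m is this structural distortion).
* No gyro-bias state: fine for few-minute recordings, not for long sessions.
* The complementary filter's white-noise optimality premise holds exactly
  only for Method B conditioned data; Method A trades that for an undistorted
  low-frequency response.
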