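# Methods

## Model

Velocity in a short sprint from a stationary start is modelled as
`v(t) = MSS·(1 − e^(−t/TAU))` with two free parameters: the maximal
sprinting speed MSS (m/s) and the time constant TAU (s). Two derived
quantities are reported because practitioners think in them: the
maximal (initial) acceleration MAC = MSS/TAU (m/s²) and the relative
propulsive peak power PMAX = MSS·MAC/4 (W/kg). PMAX ignores air
resistance by construction, so it is a net propulsive quantity, not a
total mechanical output. Eliminating time between velocity and its
derivative gives the linear acceleration–velocity profile
`a(v) = MAC − (MAC/MSS)·v`, and power `a·v` peaks at v = MSS/2 with
value PMAX.

The model assumes accelerations follow the single exponential for the
whole measured distance. Real sprints deviate (step-to-step velocity
oscillation, imperfect starts, early strategy changes); the model is a
deliberate two-parameter summary, not a gait simulation.

Integrating velocity gives distance–time; inverting it gives the
regression function for gate data,

    t(d) = TAU · W₀(−e^(−d/(MSS·TAU) − 1)) + d/MSS + TAU,

on the principal branch W₀. The argument lies in [−1/e, 0); d = 0 sits
exactly on the branch point (W₀(−1/e) = −1, t = 0). The implementation
clamps floating-point excursions below −1/e and returns t = 0 at d = 0
exactly; continuity near the branch point is covered by tests.

## Distorted starts

Two mechanisms break the assumption that timing starts at first
movement:

- **Constant time shift** (reaction time on a gun-started clock,
  premature triggering): every split moves by the same TC. Modelled by
  `t(d) + TC`, fitted (Estimated TC, TC unbounded in sign — it acts as
  a regression intercept) or fixed (Fixed TC, a predefined constant
  added to the split times before fitting).
- **Flying start** (athlete begins FD metres behind the first gate):
  the athlete carries velocity into the first gate, shortening early
  splits more than late ones — the split-time curve is shifted *and*
  bent, so no constant TC can fully absorb it. Modelled by
  `t(d + FD) − t(FD)` with FD ≥ 0, fitted (Estimated FD) or fixed
  (Fixed FD).

## Estimation

All gate models minimise the residual sum of squares in **time**
(distance is the predictor). Fitting distance-on-time with the
integrated equation is statistically backwards and biases the
parameters, so it is not offered.

Solver: SciPy's trust-region-reflective damped least squares with
bounds MSS ∈ (0, 20], TAU ∈ (0, 10] (numerical safety rails well
outside human profiles), TC ∈ [−5, 5], FD ∈ [0, 10]. The FD lower
bound is part of the model (a negative flying distance is
meaningless), and estimated FD regularly lands on it for clean-start
data. Starting values: MSS₀ = 1.5 × mean velocity to the last gate
(always above the admissible MSS for a mono-exponential profile),
TAU₀ = 1 s, TC₀ = 0, FD₀ = 0; tolerances 1e-12 on cost/step/gradient,
max 1000 function evaluations. Non-convergence is reported via a
`converged` flag rather than raised, because the estimated-FD model
genuinely fails on some trials. Unit tests check the solver against a
brute-force grid + Nelder–Mead polish of the identical objective.

One worked-example cell is knowingly not reproduced from the reference
table this demonstration mirrors: for the gun-started athlete the
estimated-FD optimum at the FD = 0 bound mathematically coincides with
the No-Correction solution, while the reference prints a point with
roughly 17× the residual sum of squares — an optimizer artifact in the
original analysis. This package returns the true optimum; the test
suite asserts the dominance explicitly.

Laser traces are fitted with the time-shifted velocity model on the
raw channel after dropping all samples before the smoothed channel
first crosses 0.5 m/s (the raw channel gates when no smoothed one
exists). The unclamped expression is used on the filtered data; the
clamped-to-zero version exists only for prediction at pre-start times.
All post-threshold samples enter unweighted.

## Synthetic data

`generate_splits` implements the exact data-generating process
`round(t(d + FD) − t(FD) + RT, clock)` with round-half-away-from-zero
(what a timing clock reporting the nearest tick does; the printed
worked examples are insensitive to half-even vs half-away, which was
verified before choosing). Rounding never moves a time by more than
half a tick, and a generated-then-fitted round trip on unrounded data
recovers the generating parameters to 1e-6 — both are tested
properties.

`generate_laser_trace` is a synthetic stand-in for a laser gun: the
model velocity (clamped to 0 pre-start) plus iid Gaussian noise
(default sd 0.05 m/s) sampled at 1000 Hz, with a 51-sample centered
moving average as the smoothed channel. It does not emulate a real
device's proprietary smoothing, step-to-step velocity oscillation, or
distance-dependent noise, so passing tests demonstrate estimator
correctness under the model, not robustness to real laser artifacts.

`generate_cohort` emulates a squad testing session: per-athlete truths
drawn from MSS ~ N(8.0, 0.7) m/s and MAC ~ N(7.0, 1.0) m/s² truncated
positive (plausible for trained field-sport athletes; these are fixture
choices, configurable), 31 athletes × 2 trials by default, gates at
5/10/20/30 m, a 0.5 m flying start, additive trial-to-trial timing
noise of sd 0.01 s (the order of the clock precision — the value is a
design choice, as instrument-level repeatability is rarely published),
then 0.01 s rounding. Monotonicity of split times is restored by a
one-tick push where noise/rounding tie adjacent gates. Every stochastic
operation takes an explicit seed; there is no hidden global state.

## Agreement statistics

Per athlete-trial and parameter, %Diff = 100·(practical −
criterion)/criterion. %Bias is its mean. %MAD defaults to the mean
absolute deviation **around the mean** (`mode="deviation"`), with the
plain mean |%Diff| available as `mode="absolute_diff"` because the
estimator's usual name suggests that reading; the two coincide exactly
when the bias is zero.

%RSE is the percent residual standard error of the OLS regression of
practical (outcome) on criterion (predictor):
`sqrt(Σ(100·(yᵢ−ŷᵢ)/ŷᵢ)² / (N−2))`. Note the square root and the √2 in
`%MDC95 = %RSE·√2·1.96`: a residual standard error must live on the %
scale and the detectable-change factor follows the standard
SEM·√2·1.96 construction (renderings of these formulas sometimes lose
the radical signs; this package implements them with the radicals).
Treating the criterion as error-free makes %RSE the percent SEM of the
practical instrument, hence %MDC95 the smallest observed change
interpretable as real. Trials are pooled as independent observations
(no athlete-level clustering adjustment is applied).

Confidence intervals are bias-corrected and accelerated (BCa)
nonparametric bootstrap (default 5000 resamples, 95%), resampling
athlete-trial rows; the %MDC95 interval resamples (criterion,
practical) pairs jointly and refits the regression per resample.
Degenerate (constant) inputs collapse to a point interval with a
warning. Coverage of the %Bias interval is property-tested (90–98%
over 500 synthetic cohorts of n = 30).

## Validation workflow

`run_validation` mirrors a criterion-validity study design: per trial
it obtains criterion parameters (either the generating truth or, by
default, a refit on a synthetic laser trace — closer to a real study
where the criterion instrument has its own noise), fits the five gate
models to the observed splits, and additionally regenerates splits
from the criterion parameters under the assumed distortion (0.5 m
flying start, 0.01 s rounding) as a "simulated" comparison arm that
shows the agreement expected from the data-generating process alone.
Trials flagged by the screening rules are dropped: any inter-gate
segment whose mean velocity falls below the preceding segment's (the
start counts as a segment from (0, 0)), or a laser trace covering less
than 29 m (strict less-than; exactly 29 m is kept). Trials where any
model fails to converge are excluded from all cells, keeping the
paired design intact.

Problem sizes in the test suite — the 31 × 2 cohort over 10 seeds for
the ordering checks, 100 Monte-Carlo seeds for laser recovery, 500
cohorts for bootstrap coverage — were chosen as the smallest designs
that make the stochastic assertions stable across seeds.

## Known limitations

- The mono-exponential form cannot represent within-sprint strategy
  changes or the oscillating step pattern visible in raw laser data.
- PMAX excludes air resistance; comparisons with drag-aware estimates
  are not like-for-like.
- %RSE assumes an error-free criterion; with a noisy criterion it
  overstates the practical instrument's SEM.
- The cohort generator draws trial-to-trial variation as additive
  timing noise only; real athletes also vary their profile between
  trials.
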