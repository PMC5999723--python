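# Methods

This note documents the generative model behind the synthetic cohorts, the
measurement chain, the switching estimators, and the choices made where the
design was genuinely open. Units are SI internally (m, s, N, N/m);
interfaces report cm, ms and N/m where those are customary.

## Experimental design

A session is 10 blocks of 45 vertical reaches (~15 cm, instructed peak
velocity 45–55 cm/s) through a one-sided elastic field rendered above an
onset position y₀:

    F(y) = 0                      y ≤ y₀ − w
         = k (y − y₀ + w)²/(4w)   y₀ − w < y < y₀ + w
         = k (y − y₀)             y ≥ y₀ + w

The quadratic blend is the unique C1 interpolation between the null and
linear branches; its half-width `w` (default 5 mm) is a free apparatus
parameter. A rendered force that switches on abruptly (w → 0) would make
stiff contacts act within a single sample; 5 mm spreads the onset over
10 mm of travel (~20–40 ms), which both protects a real haptic device and
gives the real-vs-catch acceleration comparison a finite rise time.

Force onsets are linearly spaced from 3 cm to 14.5 cm in exact steps of
0.2875 cm (41 onsets). The peak field force at the 15 cm target is linear
in the onset, 4 N at the shallowest to 14 N at the deepest, so stiffness
`k = F_max/(0.15 − y₀)` runs from 4/0.12 = 33.3 N/m to 14/0.005 =
2800 N/m. Ascending blocks run the 41 onsets in increasing-stiffness order
and hold the stiffest field for 4 plateau trials; descending blocks are the
exact reverse. Six trials per block are catch trials: the field is silently
zeroed while the scheduled (k, y₀) pair is retained as the *expected*
field. Catch positions are drawn uniformly without replacement, rejecting
draws with adjacent catch trials or with any interior 5-trial mini-block
left without a real trial (6 catches cannot cover all 7 mini-blocks, so
"each mini-block has a catch trial" holds only on average across blocks).
Trials 1–45 partition into mini-blocks of sizes [10,5,5,5,5,5,10]; for
analyses that pool block conditions at matched stiffness, descending
mini-block m is mirrored to stiffness group 8−m.

## Generative participant model

**Planned kinematics.** The ascent is a bell-shaped velocity profile
`v(t) ∝ t^p (T−t)^q`, which has the closed-form position
`y(t) = A·I_{t/T}(p+1, q+1)` (regularized incomplete beta) and the peak
speed `v_pk = c(p,q)·A/T`. The case (p,q) = (2,2) is exactly the min-jerk
velocity shape (c = 1.875) and is used for the descent. The ascent uses
(p,q) = (3.5, 2): reaches into a resistive field decelerate late, and with
this skew the planned acceleration changes sign at y = 8.38 cm — the onset
position of a ~133 N/m field — so the sign of acceleration at force onset
flips within 0.1–0.2 ln-units of the switch threshold, as the behaviour
being modelled requires. Plan amplitude is 0.15 m (the target is touched);
target peak speeds are drawn from N(0.499, 0.02) m/s truncated to
[0.45, 0.55].

**Dynamics.** The motor command compensates the expected field along the
planned path: `u(t) = a_plan(t) + F_exp(y_plan(t))/m_eff` with effective
moving mass m_eff = 1.2 kg. On real trials the compensation cancels the
rendered force exactly, so the realized trajectory equals the plan, the
target is reached in every condition, and the peak field force is the
scheduled `k(0.15 − y₀)` — 4 N in the softest and 14 N in the stiffest
field. On catch trials the same command meets no force; the deviation from
the plan obeys

    e″ = F_exp(y_plan)/m_eff − K e − B e′

with a slow, critically damped corrective servo (K = 22 s⁻², B = 9.4 s⁻¹,
~0.75 Hz), producing an overshoot of the target and a return toward home by
trial end. Trials are integrated at 1 kHz (semi-implicit Euler; real trials
need no integration) and decimated to the 500 Hz recording rate.

**Grip force.** Grip is a baseline (2 N) plus two feedforward components,
identical on real and catch trials:

* an *inertial* component, 0.25 N per m/s² of the positive part of the
  anticipated (planned) acceleration, low-passed at a muscular bandwidth of
  20 Hz and jittered in time by the trial lag noise — its first local peak
  is synchronized with the first acceleration peak. The positive part (not
  the absolute value) is used because upward acceleration is what loads the
  grip on the ascent, and because it vanishes through the impact region, so
  the anticipatory peak below is not displaced;
* an *anticipatory* Gaussian bump (SD 80 ms) centred
  `lag(ln k) + N(0, lag_sd)` ms after the trial's (expected) impact time,
  with amplitude `A(ln k) = 10 N · exp(−(ln k − θ)²/(2·1.5²))`, an
  inverted U centred on the condition's threshold. The width 1.5 ln-units
  was fixed by a design calculation: it keeps the quartic-fit argmax bias
  on the design's ln k grid below 0.03 ln-units while leaving the
  stiff-extreme amplitude (≈1.5 N) safely above the late inertial peak
  (≈0.7 N), so the global grip maximum is always the anticipatory peak.

**The switched lag controller.** The grip-peak lag follows a
rise-then-plateau function of ln k: linear from lag_soft = 4 ms at
ln 33.3 up to lag_plateau = 40 ms at the threshold, constant above it,
with trial-to-trial noise SD 6 ms. The threshold is hysteretic —
θ_asc = 5.07, θ_desc = 4.89 on the ln(N/m) axis (159.7 vs 133.2 N/m) — and
the regime flips only `switch_inertia_trials = 3` trials after the block's
schedule crosses it, the "inertia" signature of a discrete switch. Negative
(leading) soft-field lags are supported by configuring `lag_soft < 0`; the
default follows the 4 ms condition mean.

**Noise.** Two noise sources beyond the lag jitter make the measurement
problem realistic: white position measurement noise (SD 0.4 mm at 500 Hz,
the scale at which double differentiation yields ~1 m/s² acceleration
noise) and 5% multiplicative amplitude noise on the anticipatory bump.
Without them, per-bin t statistics in the divergence test are computed on
(near) zero-variance samples and participant-level estimates are
numerically identical, degenerating every inferential statistic. The
fixture generator (`make_fixtures`) zeroes all three noise sources for
exact-recovery tests: with noise off, the pipeline returns every trial's
generative lag to within one sample (2 ms) across the full stiffness grid.

## Measurement chain

Velocity, acceleration and grip-force rate are central differences of the
raw signal chain, each smoothed once with a zero-phase (forward–backward)
4th-order Butterworth low-pass at 20 Hz per pass (odd-reflection padding).
Movement onset is the earliest sample from which velocity exceeds 3 cm/s
for at least 100 ms. Impact is the argmax (earliest of ties) of the
rendered elastic force, or on catch trials of the scheduled field law
applied to the recorded position. The first acceleration peak is located
over the first 60% of the onset-to-impact interval on an 8 Hz re-smoothed
copy and refined by a local quadratic fit (±50 ms): the peak top is flat,
so a raw noisy argmax scatters by tens of ms and is biased early by the
skewed peak shape. The first local grip maximum is sought within ±150 ms
of that peak (strict maximum over a 5-sample neighbourhood); features that
cannot be measured are reported as NaN, never fabricated. Grip-force rate
and acceleration "at force onset" are read at the first crossing of the
scheduled y₀.

## Switching estimators

* **Extremum**: least-squares 4th-order polynomial of grip-force peak
  against ln k (across-participant level means per condition); argmax on a
  10⁻³ grid over the observed range, refined by the derivative's real
  roots; boundary maxima are flagged, not extrapolated.
* **Bootstrap**: participants resampled with replacement (pairs kept),
  10,000 repetitions, percentile 95% CI; statistic = difference of means,
  or the absolute difference of mean slopes for the low/high-stiffness
  slope comparison. All resampling is seeded.
* **Hinge regression**: `lag = b₀ + s_lo (x−x_b)[x<x_b] + s_hi (x−x_b)[x≥x_b]`,
  continuous at a breakpoint x_b fixed upstream (each participant's
  condition-averaged extremum); 3 mean parameters against 2 for the single
  line, so the hinge nests the line and RSS_hinge ≤ RSS_line always. An
  unconstrained two-line variant (4 parameters) is available. AIC uses the
  Gaussian least-squares form `n·ln(RSS/n) + 2(p+1)` with the residual
  variance counted; AICc by flag.
* **Divergence time**: per participant and stiffness group, real-trial and
  catch-trial filtered accelerations aligned at the true force onset
  (first crossing of y₀ − w) over a 400 ms window; 20-ms bin means, Welch
  t-test per bin; the divergence time is the start of the earliest bin from
  which p < 0.05 holds for all consecutive bins spanning ≥ 150 ms, with a
  no-divergence result otherwise.
* **Acceleration-sign threshold**: across-trial mean acceleration at force
  onset per ln k level, ordered; the first sign change is linearly
  interpolated between the bracketing levels.
* Cohort-level replacements for omnibus ANOVA are the targeted
  comparisons actually interpreted: bootstrap CIs for hysteresis and slope
  difference, and the one-sample behaviour of the inertial lag.

## Problem sizes and determinism

The packaged study runs 18 participants × 450 trials (≈40 s on one CPU for
simulation + preprocessing, ~2 s for all statistics including 10,000
bootstrap repetitions). All randomness flows from one `SeedSequence`
(participant → block → trial), so cohorts are bit-reproducible; the
default resampling seed is 20180607.

## What the generator does and does not emulate

The synthetic cohorts reproduce the design arithmetic, the extreme-field
peak forces (4 N / 14 N), the condition-mean lags (4 / 40 ms, SD 6 ms),
the hysteretic extremum locations, the plateau lag structure, the
real/catch acceleration divergence tens of ms after force onset, and the
coincidence of the acceleration-sign flip with the threshold. Passing
tests therefore show the *estimators* recover such structure when present;
they cannot show that real participants behave this way. Known departures
from real data:

* **No participant heterogeneity.** All simulated participants share one
  threshold and one lag curve, so between-participant variance reflects
  only trial noise: bootstrap CIs are far narrower than in real cohorts,
  cohort R² of the extremum fits approaches 1, and the across-participant
  correlation between the strategy threshold and the acceleration-sign
  threshold is essentially a null statistic here (the generator encodes
  their coincidence at the population level, not participant by
  participant).
* **Catch-trial overshoot is exaggerated** (~5–12 cm vs a few cm in real
  recordings): the slow corrective servo that keeps the acceleration
  divergence detectable and sustained absorbs the uncancelled compensation
  only gradually. No statistic depends on overshoot magnitude.
* A side effect of that overshoot is that the *reconstructed* expected
  impact on stiff catch trials is ~0.1 s late, which displaces the
  anticipatory bump and hence the grip-force rate at force onset on those
  trials; the catch-vs-neighbour rate symmetry therefore holds only in the
  soft half of the stiffness range.
* Sensor noise is white and position-only; no tremor spectrum, no grip
  transducer noise, no trial exclusions or artifacts.
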