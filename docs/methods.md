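# Methods

## The volatility model

Each within-session signal (per-second heart rate in bpm, head-pose
angular velocity in deg/s) and each cohort-level session summary is
modelled as an AR(p) mean process whose innovations carry GARCH(1,1)
conditional variance:

    Z_t = c + a_1 Z_{t-1} + ... + a_p Z_{t-p} + tau_t
    tau_t = sigma_t * eps_t,  eps_t ~ iid(0, 1)
    sigma2_t = delta + beta * tau2_{t-1} + gamma * sigma2_{t-1}

The model assumes a stable mean structure within a session and attributes
burstiness to the variance recursion. The process is covariance-stationary
iff the persistence `beta + gamma < 1`, with unconditional innovation
variance `delta / (1 - beta - gamma)`. The settling speed after an arousal
spike is summarised by the volatility half-life
`ln(0.5) / ln(beta + gamma)` steps (one step = one sample, 1 s at the
default rate). Half-life is reported as infinite when persistence >= 1 and
as not-applicable (NaN) when persistence <= 0, where a geometric decay
description does not apply.

### Estimation

Estimation is two-stage, matching the analysis sequencing (AR first,
variance model on AR residuals):

1. **AR stage** — conditional least squares with intercept; order chosen
   by minimising an information criterion (BIC default) over p = 0..p_max
   on the common sample that conditions on the first p_max observations,
   ties broken toward smaller p.
2. **GARCH stage** — Gaussian quasi-maximum likelihood on the AR
   residuals. The constrained fit (default) enforces delta > 0,
   beta, gamma >= 0, beta + gamma <= 0.999 through a smooth
   reparametrisation (log delta; logistic persistence and its split),
   optimised by Nelder–Mead from the documented start
   (beta = 0.05, gamma = 0.85, delta = 0.1 x sample variance) with
   log-likelihood tolerance 1e-8. The variance recursion is initialised at
   the residual sample variance and evaluated with a C-level linear filter
   (the recursion is linear in sigma2), so a fit costs milliseconds.

Two numerical choices deserve note:

- **Nested boundary point.** The homoskedastic model
  (delta = sample variance, beta = gamma = 0) is always evaluated as a
  candidate. Because gamma is unidentified when beta = 0, the fitted
  parameters are snapped to this boundary point unless the optimised
  likelihood exceeds it by more than 2 log-likelihood units (the AIC cost
  of the two extra parameters). This guarantees the AR-GARCH
  log-likelihood never falls below the constant-variance model it nests,
  and makes the homoskedastic limit return (sample variance, 0, 0)
  deterministically instead of a point on the unidentified ridge.
- **Unconstrained mode.** Published variance equations for these data
  contain negative ARCH coefficients and gamma > 1, which violate the
  recursion's own constraints. `constrained=False` reproduces raw QMLE
  subject only to a positive variance path and warns when the estimate
  leaves the stationarity region. The default is constrained.

Quasi-likelihood means the Gaussian criterion is used even under
heavy-tailed innovations; the generator offers a unit-variance scaled
Student-t option for exactly that experiment.

## Diagnostics

Moment diagnostics use the (m-1)-divisor moment-ratio convention with
kurtosis on the raw scale (normal = 3). Jarque–Bera is
`n (S^2/6 + (K-3)^2/24)` against chi-squared(2); rejection is reported as
evidence of **non**-normality (the standard reading; accounts of these
data sometimes state the inverse). Durbin–Watson, ARCH-LM (default 5
lags; the source analysis states no lag count), Ljung–Box on squared
residuals and the ADF test (constant, AIC lag selection) delegate to
statsmodels. The ADF test requires 25 observations; the assembled
diagnostic battery reports it as NaN below that.

Information criteria are computed in two conventions because the table
format this package reproduces uses nonstandard printed forms
(`SIC = -2ll + (T + T ln M)`, `HQC = -2ll + 2(T + T ln M)`): the printed
forms are the defaults, reported raw and per observation (the tables are
on the per-observation scale, ~5–7 for these sample sizes), and the
textbook BIC/HQC are returned alongside as flagged variants. Criterion
*ordering* across nested models is unaffected by the per-observation
scaling.

Theil's U is the U1 form `RMS(error) / (RMS(forecast) + RMS(actual))`,
which is bounded in [0, 1] and zero iff the forecast is perfect (the
published formula is typographically garbled; U1 satisfies every property
stated for it). Forecast evaluation is in-sample one-step-ahead from the
AR mean model. MAPE is undefined (NaN) when an actual value is zero.

## Synthetic cohort generator

The generator stands in for an unreleased 55-participant x 7-session
dataset. What it emulates:

- **Session traces**: 120 s resting baseline (HR ~ 72 bpm with 1.5-bpm
  wobble) followed by a 600-s exposure block (length chosen as a
  plausible session scale; none is reported) whose HR and head-velocity
  deviations follow the AR+GARCH recursion above. Default trace
  parameters (ar = 0.5; delta = 0.4, beta = 0.15, gamma = 0.75) give
  moderately clustered arousal with persistence 0.9. Sampling is 1 Hz by
  default (the control rule is checked each second; the sensor rate is
  not reported) and configurable.
- **Session summaries**: per-participant values drawn around the
  published per-session means/SDs for time-on-task, head movement and
  heart rate, with 60% of each SD allocated to a stable participant
  intercept. With SDs set to zero the summaries reproduce the target
  means exactly; with small SDs the session-mean trajectories are
  monotone (time increasing, HR and HMV decreasing). The published
  time-on-task table *increases* across sessions while the accompanying
  abstract reports a completion-time reduction; the generator follows the
  printed table and exposes `session_trend="reversed"` rather than
  resolving the contradiction.
- **FSQ scores**: three severity strata (high >= 80, n=18; moderate
  50–79, n=24; low-moderate 40–49, n=13) with the published pre/post
  means/SDs and a pre–post correlation of 0.92 (the value implied by the
  published total-sample paired t).
- **PSQ responses**: 15 items (two 0–100 anxiety ratings, twelve 1–7
  Likert items, one binary adverse-event flag) under calm / anxious /
  random profiles.

What it does **not** emulate: circadian or motion artefacts, sensor
dropout, floor/ceiling effects in questionnaires, or any dependence of
the trace dynamics on controller actions (traces are open-loop). Passing
tests therefore show the analysis machinery is correct under the stated
statistical structure, not that real sessions have that structure.

One structural fact falls out of the generator: the published stratum
summaries are arithmetically incompatible with the published total-sample
FSQ effect size. The spread of stratum mean changes (33.5 / 21.6 / 9.3
points) alone forces sd(diff) ≈ 9, capping the cohort-level dz near 2.6,
whereas the published paired t implies sd(diff) ≈ 4.4 (dz = 5.58). The
generator follows the stratum table, so its cohort-level dz lands near
2.3; this is reported as computed.

## Adaptive controller

The pacing rule is replayed as a deterministic 1-Hz state machine over a
trace. Signals: HR smoothed by a 5-s trailing median and z-scored to the
pre-exposure baseline segment; HMV as the 5-s trailing rolling SD of head
velocity z-scored to its distribution over the first 2 min. Trailing
windows reuse the partial window for the first samples; the median
smoother delays a step excursion's threshold crossing by 2 s.

Rules, evaluated each second of the exposure block (times are seconds
since block start):

- a trigger fires when HR z >= +1.0 has held for 10 consecutive seconds
  or HMV z >= +1.0 for 5; the sustain counter resets on any dip below
  threshold (a 9-s near-miss does not fire); simultaneous HR and HMV
  causes log as one trigger;
- a trigger starts a 30-s breathing prompt (configurable within 30–45 s)
  during which threshold evaluation is suspended and difficulty is held;
- a third trigger within any 300-s window holds difficulty for the
  remainder of the block; 300 s without a trigger steps difficulty up one
  level (never during a prompt, hold, or relaxation scene);
- raw HR above 120 bpm (raw, not smoothed — the conservative choice)
  switches immediately to the relaxation scene, exited after the smoothed
  HR has stayed below the ceiling for 30 consecutive seconds (an exit
  rule had to be chosen; this is the documented default). Accumulated
  triggers persist across a scene switch.

## Outcome and utility statistics

Paired comparisons use the two-sided paired t-test with
dz = t / sqrt(n) = mean(diff)/sd(diff), the convention that reproduces the
published effect sizes exactly (a pooled-SD d does not). No multiplicity
correction is applied by default (none was applied in the source
analysis); a Holm adjustment helper is available. The published
moderate-stratum reduction recomputes to 31.9% (printed 31.8%); the
recomputed value is reported. The FSQ classifier uses the operational
>= 40 inclusion threshold with bands at 40/50/80.

Incremental validity uses participant-level nested OLS fitted by maximum
likelihood with likelihood-ratio tests (chi-squared, df = rank of the
added block, so collinear additions shrink the df), delta AIC and delta
R^2. Mixed-effects extensions are possible but no random-effects
structure is specified for this analysis, so the fully specified fixed
effects route is the default. The EWMA volatility proxy maps a window of
w seconds to decay lambda = 1 - 2/(w+1).

## Problem sizes and tolerances in tests

The test-suite Monte-Carlo settings are: GARCH recovery at
(0.1, 0.1, 0.8), n = 3000, 20 replicates, median |persistence error|
< 0.05; null calibration of Jarque–Bera / ARCH-LM / Ljung–Box at n = 500
over 1000 replicates within 0.05 ± 0.02 plus a KS uniformity check;
long-run variance at n = 50,000 within 3 Monte-Carlo standard errors
(batch-means estimate, since the series is dependent); ADF calibration at
100 replicates; incremental-validity size at 500 replicates (n = 200) and
power at 200 replicates under a population R^2 gain of 0.05 (added
variance 0.05 against residual variance 0.65, giving high LR power at
n = 200). The transportability check (model-based vs proxy-based
incremental decisions agreeing in >= 8/10 replicates) uses 30
participants with n = 800 traces and ARCH coefficient 0.2: shorter
series identify persistence too weakly for the model-based route to be a
meaningful comparator.

## Known limitations

- Only GARCH(1,1) is fitted; no EGARCH/GJR or higher orders.
- Forecast evaluation is in-sample one-step; no multi-step generation.
- The generator's open-loop traces cannot test closed-loop feedback
  effects of the controller on physiology.
- Whether a published model label like "AR(13)" denotes a full lag order
  or a single lag at that index is ambiguous; it is treated as full order
  p throughout.
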