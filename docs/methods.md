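# Methods

## Setting

After percutaneous deep venous arterialization (pDVA) for no-option
chronic limb-threatening ischemia, the arterialized circuit is monitored
by duplex ultrasound (DUS): peak systolic velocity (PSV, cm/s) and volume
flow (VF, mL/min), each measured at the mid and distal segment of the
stented vein.  Falling values warn of a developing stenosis or occlusion
("lesion"), which can be treated by a reintervention if caught early.
`dusjm` implements the statistical machinery for such surveillance series:
mixed-effects trajectories of the log-transformed values, a relative-risk
model for lesion events tied to those trajectories, and dynamic
patient-specific lesion-free probabilities.

## Longitudinal submodel

Log-transformed values (the log transform stabilises variance and makes
the Gaussian error assumption tenable for strictly positive flow and
velocity data) follow a linear mixed model

    y_ij = x(t_ij)' beta + z(t_ij)' b_i + e_ij,
    b_i ~ N(0, D),  e_ij ~ N(0, sigma^2),

with three variants mirroring three ways of handling reinterventions:

* **basic** — time is modelled with a natural cubic spline with one
  interior knot at the median observation time (boundary knots at the
  observed extremes); the spline enters both the fixed and random parts,
  so each patient has a 3-dimensional random effect (intercept + two
  spline columns).  Fixed effects additionally adjust for age, sex and
  reintervention at baseline.
* **reintervention** — linear time plus *time since last reintervention*
  as a time-varying covariate, in both the fixed and random parts
  (unstructured 3x3 D).  The added covariate absorbs the value restoration
  a reintervention produces.
* **per-series** — every inter-reintervention span is an independent
  series with its own clock starting at 0; spline time, no subject-level
  covariates (series of one patient are deliberately treated as unrelated).

Estimation is by maximum likelihood: beta is profiled out by GLS and the
marginal likelihood is maximised over the log-Cholesky factor of D and
log sigma (L-BFGS-B with a derivative-free polish; log-scale parameters
are bounded below at 1e-7 to keep degenerate fits, e.g. noise-free data,
well-defined).  ML rather than REML is the default because the joint model
below needs a single coherent likelihood; REML is available as a flag for
standalone use.  The implementation was cross-checked against statsmodels
`MixedLM`: the two marginal likelihoods agree to 1e-6 at the same
parameters, and our optimiser attains at least as high a maximum on the
study-sized test problem.

Natural splines are built from the truncated-power representation with the
natural (linear-tail) constraints; columns and their first two derivatives
are analytic, which the slope association requires.  Even-count medians
use the mean of the two middle order statistics.  The knot is placed at
the median of all observation times of the dataset being fitted, not per
patient.

## Survival submodel and joint likelihood

Lesion risk follows a relative-risk (proportional hazards) model

    h_i(t | b_i) = h0(t) exp( gamma' w_i + alpha * f_i(t | b_i) ),

where `f` is the *current value* m_i(t) or the *current slope* m_i'(t) of
the subject-specific log trajectory.  The baseline hazard h0 is
piecewise-constant with three internal knots at event-time quantiles
(default; small-sample stable) or Weibull.  Events enter per model
variant: first lesion only (basic), recurrent counting-process intervals
with risk suspended between a lesion and the following reintervention
(reintervention), or one single-event unit per series (per-series).
Within a unit, intervals are conditionally independent given b_i.

The marginal likelihood integrates b_i out by adaptive Gauss–Hermite
quadrature (default 9 points per dimension) centred on the
empirical-Bayes posterior of b_i under the *longitudinal* part of the
model, recomputed from the current parameters at every evaluation.  This
centring makes the likelihood factorise exactly at alpha = 0 — the single
most important correctness oracle, tested to 1e-6 and observed at ~1e-13 —
while remaining smooth in the parameters.  Cumulative hazards over each
risk interval use the 15-point Gauss–Kronrod rule; on toy problems the
quadrature agrees with dense-grid integration to better than 1e-5.

Fitting starts from a two-stage initialisation (separate LMM, then the
hazard parameters with empirical-Bayes trajectories plugged in) and
maximises the joint likelihood by L-BFGS-B with 3-point finite-difference
gradients.  The optimum never falls below the two-stage value (asserted).
Standard errors come from the inverse observed information
(central-difference Hessian); a non-positive-definite information matrix
flags the fit and falls back to a pseudo-inverse with a warning.

### Hazard ratios per 20% decrease

A 20% decrease of the raw value is a change of ln(0.8) on the log scale.
`hr_per_20pct(a, se)` maps the association *per unit decrease* of the log
trajectory to HR = 0.8^(-a) with a Wald 95% CI; for the slope association
the same transform applies per log-unit per month, labelled "within
1 month".  Because the hazard above is parameterised with +alpha on m(t),
a protective marker estimates alpha < 0 and reports are produced with
a = -alpha, so that falling values yield HR > 1 — the presentation
clinicians expect from surveillance data.

## Dynamic prediction

For a subject lesion-free at time t with measurement history y(t) the
lesion-free probability at horizon u is

    pi(u | t) = S(u | b_hat, theta_hat) / S(t | b_hat, theta_hat),

with b_hat the mode of the conditional posterior of b given the history,
survival to t, and the fitted parameters (first-order empirical-Bayes
plug-in; this keeps each update interactive rather than requiring a full
Bayesian refit).  Curves are computed as cumulative-hazard increments per
grid segment, so monotonicity and pi(t|t)=1 hold by construction.
Optional Monte-Carlo bands draw theta from N(theta_hat, vcov) on the
estimation scale (Cholesky/log parameters, so covariance draws stay
valid) and b from the Laplace approximation of its posterior, then take
2.5/97.5 percentiles of the recomputed ratios; bands are widened if
necessary to bracket the plug-in estimate.  Each new measurement advances
t, re-solves b_hat and refreshes the curve; re-applying an identical
measurement is a no-op.

## Synthetic cohorts

No patient data are distributed; the generator produces cohorts with the
structure the analysis assumes and known ground truth:

* trajectory: m_i(t) = mu0 + b0 + (mu1 + b1) t + A(exp(-t/tau) - 1)
  + ln(rho) R_i(t), with mu0 = 5.7 (log mL/min, the published mid-stent
  VF scale), drift mu1 = -0.12/month, maturation transient A = 0.4 with
  tau = 1.5 months, SD(b0) = 0.55, SD(b1) = 0.18, corr -0.2, residual
  sigma = 0.25, restoration factor rho = 1.3 per reintervention;
* hazard: h = exp(xi0 + a_v (m - mu0) + a_s m'), inverted by the
  uniform/cumulative-hazard method with per-cell Gauss–Legendre
  integration and bracketed root-finding (1e-8 months);
* surveillance: visits at 0.5, 1, 1.5, 2, 3, 6, 12 months with 2-day
  jitter and 12% missed visits; administrative censoring at 12 months;
* reinterventions follow each lesion after a Uniform(0.25, 1) month delay
  and resume risk; `single_event=True` stops after the first lesion;
* covariates are drawn at the study cohort's prevalences (40% male,
  hypertension 18/23, diabetes 16/23, hyperlipidemia 17/23, ...) but do
  not drive the simulated hazard (gamma_true = 0).

The `paper_like` preset (23 patients, a_v = -1.3, i.e. HR 1.34 per 20%
decrease) was calibrated once, by a large-n run, to the published cohort
shape — ~70–75% of patients with at least one lesion and ~2 lesions per
patient — by choosing xi0 = -3.5; the `null` preset uses a flat hazard
with a 70% first-event fraction by 12 months (xi0 = -2.3).  The
`strong_slope` preset ties the hazard to the slope only (a_s = -5.6).
All four measurement streams can be produced with random effects shared
across streams at correlation 0.7; the hazard is driven by the primary
stream, reflecting one underlying patency process.

What the generator does **not** emulate: informative visit scheduling
(real patients are recalled sooner when values fall), per-patient
variation in follow-up length (a single administrative horizon is used),
measurement error that depends on operator or site, multiple simultaneous
lesion locations, and mortality/amputation as competing risks.  Passing
tests therefore demonstrate internal consistency of the estimation
machinery under the model's own assumptions, not robustness to these
real-data features.

## Validation studies and problem sizes

The published hazard-ratio table cannot be reproduced without the original
23 patients' measurements, so the estimator is validated by closure of the
simulate → build → fit loop (module `dusjm.validation`):

* **CI coverage** — 25 replicates of 200 single-event units (~5 visits
  each) with a_v = -1.3: the Wald 95% CI for alpha covers the truth in at
  least 90% of replicates.
* **Null calibration** — 100 replicates of 100 units with a_v = 0: the 5%
  Wald test rejects with empirical rate inside (0.01, 0.12).
* **Factorisation** — at alpha = 0, joint = LMM + hazard log-likelihoods
  to 1e-6.

These studies use linear trajectories (maturation transient switched off),
a random-intercept+slope longitudinal spec without covariate adjustment,
and a Weibull baseline — a 2-dimensional random effect keeps a
125-replicate study tractable on one core while exercising the identical
quadrature, optimisation and SE code paths as the 3-dimensional spline
fits, which are themselves fitted (and cross-checked against statsmodels
and between baseline families) on study-sized data in the test suite and
the end-to-end report.

## Numerical choices and edge cases

* Quadrature: 9 GH points/dimension by default (5 in the CLI report for
  the 3-dimensional spline fits); K15 Gauss–Kronrod for all hazard
  integrals, split at baseline-hazard knots and reintervention times.
* Optimisation: L-BFGS-B, ftol 1e-11; log-variance parameters bounded
  below; joint fits never return a point below their two-stage start.
* Fisher exact test: two-sided by the point-probability convention (sum of
  hypergeometric probabilities not exceeding the observed table's, with a
  1e-12 relative tolerance for float ties), clamped to 1.  This convention
  reproduces all six verifiable printed baseline p-values to 3 decimals.
* Mann–Whitney: exact permutation null when the pooled sample has at most
  20 observations and no ties; otherwise normal approximation with tie and
  continuity corrections.  Quartiles are type-7 (linear interpolation).
* Time unit: months, 1 month = 30.4375 days (slope HRs are per month, so
  months are the model's native unit).
* time-since-reintervention is 0 before the first intervention (keeps the
  covariate continuous at baseline).
* Measurements at an event time belong to the interval ending there
  (closed right endpoint); measurements between a series-ending lesion and
  the next reintervention are dropped from the per-series dataset with a
  logged warning, as they precede re-treatment.
* Basic-variant survival uses first events only; the recurrent-event
  information is carried by the reintervention (counting process) and
  per-series variants.  Reports flag this.
* Lesion-free patients are censored at their last follow-up contact.

## Known limitations

* The per-unit likelihood is fully vectorised but gradients are finite
  differences; very high-dimensional random effects (beyond the 3 used
  here) would need analytic scores.
* Dynamic-prediction bands propagate parameter and random-effect
  uncertainty by normal approximations, not by full posterior simulation.
* No multivariate (4-stream) joint model, no cure fraction, no interval
  censoring, no Bayesian estimation — single-stream analyses mirror how
  the four streams are reported separately.
* Wald inference on alpha at n = 23 is fragile (as the wide published
  intervals suggest); the validation studies quantify behaviour at n = 100
  to 200, not at the study's own size.
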