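# Methods

## The problem

In cohorts of chronic kidney disease (CKD) patients, progression to an
advanced stage — here stage 5, a measured GFR (mGFR) below
15 mL/min/1.73 m² — is only observed at intermittent clinic visits. The
onset time is therefore *interval censored* between the last visit with
mGFR ≥ 15 and the first evidence of stage 5 (a sub-threshold measure,
dialysis initiation, or preemptive transplantation). Death is observed
exactly through registry linkage and acts as a *competing event*: a patient
who dies between their last healthy visit and death may or may not have
passed through stage 5 unobserved. Standard survival analyses resolve this
by fiat — censoring the progression clock at death assumes no unobserved
passage — whereas the illness-death model for interval-censored data
integrates over the unknown onset time.

## Models

All transitions carry Weibull proportional-hazards intensities

    h(t | z) = (a/b) (t/b)^(a-1) exp(β·z),    Λ(t | z) = (t/b)^a exp(β·z)

with shape `a`, scale `b` (years since inclusion) and transition-specific
log hazard ratios `β`. Four analyses are implemented:

* **M1** — time from inclusion to stage diagnosis; undiagnosed subjects
  censored at death or the latest news. (A censor-at-last-visit variant is
  available as `make_m1(..., censor_dead_at="last_visit")` for bias
  experiments; it conditions on the future and is not the default.)
* **M2** — time to death before diagnosis; diagnosed subjects censored at
  diagnosis (cause-specific competing-risks construction).
* **M3** — time from diagnosis to death before transplantation, on the
  time-since-diagnosis clock; subjects diagnosed by preemptive transplant
  do not contribute.
* **M4** — the three-state illness-death model (healthy 0 → stage 1 →
  dead 2, plus direct 0 → 2). Each subject contributes one of three
  likelihood patterns; patterns with an unknown onset time integrate
  `S₀(u) h₀₁(u) exp(−(Λ₁₂(end) − Λ₁₂(u)))` over the feasible onset
  interval (see the `illness_death` module docstring for the exact forms).
  Death follow-up is censored at nonpreemptive transplantation in M3 and
  M4 alike.

### Clocks

The 1→2 intensity in M4 runs on the **time-since-inclusion (Markov)
clock**: the onset time is unknown for interval-censored subjects, so a
time-since-onset clock would be circular inside the onset integrals. M3,
by contrast, uses the time-since-diagnosis clock. The M3 vs M4-12
comparison therefore contrasts slightly different estimands even with
perfect data; the package reports both as the respective analyses define
them.

### Latently diseased survivors

Subjects alive at the end of follow-up whose last healthy visit precedes it
may harbor an undiagnosed stage; by default their likelihood includes that
possibility (`undiagnosed_illness_for_alive=True`), symmetric with the
treatment of deaths. Setting the flag to `False` reproduces the stricter
"known healthy at the end" convention.

### Inference

Maximization is quasi-Newton (L-BFGS-B) on `(log a, log b, β)` per
transition — positivity unconstrained — with covariates centered
internally for conditioning and the baseline scale mapped back through
`b_raw = b_c · exp(β·c̄/a)` (delta-method covariance adjustment included).
Starting values: shapes 1, scales from crude event rates, β = 0. The
covariance is the inverse observed information from central finite
differences at the optimum; confidence intervals and p-values are Wald.
Hazard ratios are reported per 10-year age increase, per
10 mL/min/1.73 m² mGFR increase, per unit of log PCR, and female vs male.

### Numerics

Onset integrals use Gauss–Legendre quadrature mapped affinely onto each
subject's interval, evaluated in log space (log-sum-exp) with cumulative
hazard exponents clipped at 250 to keep the objective finite at extreme
trial parameters. **32 nodes (the default) matter**: with 16 nodes,
pattern-(ii) intervals spanning many years (a death long after the last
healthy visit) acquire a quadrature error large enough to shift the 0→2
and 1→2 coefficient estimates by ~0.02–0.03 on the log-HR scale at
n = 3000; at 32 nodes doubling to 64 changes the total log-likelihood by
less than 1e-8. Degenerate follow-up times (e.g. death on the diagnosis
day in M3) are floored at half a day with a logged warning.

### Exactly observed onsets

`IDObservation.illness_exact` marks onsets known exactly (continuous
monitoring); the onset integral collapses to the exact-onset density and
the likelihood factorizes into cause-specific 0→1/0→2 pieces and a
left-truncated 1→2 piece. This limit is used as an independent oracle in
the tests: the joint fit must match separate cause-specific Weibull fits.
Visit-derived data never sets the flag; an unflagged interval with L = R is
rejected as degenerate.

## Progression probabilities

For a covariate profile z the cumulative incidence of stage entry under
the illness-death model is

    F₀₁(t | z) = ∫₀ᵗ S₀(u | z) h₀₁(u | z) du,

counting entry regardless of subsequent death; the stricter "in stage and
alive" state-occupancy curve is exposed separately
(`illness_alive_probability`). The naive counterpart from M1 is
`1 − exp(−Λ(t|z))`, which ignores both competing death and interval
censoring and is expected to under-estimate progression when both are
present — the package's comparison curves flag any grid point where the
ordering reverses.

## The synthetic cohort generator

No public data exist for this design (the motivating cohort is a private
hospital cohort), so the generator is a first-class component. It draws
latent three-state Weibull paths by inverse transform (competing
cause-specific draws from state 0; conditional cumulative-hazard inversion
for 1→2) and overlays the observation process:

* **Covariates** (marginals only, no correlations): sex female with
  probability 0.315; age ~ N(58.9, 15.1²) years; mGFR ~ N(43.1, 18.4²)
  truncated above 15.5; log PCR ~ N(3.31, 1.5²). Effects act relative to a
  reference profile (male, 60 y, mGFR 43.1, log PCR 3.31) so baseline
  scales stay interpretable.
* **True effects** (default scenario): proteinuria and low mGFR drive
  progression (log-HR 0.605 per log-PCR unit, −0.1079 per mGFR unit on
  0→1); age drives both death transitions (0.0784 and 0.0593 per year);
  modest female advantages on death.
* **Visit process** (not specified by any source; our choice, report it
  with any result): gaps ~ N(1.05, 0.3²) years truncated at 0.1, per-visit
  dropout probability 0.22, baseline measure at t = 0 implicit. Visit GFR
  values only encode detection — below threshold iff the visit falls after
  the latent onset — via a linear-decline proxy with noise; they are not a
  longitudinal trajectory model.
* **Renal replacement therapy**: conditional on onset, preemptive
  transplant with probability 0.05 or dialysis with probability 0.45
  within 0.8 y of onset (either acts as the diagnosis); nonpreemptive
  transplant after dialysis with probability 0.30 (exponential delay,
  mean 2 y) censors death.
* **Administrative censoring**: per-subject uniform on (0.3, 9.3) years,
  emulating staggered inclusion with a fixed study end. Death inside the
  window is always recorded (registry ascertainment), even without visits.

The default baseline scales (14, 78, 13 years for 0→1, 0→2, 1→2 with
shapes 1.3, 1.1, 1.0) were calibrated once against the observed-event
profile the scenario emulates — ≈18.6% observed diagnoses (roughly half by
dialysis), ≈7.3% deaths without diagnosis, ≈3.8% after, mean follow-up
≈4.3 y, ≈2.6 GFR measures — and are config values, not constants.
Per-subject random streams are keyed by (master seed, subject index), so
growing `n` never reshuffles earlier subjects.

### Informative observation in the default scenario

The dialysis/preemptive diagnosis route makes the examination process
*informative*: detection arrives shortly after onset regardless of the
visit schedule, violating the independent-inspection assumption of the
interval-censoring likelihood. Fitting the illness-death model to such
data inflates the 0→1 rate (the real study design shares this feature, and
the standard analysis ignores it there too). The default scenario keeps
the RRT route for structural realism; all quantitative parameter-recovery
checks use visits-only scenarios (RRT probabilities 0), where a score test
at the true parameters confirms exact generator/likelihood consistency and
50-replicate recovery at n = 3000 shows ≥99% of pivots within 3 SE and
mean |log-HR bias| < 0.02. Passing those checks therefore demonstrates
correctness of the estimator under non-informative observation, not
robustness to informative inspection, dependent visit schedules, covariate
correlations, or non-Weibull baselines — none of which the generator
emulates.

## Problem sizes used in the shipped checks

Likelihood-oracle comparisons use 50 randomized observations against
1e5-point trapezoid integration; the factorization limit uses n = 2000;
recovery uses 50 replicates of n = 3000; the directional
model-comparison experiments use 50 replicates of n = 800 with wide
(≈1.8 y) visit gaps; the end-to-end pipeline example uses one cohort of
n = 1519. These sizes make the full suite reproducible on a single CPU in
minutes while keeping Monte-Carlo error well below the tolerances tested.

## Known limitations

* The 1→2 clock choice (since inclusion) and the latently-diseased-survivor
  convention are config-exposed decisions; neither is externally fixed.
* No left truncation on the age scale (time-on-study is the only time
  scale), no spline/piecewise baselines, no frailty, no time-varying
  covariates, no landmark prediction, no confidence bands on probability
  curves.
* A first mGFR measure below threshold is treated as absorbing: recovery
  above 15 after a sub-threshold measure is not modeled (the stage is
  clinically hardly reversible, and renal replacement therapy makes the
  definition operational).
* The Wald covariance comes from a finite-difference observed information;
  for very small event counts it can be singular, in which case standard
  errors are reported absent with a warning rather than guessed.
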