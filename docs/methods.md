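# Methods

This note documents the models, the parameter choices behind the shipped
defaults, the numerical decisions, and what the synthetic-data tests do
and do not establish.

## Risk equation and recalibration

The 10-year risk of a major cardiovascular event is
`1 − S₀^exp(lp − mean_lp)` with `lp = β·x` over eight covariates.  The
transformation recipe is declarative metadata in the coefficients JSON and
defaults to natural logs of age, total cholesterol, HDL cholesterol and
systolic blood pressure, with sex-stratified fits; identity transforms and
an unstratified fit are supported switches.  Published guideline
coefficients are deliberately not hardcoded: any analysis of a specific
cohort starts by refitting anyway (occupational cohorts, for instance, run
systematically healthier than the populations guideline equations were
derived in, so the unrevised equation overestimates absolute risk), and
loading coefficients from a versioned file removes transcription risk.

`refit_coefficients` is a Cox proportional-hazards fit (lifelines
`CoxPHFitter`).  Exact duplicate rows are collapsed to frequency weights
before fitting; this makes the estimate exactly invariant to duplicating
the dataset, which the Efron tie approximation otherwise breaks, and it is
cheaper.  The 10-year baseline survival `S₀` is the predicted survival at
the covariate-mean profile, linearly interpolated between event times at
t = 10; if follow-up ends earlier the last value is carried forward with a
warning.  With fewer than two events per stratum the fit refuses rather
than returning noise.

Risk categories are lower-inclusive half-open bands — [0, 2.5%),
[2.5, 5%), [5, 7.5%), [7.5%, 1] — so a risk of exactly 7.5% is HIGH.
The high band can be split at 15% (HIGH/VERY_HIGH) for descriptive work.
Percent-versus-fraction handling lives at exactly one boundary: the whole
API speaks fractions; only report formatting multiplies by 100.

**Bundled default coefficients** (`data/default_coefficients.json`) are a
synthetic calibration, not a published equation: plausible log-hazard
magnitudes (positive for age, total cholesterol, SBP, treatment, smoking,
diabetes; negative for HDL), with a per-sex scale and baseline survival
solved once so that the default synthetic cohort lands near a 54/30/9/7%
LOW/INT_LOW/INT_HIGH/HIGH baseline split (men ≈ 45/35/11/8, women ≈
73/19/5/3).  The file is versioned `synthetic-default-1` and regenerated
only if the generator's covariate distributions change.

## Synthetic cohort

The generator emulates a middle-aged occupational cohort under 5-yearly
screening with registry follow-up.  Defaults: 70% male; baseline age with
*truncated* mean 50 and SD 6 on [40, 64] — the parent normal is solved
numerically so the observed moments match after truncation; SBP 120.4
(13.5) mm Hg; total cholesterol 6.5 (1.1) mmol/L; HDL 1.3/1.7 (0.4) by
sex; smoking 12%/16%, antihypertensives 5%/9%, diabetes 2%.  Covariates
are drawn independently, which understates the real-world clustering of
risk factors; the moments are matched, the copula is not.  Five exams at
5-year spacing, per-exam attendance 0.9 (missing completely at random;
baseline is always attended), optional ±0.5-year uniform exam jitter
(off by default).

*State mode* simulates exact category paths by the Gillespie algorithm
from an intensity matrix and reads them off at exam times; EVENT/DEATH are
recorded at their exact times by default (registry follow-up) or at the
next scheduled exam when interval censoring of absorptions is wanted.
*Covariate mode* drifts the risk-factor profiles (defaults: SBP
+0.45 mm Hg/y, TC +0.02 mmol/L/y, HDL −0.004 mmol/L/y, random-walk noise,
3%/y smoking cessation, constant competing event/death hazards) and
derives the observed category through the risk equation at each exam.
Both modes return the generating ground truth for recovery testing, and
all randomness descends from the single config seed.

Passing tests on these data show that the estimators recover the
generating process under its own assumptions (time-homogeneous Markov
progression, MCAR attendance, proportional hazards).  They do not show
robustness to informative non-attendance, age-inhomogeneous progression,
or measurement error in covariates — all outside the generator.

## Multistate model

States: transient risk categories plus absorbing EVENT and DEATH.  Two
variants: *descriptive* (five transient categories with the high band
split, adjacent moves in both directions everywhere) for describing
observed progression and recovery, and *policy* (four transient
categories, no backward move out of HIGH) for deriving screening
intervals — once someone crosses the treatment threshold the policy
question is detection, not re-classification.  Transitions are restricted
to adjacent categories because panel data observed every ~5 years cannot
distinguish a direct two-category jump from two quick adjacent ones; a
fully-connected mask is available as a switch.

The likelihood treats category observations as interval-censored
snapshots and absorptions as exactly dated; the `exact_death_times` flag
applies the density factor `[P(Δt)Q]_{r,a}` to both EVENT and DEATH.
Observation pairs are grouped by gap length into count matrices, and
`P(Δt)` for the (possibly many, with exact absorption dates) distinct gaps
is computed in one batch by eigendecomposition `V exp(Dt) V⁻¹`, validated
by a row-sum check with a per-gap `scipy.linalg.expm` fallback for
non-diagonalisable rate matrices.

Fitting maximises over the log-rates of the allowed transitions (BFGS),
which enforces every intensity-matrix invariant by construction:
positivity, masked zeros, rows summing to zero.  Convergence is the
optimiser's own success flag or a gradient negligible relative to the
log-likelihood scale (finite-difference gradients routinely trigger
"precision loss" at genuine optima).  The tolerance knobs are exposed;
the headline robustness property — different initial rate matrices reach
the same optimum to four significant figures — is tested directly.  95%
CIs are Wald intervals on the log scale from a central-difference observed
information matrix, exponentiated; a singular information matrix marks CIs
unavailable rather than fabricating them.  A transient state that never
appears as the origin of an observation interval has its exit rates pinned
at their initial values, with a warning and a flag in the result.

Summaries: per-visit sojourn time −1/q_ss; expected *total* occupancy
before absorption (rows of (−Q_TT)⁻¹), reported alongside because a
revisited category accumulates more than one visit's worth of time;
next-state probabilities q_sr/(−q_ss); occupancy π·P(t).  First-passage
times to HIGH solve `(−Q_AA)h = q_{·,HIGH}` and `(−Q_AA)m = h` over the
pre-HIGH states, and the reported mean is `m/h` — i.e. *conditional on
reaching HIGH before EVENT/DEATH*.  This convention is a genuine choice
(one could instead treat absorption as an infinite passage time); the
conditional version matches reporting one progression time per starting
category and is validated against Gillespie simulation.

**Calibrated default intensities.**  The defaults anchor to reported
summaries: sojourns 8.7 y (LOW) and 3.9 y (INT_HIGH); conditional mean
first-passage times to HIGH of 19.8 y from LOW and 11.1 y from INT_LOW;
and, in the descriptive variant, a 6.7 y HIGH sojourn with exits split
42.7/47.2/4.5/5.6% (back / very-high / event / death).  The INT_LOW
sojourn (5.7 y) and VERY_HIGH sojourn (9 y) are **not** reported anywhere;
they are package defaults derived from the first-passage identities and
should not be quoted as estimates.  Backward rates were solved numerically
so the anchors hold with every allowed rate strictly positive; keeping a
small identifiable INT_HIGH→INT_LOW rate moves that state's first-passage
anchor from 3.9 to 4.4 y, a trade-off made for testability of the full
rate set.  Q is time-homogeneous: age enters only through the risk score
that defines the states.

## Screening evaluation

Screens start at baseline; each next screen follows the interval keyed to
the category observed at the last screen; intervals are ≥1 year (the
high-risk management interval) on a half-year grid.  Detection uses the
true state at screen time — no measurement noise — matching the Markov
abstraction the intervals are derived from.  Unrecognised time accrues
from the *first* entry into the high band until detection, absorption or
the 20-year horizon, even if the person dips back below the threshold
before the detecting screen.  After detection a person leaves the
evaluated programme; their subsequent management screens are not billed to
the screening budget (which is why earlier-detecting protocols can still
be cheap).  People already high at baseline are excluded — they are under
management from day one.  Attendance at scheduled screens is perfect by
default.  Unrecognised time is truncated at the horizon for late entrants.

Comparisons are paired: every protocol sees the same trajectories, so
differences are purely schedule effects.  CIs are person-level bootstrap
percentiles (500 resamples by default, seeded).  The default grid of 21
alternative protocols spans low 6–12 y, intermediate-low 3–5 y,
intermediate-high 1–2 y (monotone non-increasing triples, including 7-4-1
and 10-5-2) and is fully overridable — the exact published list of 21 is
not enumerated anywhere, so the grid is a reconstruction.

One caveat found during development and worth stating: *pathwise*
monotonicity under element-wise interval shortening is not a theorem.  A
shorter low-risk interval can schedule a screen just before a category
transition, observe the lower category, and set a longer next gap than the
unshortened protocol would have (schedule resynchronisation).  In
aggregate over a cohort these resynchronisation cases are rare and the
monotonicity holds comfortably; the tests assert the aggregate property.

## Economics

All conversions are linear in the person-years of earlier statin
treatment, which by construction equals the reduction in unrecognised
high-risk person-years versus the reference protocol.  Constants (per
person-year under statin vs placebo): 0.01 events prevented, 0.00906
QALYs, £47.33 saved; adverse incidences 0.0015 (diabetes), 0.00015
(haemorrhagic stroke), 0.0001 (myopathy).  These trial-derived
per-person-year constants are treated as already discounted (3.5%/year in
their source); applying a second discount would not reproduce the
published comparison arithmetic, so the `discount` operation exists for
sensitivity analyses only.  Health checks cost £5.11 + £13.28 = £18.39
each, undiscounted by design (discounting deferred screens would flatter
protocols that screen late); each *performed* screen is billed one
invitation plus one screening — whether invitations to non-attenders were
billed in the source tables is unstated, and this package's convention is
the performed-screen one.  Total costs are health-check costs minus
savings, with savings carried as positive numbers.  Everything is stored
at full precision; rounding happens only in report formatting.  Currency
is GBP at the source price year, no inflation adjustment.

`population_scale` re-weights per-category cohort totals to an external
population: quantities are converted to within-category per-person rates
and multiplied by the target category head counts (target size × an
externally supplied risk-category distribution, e.g. from a national
primary-care risk model).  Outputs are per-year averages over the
evaluation horizon when the inputs are — a steady-state first-year figure
would need a different person-time basis.

## Pipeline and reproducibility

`run_pipeline` chains synth → fit → evaluate → econ → report, writing
every intermediate artifact (panel CSV, intensity-matrix JSON, comparison
CSV, economics CSV) plus a manifest with the seed, a canonical config
hash and library versions.  Stage seeds are spawned from the single run
seed via `numpy.random.SeedSequence`; floats are serialised with a fixed
format, making bundles byte-identical across runs of the same config.
Protocol evaluation simulates trajectories from the *fitted* intensity
matrix, mirroring an analysis in which the model, not the raw panel, is
the basis for policy simulation.

## Problem sizes used in the shipped checks

The test suite and acceptance script use cohorts of 2 000–10 000 people
for moment and split checks, panels of 4 000 people × 5 exams × 20 seeds
for the CI-coverage experiment, 20 000–50 000 Gillespie paths for
Monte-Carlo cross-checks, and 6 545 simulated 20-year trajectories for
protocol comparison.  These sizes give Monte-Carlo error comfortably
inside the asserted bands (3–4 SE) while keeping a full run to a few
minutes; they are package choices and can be scaled up freely.

## Known limitations

- Time-homogeneous intensities; no covariate effects on transition rates
  (no proportional-intensity multistate regression, no hidden-Markov
  misclassification layer).
- Risk-factor covariates are generated independently; real risk factors
  cluster, so covariate-mode panels are optimistic about identifiability.
- Perfect screen attendance in the evaluator's default; the cohort
  generator's non-attendance is MCAR only.
- The Wald CIs on log-rates undercover for very rare transitions (few
  observed exits); the coverage experiment uses rates where counts are
  adequate, as any real analysis should verify for its own data.
- Statin benefit constants are per-person-year averages from one trial
  population; compliance and effect heterogeneity are not modelled.
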