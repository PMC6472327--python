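# cvdscreen

How often should people *below* the cardiovascular treatment threshold be
re-screened?  Primary-prevention guidelines typically say "every 5 years"
for everyone at low or intermediate risk, an interval based on expert
opinion rather than on observed risk progression.  `cvdscreen` implements
a complete pipeline for answering the question from longitudinal screening
data: it models how people move between 10-year-risk categories over time,
simulates alternative risk-category-specific screening schedules, and
prices the difference in events prevented, QALYs and costs.

It is written for epidemiologists and health-economics modellers.  Because
the underlying cohort data are access-controlled, the package ships a
synthetic panel-cohort generator with the same statistical structure
(5-yearly exams over ~20 years, registry-dated events and deaths, exam
non-attendance), so every stage is runnable and testable out of the box.

## The model

**Risk equation.** Each person-exam gets a 10-year probability of a major
cardiovascular event (MI, coronary death, fatal or non-fatal stroke) from a
pooled-cohort-style equation

```
risk(x) = 1 − S₀ ^ exp(β·x − β·x̄)
```

with covariates age, sex, total and HDL cholesterol, systolic blood
pressure, antihypertensive treatment, smoking and diabetes (log transforms
on the continuous terms, sex-stratified fits).  The equation is
recalibrated to any cohort by a Cox proportional-hazards refit
(`cvdscreen.risk.refit_coefficients`), with `S₀` the 10-year baseline
survival at the covariate mean.  Predicted risk is binned into the
guideline categories LOW (<2.5%), INT_LOW (2.5–<5%), INT_HIGH (5–<7.5%)
and HIGH (≥7.5%, the statin-consideration threshold; optionally split at
15% into HIGH/VERY_HIGH).

**Progression model.** Category membership is observed only as snapshots
at exams (panel data), so progression is modelled as a continuous-time
Markov chain with intensity matrix Q over the transient risk categories
plus two absorbing states, EVENT and DEATH.  Transition probabilities over
a gap t are `P(t) = expm(Qt)`; the panel log-likelihood multiplies
`P_{rs}(Δt)` factors between consecutive observed states and uses the
exact-time density `[P(Δt)Q]_{r,a}` for registry-dated absorptions.
`cvdscreen.markov.fit` maximises this likelihood over log-rates (BFGS)
with Wald CIs from the observed information; sojourn times (−1/q_ss),
next-state distributions, first-passage times to HIGH and occupancy
distributions all derive from the fitted Q.

**Screening simulator.** A protocol such as `7-4-1` assigns re-screening
intervals to LOW/INT_LOW/INT_HIGH.  Screens are simulated over exact
trajectories; the time between truly crossing the 7.5% threshold and the
first screen that detects it is *unrecognised high-risk person-time*.
Protocols are compared pairwise on common trajectories against the uniform
`5-5-5` reference.

**Economics.** The reduction in unrecognised person-years equals the
person-years of earlier statin treatment, converted with trial-derived
constants: 0.01 events prevented, 0.00906 QALYs and £47.33 saved per
person-year, plus adverse-event incidences (diabetes 0.0015, haemorrhagic
stroke 0.00015, myopathy 0.0001 per person-year).  Health checks cost
£5.11 (invitation) + £13.28 (screen) each, undiscounted.

## Worked example

```python
from cvdscreen import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(seed=1, cohort=CohortConfig(n_individuals=2000),
                n_eval=6545, n_boot=200)
artifacts = run_pipeline(cfg, "out")
print(artifacts["table2"].round(2).to_string())
```

which generates a synthetic panel, fits the multistate model to it,
simulates 6545 low/intermediate-risk people for 20 years under each
protocol from the *fitted* intensities, and prints:

```
                                   5-5-5   10-5-2    7-4-1
n_people                         6095.00  6095.00  6095.00
unrecognised_person_years        8027.58  5866.51  3259.45
delta_unrecognised_person_years     0.00 -2161.08 -4768.13
events_prevented                    0.00    21.61    47.68
adverse_diabetes                    0.00     3.24     7.15
adverse_haemorrhagic_stroke         0.00     0.32     0.72
adverse_myopathy                    0.00     0.22     0.48
qalys_gained                        0.00    19.58    43.20
health_check_costs_kgbp           395.38   355.98   503.54
statin_savings_kgbp                 0.00   102.28   225.68
total_costs_kgbp                  395.38   253.69   277.86
delta_total_costs_kgbp              0.00  -141.69  -117.52
```

Read column by column: under uniform 5-yearly screening this cohort spends
~8000 person-years unrecognised above the treatment threshold.  Switching
to 7-4-1 removes ~4800 of those person-years (a ~60% reduction), which at
0.01 events per treated person-year prevents ~48 events and gains ~43
QALYs, at the price of more screens (higher health-check costs) largely
offset by statin savings; 10-5-2 prevents fewer events but is the cheaper
protocol overall.  Both risk-category-specific schedules dominate the
uniform one on unrecognised time — the pipeline's central finding.

The same stages are available from the shell:

```bash
cvdscreen all --seed 1 --out out/
cvdscreen synth --seed 1 --out out/
cvdscreen fit --panel out/panel.csv --out out/q.json
cvdscreen evaluate --q out/q.json --seed 1 --out out/comparison.csv
cvdscreen econ --comparison out/comparison.csv --out out/table2.csv
cvdscreen report --bundle out/
```

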