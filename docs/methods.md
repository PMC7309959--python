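# Methods

## Scope and model structure

`ra223cea` implements a cohort cost-effectiveness model comparing radium-223
dichloride plus best supportive care (BSC) against BSC alone in patients with
metastatic castration-resistant prostate cancer (mCRPC) who have not received
prior chemotherapy, from the perspective of the Spanish National Health
System (euros, 3% annual discounting, 10-year horizon, 1-week cycles).

Five mutually exclusive health states are tracked: progression-free without a
symptomatic skeletal event (SSE), progression-free with SSE, progressed
without SSE, progressed with SSE, and dead.  Everyone starts progression-free
without SSE; death is absorbing.

### Occupancy: partitioned survival

Only three marginal time-to-event laws are available per arm — overall
survival (OS), progression-free survival (PFS, a composite
progression-or-death endpoint) and time to first SSE — each a lognormal
distribution on time in weeks with parameters `scale = mu` and
`shape = log(sigma)` (so the negative printed shapes translate to dispersions
just below 1).  State occupancy therefore uses the partitioned-survival
("area under the curve") construction with min() guards enforcing logical
nesting:

```
alive         = S_OS(t)
PF & alive    = min(S_PFS, S_OS)(t)
noSSE & alive = min(S_SSE, S_OS)(t)
PF_noSSE      = min(S_PFS, S_SSE, S_OS)(t)
```

and the remaining states by subtraction.  No transition matrix is assumed;
this is standard practice for trial-based oncology models when only marginal
curves are published.  The min() guards correspond to a comonotone coupling
of the three clocks, and the occupancy is validated in the test suite against
a microsimulation with exactly that coupling (one uniform draw per patient
driving all three inverse survival functions).

### Event streams: hazard flows

Costs attach to *events* (deaths, progressions, first SSEs), which net
occupancy differences cannot count — once SSE patients start dying, the
"alive with SSE" pool shrinks even while new SSEs keep occurring.  Event
streams are therefore computed as per-cycle hazard flows over the at-risk
pool:

* deaths: `S_OS(t_{k-1}) - S_OS(t_k)`;
* progressions: PFS-curve events minus the deaths attributable to the
  progression-free pool, `max(0, -d[PF&alive] - deaths_k * (PF&alive)/alive)`
  — equivalently the latent progression hazard `h_PFS - h_OS` applied to the
  progression-free occupancy, so a death without progression is never counted
  as a progression;
* first SSEs: the marginal SSE hazard applied to the independent at-risk pool,
  `S_OS * S_SSE * h_SSE` (the SSE endpoint is a death-censored marginal law,
  not a composite).

These flows equal the cumulative incidences of an independent-clocks
microsimulation, against which they are tested.  Occupancy (comonotone
reading) and event flows (independent reading) are thus two deliberately
different couplings of the same marginals; the published model does not state
how its curves were combined, and this hybrid is the package's own
construction, selected because it reproduces both the published state-time
driven cost categories and the event-driven ones with plausible unit costs.

## Outcomes

QALYs multiply state occupancy by state utilities (per arm, from trial EQ-5D
measurements): progression-free utilities differ by arm (0.617 radium-223 vs
0.554 BSC without SSE); after progression both arms share the same values
(0.511 without / 0.474 with SSE), reflecting that patients are off treatment
once progressed.  The arm-specific progression-free utility applies for the
whole progression-free period; a config switch
(`utility_treatment_window_weeks`) restricts it to the on-treatment window
instead, reverting to the BSC value afterwards.

Accrual counts state membership at the start of each weekly cycle and
discounts at the cycle-start time with `(1+r)^(-t/52)`; event costs discount
at the end of the event's cycle.  No half-cycle correction is applied by
default (with weekly cycles it changes 10-year totals by well under 0.5%); a
`half_cycle_correction` switch exists and is exercised in tests.  Life-years
are reported undiscounted (QALYs and costs always discounted); the discounted
value is also computed and a switch selects it for reporting.

## Costs

Nine categories per patient: drug (mean 6.00 injections x 4532.50 EUR,
charged undiscounted — the whole course falls in the first 24 weeks),
administration, patient management (routine monitoring frequencies by disease
phase plus an aggregate weekly supportive-care cost), hospitalization,
day-care and physician visits (annual use rates by phase x SSE status x arm),
second-line treatment (progression incidence x uptake proportion x unit
cost), end-of-life care (death incidence x 4181.67 EUR), SSE treatment (first
SSE incidence x type-mix mean cost) and adverse-event treatment.

Adverse-event rates are weekly on-treatment probabilities; they are applied
to the progression-free occupancy inside a 24-week treatment window (six
4-weekly injections), since treatment stops at progression and the placebo
arm's follow-up was comparable.  Each event costs
`p_hosp x days x hospital-day cost + (1 - p_hosp) x outpatient cost`, with
one inpatient day per hospitalized event as the (overridable) default.  How
hospital days per event were counted in the source analysis is unknown, so
this category is accurate to order of magnitude only (~100-200 EUR per arm
out of ~55 000-65 000 EUR totals).

### Calibrated unit costs

Several unit costs behind the published category totals are not printed
anywhere (monitoring procedures, non-radiotherapy SSE types, second-line cost
per patient, administration fee, the aggregate weekly supportive-care cost).
Each is an explicit config field flagged `calibrated: true`, with a default
chosen once so that base-case category totals approach the published cost
breakdown, and is listed in every run manifest:

* administration: 58 EUR/injection (348/6);
* monitoring: CT 136, bone scan 168, blood count 4.50, PSA test 12 EUR
  (plausible Spanish tariffs);
* other weekly management cost: 143.47 (stable) / 653.23 (progressed)
  EUR/week — solved linearly so both arms' patient-management totals equal
  the published 25 238 / 39 881 EUR;
* second line: 2797 EUR per treated patient (least squares against the
  published 654 / 1081 EUR given modelled progression incidence);
* SSE types: fracture 2500, spinal cord compression 4000, surgery 6000 EUR
  (least squares against the published radium-arm SSE total; the BSC SSE
  total cannot be matched simultaneously because its radiotherapy share alone
  already exceeds it at the printed radiotherapy price).

All are overridable and take part in one-way and probabilistic sensitivity
analysis with the +-20% rule used for unit costs.

## Sensitivity analysis

**One-way (tornado).**  Every parameter with a registered range is pushed to
its lower and upper bound, both arms re-evaluated, and parameters ranked by
absolute ICER spread.  Ranges are 95% confidence intervals where the source
provides them, otherwise +-30% (clinical inputs / utilities) or +-20% (resource
use and unit costs).  Structural scenarios: discount rate {0%, 5%} and time
horizon {2 y, 10 y} — the lower bound approximates the core trial follow-up,
and 10 years is already a lifetime horizon for this population so no upper
extension is meaningful.

**Probabilistic.**  1000 draws; every ranged parameter is sampled
independently — beta for rates, proportions and utilities, gamma for resource
use and unit costs — with moments matched to (base value, `se = range/3.92`).
The same formula is applied to the mechanical +-20/30% ranges for lack of
anything better.  Survival-curve parameters carry no published uncertainty
and are held fixed, so the cohort traces are computed once per arm and reused
across draws; the resulting acceptability curve reflects cost/utility
uncertainty only.  No correlations are imposed (none are published).  The
CEAC reports, for each willingness-to-pay value, the fraction of draws with
strictly positive net monetary benefit (ties count as not cost-effective).

## Synthetic individual-patient data

Because the underlying trial data are not public, a generator reproduces the
*structure* of the chemotherapy-naive subgroup: n = 395 patients randomized
2:1 (radium arm size = nearest integer), three latent event times per patient
drawn independently from the arm's true laws, administrative censoring at 156
weeks by default, and death truncating the PFS/SSE observations.  It supports
the fit-and-select pipeline (right-censored MLE via lifelines for the
exponential, Weibull, log-logistic and lognormal families; AIC selection with
ties broken toward fewer parameters) and a replicated recovery experiment.

What the generator does *not* emulate: covariates, informative dropout,
interval-censored progression assessment, or the trial's actual accrual and
censoring pattern.  Passing recovery tests therefore show that the estimation
machinery is consistent under the model's own assumptions, not that the
published curves were estimated this way.

## Numerical choices

* Restricted means use adaptive quadrature (absolute tolerance 1e-8 years);
  tests cross-check with a fixed-grid trapezoid rule.
* Per-cycle event probabilities return 1 by convention once the conditioning
  survival has underflowed to zero.
* Negative computed occupancies beyond -1e-6 (severe curve crossing) raise;
  milder artefacts are clipped with a warning.
* All randomness flows from a single seed through numpy's PCG64 generator;
  identical seeds give bit-identical PSA samples and synthetic cohorts.

## Known limitations

* The published BSC QALY total (0.77) is unreachable under the printed
  inputs: 1.332 discounted life-years at a best-state utility of 0.554 cap
  BSC QALYs at 0.693, and the model yields 0.691.  The published value
  implies more life-years than the printed lognormal OS curve produces; the
  discrepancy is reported, not tuned away.
* Recurrent SSEs are not modelled; only the first SSE changes state and
  triggers a treatment cost.
* Scenario analyses with non-lognormal OS/PFS families are runnable via
  `cea scenario`, but the fitted parameters for those families were never
  published, so they require user-supplied values (e.g. fitted to synthetic
  data).
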