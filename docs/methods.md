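# Methods

## The model

`copdcea` implements a discrete-time multi-state Markov model of chronic
obstructive pulmonary disease (COPD) used to estimate the lifetime
cost-effectiveness of pulmonary rehabilitation (PR).  The health states are
the GOLD airflow-limitation grades 2 (moderate), 3 (severe) and 4 (very
severe) plus an absorbing death state; GOLD grade 1 is out of scope because
rehabilitation is not indicated there.  Progression is unidirectional — a
patient never returns to a milder grade — and the time step is one year.

Each simulated patient carries an age, a smoking status (never / ex /
current smoker) and an annual exacerbation risk.  Within every cycle the
events occur in a fixed order:

1. **Smoking turnover** — a current smoker quits with annual probability
   0.047 and an ex-smoker relapses with probability 0.026; never-smokers
   never change.
2. **Exacerbation** — a Bernoulli draw at the stage-specific annual
   probability of *at least one* exacerbation (0.3945 / 0.441 / 0.667 for
   GOLD 2/3/4).  Within-year timing and counts are not modelled, only the
   annual aggregate.
3. **Accrual** — the cycle's utility (stage- and exacerbation-specific) and
   cost (stage-specific annual cost) are credited at cycle start: a patient
   who dies later in the same cycle still accrues that cycle.  No half-cycle
   correction is applied; the source analysis states no convention and the
   cycle-start rule is the simplest one consistent with annual steps.
4. **Death** — from a mortality table indexed by integer age, stage and
   smoking status.
5. **Progression** — conditional on surviving the cycle, a draw against the
   transition table indexed by (stage, 5-year age band, smoking status,
   exacerbated-this-cycle).  Drawing death before progression avoids
   double-counting exits.
6. Age advances one year.  Anyone reaching the age cap (default 110) exits.

Utilities are 0.7511 / 0.7481 / 0.5493 for exacerbation-free years in
GOLD 2/3/4 and 0.7364 / 0.7261 / 0.5357 for years with at least one
exacerbation (the four-decimal values; the three-decimal roundings that
also circulate differ in the last digit).  Annual disease costs are
5 398 / 5 567 / 10 953 € (2015 euros, direct costs only; co-morbidity costs
are excluded by design, which biases results against rehabilitation).

### The rehabilitation arm

The PR policy is deliberately conservative at baseline: rehabilitation
adds a utility increment of **0.09 per alive year** and a program cost of
**1 583 € per patient-year**, and does not alter exacerbations, mortality,
smoking behaviour or disease costs.  Dosing is annualized
(`course_interval_years = 1`): the per-course schedule of "one course every
two years" is represented by its per-patient-per-year cost, which is the
only reading under which the published incremental algebra
(ICER ≈ annual cost / utility increment) holds; a literal biennial charge
is available via `course_interval_years = 2`.  Scenario knobs:
`utility_decay_per_period` erodes the increment multiplicatively every two
years (`increment · decay^(cycle // 2)`); `exacerbation_multiplier`,
`copd_cost_multiplier` and `mortality_multiplier` scale the respective
usual-care quantities in the PR arm only.  If an increment would push a
utility above 1, the value is clipped at 1 and a warning is emitted.

### Discounting and outcome conventions

Costs and QALYs are discounted at 3.5 %/year with factor ``(1+r)^-t``,
``t = 0`` for the first cycle; life-years are reported undiscounted.  All
three flags are configurable.  `discounted_person_years` (D) is the
discounted expected alive time; with a dynamics-neutral PR policy both
increments factor through it (ΔC = D·c, ΔQ = D·u), so the ICER equals
c/u = 1583/0.09 ≈ 17 589 €/QALY *independently of the transition and
mortality inputs* — the package's central analytic identity, enforced by a
property test over random parameter sets.

### Mortality construction

Stage- and smoking-specific mortality is built from an all-cause life table
by multiplicative proportional hazards on the continuous-time scale:

    q'(a, s, k) = 1 − exp(ln(1 − q(a)) · HR_stage(s) · HR_smoking(k))

equivalently ``1 − (1 − q)^(HR_s·HR_k)``.  A pre-built (age, stage,
smoking) table is accepted verbatim, bypassing construction.  Smoking
hazard ratios may be global or per-stage.

## Engines

Two interchangeable engines evaluate one arm:

* **Microsimulation** (`simulate_cohort`): patient-level Monte Carlo.  Each
  patient has a dedicated random substream keyed by `(seed, patient
  index)`, so results are independent of iteration order, and every cycle
  consumes exactly four uniforms in the fixed event order.  Common random
  numbers are the default: both arms replay identical streams, which
  removes spurious Monte Carlo differences and reproduces the exact
  zero life-year difference of a dynamics-neutral policy.
* **Deterministic evaluator** (`evaluate_cohort`): exact expectation by
  forward propagation of the occupancy distribution over (age × stage ×
  smoking), with the exacerbation outcome marginalised within each cycle.
  It is the microsimulation's oracle (agreement within 3 Monte Carlo SEs is
  an acceptance property) and requires memoryless dynamics: the optional
  per-prior-exacerbation risk multiplier (`exacerbation_history_multiplier`,
  default 1 — the hook for history-dependent exacerbation risk whose
  functional form no source specifies) must be 1, otherwise it raises.
  State mass is conserved to 1e-12 per cycle (audited).

## Synthetic stand-in tables and calibration

The age-distribution, stage-transition and stage-mortality tables of the
original cohort model are not publicly printed, so the packaged baseline
ships *synthetic stand-ins*, flagged `calibrated: false`; any user CSV in
the documented dialects replaces them.

* **Life table**: Gompertz–Makeham, hazard ``a + b·e^(c·x)`` with
  a = 5.0e-4, b = 2.5e-5, c = 0.093 over ages 30–110 — adult all-cause
  mortality of a contemporary Western European population (q ≈ 0.011 at
  65, 0.063 at 85).
* **Stage hazard ratios** 1.25 / 1.7 / 3.0 (GOLD 2/3/4) and smoking hazard
  ratios 1.0 / 1.15 / 1.5 (never/ex/current).
* **Transition table**: base annual progression 0.025 (GOLD2→3) and 0.05
  (GOLD3→4), rising multiplicatively across 5-year age bands (overall
  gradient 1.5 from the first band to the last), with smoking factors
  (1, √1.5, 1.5), an exacerbation factor √1.5, a seeded log-normal jitter
  (σ = 0.05, seed 2016) per (band, stage) cell, monotonicity enforced after
  jittering, and a 0.35 cap.  GOLD4 never progresses.
* **Entry ages**: per-stage band distributions with means ≈ 64.5 / 66 /
  67.5 years for GOLD 2/3/4, uniform within 5-year bands.

The free constants were fixed **once** so that the usual-care cohort's
undiscounted life expectancy (16.58 y) and lifetime discounted cost
(72 976 €) sit in the regime of the published baseline (16.608 y,
72 993 €); the published arm-level QALYs cannot be matched simultaneously
because the printed cost and QALY identities imply different discounted
person-times, so the package documents its own convention and targets the
identity-driven incrementals instead.  What passing tests show is that the
model *mechanics* are right (the ICER identity, oracle equivalence,
conservation, monotonicities) and that magnitudes are plausible — not that
the stand-in tables equal the unpublished cohort tables.  Real COPD data
would add correlated age–stage structure, secular mortality trends and
exacerbation clustering that the stand-ins do not emulate.

## Scenario analysis

`run_scenario_table` re-evaluates both arms under named perturbations and
always reports the unperturbed baseline first.  The packaged set covers:
utility increment 0.03 and 0.17; benefit decay 5 % and 50 % per two years;
exacerbation rate −46 % (the largest published effect); disease costs −5 %
and −10 % in the PR arm; program cost ±50 %; and three combined
simulations (1: exacerbations −46 % with utility +0.125; 2: exacerbations
−46 % with costs −10 %; 3: all three).  The published description of the
combined simulations is internally contradictory between its prose and its
results table; the package follows the composition consistent with the
printed row values.

## Probabilistic sensitivity analysis

Second-order Monte Carlo: each replicate draws a full parameter set
(substream keyed by `(seed, replicate)`), evaluates both arms — the
deterministic engine by default, so replicate noise is purely parametric —
and records (ΔC, ΔQ).  Prior families (none are specified by the source;
these follow standard health-economics practice, all spreads configurable):

* stable utilities, exacerbation and smoking-turnover probabilities:
  **beta**, method-of-moments at 10 % relative SE;
* each exacerbated utility: the drawn stable utility **minus a gamma
  disutility decrement** whose mean is the point-estimate gap.  (Drawing
  the two utilities independently and rejecting mis-ordered pairs was
  tried first and rejected: with means only ~0.015 apart it discards
  nearly half the draws and biases the stable utility upward by ~5 %.)
* stage and rehabilitation costs: **gamma** at 20 % relative SE;
* rehabilitation utility increment: **beta** centred on 0.09 — strictly
  positive, so every replicate gains QALYs and the cost-effectiveness
  plane cloud lies right of the vertical axis;
* stage prevalence: **Dirichlet** with concentration 200 on the
  0.883/0.105/0.012 split.

All prior means equal the point estimates; transition and mortality tables
are treated as structural and not varied.  Summaries: nonparametric 95 %
percentile intervals (linear-interpolation quantiles, NumPy's default
definition), and the acceptability curve CEAC(λ) = P(λ·ΔQ − ΔC ≥ 0) on a
default λ grid 0–100 000 €/QALY in steps of 1 000, using the weak
inequality.

## Numerical choices

* Probabilities are validated to [0, 1]; every violation in a document is
  reported with its dotted path in one error.
* Rescaled mortality probabilities are clipped to [0, 1); a life-table
  entry of exactly 1 is rejected (infinite hazard).
* Transition lookups use nearest-band without interpolation; ages outside
  the banded range clamp to the nearest edge band.
* ICERs are rounded to the nearest euro for reporting only.
* A zero QALY difference yields the label `indeterminate` (no division);
  sign-discordant increments yield `dominant`/`dominated`.
* Degenerate inputs: a dead patient is absorbing with zero accrual;
  mortality ≡ 1 gives exactly one accrued cycle; zero dynamics run to the
  age cap.

## Problem sizes

The packaged acceptance script evaluates the deterministic baseline
(exact), a 100 000-patient microsimulation cross-check, the full scenario
table, and a 10 000-replicate PSA with the deterministic inner engine —
about two minutes end to end on one CPU.  The test suite uses smaller
cohorts (2 000–20 000 patients) sized so that 3-SE oracle comparisons are
sharp at desk scale.

## Known limitations

* The stand-in tables are structural stand-ins, not estimates; absolute
  arm-level outputs with the packaged baseline carry that caveat.
* Exacerbations are annual Bernoulli aggregates; hospitalisation
  sub-events, within-year timing and severity grading are not modelled.
* The history-dependence hook is a bare risk multiplier with no published
  functional form, and disables the deterministic engine when active.
* Costs of co-morbidities are excluded, so cost-effectiveness estimates
  are conservative lower bounds for the intervention.
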