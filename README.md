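# copdcea

Lifetime cost-effectiveness of pulmonary rehabilitation (PR) in chronic
obstructive pulmonary disease (COPD), as a tested, reusable simulation
package for health economists and respiratory-medicine researchers.

COPD patients in GOLD grades 2–4 progress irreversibly through severity
stages, exacerbate, and die at rates shaped by age, stage and smoking.
Pulmonary rehabilitation — supervised exercise training plus education —
reliably improves quality of life, but its *lifetime* economic value is
hard to measure in trials with one-year horizons.  This package answers
that question by simulation: a discrete-time multi-state Markov model with
annual cycles compares a usual-care cohort against the same cohort
receiving rehabilitation (modelled conservatively as a utility increment
*u* = 0.09 per alive year at a program cost *c* = 1 583 €/year, with no
effect on disease dynamics), and reports

* discounted lifetime costs and QALYs per arm (3.5 %/year),
* undiscounted life expectancy,
* the incremental cost-effectiveness ratio
  ICER = ΔC/ΔQ,
* one-way scenario tables, and a probabilistic sensitivity analysis with
  cost-effectiveness acceptability curves
  CEAC(λ) = P(λ·ΔQ − ΔC ≥ 0).

Because the baseline policy leaves the disease dynamics untouched, both
increments factor through the discounted person-time D:
ΔC = D·c and ΔQ = D·u, hence **ICER = c/u = 1583/0.09 ≈ 17 589 €/QALY**
regardless of the mortality and progression inputs — the model's central
identity, verified exactly by the test suite and reproduced (to
Monte Carlo error zero, thanks to common random numbers) by the
patient-level microsimulation.

## Worked example

```python
import copdcea as c

params = c.make_baseline_fixture()          # packaged baseline (2015 euros)
uc = c.evaluate_cohort(params, "usual_care")  # exact cohort expectation
pr = c.evaluate_cohort(params, "pr")
inc = c.compute_icer(uc, pr)
print(f"usual care: {uc.mean_ly:.3f} LY, {uc.mean_qaly:.3f} QALY, {uc.mean_cost:,.0f} EUR")
print(f"rehab     : {pr.mean_ly:.3f} LY, {pr.mean_qaly:.3f} QALY, {pr.mean_cost:,.0f} EUR")
print(f"increment : {inc.delta_cost:,.0f} EUR for {inc.delta_qaly:.3f} QALY "
      f"-> ICER {inc.icer_rounded:,} EUR/QALY")
```

prints

```
usual care: 16.579 LY, 8.584 QALY, 72,976 EUR
rehab     : 16.579 LY, 9.658 QALY, 91,879 EUR
increment : 18,903 EUR for 1.075 QALY -> ICER 17,589 EUR/QALY
```

Life expectancy is identical across arms (rehabilitation does not change
dynamics at baseline), every alive year costs 1 583 € more and yields
0.09 extra QALYs, and the ICER lands on c/u.  The same pipeline is
available from the shell:

```bash
copdcea compare --engine deterministic --out-dir out/
copdcea scenarios --out-dir out/            # one-way sensitivity table
copdcea psa --reps 10000 --seed 1 --out-dir out/   # PSA scatter + CEAC
```

The packaged baseline encodes the published point estimates (stage
prevalence 88.3/10.5/1.2 %, smoking splits and turnover, exacerbation
probabilities, utilities, stage costs) verbatim; the unpublished
age/transition/mortality tables are synthetic stand-ins flagged
`calibrated: false` and documented in `docs/methods.md` — supply your own
via CSV (`age,qx` life tables; `age_band,stage,smoking[,exacerbated],prob`
tables) to override them.

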