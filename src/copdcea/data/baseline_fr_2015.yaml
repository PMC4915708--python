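# Baseline parameter set: French GOLD 2-4 COPD cohort, 2015 euros,
# usual care vs annualized pulmonary rehabilitation (+0.09 utility,
# 1583 EUR per patient-year), 3.5%/year discounting.
#
# Point estimates (stage prevalence, smoking splits and turnover,
# exacerbation probabilities, utilities, annual costs, rehabilitation
# policy, discount rate) are published values and are used verbatim.
# NOTE: the GOLD3 smoking split is renormalized from the published
# 10.2/63.6/26.3 (sums to 100.1%) by proportional scaling.
#
# The age-distribution, stage-transition and mortality tables are
# SYNTHETIC STAND-INS (calibrated: false): the source cohort tables are
# not publicly printed.  Their constants were chosen once so that the
# cohort's undiscounted life expectancy and lifetime discounted cost
# are of the magnitude the published model reports (see docs/methods.md
# for the calibration account).  Any user-supplied CSV table overrides
# them.
schema: copdcea/1
label: baseline_fr_2015

stage_params:
  GOLD2:
    exacerbation_prob: 0.3945
    utility_stable: 0.7511
    utility_exacerbated: 0.7364
    annual_cost: 5398.0
  GOLD3:
    exacerbation_prob: 0.441
    utility_stable: 0.7481
    utility_exacerbated: 0.7261
    annual_cost: 5567.0
  GOLD4:
    exacerbation_prob: 0.667
    utility_stable: 0.5493
    utility_exacerbated: 0.5357
    annual_cost: 10953.0

smoking:
  cessation_prob: 0.047
  relapse_prob: 0.026

discount:
  annual_rate: 0.035
  discount_costs: true
  discount_qalys: true
  discount_ly: false

pr_policy:
  utility_increment: 0.09
  annual_cost: 1583.0
  course_interval_years: 1
  utility_decay_per_period: 1.0
  exacerbation_multiplier: 1.0
  copd_cost_multiplier: 1.0
  mortality_multiplier: 1.0

exacerbation_history_multiplier: 1.0

cohort:
  max_age: 110
  stage_prevalence:
    GOLD2: 0.883
    GOLD3: 0.105
    GOLD4: 0.012
  smoking_distribution:
    GOLD2: {NON_SMOKER: 0.125, EX_SMOKER: 0.622, SMOKER: 0.253}
    GOLD3: {NON_SMOKER: 0.101898101898102, EX_SMOKER: 0.635364635364635, SMOKER: 0.262737262737263}
    GOLD4: {NON_SMOKER: 0.087, EX_SMOKER: 0.714, SMOKER: 0.199}
  age_distribution:
    GOLD2:
      "45-49": 0.05
      "50-54": 0.10
      "55-59": 0.15
      "60-64": 0.20
      "65-69": 0.20
      "70-74": 0.15
      "75-79": 0.10
      "80-84": 0.05
    GOLD3:
      "45-49": 0.03
      "50-54": 0.07
      "55-59": 0.12
      "60-64": 0.18
      "65-69": 0.22
      "70-74": 0.18
      "75-79": 0.12
      "80-84": 0.08
    GOLD4:
      "45-49": 0.02
      "50-54": 0.05
      "55-59": 0.10
      "60-64": 0.16
      "65-69": 0.22
      "70-74": 0.20
      "75-79": 0.15
      "80-84": 0.10

mortality:
  calibrated: false
  life_table:
    gompertz_makeham:
      makeham_a: 5.0e-4
      gompertz_b: 2.5e-5
      gompertz_c: 0.093
      age_min: 30
      age_max: 110
  stage_hazard_ratios:
    GOLD2: 1.25
    GOLD3: 1.7
    GOLD4: 3.0
  smoking_hazard_ratios:
    NON_SMOKER: 1.0
    EX_SMOKER: 1.15
    SMOKER: 1.5

transitions:
  calibrated: false
  synthetic:
    seed: 2016
    severity_gradient: 1.5
    base_progression:
      GOLD2: 0.025
      GOLD3: 0.05
    band_starts: [40, 45, 50, 55, 60, 65, 70, 75, 80, 85]
    jitter_sd: 0.05
    cap: 0.35
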