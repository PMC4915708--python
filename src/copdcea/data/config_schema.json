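{
  "$comment": "Reference schema for copdcea configuration documents (schema id copdcea/1). Enforced by the package's own validator, which reports every violation with its dotted path; this file documents the expected structure.",
  "type": "object",
  "required": ["stage_params", "smoking", "cohort", "mortality", "transitions"],
  "properties": {
    "schema": {"const": "copdcea/1"},
    "label": {"type": "string"},
    "stage_params": {
      "type": "object",
      "required": ["GOLD2", "GOLD3", "GOLD4"],
      "additionalProperties": {
        "type": "object",
        "required": ["exacerbation_prob", "utility_stable", "utility_exacerbated", "annual_cost"],
        "properties": {
          "exacerbation_prob": {"type": "number", "minimum": 0, "maximum": 1},
          "utility_stable": {"type": "number", "minimum": 0, "maximum": 1},
          "utility_exacerbated": {"type": "number", "minimum": 0, "maximum": 1,
            "$comment": "must not exceed utility_stable"},
          "annual_cost": {"type": "number", "minimum": 0}
        }
      }
    },
    "smoking": {
      "type": "object",
      "required": ["cessation_prob", "relapse_prob"],
      "properties": {
        "cessation_prob": {"type": "number", "minimum": 0, "maximum": 1},
        "relapse_prob": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "discount": {
      "type": "object",
      "properties": {
        "annual_rate": {"type": "number", "minimum": 0, "default": 0.035},
        "discount_costs": {"type": "boolean", "default": true},
        "discount_qalys": {"type": "boolean", "default": true},
        "discount_ly": {"type": "boolean", "default": false}
      }
    },
    "pr_policy": {
      "type": "object",
      "properties": {
        "utility_increment": {"type": "number", "minimum": 0, "default": 0.09},
        "annual_cost": {"type": "number", "minimum": 0, "default": 1583},
        "course_interval_years": {"type": "integer", "minimum": 1, "default": 1},
        "utility_decay_per_period": {"type": "number", "exclusiveMinimum": 0, "maximum": 1, "default": 1.0,
          "$comment": "multiplies the utility increment every 2 years"},
        "exacerbation_multiplier": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
        "copd_cost_multiplier": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
        "mortality_multiplier": {"type": "number", "exclusiveMinimum": 0, "default": 1.0}
      }
    },
    "exacerbation_history_multiplier": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
    "cohort": {
      "type": "object",
      "required": ["stage_prevalence", "smoking_distribution", "age_distribution"],
      "properties": {
        "max_age": {"type": "integer", "exclusiveMinimum": 30, "default": 110},
        "stage_prevalence": {
          "type": "object",
          "$comment": "per GOLD stage; must sum to 1 within 1e-9",
          "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
        },
        "smoking_distribution": {
          "type": "object",
          "$comment": "per stage: {NON_SMOKER, EX_SMOKER, SMOKER}; each row sums to 1",
          "additionalProperties": {"type": "object"}
        },
        "age_distribution": {
          "type": "object",
          "$comment": "per stage: closed age-band labels like '60-64' mapping to weights summing to 1; ages in [30, max_age)",
          "additionalProperties": {"type": "object"}
        }
      }
    },
    "mortality": {
      "type": "object",
      "$comment": "exactly one of: grid {age_min, probs[age][stage][smoking]}; table {csv} in the age_band,stage,smoking,prob dialect; life_table {csv | gompertz_makeham} + stage_hazard_ratios + smoking_hazard_ratios (global or per-stage)",
      "properties": {
        "calibrated": {"type": "boolean", "default": false},
        "grid": {"type": "object"},
        "table": {"type": "object"},
        "life_table": {"type": "object"},
        "stage_hazard_ratios": {"type": "object"},
        "smoking_hazard_ratios": {"type": "object"}
      }
    },
    "transitions": {
      "type": "object",
      "$comment": "exactly one of: grid {band_starts, probs[band][stage][smoking][exacerbated]}; table {csv} in the age_band,stage,smoking,exacerbated,prob dialect; synthetic {seed, severity_gradient, base_progression, ...}",
      "properties": {
        "calibrated": {"type": "boolean", "default": false},
        "grid": {"type": "object"},
        "table": {"type": "object"},
        "synthetic": {"type": "object"}
      }
    }
  }
}
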