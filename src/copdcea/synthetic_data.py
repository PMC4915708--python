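"""Synthetic inputs: life tables, transition tables, the packaged baseline
parameter set, and randomized-but-valid parameter draws for probabilistic
sensitivity analysis.

The published point estimates (stage prevalences, smoking splits and
turnover, exacerbation probabilities, utilities, annual costs, the
rehabilitation policy) ship verbatim in ``data/baseline_fr_2015.yaml``.  The
age-distribution, stage-transition and mortality tables of the source cohort
model are not publicly printed, so this module generates *synthetic
stand-ins* with the structure the model assumes: a Gompertz–Makeham life
table scaled by stage/smoking hazard ratios, and a progression table that is
monotone in age band, smoking exposure and exacerbation status.  All
stand-ins are flagged ``calibrated: false`` and any user-supplied CSV table
overrides them.

Every generator here is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .parameters import (
    LIVING_STAGES,
    N_LIVING,
    CohortSpec,
    ModelParameters,
    ParameterError,
    SmokingStatus,
    StageParameters,
    TransitionModel,
    load_parameters,
)

__all__ = [
    "LifeTableSpec",
    "UncertaintySpec",
    "make_lifetable",
    "make_transition_fixture",
    "make_baseline_fixture",
    "sample_parameters",
    "BASELINE_CONFIG_NAME",
]

BASELINE_CONFIG_NAME = "baseline_fr_2015.yaml"


# ---------------------------------------------------------------------------
# life table


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz–Makeham all-cause mortality stand-in.

    The annual hazard at age *x* is ``a + b * exp(c * x)``: a constant
    background term plus an exponentially age-increasing term, the classical
    two-component description of adult mortality.  The implied annual death
    probability is ``q(x) = 1 - exp(-(a + b * exp(c * x)))``.
    """

    makeham_a: float = 5.0e-4
    gompertz_b: float = 2.5e-5
    gompertz_c: float = 0.093
    age_min: int = 30
    age_max: int = 110
    model: str = "gompertz_makeham"

    def hazard(self, age: np.ndarray) -> np.ndarray:
        return self.makeham_a + self.gompertz_b * np.exp(self.gompertz_c * age)


def make_lifetable(spec: LifeTableSpec) -> pd.DataFrame:
    """Realize a life table (columns ``age``, ``qx``) from a spec.

    Raises :class:`ParameterError` if the spec is out of range or implies a
    death probability of 1 or more before the end of the age range.
    """
    if spec.makeham_a < 0 or spec.gompertz_b < 0 or spec.gompertz_c < 0:
        raise ParameterError("life-table spec: a, b, c must all be >= 0")
    if spec.age_max < spec.age_min:
        raise ParameterError("life-table spec: age_max < age_min")
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qx = -np.expm1(-spec.hazard(ages))
    if np.any(qx >= 1.0):
        first = int(ages[np.argmax(qx >= 1.0)])
        raise ParameterError(
            f"life-table spec implies q >= 1 from age {first}; reduce the "
            "hazard parameters or the age range"
        )
    return pd.DataFrame({"age": ages, "qx": qx})


# ---------------------------------------------------------------------------
# transition table


def make_transition_fixture(
    seed: int = 0,
    severity_gradient: float = 1.5,
    base_progression: Mapping[str, float] | tuple[float, float] = (0.05, 0.10),
    band_starts: tuple[int, ...] = (40, 45, 50, 55, 60, 65, 70, 75, 80, 85),
    age_factor: float | None = None,
    exacerbation_factor: float | None = None,
    jitter_sd: float = 0.05,
    cap: float = 0.35,
) -> TransitionModel:
    """Synthetic stage-progression table (stand-in for cohort-derived data).

    Progression probabilities rise multiplicatively with age band, smoking
    exposure (never < ex < current, factors ``1, sqrt(g), g`` where *g* is
    ``severity_gradient``) and with an exacerbation in the current cycle
    (factor ``sqrt(g)`` by default).  A small seeded log-normal jitter per
    (band, stage) cell keeps the table from being perfectly geometric; the
    monotone orderings are enforced after jittering, and everything is
    capped.  GOLD4 never progresses.  ``severity_gradient=1`` collapses all
    the gradients, giving probabilities constant across smoking status and
    exacerbation.  The result is a deterministic function of the arguments.
    """
    if severity_gradient < 1.0:
        raise ParameterError("severity_gradient must be >= 1")
    if isinstance(base_progression, Mapping):
        base = np.array([
            float(base_progression["GOLD2"]), float(base_progression["GOLD3"])
        ])
    else:
        base = np.asarray(base_progression, dtype=np.float64)
    n_bands = len(band_starts)
    g = float(severity_gradient)
    if age_factor is None:
        age_factor = g ** (1.0 / max(n_bands - 1, 1))
    if exacerbation_factor is None:
        exacerbation_factor = math.sqrt(g)
    smoke = np.array([1.0, math.sqrt(g), g])

    rng = np.random.default_rng(seed)
    jitter = np.exp(jitter_sd * rng.standard_normal((n_bands, 2)))

    probs = np.zeros((n_bands, N_LIVING, len(SmokingStatus), 2))
    bands = np.arange(n_bands)
    for s in range(2):  # GOLD2 and GOLD3 progress; GOLD4 does not
        core = base[s] * age_factor ** bands * jitter[:, s]  # (B,)
        cell = core[:, None, None] * smoke[None, :, None] * np.array(
            [1.0, exacerbation_factor])[None, None, :]
        probs[:, s] = cell
    # enforce monotonicity in age band and smoking after jittering
    probs = np.maximum.accumulate(probs, axis=0)
    probs = np.maximum.accumulate(probs, axis=2)
    probs[..., 1] = np.maximum(probs[..., 1], probs[..., 0])
    probs = np.clip(probs, 0.0, cap)
    probs[:, 2] = 0.0
    return TransitionModel(band_starts, probs, calibrated=False)


# ---------------------------------------------------------------------------
# packaged baseline


def baseline_document() -> dict:
    """The packaged baseline configuration document as a plain mapping."""
    text = (
        resources.files("copdcea").joinpath(f"data/{BASELINE_CONFIG_NAME}").read_text()
    )
    return yaml.safe_load(text)


def make_baseline_fixture() -> ModelParameters:
    """The packaged baseline parameter set.

    All published point estimates are included verbatim; the age, transition
    and mortality tables are the synthetic stand-ins described in the module
    docstring (``calibrated: false``).
    """
    return load_parameters(baseline_document())


# ---------------------------------------------------------------------------
# parameter uncertainty


@dataclass(frozen=True)
class UncertaintySpec:
    """Spread of the second-order (parameter-uncertainty) distributions.

    Each group keeps its mean at the base value: utilities and probabilities
    are drawn from beta distributions and costs from gamma distributions
    matched by method of moments; stage prevalence comes from a Dirichlet
    centred on the base split (``prevalence_concentration`` is the Dirichlet
    concentration mass; 0 disables that group, as does any zero relative
    SE).  Transition and mortality tables are treated as fixed structural
    inputs and are not varied.
    """

    utility_rel_se: float = 0.10
    exacerbation_rel_se: float = 0.10
    smoking_rel_se: float = 0.10
    cost_rel_se: float = 0.20
    pr_cost_rel_se: float = 0.20
    pr_utility_rel_se: float = 0.10
    prevalence_concentration: float = 200.0

    @classmethod
    def none(cls) -> "UncertaintySpec":
        """Degenerate spreads: every draw returns the base values."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _draw_beta(rng: np.random.Generator, mean: float, rel_se: float) -> float:
    if rel_se == 0.0 or mean == 0.0:
        return mean
    var = (rel_se * mean) ** 2
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"beta spread too wide for mean {mean}: rel SE {rel_se}")
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_gamma(rng: np.random.Generator, mean: float, rel_se: float) -> float:
    if rel_se == 0.0 or mean == 0.0:
        return mean
    shape = 1.0 / rel_se**2
    return float(rng.gamma(shape, mean / shape))


def sample_parameters(
    base: ModelParameters,
    unc: UncertaintySpec,
    rng: np.random.Generator,
) -> ModelParameters:
    """Draw one fully valid random parameter set centred on ``base``.

    Stable utilities, exacerbation and smoking-turnover probabilities are
    beta draws; stage and rehabilitation costs gamma draws; stage
    prevalence a Dirichlet draw; each exacerbated utility is its stable
    utility minus a gamma-distributed disutility decrement (which keeps the
    ordering without rejection bias).
    """
    stage_params = {}
    for stage in LIVING_STAGES:
        sp = base.stage_params[stage]
        u_stable = _draw_beta(rng, sp.utility_stable, unc.utility_rel_se)
        # the exacerbated utility is the stable one minus a nonnegative
        # disutility decrement (gamma), so the within-stage ordering holds
        # by construction and both means stay centred on the base values
        decrement = _draw_gamma(
            rng, sp.utility_stable - sp.utility_exacerbated, unc.utility_rel_se)
        u_exac = max(u_stable - decrement, 0.0)
        stage_params[stage] = StageParameters(
            exacerbation_prob=_draw_beta(rng, sp.exacerbation_prob,
                                         unc.exacerbation_rel_se),
            utility_stable=u_stable,
            utility_exacerbated=u_exac,
            annual_cost=_draw_gamma(rng, sp.annual_cost, unc.cost_rel_se),
        )

    smoking = replace(
        base.smoking,
        cessation_prob=_draw_beta(rng, base.smoking.cessation_prob,
                                  unc.smoking_rel_se),
        relapse_prob=_draw_beta(rng, base.smoking.relapse_prob,
                                unc.smoking_rel_se),
    )
    pr_policy = replace(
        base.pr_policy,
        utility_increment=_draw_beta(rng, base.pr_policy.utility_increment,
                                     unc.pr_utility_rel_se),
        annual_cost=_draw_gamma(rng, base.pr_policy.annual_cost,
                                unc.pr_cost_rel_se),
    )

    prevalence = base.cohort.stage_prevalence
    if unc.prevalence_concentration > 0.0:
        alpha = prevalence * unc.prevalence_concentration
        prevalence = rng.dirichlet(alpha)
    cohort = CohortSpec(
        stage_prevalence=prevalence,
        smoking_distribution=base.cohort.smoking_distribution.copy(),
        age_distribution={s: dict(d) for s, d in base.cohort.age_distribution.items()},
        max_age=base.cohort.max_age,
    )

    drawn = ModelParameters(
        stage_params=stage_params,
        transitions=base.transitions,  # structural, not varied
        mortality=base.mortality,
        smoking=smoking,
        cohort=cohort,
        discount=base.discount,
        pr_policy=pr_policy,
        exacerbation_history_multiplier=base.exacerbation_history_multiplier,
    )
    return drawn.validate()
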