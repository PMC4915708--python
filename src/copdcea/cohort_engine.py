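"""Two engines for one arm of the COPD model.

``simulate_cohort`` is the patient-level Monte Carlo microsimulation: each
patient is drawn from the cohort composition and walked through annual
cycles until death or the age cap.  ``evaluate_cohort`` propagates the
state-occupancy distribution deterministically and returns exact expected
values; it serves as the microsimulation's oracle whenever the dynamics are
memoryless (the default).

Within-cycle event order (identical in both engines):

1. smoking turnover (cessation / relapse),
2. exacerbation draw at the stage-specific annual probability,
3. accrual of the cycle's utility and cost (cycle-start convention: a
   patient dying later in the cycle still accrues it),
4. death draw from the mortality table,
5. stage-progression draw, conditional on surviving the cycle,
6. age advances one year.

Randomness is organised as one substream per patient, keyed by
``(master seed, patient index)`` so results do not depend on iteration
order; each cycle consumes exactly four uniforms in the order above, which
lets the two arms run on common random numbers.  Under the baseline
rehabilitation policy (utility and cost effects only) paired arms then
produce *identical* lifespans, so the life-year difference is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    LIVING_STAGES,
    N_LIVING,
    ModelParameters,
    SeverityStage,
    SmokingStatus,
    stage_index,
)

__all__ = [
    "ARMS",
    "PatientState",
    "CycleRecord",
    "Trajectory",
    "ArmResult",
    "UnsupportedConfigurationError",
    "advance_cycle",
    "simulate_patient",
    "simulate_cohort",
    "evaluate_cohort",
    "draw_initial_state",
    "trajectories_to_frame",
]

ARMS = ("usual_care", "pr")


class UnsupportedConfigurationError(RuntimeError):
    """The deterministic evaluator was asked to run with history-dependent
    dynamics, which its expanded state space cannot represent."""


# ---------------------------------------------------------------------------
# patient-level records


@dataclass(frozen=True)
class PatientState:
    age: int
    stage: SeverityStage
    smoking: SmokingStatus
    exacerbated_this_cycle: bool = False
    cumulative_exacerbations: int = 0
    alive: bool = True

    def __post_init__(self):
        if (self.stage is SeverityStage.DEAD) != (not self.alive):
            raise ValueError("DEAD stage and alive flag are inconsistent")


@dataclass(frozen=True)
class CycleRecord:
    """Undiscounted accruals of one annual cycle."""

    cycle_index: int
    stage: SeverityStage
    exacerbated: bool
    utility_accrued: float
    cost_accrued: float
    alive_at_start: bool


@dataclass
class Trajectory:
    """Ordered per-cycle records for one simulated patient."""

    initial: PatientState
    records: list[CycleRecord] = field(default_factory=list)

    @property
    def life_years(self) -> float:
        return float(sum(r.alive_at_start for r in self.records))

    @property
    def n_exacerbated_cycles(self) -> int:
        return sum(bool(r.exacerbated) for r in self.records)

    def to_frame(self, patient_id: int = 0) -> pd.DataFrame:
        rows = [
            (patient_id, r.cycle_index, self.initial.age + r.cycle_index,
             r.stage.name, r.exacerbated, r.utility_accrued, r.cost_accrued,
             r.alive_at_start)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=[
            "patient_id", "cycle", "age", "stage", "exacerbated",
            "utility", "cost", "alive",
        ])


def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    frames = [t.to_frame(i) for i, t in enumerate(trajectories)]
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ArmResult:
    """Cohort summary for one arm.

    Life-years are undiscounted by default; QALYs and costs are discounted
    per the configuration's :class:`~copdcea.parameters.DiscountSpec`.
    ``discounted_person_years`` is the discounted expected alive time — the
    quantity that converts per-year policy effects into lifetime
    increments.  Standard errors are Monte Carlo SEs of the means (zero for
    the deterministic engine, whose ``n`` is reported as 0).
    """

    arm: str
    engine: str
    n: int
    mean_ly: float
    mean_qaly: float
    mean_cost: float
    discounted_person_years: float
    se_ly: float = 0.0
    se_qaly: float = 0.0
    se_cost: float = 0.0
    digest: str | None = None
    seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "arm": self.arm,
            "engine": self.engine,
            "n": self.n,
            "mean_ly": self.mean_ly,
            "mean_qaly": self.mean_qaly,
            "mean_cost": self.mean_cost,
            "discounted_person_years": self.discounted_person_years,
            "se_ly": self.se_ly,
            "se_qaly": self.se_qaly,
            "se_cost": self.se_cost,
            "config_digest": self.digest,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# compiled lookup tables


class _EngineTables:
    """Dense per-age / per-cycle arrays compiled once per (params, arm)."""

    def __init__(self, params: ModelParameters, arm: str):
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
        self.params = params
        self.arm = arm
        pr = arm == "pr"
        policy = params.pr_policy
        max_age = params.cohort.max_age
        self.max_age = max_age
        n_cycles = max_age + 1  # safe upper bound on cycle indices

        sp = [params.stage_params[s] for s in LIVING_STAGES]
        exac = np.array([p.exacerbation_prob for p in sp])
        self.exac_p = np.clip(
            exac * (policy.exacerbation_multiplier if pr else 1.0), 0.0, 1.0)
        util = np.array([[p.utility_stable, p.utility_exacerbated] for p in sp])
        cycles = np.arange(n_cycles)
        inc = (np.array([policy.utility_increment_at(int(t)) for t in cycles])
               if pr else np.zeros(n_cycles))
        # per-cycle utilities with the rehabilitation increment, clipped at 1
        self.util_cycle = np.clip(util[None, :, :] + inc[:, None, None], 0.0, 1.0)

        cost = np.array([p.annual_cost for p in sp])
        if pr:
            cost = cost * policy.copd_cost_multiplier
            dose = np.array([policy.annual_cost if policy.is_dosing_cycle(int(t))
                             else 0.0 for t in cycles])
        else:
            dose = np.zeros(n_cycles)
        self.cost_cycle = cost[None, :] + dose[:, None]

        mort_mult = policy.mortality_multiplier if pr else 1.0
        self.q_grid = np.clip(params.mortality.per_age(max_age) * mort_mult, 0.0, 1.0)
        self.trans = params.transitions.per_age(max_age)

        self.cessation = params.smoking.cessation_prob
        self.relapse = params.smoking.relapse_prob
        self.hist_mult = params.exacerbation_history_multiplier

        base_df = (1.0 + params.discount.annual_rate) ** (-cycles.astype(np.float64))
        ones = np.ones(n_cycles)
        self.df_rate = base_df
        self.df_cost = base_df if params.discount.discount_costs else ones
        self.df_qaly = base_df if params.discount.discount_qalys else ones
        self.df_ly = base_df if params.discount.discount_ly else ones

        # initial-state inverse CDFs
        self.cum_prev = np.cumsum(params.cohort.stage_prevalence)
        self.cum_smoke = np.cumsum(params.cohort.smoking_distribution, axis=1)
        self.age_values = []
        self.age_cum = []
        for stage in LIVING_STAGES:
            ages, probs = params.cohort.age_pmf(stage)
            self.age_values.append(ages)
            self.age_cum.append(np.cumsum(probs))


def _pick(cum: np.ndarray, u: float) -> int:
    return int(min(np.searchsorted(cum, u, side="right"), cum.size - 1))


def draw_initial_state(params: ModelParameters,
                       rng: np.random.Generator) -> PatientState:
    """Draw one entry state (stage, then age within the stage's band
    distribution, then smoking status) using three uniforms."""
    t = _EngineTables(params, "usual_care")
    u = rng.random(3)
    s = _pick(t.cum_prev, u[0])
    age = int(t.age_values[s][_pick(t.age_cum[s], u[1])])
    k = _pick(t.cum_smoke[s], u[2])
    return PatientState(age=age, stage=LIVING_STAGES[s],
                        smoking=SmokingStatus(k))


# ---------------------------------------------------------------------------
# microsimulation


def advance_cycle(
    state: PatientState,
    params: ModelParameters,
    arm: str,
    rng: np.random.Generator,
    cycle: int = 0,
    _tables: _EngineTables | None = None,
) -> tuple[PatientState, CycleRecord]:
    """Advance one patient by one annual cycle.

    Consumes exactly four uniforms from ``rng`` (smoking, exacerbation,
    death, progression — in that order) for a living patient, and none for a
    dead one, which returns unchanged with zero accruals.
    """
    t = _tables if _tables is not None else _EngineTables(params, arm)
    if not state.alive:
        return state, CycleRecord(cycle, state.stage, False, 0.0, 0.0, False)

    u = rng.random(4)
    smoking = state.smoking
    if smoking is SmokingStatus.SMOKER and u[0] < t.cessation:
        smoking = SmokingStatus.EX_SMOKER
    elif smoking is SmokingStatus.EX_SMOKER and u[0] < t.relapse:
        smoking = SmokingStatus.SMOKER

    s = stage_index(state.stage)
    p_ex = t.exac_p[s]
    if t.hist_mult != 1.0:
        p_ex = min(1.0, p_ex * t.hist_mult ** state.cumulative_exacerbations)
    exacerbated = bool(u[1] < p_ex)

    utility = float(t.util_cycle[cycle, s, int(exacerbated)])
    cost = float(t.cost_cycle[cycle, s])

    dead = bool(u[2] < t.q_grid[state.age, s, int(smoking)])
    stage = state.stage
    if not dead and s < N_LIVING - 1:
        if u[3] < t.trans[state.age, s, int(smoking), int(exacerbated)]:
            stage = stage.next_worse()

    new_state = PatientState(
        age=state.age + 1,
        stage=SeverityStage.DEAD if dead else stage,
        smoking=smoking,
        exacerbated_this_cycle=exacerbated,
        cumulative_exacerbations=state.cumulative_exacerbations + int(exacerbated),
        alive=not dead,
    )
    record = CycleRecord(cycle, state.stage, exacerbated, utility, cost, True)
    return new_state, record


def simulate_patient(
    initial: PatientState,
    params: ModelParameters,
    arm: str,
    rng: np.random.Generator,
) -> Trajectory:
    """Walk one patient from entry to death or the age cap."""
    if not initial.alive:
        raise ValueError("initial patient state must be alive")
    tables = _EngineTables(params, arm)
    traj = Trajectory(initial=initial)
    state, cycle = initial, 0
    while state.alive and state.age < tables.max_age:
        state, record = advance_cycle(state, params, arm, rng, cycle, _tables=tables)
        traj.records.append(record)
        cycle += 1
    return traj


def _run_patient_fast(t: _EngineTables, age: int, s: int, k: int,
                      g: np.random.Generator) -> tuple[float, float, float, float]:
    """Accrual-only inner loop; draw-for-draw identical to
    :func:`advance_cycle` (verified by test)."""
    ly = qaly = cost = dpy = 0.0
    cycle = 0
    cum_ex = 0
    q_grid = t.q_grid
    trans = t.trans
    util_cycle = t.util_cycle
    cost_cycle = t.cost_cycle
    max_age = t.max_age
    hist = t.hist_mult
    while age < max_age:
        u0, u1, u2, u3 = g.random(4)
        if k == 2:
            if u0 < t.cessation:
                k = 1
        elif k == 1 and u0 < t.relapse:
            k = 2
        p_ex = t.exac_p[s]
        if hist != 1.0:
            p_ex = min(1.0, p_ex * hist**cum_ex)
        ex = 1 if u1 < p_ex else 0
        ly += t.df_ly[cycle]
        qaly += t.df_qaly[cycle] * util_cycle[cycle, s, ex]
        cost += t.df_cost[cycle] * cost_cycle[cycle, s]
        dpy += t.df_rate[cycle]
        if u2 < q_grid[age, s, k]:
            break
        if s < 2 and u3 < trans[age, s, k, ex]:
            s += 1
        cum_ex += ex
        age += 1
        cycle += 1
    return ly, qaly, cost, dpy


def simulate_cohort(
    params: ModelParameters,
    arm: str,
    n: int,
    seed: int,
    common_random_numbers: bool = True,
) -> ArmResult:
    """Microsimulate a cohort of ``n`` patients for one arm.

    With ``common_random_numbers=True`` (the default) the per-patient random
    substreams are keyed by ``(seed, patient)`` only, so the usual-care and
    rehabilitation arms consume identical draws; with a dynamics-neutral
    rehabilitation policy the two arms then yield exactly equal lifespans.
    Setting it to ``False`` keys the streams by arm as well, making the arms
    independent.
    """
    if not (isinstance(n, int) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    t = _EngineTables(params, arm)
    arm_key = () if common_random_numbers else (1 + ARMS.index(arm),)

    ly = np.empty(n)
    qaly = np.empty(n)
    cost = np.empty(n)
    dpy = np.empty(n)
    for i in range(n):
        g = np.random.default_rng((seed, *arm_key, i))
        u = g.random(3)
        s = _pick(t.cum_prev, u[0])
        age = int(t.age_values[s][_pick(t.age_cum[s], u[1])])
        k = _pick(t.cum_smoke[s], u[2])
        ly[i], qaly[i], cost[i], dpy[i] = _run_patient_fast(t, age, s, k, g)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return ArmResult(
        arm=arm,
        engine="microsim",
        n=n,
        mean_ly=float(ly.mean()),
        mean_qaly=float(qaly.mean()),
        mean_cost=float(cost.mean()),
        discounted_person_years=float(dpy.mean()),
        se_ly=se(ly),
        se_qaly=se(qaly),
        se_cost=se(cost),
        digest=params.digest(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic expected-value evaluation


def evaluate_cohort(
    params: ModelParameters,
    arm: str,
    return_audit: bool = False,
) -> ArmResult | tuple[ArmResult, dict]:
    """Exact expected values by forward propagation of state occupancy.

    The state space is (age × stage × smoking status), with the
    exacerbation outcome marginalised within each cycle; this is exact as
    long as the dynamics are memoryless, so a non-unit
    ``exacerbation_history_multiplier`` raises
    :class:`UnsupportedConfigurationError`.

    With ``return_audit=True`` also returns per-cycle mass-conservation
    errors (|alive + dead + age-capped − 1| at every cycle).
    """
    if params.exacerbation_history_multiplier != 1.0:
        raise UnsupportedConfigurationError(
            "deterministic evaluation requires memoryless exacerbation "
            "dynamics (exacerbation_history_multiplier == 1)"
        )
    t = _EngineTables(params, arm)
    max_age = t.max_age
    cohort = params.cohort

    occ = np.zeros((max_age, N_LIVING, len(SmokingStatus)))
    for s, stage in enumerate(LIVING_STAGES):
        ages, probs = cohort.age_pmf(stage)
        weight = cohort.stage_prevalence[s] * probs  # (n_ages,)
        occ[ages, s, :] += weight[:, None] * cohort.smoking_distribution[s][None, :]

    q_grid = t.q_grid[:max_age]
    trans = t.trans[:max_age]
    e = t.exac_p  # (3,)

    dead = 0.0
    capped = 0.0
    ly = qaly = cost = dpy = 0.0
    mass_errors: list[float] = []
    cycle = 0
    while cycle <= max_age:
        alive = occ.sum()
        if alive <= 0.0:
            break
        ly += t.df_ly[cycle] * alive
        dpy += t.df_rate[cycle] * alive

        # 1. smoking turnover
        to_ex = occ[:, :, 2] * t.cessation
        to_smoker = occ[:, :, 1] * t.relapse
        occ[:, :, 1] += to_ex - to_smoker
        occ[:, :, 2] += to_smoker - to_ex

        # 2-3. exacerbation expectation and cycle-start accrual
        u_exp = (1.0 - e) * t.util_cycle[cycle, :, 0] + e * t.util_cycle[cycle, :, 1]
        stage_mass = occ.sum(axis=(0, 2))  # (3,)
        qaly += t.df_qaly[cycle] * float(stage_mass @ u_exp)
        cost += t.df_cost[cycle] * float(stage_mass @ t.cost_cycle[cycle])

        # 4. death
        deaths = occ * q_grid
        dead += deaths.sum()
        occ -= deaths

        # 5. progression, conditional on survival; the exacerbated and
        # stable sub-populations carry different progression probabilities
        g_bar = (1.0 - e)[None, :, None] * trans[..., 0] + e[None, :, None] * trans[..., 1]
        moved = occ * g_bar
        occ[:, 1] += moved[:, 0]
        occ[:, 2] += moved[:, 1]
        occ[:, 0] -= moved[:, 0]
        occ[:, 1] -= moved[:, 1]

        # 6. ageing; mass reaching the cap exits the simulation
        capped += occ[-1].sum()
        occ = np.roll(occ, 1, axis=0)
        occ[0] = 0.0

        mass_errors.append(abs(occ.sum() + dead + capped - 1.0))
        cycle += 1

    result = ArmResult(
        arm=arm,
        engine="deterministic",
        n=0,
        mean_ly=float(ly),
        mean_qaly=float(qaly),
        mean_cost=float(cost),
        discounted_person_years=float(dpy),
        digest=params.digest(),
    )
    if return_audit:
        audit = {
            "cycles": cycle,
            "max_mass_error": max(mass_errors) if mass_errors else 0.0,
            "dead_mass": dead,
            "age_capped_mass": capped,
        }
        return result, audit
    return result
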