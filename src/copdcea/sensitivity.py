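"""Uncertainty analysis: one-way scenario tables, second-order Monte Carlo
probabilistic sensitivity analysis (PSA), nonparametric confidence
intervals, and cost-effectiveness acceptability curves (CEAC).

The scenario engine re-evaluates both arms under each named perturbation of
the parameter set and reports the incremental row (additional cost,
life-years and QALYs gained, ICER), with the unperturbed baseline always
first.  The PSA draws full parameter sets from the second-order uncertainty
distributions (see :class:`copdcea.synthetic_data.UncertaintySpec`),
re-evaluates both arms per draw, and summarises the (ΔC, ΔQ) cloud by
percentile intervals and the CEAC — the probability that
``λ·ΔQALY − ΔCost ≥ 0`` as a function of the willingness to pay λ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import synthetic_data
from .cohort_engine import ArmResult, evaluate_cohort, simulate_cohort
from .economics import IncrementalResult, compute_icer
from .parameters import (
    ModelParameters,
    ParameterError,
    ScenarioSpec,
    apply_scenario,
)

__all__ = [
    "ScenarioResult",
    "PSASample",
    "PSAResult",
    "TABLE_SCENARIOS",
    "BASELINE_LABEL",
    "run_scenario_table",
    "run_psa",
    "ceac",
    "percentile_ci",
    "default_lambda_grid",
    "scenario_table_to_frame",
]

BASELINE_LABEL = "Baseline case"

#: The packaged one-way scenario set: utility-increment bounds, erosion of
#: the rehabilitation benefit over time, the largest published exacerbation
#: reduction, disease-cost offsets, program-cost bounds, and three combined
#: simulations.
TABLE_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec.build("Increase QALY = 0.03",
                       sets={"pr_policy.utility_increment": 0.03}),
    ScenarioSpec.build("Increase QALY = 0.17",
                       sets={"pr_policy.utility_increment": 0.17}),
    ScenarioSpec.build("Discount Qaly over time: 5%",
                       sets={"pr_policy.utility_decay_per_period": 0.95}),
    ScenarioSpec.build("Discount Qaly over time: 50%",
                       sets={"pr_policy.utility_decay_per_period": 0.50}),
    ScenarioSpec.build("Exacerbation rate = -46%",
                       sets={"pr_policy.exacerbation_multiplier": 0.54}),
    ScenarioSpec.build("COPD costs = -5%",
                       sets={"pr_policy.copd_cost_multiplier": 0.95}),
    ScenarioSpec.build("COPD costs = -10%",
                       sets={"pr_policy.copd_cost_multiplier": 0.90}),
    ScenarioSpec.build("Rehabilitation Costs = -50%",
                       muls={"pr_policy.annual_cost": 0.5}),
    ScenarioSpec.build("Rehabilitation Costs = +50%",
                       muls={"pr_policy.annual_cost": 1.5}),
    ScenarioSpec.build("Simulation 1",
                       sets={"pr_policy.exacerbation_multiplier": 0.54,
                             "pr_policy.utility_increment": 0.125}),
    ScenarioSpec.build("Simulation 2",
                       sets={"pr_policy.exacerbation_multiplier": 0.54,
                             "pr_policy.copd_cost_multiplier": 0.90}),
    ScenarioSpec.build("Simulation 3",
                       sets={"pr_policy.exacerbation_multiplier": 0.54,
                             "pr_policy.copd_cost_multiplier": 0.90,
                             "pr_policy.utility_increment": 0.125}),
)


@dataclass(frozen=True)
class ScenarioResult:
    """One row of the one-way sensitivity table."""

    label: str
    additional_cost: float
    ly_gained: float
    qaly_gained: float
    icer: float | None
    dominance: str | None = None

    @property
    def icer_display(self) -> str:
        return str(self.dominance) if self.icer is None else str(round(self.icer))

    @classmethod
    def from_incremental(cls, label: str, inc: IncrementalResult) -> "ScenarioResult":
        return cls(label, inc.delta_cost, inc.delta_ly, inc.delta_qaly,
                   inc.icer, inc.dominance)


def _make_evaluator(
    engine: str, n_patients: int, seed: int, common_random_numbers: bool,
) -> Callable[[ModelParameters, str], ArmResult]:
    if engine == "deterministic":
        return lambda params, arm: evaluate_cohort(params, arm)
    if engine == "microsim":
        return lambda params, arm: simulate_cohort(
            params, arm, n_patients, seed,
            common_random_numbers=common_random_numbers)
    raise ValueError(f"unknown engine {engine!r}; "
                     "expected 'deterministic' or 'microsim'")


def run_scenario_table(
    params: ModelParameters,
    scenarios: Sequence[ScenarioSpec] = TABLE_SCENARIOS,
    engine: str = "deterministic",
    n_patients: int = 10_000,
    seed: int = 0,
    common_random_numbers: bool = True,
) -> list[ScenarioResult]:
    """Evaluate both arms under each scenario; the baseline row comes first.

    A scenario whose overrides fail validation raises
    :class:`~copdcea.parameters.ParameterError` naming the scenario label.
    """
    evaluate = _make_evaluator(engine, n_patients, seed, common_random_numbers)
    rows: list[ScenarioResult] = []

    def one(label: str, p: ModelParameters) -> ScenarioResult:
        inc = compute_icer(evaluate(p, "usual_care"), evaluate(p, "pr"))
        return ScenarioResult.from_incremental(label, inc)

    rows.append(one(BASELINE_LABEL, params))
    for spec in scenarios:
        try:
            perturbed = apply_scenario(params, spec)
        except ParameterError as exc:
            raise ParameterError(f"scenario {spec.label!r}: {exc}") from exc
        rows.append(one(spec.label, perturbed))
    return rows


def scenario_table_to_frame(rows: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Reporting layout: ``label,additional_cost,ly_gained,qaly_gained,icer``."""
    return pd.DataFrame([
        {
            "label": r.label,
            "additional_cost": r.additional_cost,
            "ly_gained": r.ly_gained,
            "qaly_gained": r.qaly_gained,
            "icer": r.icer_display,
        }
        for r in rows
    ])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSASample:
    replicate: int
    digest: str
    delta_cost: float
    delta_qaly: float


@dataclass
class PSAResult:
    """Replicate-level increments with their nonparametric summaries."""

    samples: list[PSASample]
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    lambda_grid: np.ndarray
    ceac_probs: np.ndarray
    level: float = 0.95
    seed: int | None = None

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([s.delta_cost for s in self.samples])

    @property
    def delta_qaly(self) -> np.ndarray:
        return np.array([s.delta_qaly for s in self.samples])

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"replicate": s.replicate, "delta_cost": s.delta_cost,
             "delta_qaly": s.delta_qaly}
            for s in self.samples
        ])

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambda_grid, "probability": self.ceac_probs})


def percentile_ci(values: Sequence[float] | np.ndarray,
                  level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval at the given coverage level.

    Quantiles use the linear-interpolation definition (NumPy's default
    ``method="linear"``): the ``p``-quantile of sorted values ``x_1..x_n``
    interpolates between order statistics at rank ``1 + p (n - 1)``.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least two values for a percentile interval")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def default_lambda_grid(lambda_max: float = 100_000.0,
                        step: float = 1_000.0) -> np.ndarray:
    return np.arange(0.0, lambda_max + step / 2, step)


def ceac(samples: Sequence[tuple[float, float]] | np.ndarray | Iterable[PSASample],
         lambda_grid: Sequence[float] | np.ndarray | None = None) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay λ, the fraction of (ΔCost, ΔQALY) samples
    with nonnegative net monetary benefit ``λ·ΔQ − ΔC`` (weak inequality).
    """
    samples = list(samples)
    if len(samples) == 0:
        raise ValueError("ceac requires at least one sample")
    if isinstance(samples[0], PSASample):
        pairs = np.array([(s.delta_cost, s.delta_qaly) for s in samples])
    else:
        pairs = np.asarray(samples, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("samples must be (delta_cost, delta_qaly) pairs")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(
        lambda_grid, dtype=np.float64)
    nmb = grid[:, None] * pairs[None, :, 1] - pairs[None, :, 0]
    return (nmb >= 0.0).mean(axis=1)


def run_psa(
    params: ModelParameters,
    prior_spec: "synthetic_data.UncertaintySpec | None" = None,
    n_reps: int = 10_000,
    engine: str = "deterministic",
    seed: int = 0,
    n_patients: int = 2_000,
    lambda_grid: np.ndarray | None = None,
    level: float = 0.95,
    max_retries: int = 10,
) -> PSAResult:
    """Second-order Monte Carlo over the parameter uncertainty.

    Each replicate draws one full parameter set from ``prior_spec`` (keyed
    by ``(seed, replicate)`` so replicates are order-independent),
    re-evaluates both arms with the chosen engine, and records the
    incremental cost and QALYs.  A draw that fails validation is retried up
    to ``max_retries`` times before erroring out.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    prior = synthetic_data.UncertaintySpec() if prior_spec is None else prior_spec
    evaluate = _make_evaluator(engine, n_patients, seed, True)

    samples: list[PSASample] = []
    for rep in range(n_reps):
        rng = np.random.default_rng((seed, rep))
        for attempt in range(max_retries + 1):
            try:
                drawn = synthetic_data.sample_parameters(params, prior, rng)
                break
            except ParameterError:
                if attempt == max_retries:
                    raise
        uc = evaluate(drawn, "usual_care")
        pr = evaluate(drawn, "pr")
        samples.append(PSASample(
            replicate=rep,
            digest=drawn.digest(),
            delta_cost=pr.mean_cost - uc.mean_cost,
            delta_qaly=pr.mean_qaly - uc.mean_qaly,
        ))

    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(
        lambda_grid, dtype=np.float64)
    return PSAResult(
        samples=samples,
        ci_cost=percentile_ci(dc, level),
        ci_qaly=percentile_ci(dq, level),
        lambda_grid=grid,
        ceac_probs=ceac(np.column_stack([dc, dq]), grid),
        level=level,
        seed=seed,
    )
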