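"""Model inputs for the COPD pulmonary-rehabilitation cost-effectiveness model.

The disease model is a discrete-time multi-state Markov process over four
health states — the GOLD airflow-limitation grades 2, 3 and 4 plus an
absorbing death state — with one-year cycles.  Progression is unidirectional
(a patient never moves to a milder grade) and is modulated by age, smoking
status and whether the patient exacerbated during the cycle.  Mortality is
obtained by scaling an all-cause life table with proportional hazard ratios
for COPD severity and smoking.

This module defines the typed parameter containers, loads and validates
hierarchical YAML/JSON configuration documents, builds the stage/smoking
specific mortality table from a life table and hazard ratios, and applies
named scenario perturbations for one-way sensitivity analysis.

Validation is *total*: every out-of-range value in a document is reported
with its dotted path, not just the first one encountered.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SeverityStage",
    "SmokingStatus",
    "LIVING_STAGES",
    "N_LIVING",
    "stage_index",
    "StageParameters",
    "TransitionModel",
    "MortalityModel",
    "SmokingDynamics",
    "PRPolicy",
    "DiscountSpec",
    "CohortSpec",
    "ModelParameters",
    "Override",
    "ScenarioSpec",
    "ParameterError",
    "SchemaError",
    "ValidationError",
    "DegenerateHazardError",
    "load_parameters",
    "build_mortality_model",
    "apply_scenario",
]

SCHEMA_ID = "copdcea/1"


# ---------------------------------------------------------------------------
# enumerations


class SeverityStage(IntEnum):
    """GOLD airflow-limitation grade, plus the absorbing death state.

    Values are ordered by severity (``GOLD2 < GOLD3 < GOLD4 < DEAD``) so the
    usual comparison operators express "worse than".  Disease progression is
    unidirectional: a living patient either stays put, moves to the next
    worse grade, or dies.  GOLD grade 1 is outside the model scope.
    """

    GOLD2 = 2
    GOLD3 = 3
    GOLD4 = 4
    DEAD = 5

    @property
    def is_alive(self) -> bool:
        return self is not SeverityStage.DEAD

    def next_worse(self) -> "SeverityStage":
        if self is SeverityStage.DEAD:
            raise ValueError("DEAD is absorbing and has no successor state")
        return SeverityStage(self.value + 1)


LIVING_STAGES: tuple[SeverityStage, ...] = (
    SeverityStage.GOLD2,
    SeverityStage.GOLD3,
    SeverityStage.GOLD4,
)
N_LIVING = len(LIVING_STAGES)


def stage_index(stage: SeverityStage) -> int:
    """0-based array index of a living stage (``GOLD2 -> 0``)."""
    stage = SeverityStage(stage)
    if not stage.is_alive:
        raise ValueError("DEAD has no parameter-table index")
    return stage.value - SeverityStage.GOLD2.value


class SmokingStatus(IntEnum):
    """Smoking status.  After cohort initialisation only the SMOKER ↔
    EX_SMOKER transitions occur (never-smokers stay never-smokers)."""

    NON_SMOKER = 0
    EX_SMOKER = 1
    SMOKER = 2


_SMOKING_NAMES = tuple(s.name for s in SmokingStatus)
_STAGE_NAMES = tuple(s.name for s in LIVING_STAGES)


# ---------------------------------------------------------------------------
# errors


class ParameterError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ParameterError):
    """The document is structurally wrong: a key is missing or unknown."""


class ValidationError(ParameterError):
    """One or more parameter values are out of range.

    ``errors`` is a list of ``(dotted_path, message)`` pairs covering every
    violation found, not only the first.
    """

    def __init__(self, errors: Iterable[tuple[str, str]]):
        self.errors = list(errors)
        lines = "\n".join(f"  - {p}: {m}" for p, m in self.errors)
        super().__init__(
            f"{len(self.errors)} invalid parameter value(s):\n{lines}"
        )


class DegenerateHazardError(ParameterError):
    """A life-table probability of exactly 1 cannot be rescaled by a hazard
    ratio (the underlying rate is infinite)."""


# ---------------------------------------------------------------------------
# validation helpers

_Errors = list[tuple[str, str]]


def _check_range(
    errors: _Errors,
    path: str,
    value: Any,
    lo: float | None = None,
    hi: float | None = None,
    *,
    lo_strict: bool = False,
    hi_strict: bool = False,
) -> None:
    try:
        v = float(value)
    except (TypeError, ValueError):
        errors.append((path, f"not a number: {value!r}"))
        return
    if not math.isfinite(v):
        errors.append((path, f"not finite: {v!r}"))
        return
    if lo is not None and (v < lo or (lo_strict and v == lo)):
        op = ">" if lo_strict else ">="
        errors.append((path, f"must be {op} {lo}, got {v}"))
    if hi is not None and (v > hi or (hi_strict and v == hi)):
        op = "<" if hi_strict else "<="
        errors.append((path, f"must be {op} {hi}, got {v}"))


def _check_array_range(
    errors: _Errors, path: str, arr: np.ndarray, lo: float, hi: float,
    index_names: Sequence[str],
) -> None:
    bad = ~((arr >= lo) & (arr <= hi) & np.isfinite(arr))
    if not bad.any():
        return
    for idx in zip(*np.nonzero(bad)):
        tags = ",".join(f"{n}={i}" for n, i in zip(index_names, idx))
        errors.append(
            (f"{path}[{tags}]", f"must be in [{lo},{hi}], got {arr[idx]}")
        )


# ---------------------------------------------------------------------------
# leaf parameter blocks


@dataclass(frozen=True)
class StageParameters:
    """Annual inputs attached to one GOLD grade.

    Parameters
    ----------
    exacerbation_prob
        Annual probability that the patient has at least one exacerbation.
    utility_stable, utility_exacerbated
        Health utility accrued over an exacerbation-free year, and over a
        year with at least one exacerbation (``utility_exacerbated`` may not
        exceed ``utility_stable``).
    annual_cost
        Direct disease-related cost, euros per patient-year.
    """

    exacerbation_prob: float
    utility_stable: float
    utility_exacerbated: float
    annual_cost: float

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_range(errors, f"{prefix}exacerbation_prob", self.exacerbation_prob, 0.0, 1.0)
        _check_range(errors, f"{prefix}utility_stable", self.utility_stable, 0.0, 1.0)
        _check_range(errors, f"{prefix}utility_exacerbated", self.utility_exacerbated, 0.0, 1.0)
        _check_range(errors, f"{prefix}annual_cost", self.annual_cost, 0.0, None)
        try:
            if float(self.utility_exacerbated) > float(self.utility_stable):
                errors.append((
                    f"{prefix}utility_exacerbated",
                    "exacerbated utility exceeds stable utility",
                ))
        except (TypeError, ValueError):
            pass
        return errors


@dataclass(frozen=True)
class SmokingDynamics:
    """Annual smoking turnover: cessation among smokers, relapse among
    ex-smokers.  Never-smokers do not change status."""

    cessation_prob: float
    relapse_prob: float

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_range(errors, f"{prefix}cessation_prob", self.cessation_prob, 0.0, 1.0)
        _check_range(errors, f"{prefix}relapse_prob", self.relapse_prob, 0.0, 1.0)
        return errors


@dataclass(frozen=True)
class PRPolicy:
    """How the pulmonary-rehabilitation arm differs from usual care.

    The baseline policy is deliberately conservative: rehabilitation adds a
    constant utility increment and an annual program cost, and leaves
    exacerbations, mortality, smoking behaviour and disease costs untouched
    (all multipliers 1).  Scenario analyses move the multipliers.

    ``course_interval_years=1`` annualises the program cost (the default);
    ``2`` charges it literally every second cycle.  The utility increment is
    optionally eroded by ``utility_decay_per_period`` every two years
    (``increment * decay ** (cycle // 2)``).
    """

    utility_increment: float = 0.09
    annual_cost: float = 1583.0
    course_interval_years: int = 1
    utility_decay_per_period: float = 1.0
    exacerbation_multiplier: float = 1.0
    copd_cost_multiplier: float = 1.0
    mortality_multiplier: float = 1.0

    def utility_increment_at(self, cycle: int) -> float:
        """Effective utility increment in a given cycle (decay applied)."""
        return self.utility_increment * self.utility_decay_per_period ** (cycle // 2)

    def is_dosing_cycle(self, cycle: int) -> bool:
        return cycle % self.course_interval_years == 0

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_range(errors, f"{prefix}utility_increment", self.utility_increment, 0.0, None)
        _check_range(errors, f"{prefix}annual_cost", self.annual_cost, 0.0, None)
        if not (isinstance(self.course_interval_years, int) and self.course_interval_years >= 1):
            errors.append((f"{prefix}course_interval_years",
                           f"must be an integer >= 1, got {self.course_interval_years!r}"))
        _check_range(errors, f"{prefix}utility_decay_per_period",
                     self.utility_decay_per_period, 0.0, 1.0, lo_strict=True)
        for name in ("exacerbation_multiplier", "copd_cost_multiplier", "mortality_multiplier"):
            _check_range(errors, f"{prefix}{name}", getattr(self, name), 0.0, None, lo_strict=True)
        return errors


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of future outcomes.

    By convention life-years are reported undiscounted while QALYs and costs
    are discounted; each stream has its own flag.  The per-cycle factor is
    ``(1 + annual_rate) ** -cycle`` with cycle 0 undiscounted.
    """

    annual_rate: float = 0.035
    discount_costs: bool = True
    discount_qalys: bool = True
    discount_ly: bool = False

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_range(errors, f"{prefix}annual_rate", self.annual_rate, 0.0, None)
        return errors


# ---------------------------------------------------------------------------
# lookup tables


def _parse_band_label(label: str) -> tuple[int, int | None]:
    """Parse an age-band label: ``"60-64"`` -> (60, 64); ``"85+"`` -> (85, None)."""
    label = str(label).strip()
    if label.endswith("+"):
        return int(label[:-1]), None
    lo, _, hi = label.partition("-")
    if not hi:
        raise SchemaError(f"malformed age band label: {label!r}")
    return int(lo), int(hi)


class TransitionModel:
    """Annual probability of progressing to the next worse GOLD grade.

    The lookup is ``(stage, age, smoking status, exacerbated-this-cycle)``.
    Ages are mapped to bands by nearest-band lookup without interpolation:
    band *i* covers ``[band_starts[i], band_starts[i+1])`` and the first/last
    bands absorb ages outside the covered range.  GOLD4 never progresses
    (only death exits GOLD4), which the stored table must respect.
    """

    _INDEX_NAMES = ("band", "stage", "smoking", "exacerbated")

    def __init__(self, band_starts: Sequence[int], probs: np.ndarray,
                 calibrated: bool = False):
        self.band_starts = np.asarray(band_starts, dtype=np.int64)
        self.probs = np.asarray(probs, dtype=np.float64)
        self.calibrated = bool(calibrated)
        self._hash: bytes | None = None
        if self.band_starts.ndim != 1 or self.band_starts.size < 1:
            raise SchemaError("transitions: band_starts must be a non-empty 1-D sequence")
        if np.any(np.diff(self.band_starts) <= 0):
            raise SchemaError("transitions: band_starts must be strictly increasing")
        expected = (self.band_starts.size, N_LIVING, len(SmokingStatus), 2)
        if self.probs.shape != expected:
            raise SchemaError(
                f"transitions: probability grid has shape {self.probs.shape}, "
                f"expected {expected} (band, stage, smoking, exacerbated)"
            )

    # -- lookup ------------------------------------------------------------

    def band_index(self, age: int) -> int:
        return int(np.clip(
            np.searchsorted(self.band_starts, age, side="right") - 1,
            0, self.band_starts.size - 1,
        ))

    def prob(self, stage: SeverityStage, age: int,
             smoking: SmokingStatus, exacerbated: bool) -> float:
        if SeverityStage(stage) is SeverityStage.GOLD4:
            return 0.0
        return float(self.probs[
            self.band_index(age), stage_index(stage), int(smoking), int(bool(exacerbated))
        ])

    def per_age(self, max_age: int) -> np.ndarray:
        """Expand to a dense ``(max_age + 1, stage, smoking, exacerbated)``
        grid indexed directly by integer age (used by the engines)."""
        idx = np.clip(
            np.searchsorted(self.band_starts, np.arange(max_age + 1), side="right") - 1,
            0, self.band_starts.size - 1,
        )
        return self.probs[idx]

    # -- serialization -----------------------------------------------------

    def band_labels(self) -> list[str]:
        labels = [
            f"{lo}-{hi - 1}"
            for lo, hi in zip(self.band_starts[:-1], self.band_starts[1:])
        ]
        labels.append(f"{self.band_starts[-1]}+")
        return labels

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns
        ``age_band,stage,smoking,exacerbated,prob``."""
        rows = []
        for b, label in enumerate(self.band_labels()):
            for s, sname in enumerate(_STAGE_NAMES):
                for k, kname in enumerate(_SMOKING_NAMES):
                    for e in (0, 1):
                        rows.append((label, sname, kname, e, self.probs[b, s, k, e]))
        return pd.DataFrame(
            rows, columns=["age_band", "stage", "smoking", "exacerbated", "prob"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, calibrated: bool = False) -> "TransitionModel":
        required = {"age_band", "stage", "smoking", "exacerbated", "prob"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"transition table: missing columns {sorted(missing)}")
        starts = sorted({_parse_band_label(b)[0] for b in df["age_band"]})
        b_of = {}
        for label in df["age_band"].unique():
            b_of[label] = starts.index(_parse_band_label(label)[0])
        probs = np.full((len(starts), N_LIVING, len(SmokingStatus), 2), np.nan)
        for row in df.itertuples(index=False):
            s = _STAGE_NAMES.index(str(row.stage))
            k = _SMOKING_NAMES.index(str(row.smoking))
            probs[b_of[row.age_band], s, k, int(row.exacerbated)] = float(row.prob)
        if np.isnan(probs).any():
            raise SchemaError("transition table: incomplete coverage of "
                              "(age_band, stage, smoking, exacerbated) cells")
        return cls(starts, probs, calibrated=calibrated)

    def array_hash(self) -> bytes:
        if self._hash is None:
            h = hashlib.sha256()
            h.update(self.band_starts.tobytes())
            h.update(np.ascontiguousarray(self.probs).tobytes())
            self._hash = h.digest()
        return self._hash

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_array_range(errors, f"{prefix}probs", self.probs, 0.0, 1.0,
                           self._INDEX_NAMES)
        g4 = self.probs[:, stage_index(SeverityStage.GOLD4)]
        if np.any(g4 != 0.0):
            errors.append((f"{prefix}probs", "GOLD4 progression probability must be 0 "
                                             "(only death exits GOLD4)"))
        return errors


class MortalityModel:
    """Annual death probability by integer age, GOLD grade and smoking status.

    Normally built from an all-cause life table and proportional hazard
    ratios (see :func:`build_mortality_model`); a pre-built table in the same
    shape is accepted verbatim.
    """

    _INDEX_NAMES = ("age", "stage", "smoking")

    def __init__(self, age_min: int, q: np.ndarray, calibrated: bool = False):
        self.age_min = int(age_min)
        self.q = np.asarray(q, dtype=np.float64)
        self.calibrated = bool(calibrated)
        self._hash: bytes | None = None
        if self.q.ndim != 3 or self.q.shape[1:] != (N_LIVING, len(SmokingStatus)):
            raise SchemaError(
                f"mortality: grid has shape {self.q.shape}, expected "
                f"(n_ages, {N_LIVING}, {len(SmokingStatus)})"
            )

    @property
    def age_max(self) -> int:
        return self.age_min + self.q.shape[0] - 1

    def prob(self, age: int, stage: SeverityStage,
             smoking: SmokingStatus) -> float:
        i = int(np.clip(age - self.age_min, 0, self.q.shape[0] - 1))
        return float(self.q[i, stage_index(stage), int(smoking)])

    def per_age(self, max_age: int) -> np.ndarray:
        """Dense ``(max_age + 1, stage, smoking)`` grid indexed by age, with
        nearest-edge extension outside the covered range."""
        idx = np.clip(np.arange(max_age + 1) - self.age_min, 0, self.q.shape[0] - 1)
        return self.q[idx]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``age_band,stage,smoking,prob`` with one-year
        bands (``"70-70"``)."""
        rows = []
        for i in range(self.q.shape[0]):
            a = self.age_min + i
            for s, sname in enumerate(_STAGE_NAMES):
                for k, kname in enumerate(_SMOKING_NAMES):
                    rows.append((f"{a}-{a}", sname, kname, self.q[i, s, k]))
        return pd.DataFrame(rows, columns=["age_band", "stage", "smoking", "prob"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, calibrated: bool = False) -> "MortalityModel":
        required = {"age_band", "stage", "smoking", "prob"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"mortality table: missing columns {sorted(missing)}")
        cells: dict[tuple[int, int, int], float] = {}
        for row in df.itertuples(index=False):
            lo, hi = _parse_band_label(row.age_band)
            hi = lo if hi is None else hi
            s = _STAGE_NAMES.index(str(row.stage))
            k = _SMOKING_NAMES.index(str(row.smoking))
            for a in range(lo, hi + 1):
                cells[(a, s, k)] = float(row.prob)
        ages = sorted({a for a, _, _ in cells})
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise SchemaError("mortality table: age coverage has gaps")
        q = np.full((len(ages), N_LIVING, len(SmokingStatus)), np.nan)
        for (a, s, k), p in cells.items():
            q[a - ages[0], s, k] = p
        if np.isnan(q).any():
            raise SchemaError("mortality table: incomplete (age, stage, smoking) coverage")
        return cls(ages[0], q, calibrated=calibrated)

    def array_hash(self) -> bytes:
        if self._hash is None:
            h = hashlib.sha256()
            h.update(np.int64(self.age_min).tobytes())
            h.update(np.ascontiguousarray(self.q).tobytes())
            self._hash = h.digest()
        return self._hash

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_array_range(errors, f"{prefix}q", self.q, 0.0, 1.0, self._INDEX_NAMES)
        return errors


def build_mortality_model(
    all_cause: pd.DataFrame | Mapping[int, float],
    stage_hazard_ratio: Mapping[Any, float],
    smoking_hazard_ratio: Mapping[Any, Any],
    *,
    max_age: int | None = None,
    calibrated: bool = False,
) -> MortalityModel:
    """Scale an all-cause life table by proportional hazard ratios.

    The annual probability ``q(age)`` is converted to a rate, multiplied by
    the stage and smoking hazard ratios, and converted back::

        q'(age, stage, smoking) = 1 - exp(ln(1 - q(age)) * HR_stage * HR_smoking)

    Parameters
    ----------
    all_cause
        Life table: a DataFrame with columns ``age``/``qx``, or a mapping of
        integer age to annual death probability.  Ages must be contiguous.
    stage_hazard_ratio
        ``{stage: HR}`` for GOLD2-GOLD4, HR > 0.
    smoking_hazard_ratio
        Either ``{smoking status: HR}`` (applied at every stage) or a nested
        ``{stage: {smoking status: HR}}`` per-stage form.
    max_age
        If given, require the life table to cover ages up to ``max_age - 1``
        (the last age at which a death draw can occur).

    Raises
    ------
    DegenerateHazardError
        If any ``q(age) == 1`` (infinite rate cannot be rescaled).
    SchemaError
        On gaps in age coverage or coverage short of ``max_age``.
    """
    if isinstance(all_cause, pd.DataFrame):
        if not {"age", "qx"} <= set(all_cause.columns):
            raise SchemaError("life table must have columns 'age' and 'qx'")
        ages = all_cause["age"].to_numpy(dtype=np.int64)
        qx = all_cause["qx"].to_numpy(dtype=np.float64)
    else:
        items = sorted((int(a), float(p)) for a, p in dict(all_cause).items())
        ages = np.array([a for a, _ in items], dtype=np.int64)
        qx = np.array([p for _, p in items], dtype=np.float64)
    order = np.argsort(ages)
    ages, qx = ages[order], qx[order]
    if ages.size == 0:
        raise SchemaError("life table is empty")
    if np.any(np.diff(ages) != 1):
        raise SchemaError("life table: ages must be contiguous integers")
    if np.any((qx < 0) | (qx > 1) | ~np.isfinite(qx)):
        raise ValidationError([("life_table.qx", "probabilities must lie in [0, 1)")])
    if np.any(qx == 1.0):
        raise DegenerateHazardError(
            "life table contains q = 1; the hazard is infinite and cannot be "
            "rescaled by a finite hazard ratio"
        )
    if max_age is not None and ages[-1] < max_age - 1:
        raise SchemaError(
            f"life table covers ages up to {ages[-1]} but coverage up to "
            f"{max_age - 1} is required for max_age={max_age}"
        )

    hr = np.empty((N_LIVING, len(SmokingStatus)), dtype=np.float64)
    for s, stage in enumerate(LIVING_STAGES):
        try:
            hr_s = float(_stage_key_get(stage_hazard_ratio, stage))
        except KeyError:
            raise SchemaError(f"stage_hazard_ratio missing {stage.name}") from None
        per_stage = _stage_key_get(smoking_hazard_ratio, stage, default=None)
        table = per_stage if isinstance(per_stage, Mapping) else smoking_hazard_ratio
        for k, status in enumerate(SmokingStatus):
            try:
                hr_k = float(_stage_key_get(table, status))
            except KeyError:
                raise SchemaError(
                    f"smoking_hazard_ratio missing {status.name}"
                ) from None
            hr[s, k] = hr_s * hr_k
    if np.any(hr <= 0):
        raise ValidationError([("hazard_ratios", "all hazard ratios must be > 0")])

    rate = -np.log1p(-qx)[:, None, None] * hr[None, :, :]
    q = -np.expm1(-rate)
    q = np.clip(q, 0.0, np.nextafter(1.0, 0.0))
    return MortalityModel(int(ages[0]), q, calibrated=calibrated)


def _stage_key_get(mapping: Mapping, key: IntEnum, default=KeyError):
    """Look up an enum key stored as the enum, its name, or its value."""
    for candidate in (key, key.name, key.value):
        if candidate in mapping:
            return mapping[candidate]
    if default is KeyError:
        raise KeyError(key)
    return default


# ---------------------------------------------------------------------------
# cohort composition


@dataclass
class CohortSpec:
    """Initial composition of the simulated cohort.

    ``stage_prevalence`` is the distribution over GOLD2/3/4 at entry;
    ``smoking_distribution[stage]`` the per-stage split over never/ex/current
    smokers; ``age_distribution[stage]`` a distribution over closed age-band
    labels (``"60-64"``), spread uniformly over the integer ages inside each
    band when states are drawn.
    """

    stage_prevalence: np.ndarray
    smoking_distribution: np.ndarray
    age_distribution: dict[SeverityStage, dict[str, float]]
    max_age: int = 110

    def __post_init__(self) -> None:
        self.stage_prevalence = np.asarray(self.stage_prevalence, dtype=np.float64)
        self.smoking_distribution = np.asarray(self.smoking_distribution, dtype=np.float64)
        if self.stage_prevalence.shape != (N_LIVING,):
            raise SchemaError("cohort.stage_prevalence must have one entry per GOLD stage")
        if self.smoking_distribution.shape != (N_LIVING, len(SmokingStatus)):
            raise SchemaError("cohort.smoking_distribution must be (stage, smoking status)")
        self.age_distribution = {
            SeverityStage(s): dict(d) for s, d in self.age_distribution.items()
        }
        for stage in LIVING_STAGES:
            if stage not in self.age_distribution:
                raise SchemaError(f"cohort.age_distribution.{stage.name}: missing block")

    def age_pmf(self, stage: SeverityStage) -> tuple[np.ndarray, np.ndarray]:
        """Integer ages and their probabilities for one stage (uniform
        within each band)."""
        ages: list[int] = []
        probs: list[float] = []
        for label, p in self.age_distribution[SeverityStage(stage)].items():
            lo, hi = _parse_band_label(label)
            if hi is None:
                raise SchemaError(
                    f"cohort.age_distribution: open-ended band {label!r} not allowed"
                )
            width = hi - lo + 1
            for a in range(lo, hi + 1):
                ages.append(a)
                probs.append(float(p) / width)
        order = np.argsort(ages)
        return np.asarray(ages, dtype=np.int64)[order], np.asarray(probs)[order]

    def validation_errors(self, prefix: str = "") -> _Errors:
        errors: _Errors = []
        _check_array_range(errors, f"{prefix}stage_prevalence",
                           self.stage_prevalence, 0.0, 1.0, ("stage",))
        if abs(self.stage_prevalence.sum() - 1.0) > 1e-9:
            errors.append((f"{prefix}stage_prevalence",
                           f"must sum to 1, got {self.stage_prevalence.sum():.12g}"))
        _check_array_range(errors, f"{prefix}smoking_distribution",
                           self.smoking_distribution, 0.0, 1.0, ("stage", "smoking"))
        sums = self.smoking_distribution.sum(axis=1)
        for s, total in enumerate(sums):
            if abs(total - 1.0) > 1e-9:
                errors.append((
                    f"{prefix}smoking_distribution.{_STAGE_NAMES[s]}",
                    f"must sum to 1, got {total:.12g}",
                ))
        if not (isinstance(self.max_age, int) and self.max_age > 30):
            errors.append((f"{prefix}max_age", f"must be an integer > 30, got {self.max_age!r}"))
            return errors
        for stage in LIVING_STAGES:
            p = prefix + f"age_distribution.{stage.name}"
            total = 0.0
            for label, weight in self.age_distribution[stage].items():
                _check_range(errors, f"{p}.{label}", weight, 0.0, 1.0)
                try:
                    lo, hi = _parse_band_label(label)
                except (SchemaError, ValueError):
                    errors.append((f"{p}.{label}", "malformed age band label"))
                    continue
                if lo < 30 or (hi is not None and hi >= self.max_age):
                    errors.append((f"{p}.{label}",
                                   f"ages must lie in [30, {self.max_age})"))
                try:
                    total += float(weight)
                except (TypeError, ValueError):
                    pass
            if abs(total - 1.0) > 1e-9:
                errors.append((p, f"must sum to 1, got {total:.12g}"))
        return errors


# ---------------------------------------------------------------------------
# the aggregate


@dataclass
class ModelParameters:
    """Every input of the two-arm cost-effectiveness model, validated.

    ``exacerbation_history_multiplier`` is an optional hook scaling a
    patient's exacerbation probability by ``m ** (previous exacerbations)``;
    the default 1.0 keeps the process memoryless (required by the
    deterministic evaluator).
    """

    stage_params: dict[SeverityStage, StageParameters]
    transitions: TransitionModel
    mortality: MortalityModel
    smoking: SmokingDynamics
    cohort: CohortSpec
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    pr_policy: PRPolicy = field(default_factory=PRPolicy)
    exacerbation_history_multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.stage_params = {
            SeverityStage(s): sp for s, sp in self.stage_params.items()
        }
        for stage in LIVING_STAGES:
            if stage not in self.stage_params:
                raise SchemaError(f"stage_params.{stage.name}: missing block")

    # -- validation --------------------------------------------------------

    def validation_errors(self) -> _Errors:
        errors: _Errors = []
        for stage in LIVING_STAGES:
            errors += self.stage_params[stage].validation_errors(
                f"stage_params.{stage.name}.")
        errors += self.transitions.validation_errors("transitions.")
        errors += self.mortality.validation_errors("mortality.")
        errors += self.smoking.validation_errors("smoking.")
        errors += self.cohort.validation_errors("cohort.")
        errors += self.discount.validation_errors("discount.")
        errors += self.pr_policy.validation_errors("pr_policy.")
        _check_range(errors, "exacerbation_history_multiplier",
                     self.exacerbation_history_multiplier, 0.0, None, lo_strict=True)
        if self.mortality.age_max < self.cohort.max_age - 1:
            errors.append((
                "mortality",
                f"table covers ages up to {self.mortality.age_max} but "
                f"cohort.max_age={self.cohort.max_age} requires coverage to "
                f"{self.cohort.max_age - 1}",
            ))
        # warn-and-clip check for the PR utility ceiling
        top = max(sp.utility_stable for sp in self.stage_params.values())
        if top + self.pr_policy.utility_increment > 1.0:
            warnings.warn(
                "PR utility increment pushes per-cycle utility above 1; "
                "utilities will be clipped to 1 during accrual",
                RuntimeWarning,
                stacklevel=3,
            )
        return errors

    def validate(self) -> "ModelParameters":
        errors = self.validation_errors()
        if errors:
            raise ValidationError(errors)
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Fully realized document (lookup tables embedded as grids)."""
        return {
            "schema": SCHEMA_ID,
            "stage_params": {
                stage.name: {
                    "exacerbation_prob": sp.exacerbation_prob,
                    "utility_stable": sp.utility_stable,
                    "utility_exacerbated": sp.utility_exacerbated,
                    "annual_cost": sp.annual_cost,
                }
                for stage, sp in sorted(self.stage_params.items())
            },
            "smoking": {
                "cessation_prob": self.smoking.cessation_prob,
                "relapse_prob": self.smoking.relapse_prob,
            },
            "discount": {
                "annual_rate": self.discount.annual_rate,
                "discount_costs": self.discount.discount_costs,
                "discount_qalys": self.discount.discount_qalys,
                "discount_ly": self.discount.discount_ly,
            },
            "pr_policy": {
                "utility_increment": self.pr_policy.utility_increment,
                "annual_cost": self.pr_policy.annual_cost,
                "course_interval_years": self.pr_policy.course_interval_years,
                "utility_decay_per_period": self.pr_policy.utility_decay_per_period,
                "exacerbation_multiplier": self.pr_policy.exacerbation_multiplier,
                "copd_cost_multiplier": self.pr_policy.copd_cost_multiplier,
                "mortality_multiplier": self.pr_policy.mortality_multiplier,
            },
            "exacerbation_history_multiplier": self.exacerbation_history_multiplier,
            "cohort": {
                "stage_prevalence": {
                    name: float(p)
                    for name, p in zip(_STAGE_NAMES, self.cohort.stage_prevalence)
                },
                "smoking_distribution": {
                    sname: {
                        kname: float(self.cohort.smoking_distribution[s, k])
                        for k, kname in enumerate(_SMOKING_NAMES)
                    }
                    for s, sname in enumerate(_STAGE_NAMES)
                },
                "age_distribution": {
                    stage.name: {
                        label: float(p)
                        for label, p in self.cohort.age_distribution[stage].items()
                    }
                    for stage in LIVING_STAGES
                },
                "max_age": self.cohort.max_age,
            },
            "mortality": {
                "grid": {
                    "age_min": self.mortality.age_min,
                    "calibrated": self.mortality.calibrated,
                    "probs": self.mortality.q.tolist(),
                }
            },
            "transitions": {
                "grid": {
                    "band_starts": self.transitions.band_starts.tolist(),
                    "calibrated": self.transitions.calibrated,
                    "probs": self.transitions.probs.tolist(),
                }
            },
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        """SHA-256 digest of the full parameter set (configuration
        fingerprint carried into every result)."""
        h = hashlib.sha256()
        scalars = {k: v for k, v in self.to_dict().items()
                   if k not in ("mortality", "transitions")}
        h.update(json.dumps(scalars, sort_keys=True).encode())
        h.update(self.mortality.array_hash())
        h.update(self.transitions.array_hash())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# document loading


_TOP_LEVEL_KEYS = {
    "schema", "label", "calibrated", "stage_params", "smoking", "discount",
    "pr_policy", "exacerbation_history_multiplier", "cohort", "mortality",
    "transitions",
}


def _read_document(source: Any) -> tuple[Mapping, Path | None]:
    if isinstance(source, Mapping):
        return source, None
    if isinstance(source, (str, Path)):
        path = Path(source)
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, Mapping):
            raise SchemaError(f"{path}: document root must be a mapping")
        return doc, path.parent
    raise SchemaError(f"unsupported configuration source: {type(source).__name__}")


def _require(doc: Mapping, key: str, where: str = "") -> Any:
    if key not in doc:
        raise SchemaError(f"missing required block: {where}{key}")
    return doc[key]


def _block(doc: Mapping, key: str, where: str = "") -> Mapping:
    value = _require(doc, key, where)
    if not isinstance(value, Mapping):
        raise SchemaError(f"{where}{key}: expected a mapping")
    return value


def _dataclass_from(block: Mapping, cls, path: str, defaults_ok: bool = False):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(block) - fields
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    return cls(**dict(block))


def _resolve_path(base_dir: Path | None, p: str) -> Path:
    path = Path(p)
    if not path.is_absolute() and base_dir is not None:
        path = base_dir / path
    return path


def load_parameters(source: Mapping | str | Path) -> ModelParameters:
    """Load and validate a hierarchical configuration document.

    ``source`` may be a mapping or a path to a YAML/JSON file.  Lookup
    tables may be given as embedded grids, as CSV references, or as
    generative stand-in specifications (a Gompertz–Makeham life table plus
    hazard ratios for mortality; a seeded synthetic table for transitions).

    Raises :class:`SchemaError` on structural problems (named path) and
    :class:`ValidationError` listing *every* out-of-range value.
    """
    doc, base_dir = _read_document(source)
    unknown = set(doc) - _TOP_LEVEL_KEYS
    if unknown:
        raise SchemaError(f"unknown top-level key(s): {sorted(unknown)}")

    stage_blocks = _block(doc, "stage_params")
    stage_params: dict[SeverityStage, StageParameters] = {}
    for stage in LIVING_STAGES:
        if stage.name not in stage_blocks:
            raise SchemaError(f"missing required block: stage_params.{stage.name}")
        stage_params[stage] = _dataclass_from(
            stage_blocks[stage.name], StageParameters, f"stage_params.{stage.name}")

    smoking = _dataclass_from(_block(doc, "smoking"), SmokingDynamics, "smoking")
    discount = (_dataclass_from(doc["discount"], DiscountSpec, "discount")
                if "discount" in doc else DiscountSpec())
    pr_policy = (_dataclass_from(doc["pr_policy"], PRPolicy, "pr_policy")
                 if "pr_policy" in doc else PRPolicy())

    cohort_block = _block(doc, "cohort")
    for key in ("stage_prevalence", "smoking_distribution", "age_distribution"):
        _require(cohort_block, key, "cohort.")
    prevalence = np.array([
        float(_stage_key_get(cohort_block["stage_prevalence"], stage))
        for stage in LIVING_STAGES
    ])
    smoking_dist = np.array([
        [float(_stage_key_get(cohort_block["smoking_distribution"][stage.name], status))
         for status in SmokingStatus]
        for stage in LIVING_STAGES
    ])
    age_dist = {
        stage: dict(cohort_block["age_distribution"][stage.name])
        for stage in LIVING_STAGES
        if stage.name in cohort_block["age_distribution"]
    }
    if len(age_dist) < N_LIVING:
        missing = [s.name for s in LIVING_STAGES if s not in age_dist]
        raise SchemaError(f"cohort.age_distribution: missing stage block(s) {missing}")
    cohort = CohortSpec(
        prevalence, smoking_dist, age_dist,
        max_age=int(cohort_block.get("max_age", 110)),
    )

    mortality = _load_mortality(_block(doc, "mortality"), base_dir, cohort.max_age)
    transitions = _load_transitions(_block(doc, "transitions"), base_dir)

    params = ModelParameters(
        stage_params=stage_params,
        transitions=transitions,
        mortality=mortality,
        smoking=smoking,
        cohort=cohort,
        discount=discount,
        pr_policy=pr_policy,
        exacerbation_history_multiplier=float(
            doc.get("exacerbation_history_multiplier", 1.0)),
    )
    return params.validate()


def _load_mortality(block: Mapping, base_dir: Path | None, max_age: int) -> MortalityModel:
    calibrated = bool(block.get("calibrated", False))
    if "grid" in block:
        grid = block["grid"]
        return MortalityModel(
            int(grid["age_min"]), np.asarray(grid["probs"], dtype=np.float64),
            calibrated=bool(grid.get("calibrated", calibrated)),
        )
    if "table" in block:
        ref = block["table"]
        df = pd.read_csv(_resolve_path(base_dir, ref["csv"]))
        model = MortalityModel.from_frame(df, calibrated=calibrated)
        if model.age_max < max_age - 1:
            raise SchemaError(
                f"mortality.table: coverage up to {model.age_max} is short of "
                f"max_age={max_age}")
        return model
    if "life_table" in block:
        lt = block["life_table"]
        if "csv" in lt:
            life = pd.read_csv(_resolve_path(base_dir, lt["csv"]))
        elif "gompertz_makeham" in lt:
            from . import synthetic_data  # lazy: synthetic_data imports this module

            spec = synthetic_data.LifeTableSpec(**lt["gompertz_makeham"])
            life = synthetic_data.make_lifetable(spec)
        else:
            raise SchemaError(
                "mortality.life_table: expected 'csv' or 'gompertz_makeham'")
        return build_mortality_model(
            life,
            _require(block, "stage_hazard_ratios", "mortality."),
            _require(block, "smoking_hazard_ratios", "mortality."),
            max_age=max_age,
            calibrated=calibrated,
        )
    raise SchemaError("mortality: expected one of 'grid', 'table', 'life_table'")


def _load_transitions(block: Mapping, base_dir: Path | None) -> TransitionModel:
    calibrated = bool(block.get("calibrated", False))
    if "grid" in block:
        grid = block["grid"]
        return TransitionModel(
            grid["band_starts"], np.asarray(grid["probs"], dtype=np.float64),
            calibrated=bool(grid.get("calibrated", calibrated)),
        )
    if "table" in block:
        df = pd.read_csv(_resolve_path(base_dir, block["table"]["csv"]))
        return TransitionModel.from_frame(df, calibrated=calibrated)
    if "synthetic" in block:
        from . import synthetic_data  # lazy import, see above

        return synthetic_data.make_transition_fixture(**dict(block["synthetic"]))
    raise SchemaError("transitions: expected one of 'grid', 'table', 'synthetic'")


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class Override:
    """One parameter perturbation: ``set`` replaces the value at a dotted
    path, ``mul`` scales it."""

    path: str
    value: float
    mode: str = "set"  # "set" | "mul"


@dataclass(frozen=True)
class ScenarioSpec:
    """A labelled bundle of parameter overrides for one-way sensitivity
    analysis."""

    label: str
    overrides: tuple[Override, ...] = ()

    @classmethod
    def build(cls, label: str, sets: Mapping[str, float] | None = None,
              muls: Mapping[str, float] | None = None) -> "ScenarioSpec":
        ovs = [Override(p, v, "set") for p, v in (sets or {}).items()]
        ovs += [Override(p, v, "mul") for p, v in (muls or {}).items()]
        return cls(label, tuple(ovs))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ScenarioSpec":
        return cls.build(
            str(doc["label"]), doc.get("set") or {}, doc.get("mul") or {})


def _apply_override(doc: dict, ov: Override) -> None:
    parts = ov.path.split(".")
    node: Any = doc
    for part in parts[:-1]:
        if isinstance(node, Mapping) and part in node:
            node = node[part]
        else:
            raise SchemaError(f"scenario override path not found: {ov.path}")
    leaf = parts[-1]
    if not (isinstance(node, dict) and leaf in node):
        raise SchemaError(f"scenario override path not found: {ov.path}")
    if ov.mode == "set":
        node[leaf] = ov.value
    elif ov.mode == "mul":
        node[leaf] = node[leaf] * ov.value
    else:
        raise SchemaError(f"unknown override mode: {ov.mode!r}")


def apply_scenario(params: ModelParameters, scenario: ScenarioSpec) -> ModelParameters:
    """Return a new, fully re-validated parameter set with the scenario's
    overrides applied.  The input set is never modified."""
    doc = params.to_dict()
    for ov in scenario.overrides:
        _apply_override(doc, ov)
        if ov.path == "pr_policy.course_interval_years":
            doc["pr_policy"]["course_interval_years"] = int(
                doc["pr_policy"]["course_interval_years"])
    return load_parameters(doc)
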