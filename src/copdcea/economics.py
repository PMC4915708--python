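"""Discounting and incremental cost-effectiveness computation.

The incremental cost-effectiveness ratio (ICER) of an intervention against
a reference arm is ΔCost / ΔQALY.  The ratio is only meaningful when both
increments share a sign: a cheaper-and-more-effective intervention is
*dominant*, a dearer-and-less-effective one *dominated*, and a zero QALY
difference leaves the ratio undefined (*indeterminate*).  ICERs are carried
at full precision and rounded to the nearest euro for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # only needed for type checking; avoids an import cycle
    from .cohort_engine import ArmResult

__all__ = ["discount_factor", "IncrementalResult", "compute_icer",
           "DOMINANT", "DOMINATED", "INDETERMINATE"]

DOMINANT = "dominant"
DOMINATED = "dominated"
INDETERMINATE = "indeterminate"


def discount_factor(cycle: int, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** -cycle``; cycle 0 is undiscounted."""
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-cycle)


@dataclass(frozen=True)
class IncrementalResult:
    """Two-arm increments (intervention minus reference) and their ICER.

    ``icer`` is the full-precision ratio when it is meaningful and ``None``
    otherwise, in which case ``dominance`` carries the label.
    """

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer: float | None
    dominance: str | None = None

    @property
    def icer_rounded(self) -> int | None:
        return None if self.icer is None else round(self.icer)

    @property
    def icer_display(self) -> str:
        if self.icer is None:
            return str(self.dominance)
        return str(self.icer_rounded)

    def to_json_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "icer_rounded": self.icer_rounded,
            "dominance": self.dominance,
        }

    def to_frame(self) -> pd.DataFrame:
        """One-row frame in the reporting column order (cost, LY, QALY, ICER)."""
        return pd.DataFrame([{
            "additional_cost": self.delta_cost,
            "ly_gained": self.delta_ly,
            "qaly_gained": self.delta_qaly,
            "icer": self.icer_display,
        }])


def incremental(delta_cost: float, delta_ly: float,
                delta_qaly: float) -> IncrementalResult:
    """Classify raw increments into an ICER or a dominance label."""
    if (delta_cost > 0 and delta_qaly > 0) or (delta_cost < 0 and delta_qaly < 0):
        return IncrementalResult(delta_cost, delta_ly, delta_qaly,
                                 delta_cost / delta_qaly)
    if delta_qaly == 0:
        if delta_cost == 0:
            label = INDETERMINATE
        else:
            label = INDETERMINATE  # no division by a zero QALY difference
    elif delta_cost <= 0 and delta_qaly > 0:
        label = DOMINANT
    else:  # delta_cost >= 0 and delta_qaly < 0
        label = DOMINATED
    return IncrementalResult(delta_cost, delta_ly, delta_qaly, None, label)


def compute_icer(reference: "ArmResult",
                 intervention: "ArmResult") -> IncrementalResult:
    """Increments of ``intervention`` over ``reference`` and their ICER.

    Both results must come from the same parameter configuration (their
    digests are compared when present); only the arm may differ.
    """
    if (reference.digest is not None and intervention.digest is not None
            and reference.digest != intervention.digest):
        raise ValueError(
            "arm results come from different parameter configurations "
            f"({reference.digest[:12]}… vs {intervention.digest[:12]}…)")
    return incremental(
        intervention.mean_cost - reference.mean_cost,
        intervention.mean_ly - reference.mean_ly,
        intervention.mean_qaly - reference.mean_qaly,
    )
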