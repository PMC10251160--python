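"""Cost accumulation under the two diagnostic strategies.

The comparison is a cost-minimization analysis: the FNAC-first pathway
and the everyone-gets-a-biopsy pathway are assumed equally effective at
reaching a final diagnosis, so they are compared on cost alone.

Counting rules (exposed on :class:`~lnfnac.cohort.CostSchedule`):

* each FNAC performed is billed, repeats included;
* each *biopsied node* is billed one excision; a technically repeated
  excision of the same node is not billed twice;
* clinical follow-up visits and ancillary techniques carry zero cost —
  follow-up costs are hard to attribute and ancillary work-ups are
  assumed equivalent between the two strategies.

All arithmetic is carried unrounded; :func:`round_currency` rounds
half-up to the cent for presentation only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohort import CostSchedule, PatientPathway, StateLabel

__all__ = [
    "Strategy",
    "CostReport",
    "StrategyComparison",
    "cost_fnac_first",
    "cost_sb_only",
    "cost_by_initial_state",
    "compare_strategies",
    "one_way_sensitivity",
    "round_currency",
]


def round_currency(x: float, ndigits: int = 2) -> float:
    """Round half-up (commercial rounding), for presentation only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class Strategy(str, enum.Enum):
    FNAC_FIRST = "fnac_first"
    SB_ONLY = "sb_only"


@dataclass(frozen=True)
class CostReport:
    strategy: Strategy
    total_cost: float
    cost_per_patient: float
    sb_component_per_patient: float
    sb_component_share: float
    per_initial_state_cost: Mapping[StateLabel, float]

    def __post_init__(self) -> None:
        if self.sb_component_per_patient > self.cost_per_patient + 1e-9:
            raise ValueError("SB component cannot exceed the total per-patient cost")


@dataclass(frozen=True)
class StrategyComparison:
    """Head-to-head comparison; saving is SB-only minus FNAC-first."""

    saving_per_patient: float
    cost_ratio: float
    fnac_first: CostReport
    sb_only: CostReport


def _require_nonempty(cohort: Sequence[PatientPathway]) -> None:
    if not cohort:
        raise ValueError("cohort must be non-empty")


def cost_fnac_first(
    cohort: Sequence[PatientPathway], schedule: CostSchedule = CostSchedule()
) -> CostReport:
    """Cost of the FNAC-first strategy actually followed by the cohort.

    Total = FNAC unit cost × all FNACs performed (repeats included by
    default) + SB unit cost × biopsied nodes (technical SB repeats not
    double-billed by default).
    """
    _require_nonempty(cohort)
    n = len(cohort)
    fnac_total = schedule.fnac_unit_cost * sum(
        schedule.fnac_procedures(p) for p in cohort
    )
    sb_total = schedule.sb_unit_cost * sum(schedule.sb_procedures(p) for p in cohort)
    total = fnac_total + sb_total
    return CostReport(
        strategy=Strategy.FNAC_FIRST,
        total_cost=total,
        cost_per_patient=total / n,
        sb_component_per_patient=sb_total / n,
        sb_component_share=sb_total / total,
        per_initial_state_cost=cost_by_initial_state(cohort, schedule),
    )


def cost_sb_only(
    cohort: Sequence[PatientPathway], schedule: CostSchedule = CostSchedule()
) -> CostReport:
    """Counterfactual strategy: every node excised upfront, no cytology.

    By construction the per-patient cost equals the SB unit cost.
    """
    _require_nonempty(cohort)
    n = len(cohort)
    states = {p.initial_state.label for p in cohort}
    return CostReport(
        strategy=Strategy.SB_ONLY,
        total_cost=schedule.sb_unit_cost * n,
        cost_per_patient=schedule.sb_unit_cost,
        sb_component_per_patient=schedule.sb_unit_cost,
        sb_component_share=1.0,
        per_initial_state_cost={s: schedule.sb_unit_cost for s in states},
    )


def cost_by_initial_state(
    cohort: Sequence[PatientPathway], schedule: CostSchedule = CostSchedule()
) -> dict:
    """FNAC-first cost per patient, stratified by initial cytology state.

    All of a node's procedures (including repeat FNACs and any biopsy)
    are attributed to the state its *first* FNAC assigned it.
    """
    _require_nonempty(cohort)
    totals: dict = {}
    counts: dict = {}
    for p in cohort:
        s = p.initial_state.label
        counts[s] = counts.get(s, 0) + 1
        totals[s] = (
            totals.get(s, 0.0)
            + schedule.fnac_unit_cost * schedule.fnac_procedures(p)
            + schedule.sb_unit_cost * schedule.sb_procedures(p)
        )
    return {s: totals[s] / counts[s] for s in totals}


def compare_strategies(
    cohort: Sequence[PatientPathway], schedule: CostSchedule = CostSchedule()
) -> StrategyComparison:
    """Per-patient saving and cost ratio of FNAC-first versus SB-only."""
    fnac_first = cost_fnac_first(cohort, schedule)
    sb_only = cost_sb_only(cohort, schedule)
    return StrategyComparison(
        saving_per_patient=sb_only.cost_per_patient - fnac_first.cost_per_patient,
        cost_ratio=fnac_first.cost_per_patient / sb_only.cost_per_patient,
        fnac_first=fnac_first,
        sb_only=sb_only,
    )


_SENSITIVITY_PARAMS = ("fnac_unit_cost", "sb_unit_cost", "biopsy_rate")


def one_way_sensitivity(
    cohort: Sequence[PatientPathway],
    schedule: CostSchedule,
    parameter: str,
    values: Sequence[float],
) -> pd.DataFrame:
    """One-way sensitivity of the per-patient saving to one parameter.

    The saving is linear in each supported parameter, so the table is
    monotone; the break-even value (saving = 0) is inserted as an extra
    row whenever it falls inside the scanned range.

    ``biopsy_rate`` scans a hypothetical fraction of nodes biopsied while
    keeping the cohort's mean number of FNACs per node fixed.
    """
    if parameter not in _SENSITIVITY_PARAMS:
        raise ValueError(f"parameter must be one of {_SENSITIVITY_PARAMS}")
    if len(values) == 0:
        raise ValueError("values range must be non-empty")
    _require_nonempty(cohort)

    n = len(cohort)
    mean_fnacs = sum(schedule.fnac_procedures(p) for p in cohort) / n
    biopsy_rate = sum(schedule.sb_procedures(p) for p in cohort) / n

    def saving(v: float) -> float:
        c_f, c_s, r = schedule.fnac_unit_cost, schedule.sb_unit_cost, biopsy_rate
        if parameter == "fnac_unit_cost":
            c_f = v
        elif parameter == "sb_unit_cost":
            c_s = v
        else:
            r = v
        return c_s - (c_f * mean_fnacs + c_s * r)

    points = sorted(float(v) for v in values)
    # saving(v) = a + b·v; solve the break-even from two evaluations
    s0, s1 = saving(points[0]), saving(points[-1])
    if points[-1] > points[0] and s0 != s1:
        b = (s1 - s0) / (points[-1] - points[0])
        v_star = points[0] - s0 / b
        if points[0] < v_star < points[-1] and not any(
            abs(v_star - v) < 1e-12 for v in points
        ):
            points = sorted(points + [v_star])
    table = pd.DataFrame(
        {"value": points, "saving_per_patient": [saving(v) for v in points]}
    )
    table.attrs["parameter"] = parameter
    return table
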