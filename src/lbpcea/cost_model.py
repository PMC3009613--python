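"""Per-cycle chronic-state costs for each strategy (2009 KRW).

Costs accrue only while a patient occupies the chronic LBP state: acute-state
treatment is identical across strategies (and therefore cancels), and the
well state needs no treatment.  A per-cycle cost has three components:

* direct medical — the reimbursed visit schedule over the 3-month cycle,
* direct non-medical — transport, waiting and treatment time,
* indirect non-medical — productivity loss, excluded in the base case and
  toggled on for the univariate sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .parameters import ParameterError

__all__ = [
    "VisitType",
    "VisitSchedule",
    "CycleCosts",
    "visit_schedule_cost",
    "indirect_cost",
    "cycle_cost_total",
    "USUAL_CARE_SCHEDULE",
    "COLLABORATIVE_SCHEDULE",
    "DIRECT_NONMEDICAL_PER_CYCLE",
    "INDIRECT_NONMEDICAL_PER_CYCLE",
    "KRW_PER_USD",
]


@dataclass(frozen=True)
class VisitType:
    """One visit category: its per-visit reimbursement and 3-month frequency."""

    label: str
    per_visit_cost: float  # KRW
    frequency: int  # visits per 3-month cycle

    def __post_init__(self) -> None:
        if self.per_visit_cost < 0:
            raise ParameterError(f"per-visit cost must be >= 0: {self.label}")
        if self.frequency < 0 or int(self.frequency) != self.frequency:
            raise ParameterError(f"frequency must be a non-negative integer: {self.label}")


@dataclass(frozen=True)
class VisitSchedule:
    """The visit mix a chronic patient receives during one 3-month cycle."""

    visit_types: Sequence[VisitType]


def visit_schedule_cost(schedule: VisitSchedule) -> float:
    """Total direct medical cost of a visit schedule: sum(cost x frequency)."""
    if not schedule.visit_types:
        raise ParameterError("visit schedule must be non-empty")
    return float(sum(v.per_visit_cost * v.frequency for v in schedule.visit_types))


def indirect_cost(
    daily_wage: float,
    prop_economically_active: float,
    employment_rate: float,
    lost_days: float,
) -> float:
    """Productivity loss: wage x economically-active share x employment rate x days lost.

    The calibrated national inputs behind the shipped constant
    (:data:`INDIRECT_NONMEDICAL_PER_CYCLE`) are survey-derived and not part
    of this package; this function documents and implements the formula for
    user-supplied inputs.
    """
    for name, value in [
        ("daily_wage", daily_wage),
        ("prop_economically_active", prop_economically_active),
        ("employment_rate", employment_rate),
        ("lost_days", lost_days),
    ]:
        if value < 0:
            raise ParameterError(f"{name} must be >= 0, got {value}")
    for name, value in [
        ("prop_economically_active", prop_economically_active),
        ("employment_rate", employment_rate),
    ]:
        if value > 1:
            raise ParameterError(f"{name} is a fraction and must be <= 1, got {value}")
    return daily_wage * prop_economically_active * employment_rate * lost_days


# ---------------------------------------------------------------------------
# 2009 Korean reimbursement schedules for one 3-month cycle in chronic LBP.
# Only the per-visit-type totals are authoritative inputs; the itemized
# composition is kept as documentation:
#   usual care, first visit (53,983): first examination 14,730; diagnostic
#     testing 18,648; pharmacy 7,510; drugs 5,650; physical therapy 7,439.
#   usual care, regular visit (31,685): recursive examination 11,080;
#     diagnostic testing 7,510; pharmacy 5,650; drugs 7,439 (as printed).
#   usual care, simple visit (10,549): hospital management fee 3,110;
#     physical treatment 7,439.
#   collaboration, first visit (57,463): adds the first oriental-medical and
#     collaborative examinations plus general/special-spine acupuncture.
#   collaboration, regular visit (50,223) and simple visit (24,877): likewise.
# ---------------------------------------------------------------------------

USUAL_CARE_SCHEDULE = VisitSchedule(
    (
        VisitType("first visit", 53_983, 1),
        VisitType("regular visit (diagnosis and treatment)", 31_685, 6),
        VisitType("simple visit (treatment only)", 10_549, 3),
    )
)

COLLABORATIVE_SCHEDULE = VisitSchedule(
    (
        VisitType("first visit", 57_463, 1),
        VisitType("regular visit (diagnosis and treatment)", 50_223, 6),
        VisitType("simple visit (treatment only)", 24_877, 3),
    )
)

DIRECT_NONMEDICAL_PER_CYCLE = {"usual_care": 232_036.0, "collaborative": 296_897.0}

# Productivity loss per 3-month chronic cycle, identical for both strategies.
INDIRECT_NONMEDICAL_PER_CYCLE = 239_142.0

KRW_PER_USD = 1_181.50  # 2009 exchange rate, display only


@dataclass(frozen=True)
class CycleCosts:
    """Cost components for one 3-month cycle in the chronic state."""

    direct_medical: float
    direct_nonmedical: float
    indirect_nonmedical: float = INDIRECT_NONMEDICAL_PER_CYCLE
    include_indirect: bool = False

    def __post_init__(self) -> None:
        for name in ("direct_medical", "direct_nonmedical", "indirect_nonmedical"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def cycle_cost_total(costs: CycleCosts) -> float:
    """Per-cycle chronic-state cost: direct components, plus indirect if enabled."""
    total = costs.direct_medical + costs.direct_nonmedical
    if costs.include_indirect:
        total += costs.indirect_nonmedical
    return float(total)


def default_cycle_costs(strategy: str, include_indirect: bool = False) -> CycleCosts:
    """Assemble the shipped base-case cost components for a strategy."""
    schedule = COLLABORATIVE_SCHEDULE if strategy == "collaborative" else USUAL_CARE_SCHEDULE
    return CycleCosts(
        direct_medical=visit_schedule_cost(schedule),
        direct_nonmedical=DIRECT_NONMEDICAL_PER_CYCLE[strategy],
        include_indirect=include_indirect,
    )
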