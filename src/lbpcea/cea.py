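"""Incremental cost-effectiveness analysis and net monetary benefit.

The incremental cost-effectiveness ratio (ICER) is the extra cost per extra
QALY of one strategy over another, computed from full-precision deltas.
Dominance labels replace the ratio where it is not meaningful (a strategy
that is cheaper and more effective "dominates").  The net monetary benefit
(NMB) at a willingness-to-pay threshold lambda is ``lambda x QALY - cost``;
for two strategies the NMB difference changes sign exactly at the ICER.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math

import pandas as pd

from .markov_engine import StrategyOutcome
from .parameters import ParameterError

__all__ = ["IncrementalResult", "incremental_analysis", "net_monetary_benefit", "incremental_table"]


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison of two strategies."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str  # "", "equivalent", "dominant", "dominated", "infinite"


def incremental_analysis(
    reference: StrategyOutcome, comparator: StrategyOutcome
) -> IncrementalResult:
    """Compare ``comparator`` against ``reference`` (deltas are comparator - reference)."""
    dc = comparator.cost - reference.cost
    dq = comparator.qaly - reference.qaly
    icer: float | None = None
    label = ""
    if dq == 0.0 and dc == 0.0:
        label = "equivalent"
    elif dq == 0.0:
        label = "infinite"  # effect identical, cost differs: ratio undefined
    elif dq > 0.0 and dc <= 0.0:
        label = "dominant"  # comparator cheaper (or free) and more effective
    elif dq < 0.0 and dc >= 0.0:
        label = "dominated"
    else:
        icer = dc / dq
    return IncrementalResult(
        reference=reference.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        label=label,
    )


def net_monetary_benefit(outcome: StrategyOutcome, lam: float) -> float:
    """NMB at threshold ``lam`` (KRW per QALY): lam x QALY - cost."""
    if lam < 0:
        raise ParameterError("willingness-to-pay threshold must be >= 0")
    return lam * outcome.qaly - outcome.cost


def incremental_table(outcomes: Mapping[str, StrategyOutcome]) -> pd.DataFrame:
    """Incremental analysis over any number of strategies.

    Strategies are ordered by cost; strictly dominated entries (more costly,
    no more effective than a cheaper one) and extendedly dominated entries
    (beaten by a blend of neighbours, i.e. non-increasing ICER along the
    frontier) are labelled rather than dropped.  For the two-strategy case
    this reduces to :func:`incremental_analysis`.
    """
    if not outcomes:
        raise ParameterError("no strategies to compare")
    ordered = sorted(outcomes.values(), key=lambda o: (o.cost, -o.qaly))
    rows = [
        {
            "strategy": o.strategy,
            "cost": o.cost,
            "qaly": o.qaly,
            "delta_cost": math.nan,
            "delta_qaly": math.nan,
            "icer": math.nan,
            "status": "reference" if i == 0 else "",
        }
        for i, o in enumerate(ordered)
    ]
    # strict dominance against the best cheaper-or-equal alternative
    best_qaly = ordered[0].qaly
    for i in range(1, len(ordered)):
        if ordered[i].qaly <= best_qaly:
            rows[i]["status"] = "dominated"
        best_qaly = max(best_qaly, ordered[i].qaly)
    # ICERs along the non-dominated frontier, pruning extended dominance
    frontier = [i for i, row in enumerate(rows) if row["status"] != "dominated"]
    changed = True
    while changed:
        changed = False
        icers = []
        for j in range(1, len(frontier)):
            a, b = ordered[frontier[j - 1]], ordered[frontier[j]]
            icers.append((b.cost - a.cost) / (b.qaly - a.qaly))
        for j in range(1, len(icers)):
            if icers[j] < icers[j - 1]:
                rows[frontier[j]]["status"] = "extended-dominated"
                frontier.pop(j)
                changed = True
                break
    for j in range(1, len(frontier)):
        a, b = ordered[frontier[j - 1]], ordered[frontier[j]]
        row = rows[frontier[j]]
        row["delta_cost"] = b.cost - a.cost
        row["delta_qaly"] = b.qaly - a.qaly
        row["icer"] = row["delta_cost"] / row["delta_qaly"]
    return pd.DataFrame(rows)
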