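"""Incremental cost-effectiveness analysis: dominance, frontier, ICERs, NMB.

Strategies are ranked on the efficiency frontier.  A strategy is *strictly
dominated* when another costs no more and yields at least as many QALYs
(with at least one strict inequality); it is *extendedly dominated* when its
incremental cost-effectiveness ratio (ICER) exceeds that of the next, more
effective frontier step — a blend of its neighbours would dominate it.  The
remaining frontier has strictly increasing ICERs, and the decision rule at a
willingness-to-pay threshold ``wtp`` picks the highest-QALY frontier
strategy whose step ICER does not exceed ``wtp`` — equivalently the
maximiser of net monetary benefit ``NMB = QALYs * wtp - cost``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_model import StrategyOutcome

__all__ = [
    "CEARow",
    "UndefinedICERError",
    "icer",
    "nmb",
    "efficiency_frontier",
    "decide_cost_effective",
    "cea_table",
    "frontier_table",
]

UNDOMINATED = "undominated"
DOMINATED_STRICT = "dominated-strict"
DOMINATED_EXTENDED = "dominated-extended"


class UndefinedICERError(ZeroDivisionError):
    """ICER between strategies with identical effectiveness is undefined."""


def icer(cost1: float, cost2: float, eff1: float, eff2: float) -> float:
    """Incremental cost-effectiveness ratio ``(C1 - C2) / (E1 - E2)``."""
    if eff1 == eff2:
        raise UndefinedICERError("equal effectiveness: ICER undefined")
    return (cost1 - cost2) / (eff1 - eff2)


def nmb(cost: float, qalys: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``."""
    return qalys * wtp - cost


@dataclass(frozen=True)
class CEARow:
    """One strategy's line in the incremental analysis.

    For frontier members, ``incremental_*`` and ``icer`` are relative to the
    previous (cheaper) frontier strategy; the cheapest frontier strategy has
    no comparator (None).  Dominated strategies carry no chained ICER.
    """

    strategy: str
    cost: float
    qalys: float
    category: str
    incremental_cost: float | None = None
    incremental_qalys: float | None = None
    icer: float | None = None


def _sort_key(outcome: StrategyOutcome):
    # ties broken toward lower cost, then higher QALYs, then name
    return (outcome.discounted_cost, -outcome.discounted_qalys, outcome.strategy)


def efficiency_frontier(outcomes: list[StrategyOutcome]) -> list[CEARow]:
    """Classify every strategy and chain ICERs along the frontier.

    Returns one :class:`CEARow` per input strategy, sorted by cost.  The
    result is invariant to the input order.
    """
    if not outcomes:
        raise ValueError("need at least one strategy outcome")
    ranked = sorted(outcomes, key=_sort_key)

    # strict dominance: scan in cost order keeping the best QALYs seen so far
    category: dict[str, str] = {}
    candidates: list[StrategyOutcome] = []
    best_qalys = float("-inf")
    for out in ranked:
        if out.discounted_qalys <= best_qalys:
            category[out.strategy] = DOMINATED_STRICT
        else:
            candidates.append(out)
            best_qalys = out.discounted_qalys

    # extended dominance: drop interior strategies until ICERs increase
    frontier = list(candidates)
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = icer(
                mid.discounted_cost, lo.discounted_cost,
                mid.discounted_qalys, lo.discounted_qalys,
            )
            icer_hi = icer(
                hi.discounted_cost, mid.discounted_cost,
                hi.discounted_qalys, mid.discounted_qalys,
            )
            if icer_lo >= icer_hi:
                category[mid.strategy] = DOMINATED_EXTENDED
                del frontier[i]
                changed = True
                break

    rows: list[CEARow] = []
    prev: StrategyOutcome | None = None
    frontier_names = {o.strategy for o in frontier}
    for out in ranked:
        if out.strategy in frontier_names:
            if prev is None:
                row = CEARow(
                    out.strategy, out.discounted_cost, out.discounted_qalys,
                    UNDOMINATED,
                )
            else:
                row = CEARow(
                    out.strategy,
                    out.discounted_cost,
                    out.discounted_qalys,
                    UNDOMINATED,
                    incremental_cost=out.discounted_cost - prev.discounted_cost,
                    incremental_qalys=out.discounted_qalys - prev.discounted_qalys,
                    icer=icer(
                        out.discounted_cost, prev.discounted_cost,
                        out.discounted_qalys, prev.discounted_qalys,
                    ),
                )
            prev = out
        else:
            row = CEARow(
                out.strategy, out.discounted_cost, out.discounted_qalys,
                category[out.strategy],
            )
        rows.append(row)
    return rows


def decide_cost_effective(rows: list[CEARow], wtp: float) -> str:
    """The cost-effective strategy at threshold ``wtp``: the highest-QALY
    frontier strategy whose step ICER is at most ``wtp``."""
    frontier = [r for r in rows if r.category == UNDOMINATED]
    if not frontier:
        raise ValueError("empty frontier")
    frontier.sort(key=lambda r: r.cost)
    choice = frontier[0]
    for row in frontier[1:]:
        if row.icer is not None and row.icer <= wtp:
            choice = row
    return choice.strategy


def cea_table(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """Full incremental table referencing the cheapest strategy as the
    common baseline, with dominance categories from the frontier analysis.

    Negative ICERs of dominated comparisons are reported as printed but play
    no role in the decision rule.
    """
    rows = efficiency_frontier(outcomes)
    by_name = {o.strategy: o for o in outcomes}
    ranked = sorted(outcomes, key=_sort_key)
    base = ranked[0]
    records = []
    for row in rows:
        out = by_name[row.strategy]
        if out is base:
            inc_c = inc_q = ratio = None
        else:
            inc_c = out.discounted_cost - base.discounted_cost
            inc_q = out.discounted_qalys - base.discounted_qalys
            try:
                ratio = icer(
                    out.discounted_cost, base.discounted_cost,
                    out.discounted_qalys, base.discounted_qalys,
                )
            except UndefinedICERError:
                ratio = None
        records.append(
            {
                "strategy": row.strategy,
                "cost": out.discounted_cost,
                "incremental_cost": inc_c,
                "qalys": out.discounted_qalys,
                "incremental_qalys": inc_q,
                "icer": ratio,
                "category": "Dominated" if row.category != UNDOMINATED else UNDOMINATED,
            }
        )
    return pd.DataFrame.from_records(records)


def frontier_table(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """Frontier-only table with chained incremental comparisons."""
    rows = [r for r in efficiency_frontier(outcomes) if r.category == UNDOMINATED]
    return pd.DataFrame.from_records(
        [
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "incremental_cost": r.incremental_cost,
                "qalys": r.qalys,
                "incremental_qalys": r.incremental_qalys,
                "icer": r.icer,
            }
            for r in rows
        ]
    )
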