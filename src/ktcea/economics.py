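"""Incremental cost-effectiveness: ICERs, dominance, net monetary benefit.

Classification rules relative to a willingness-to-pay (WTP) threshold:

* cost-saving  — cheaper with at least equal QALYs (the dominant case);
* dominated    — dearer with at most equal QALYs (at least one strict);
* cost-effective / not cost-effective — otherwise, by comparing the ICER
  with the WTP (sign-reversed when QALYs are forgone: a cheaper but less
  effective option is acceptable only if it saves more than WTP per QALY
  forgone).  Exact ties classify as cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StrategyOutcome",
    "ComparisonResult",
    "icer",
    "classify",
    "frontier",
    "nmb",
]

COST_SAVING = "cost-saving"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"
DOMINATED = "dominated"


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted lifetime totals of one strategy."""

    name: str
    cost: float
    qaly: float
    ly: float = math.nan

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"{self.name}: negative total cost")
        if not math.isnan(self.ly) and self.qaly > self.ly + 1e-9:
            raise ValueError(f"{self.name}: QALYs exceed life-years")


@dataclass(frozen=True)
class ComparisonResult:
    reference: str
    comparator: str
    incremental_cost: float
    qaly_gained: float
    icer: float | None
    classification: str


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio, delta cost / delta QALY."""
    if delta_qaly == 0:
        raise ZeroDivisionError(
            "ICER undefined for zero QALY difference; report dominance instead"
        )
    return delta_cost / delta_qaly


def classify(
    reference: StrategyOutcome, comparator: StrategyOutcome, wtp: float
) -> ComparisonResult:
    """Compare ``reference`` against ``comparator`` at a WTP threshold."""
    d_cost = reference.cost - comparator.cost
    d_qaly = reference.qaly - comparator.qaly
    ratio = d_cost / d_qaly if d_qaly != 0 else None

    if d_cost == 0 and d_qaly == 0:
        label = COST_EFFECTIVE
    elif d_cost < 0 and d_qaly >= 0:
        label = COST_SAVING
    elif d_cost > 0 and d_qaly <= 0:
        label = DOMINATED
    elif d_qaly > 0:
        label = COST_EFFECTIVE if ratio <= wtp else NOT_COST_EFFECTIVE
    else:  # d_qaly < 0 and d_cost < 0: savings per QALY forgone must beat WTP
        label = COST_EFFECTIVE if ratio >= wtp else NOT_COST_EFFECTIVE
    return ComparisonResult(
        reference=reference.name,
        comparator=comparator.name,
        incremental_cost=d_cost,
        qaly_gained=d_qaly,
        icer=ratio,
        classification=label,
    )


def _strictly_dominated(o: StrategyOutcome, others: Iterable[StrategyOutcome]) -> bool:
    """Strict dominance: some other strategy has at least the QALYs for strictly less money."""
    return any(
        other.qaly >= o.qaly and other.cost < o.cost
        for other in others
        if other.name != o.name
    )


def frontier(outcomes: Sequence[StrategyOutcome], wtp: float) -> pd.DataFrame:
    """Dominance table sorted by effectiveness.

    Strategies are ordered by ascending QALY; each strictly dominated strategy
    is flagged; each non-dominated strategy is compared (ICER) against the
    next-less-effective non-dominated one.  The result is order-invariant in
    the input.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier needs at least two strategies")
    ordered = sorted(outcomes, key=lambda o: (o.qaly, -o.cost, o.name))
    rows = []
    last_nondominated: StrategyOutcome | None = None
    for o in ordered:
        dominated = _strictly_dominated(o, outcomes)
        row = {
            "strategy": o.name,
            "cost": o.cost,
            "qaly": o.qaly,
            "dominated": dominated,
            "incremental_cost": math.nan,
            "qaly_gained": math.nan,
            "icer": math.nan,
            "classification": DOMINATED if dominated else "",
        }
        if not dominated:
            if last_nondominated is not None:
                res = classify(o, last_nondominated, wtp)
                row.update(
                    incremental_cost=res.incremental_cost,
                    qaly_gained=res.qaly_gained,
                    icer=math.nan if res.icer is None else res.icer,
                    classification=res.classification,
                )
            last_nondominated = o
        rows.append(row)
    return pd.DataFrame(rows)


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit, wtp * QALY - cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * outcome.qaly - outcome.cost
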