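"""Decision tree + five-state annual-cycle Markov cohort engine.

Strategies differ in their entry state (preemptive recipients enter the model
already transplanted; non-preemptive recipients enter on dialysis), in the
annual probability of obtaining a graft while on dialysis, and in their cost
schedules.  The chain has five health states:

    dialysis -> kt -> 1-year post-KT -> subsequent-years post-KT -> death

Within a cycle death is applied first; the conditional probabilities of the
non-death moves are scaled by (1 - p_death) so each row sums to one.  Costs,
life-years and QALYs accrue on full cycles with membership measured at the
cycle start (no half-cycle correction) and are discounted at (1+r)^-t with
t = 0 at model entry.

Internally the engine splits the dialysis state into a pre-transplant and a
post-graft-failure compartment so that re-transplantation can be switched off
without losing the Markov property; the reported trace aggregates the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import (
    DEATH,
    DIALYSIS,
    KT,
    POST1,
    STATES,
    SUBSEQUENT,
    MortalityModel,
)
from .parameters import ParameterError, ParameterSet

__all__ = [
    "STRATEGIES",
    "StrategySpec",
    "strategy_from_parameters",
    "all_strategies",
    "discount_factor",
    "build_transition_matrix",
    "run_cohort",
    "CohortTrace",
    "cost_per_ly",
]

#: Canonical strategy names.
P_LRKT = "P-LRKT"
NP_LRKT = "NP-LRKT"
NP_DDKT = "NP-DDKT"
STRATEGIES = (P_LRKT, NP_LRKT, NP_DDKT)

_OCCUPANCY_MASS_TOL = 1e-9


@dataclass(frozen=True)
class StrategySpec:
    """Entry state, transplant access and cost schedule of one strategy."""

    name: str
    entry_state: str
    p_dialysis_to_kt: float
    annual_costs: dict  # state label -> USD/yr
    one_off_costs: dict  # {"kt_event": USD per transplant, "waiting": USD at entry}
    allow_retransplant: bool = True

    def __post_init__(self) -> None:
        if self.entry_state not in (KT, DIALYSIS):
            raise ParameterError(f"entry_state must be kt or dialysis, got {self.entry_state}")
        if not 0.0 <= self.p_dialysis_to_kt <= 1.0:
            raise ParameterError("p_dialysis_to_kt must lie in [0, 1]")
        for label, cost in {**self.annual_costs, **self.one_off_costs}.items():
            if cost < 0:
                raise ParameterError(f"{self.name}: negative cost for {label}")


def _dialysis_annual_cost(params: ParameterSet) -> float:
    """Annual dialysis-state cost under the configured costing profile."""
    profile = params.settings.get("dialysis_costing", "cohort")
    nonmed = params.value("cost_direct_nonmedical")
    if profile == "cohort":
        return params.value("cost_dialysis") + nonmed
    if profile == "literature":
        return (
            params.value("cost_dialysis_literature")
            + 12.0 * params.value("cost_dialysis_complication_monthly")
            + nonmed
        )
    raise ParameterError(f"unknown dialysis_costing profile {profile!r}")


def strategy_from_parameters(params: ParameterSet, name: str) -> StrategySpec:
    """Assemble a :class:`StrategySpec` from a parameter set.

    The ``cost_attachment`` setting decides which printed cost the transplant
    year carries.  Under the default ``literal`` mapping each state is charged
    the cost bearing its name: the KT state carries only the per-visit
    transplant cost, the 1-year-post state the first-year cost, and the
    subsequent state the subsequent-year cost.  Under ``first_year_at_kt``
    the transplant year carries the first-year annual cost on top of the
    per-visit cost, and both post-KT states carry the subsequent-year cost.
    """
    key = {P_LRKT: "plrkt", NP_LRKT: "nplrkt", NP_DDKT: "npddkt"}.get(name)
    if key is None:
        raise ParameterError(f"unknown strategy {name!r}; expected one of {STRATEGIES}")
    attachment = params.settings.get("cost_attachment", "literal")
    dial_cost = _dialysis_annual_cost(params)
    post1 = params.value(f"cost_post1_{key}")
    subsequent = params.value(f"cost_subsequent_{key}")
    if attachment == "literal":
        annual = {DIALYSIS: dial_cost, KT: 0.0, POST1: post1, SUBSEQUENT: subsequent}
    elif attachment == "first_year_at_kt":
        annual = {DIALYSIS: dial_cost, KT: post1, POST1: subsequent, SUBSEQUENT: subsequent}
    else:
        raise ParameterError(f"unknown cost_attachment {attachment!r}")
    p_kt = {
        P_LRKT: 0.0,
        NP_LRKT: params.value("p_dialysis_to_kt_lrkt"),
        NP_DDKT: params.value("p_dialysis_to_kt_ddkt"),
    }[name]
    return StrategySpec(
        name=name,
        entry_state=KT if name == P_LRKT else DIALYSIS,
        p_dialysis_to_kt=p_kt,
        annual_costs=annual,
        one_off_costs={
            "kt_event": params.value(f"cost_kt_{key}"),
            "waiting": params.value("cost_waiting_plrkt") if name == P_LRKT else 0.0,
        },
        allow_retransplant=bool(params.settings.get("allow_retransplant", True)),
    )


def all_strategies(params: ParameterSet) -> dict[str, StrategySpec]:
    return {name: strategy_from_parameters(params, name) for name in STRATEGIES}


def discount_factor(rate: float, cycle: int) -> float:
    """(1 + rate)^-cycle; cycle 0 is undiscounted."""
    if rate < 0 or cycle < 0:
        raise ValueError("rate and cycle must be non-negative")
    return (1.0 + rate) ** (-cycle)


def build_transition_matrix(
    params: ParameterSet,
    mortality: MortalityModel,
    strategy: StrategySpec,
    age: float,
    retransplant_eligible: bool = True,
) -> np.ndarray:
    """Per-cycle 5x5 transition matrix at a given cohort age.

    Rows and columns follow :data:`ktcea.life_tables.STATES`.  Death is the
    absorbing fifth state; every row sums to one.  ``retransplant_eligible``
    selects the dialysis row for cohort members who have (False) or have not
    (True, including never transplanted) exhausted their transplant access.
    """
    pg1 = params.value("p_graft_loss_year1")
    pgs = params.value("p_graft_loss_subsequent")
    q_dial = mortality.death_prob(age, DIALYSIS)
    q_kt = mortality.death_prob(age, KT)
    eligible = age <= params.kt_stop_age and (
        retransplant_eligible or strategy.allow_retransplant
    )
    p_kt = strategy.p_dialysis_to_kt if eligible else 0.0

    m = np.zeros((5, 5))
    i = {s: k for k, s in enumerate(STATES)}
    m[i[DIALYSIS], i[DEATH]] = q_dial
    m[i[DIALYSIS], i[KT]] = (1.0 - q_dial) * p_kt
    m[i[DIALYSIS], i[DIALYSIS]] = (1.0 - q_dial) * (1.0 - p_kt)
    m[i[KT], i[DEATH]] = q_kt
    m[i[KT], i[DIALYSIS]] = (1.0 - q_kt) * pg1
    m[i[KT], i[POST1]] = (1.0 - q_kt) * (1.0 - pg1)
    m[i[POST1], i[DEATH]] = q_kt
    m[i[POST1], i[DIALYSIS]] = (1.0 - q_kt) * pgs
    m[i[POST1], i[SUBSEQUENT]] = (1.0 - q_kt) * (1.0 - pgs)
    m[i[SUBSEQUENT], i[DEATH]] = q_kt
    m[i[SUBSEQUENT], i[DIALYSIS]] = (1.0 - q_kt) * pgs
    m[i[SUBSEQUENT], i[SUBSEQUENT]] = (1.0 - q_kt) * (1.0 - pgs)
    m[i[DEATH], i[DEATH]] = 1.0

    if np.any((m < 0) | (m > 1)) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ParameterError(f"inconsistent transition matrix at age {age}")
    return m


@dataclass
class CohortTrace:
    """Per-cycle state occupancy with accumulated discounted totals."""

    strategy: str
    trace: pd.DataFrame
    total_cost: float
    total_ly: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_ly: float
    undiscounted_qaly: float
    discount_rate: float = 0.03

    def totals(self) -> dict:
        return {
            "strategy": self.strategy,
            "cost": self.total_cost,
            "ly": self.total_ly,
            "qaly": self.total_qaly,
        }


def run_cohort(
    params: ParameterSet,
    mortality: MortalityModel,
    strategy: StrategySpec,
    discount_rate: float | None = None,
) -> CohortTrace:
    """Propagate a unit cohort to the lifetime horizon and accumulate outcomes.

    The cohort starts fully in the strategy's entry state at ``start_age``.
    Each cycle accrues (occupancy-weighted) state costs plus the per-visit
    transplant cost for new entrants to the KT state, life-years over living
    occupancy, and utility-weighted QALYs; the one-off waiting cost is charged
    at entry.  The run stops at ``max_age`` or when living mass falls below
    1e-9, whichever comes first.
    """
    rate = params.discount_rate if discount_rate is None else discount_rate
    utilities = {
        DIALYSIS: params.value("utility_dialysis"),
        KT: params.value("utility_kt"),
        POST1: params.value("utility_post1"),
        SUBSEQUENT: params.value("utility_subsequent"),
    }
    pg1 = params.value("p_graft_loss_year1")
    pgs = params.value("p_graft_loss_subsequent")

    # Compartments: 0 dialysis (pre-KT), 1 KT, 2 post1, 3 subsequent,
    # 4 death, 5 dialysis (post graft failure).
    occ = np.zeros(6)
    occ[1 if strategy.entry_state == KT else 0] = 1.0
    entrants = occ[1]

    rows = []
    disc = np.zeros(3)  # cost, ly, qaly
    undisc = np.zeros(3)
    t = 0
    while True:
        age = params.start_age + t
        living = occ[0] + occ[1] + occ[2] + occ[3] + occ[5]
        if living < _OCCUPANCY_MASS_TOL or age > params.max_age:
            if living >= _OCCUPANCY_MASS_TOL:
                warnings.warn(
                    f"{strategy.name}: living mass {living:.3g} remaining at "
                    f"max_age {params.max_age}; trace truncated",
                    stacklevel=2,
                )
            break
        df = discount_factor(rate, t)
        dial_occ = occ[0] + occ[5]
        cost = (
            dial_occ * strategy.annual_costs[DIALYSIS]
            + occ[1] * strategy.annual_costs[KT]
            + occ[2] * strategy.annual_costs[POST1]
            + occ[3] * strategy.annual_costs[SUBSEQUENT]
            + entrants * strategy.one_off_costs["kt_event"]
        )
        if t == 0:
            cost += strategy.one_off_costs["waiting"]
        qaly = (
            dial_occ * utilities[DIALYSIS]
            + occ[1] * utilities[KT]
            + occ[2] * utilities[POST1]
            + occ[3] * utilities[SUBSEQUENT]
        )
        cycle = np.array([cost, living, qaly])
        disc += df * cycle
        undisc += cycle
        rows.append(
            {
                "cycle": t,
                "age": age,
                "occ_dialysis": dial_occ,
                "occ_kt": occ[1],
                "occ_post_kt_year1": occ[2],
                "occ_post_kt_subsequent": occ[3],
                "occ_death": occ[4],
                "kt_entrants": entrants,
                "discount": df,
                "cycle_cost": cost,
                "cycle_ly": living,
                "cycle_qaly": qaly,
            }
        )

        q_dial = mortality.death_prob(age, DIALYSIS)
        q_kt = mortality.death_prob(age, KT)
        p_first = strategy.p_dialysis_to_kt if age <= params.kt_stop_age else 0.0
        p_re = p_first if strategy.allow_retransplant else 0.0
        new = np.zeros(6)
        new[4] = occ[4] + (occ[0] + occ[5]) * q_dial + (occ[1] + occ[2] + occ[3]) * q_kt
        inflow_kt = occ[0] * (1 - q_dial) * p_first + occ[5] * (1 - q_dial) * p_re
        new[0] = occ[0] * (1 - q_dial) * (1 - p_first)
        new[5] = (
            occ[5] * (1 - q_dial) * (1 - p_re)
            + occ[1] * (1 - q_kt) * pg1
            + (occ[2] + occ[3]) * (1 - q_kt) * pgs
        )
        new[1] = inflow_kt
        new[2] = occ[1] * (1 - q_kt) * (1 - pg1)
        new[3] = (occ[2] + occ[3]) * (1 - q_kt) * (1 - pgs)
        if abs(new.sum() - occ.sum()) > 1e-9:
            raise ParameterError("occupancy mass not conserved")
        occ = new
        entrants = inflow_kt
        t += 1

    return CohortTrace(
        strategy=strategy.name,
        trace=pd.DataFrame(rows),
        total_cost=float(disc[0]),
        total_ly=float(disc[1]),
        total_qaly=float(disc[2]),
        undiscounted_cost=float(undisc[0]),
        undiscounted_ly=float(undisc[1]),
        undiscounted_qaly=float(undisc[2]),
        discount_rate=rate,
    )


def cost_per_ly(trace_or_cost, ly: float | None = None) -> float:
    """Total discounted cost per discounted life-year."""
    if ly is None:
        cost, ly = trace_or_cost.total_cost, trace_or_cost.total_ly
    else:
        cost = float(trace_or_cost)
    if ly <= 0:
        raise ZeroDivisionError("life-years must be positive")
    return cost / ly
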