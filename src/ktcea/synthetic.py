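"""Synthetic patient-level cohort emulating the transplant-centre database.

The generator simulates individual patients under the same structural
assumptions as the cohort model: waiting time to transplantation is
geometric (memoryless annual access probability), graft failure has a
first-year and a subsequent-year annual probability, death follows the
SMR-adjusted life table, and each observed state-year carries a cost drawn
from the moment-matched gamma of that state's true mean cost (per-year SD
equal to the printed standard error).  Default sizes mirror the source
cohort: 40 preemptive LRKT, 50 non-preemptive LRKT, 50 non-preemptive DDKT
patients followed for up to 10 years.

``estimate_inputs`` then recovers transition probabilities (events divided
by person-years at risk, binomial standard errors) and per-state mean annual
costs (standard error = sample SD / sqrt(n)), shaped as an overlay that can
be applied back onto a parameter set — making the estimation -> model
pipeline testable end to end without the hospital database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_tables import DIALYSIS, KT, POST1, SUBSEQUENT, MortalityModel, make_gompertz_life_table
from .markov import NP_DDKT, NP_LRKT, P_LRKT, STRATEGIES
from .parameters import ParameterSet, fit_gamma_moments

__all__ = ["generate_cohort", "estimate_inputs", "CohortEstimates", "DEFAULT_COHORT_SIZES"]

DEFAULT_COHORT_SIZES = {P_LRKT: 40, NP_LRKT: 50, NP_DDKT: 50}

_STRATEGY_KEY = {P_LRKT: "plrkt", NP_LRKT: "nplrkt", NP_DDKT: "npddkt"}
_STATE_COST_PARAM = {KT: "cost_kt", POST1: "cost_post1", SUBSEQUENT: "cost_subsequent"}


def _cost_draw(rng, params: ParameterSet, strategy: str, state: str) -> float:
    if state == DIALYSIS:
        name = "cost_dialysis"
    else:
        name = f"{_STATE_COST_PARAM[state]}_{_STRATEGY_KEY[strategy]}"
    spec = params.spec(name)
    shape, scale = fit_gamma_moments(spec.value, spec.se)
    return float(rng.gamma(shape, scale))


def generate_cohort(
    params: ParameterSet,
    mortality: MortalityModel | None = None,
    n_per_strategy: dict[str, int] | None = None,
    horizon: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate patient-year records under the true parameter values.

    Returns one row per patient-year: patient id, strategy, age, follow-up
    year, state occupied at the start of the year, end-of-year event flags
    (kt_transition, graft_failure, death) and the year's cost draw.  Events
    are drawn with death applied first, exactly as in the cohort engine.
    """
    if mortality is None:
        mortality = MortalityModel.from_parameters(params, make_gompertz_life_table())
    sizes = dict(DEFAULT_COHORT_SIZES if n_per_strategy is None else n_per_strategy)
    if any(n < 1 for n in sizes.values()):
        raise ValueError("need at least one patient per strategy")
    rng = np.random.default_rng(seed)
    pg1 = params.value("p_graft_loss_year1")
    pgs = params.value("p_graft_loss_subsequent")
    p_kt = {
        P_LRKT: 0.0,
        NP_LRKT: params.value("p_dialysis_to_kt_lrkt"),
        NP_DDKT: params.value("p_dialysis_to_kt_ddkt"),
    }
    allow_retx = bool(params.settings.get("allow_retransplant", True))

    rows = []
    pid = 0
    for strategy, n in sizes.items():
        for _ in range(n):
            pid += 1
            state = KT if strategy == P_LRKT else DIALYSIS
            ever_kt = strategy == P_LRKT
            for year in range(horizon):
                age = params.start_age + year
                if age > params.max_age:
                    break
                mort_state = DIALYSIS if state == DIALYSIS else KT
                died = rng.random() < mortality.death_prob(age, mort_state)
                kt_transition = graft_failure = False
                if not died:
                    if state == DIALYSIS:
                        eligible = age <= params.kt_stop_age and (not ever_kt or allow_retx)
                        access = p_kt[strategy] if eligible else 0.0
                        kt_transition = rng.random() < access
                    elif state == KT:
                        graft_failure = rng.random() < pg1
                    else:
                        graft_failure = rng.random() < pgs
                rows.append(
                    {
                        "patient_id": pid,
                        "strategy": strategy,
                        "age": age,
                        "year": year,
                        "state": state,
                        "ever_kt": ever_kt,
                        "kt_transition": kt_transition,
                        "graft_failure": graft_failure,
                        "death": died,
                        "cost": _cost_draw(rng, params, strategy, state),
                    }
                )
                if died:
                    break
                if state == DIALYSIS and kt_transition:
                    state, ever_kt = KT, True
                elif state == KT:
                    state = DIALYSIS if graft_failure else POST1
                elif state in (POST1, SUBSEQUENT):
                    state = DIALYSIS if graft_failure else SUBSEQUENT
    return pd.DataFrame(rows)


@dataclass
class CohortEstimates:
    """Transition probabilities and mean costs estimated from patient records.

    ``probabilities`` and ``costs`` map parameter names to
    (estimate, standard error, n); an SE is NaN when it cannot be computed
    (single observation) and an entry is absent when there was no exposure.
    """

    probabilities: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    costs: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_overrides(self) -> dict[str, float]:
        """Point estimates shaped as a parameter-set overlay."""
        out = {k: v[0] for k, v in self.probabilities.items()}
        out.update({k: v[0] for k, v in self.costs.items()})
        return out

    def apply(self, params: ParameterSet) -> ParameterSet:
        return params.with_values(self.to_overrides())


def _binomial(events: int, exposure: int) -> tuple[float, float, int]:
    p = events / exposure
    se = math.sqrt(p * (1.0 - p) / exposure)
    return p, se, exposure


def estimate_inputs(cohort: pd.DataFrame) -> CohortEstimates:
    """Estimate model inputs from patient-year records.

    Transition probabilities use person-year risk sets conditional on
    surviving the year (matching the engine's death-first ordering); costs
    are per-state sample means.  Quantities with zero exposure are flagged
    missing by omission rather than reported as zero.
    """
    est = CohortEstimates()
    est.counts = cohort.groupby("strategy")["patient_id"].nunique().to_dict()
    survivors = cohort[~cohort["death"]]

    for name, strategy in (
        ("p_dialysis_to_kt_lrkt", NP_LRKT),
        ("p_dialysis_to_kt_ddkt", NP_DDKT),
    ):
        at_risk = survivors[
            (survivors["strategy"] == strategy)
            & (survivors["state"] == DIALYSIS)
            & (~survivors["ever_kt"])
        ]
        if len(at_risk):
            est.probabilities[name] = _binomial(int(at_risk["kt_transition"].sum()), len(at_risk))

    first_year = survivors[survivors["state"] == KT]
    if len(first_year):
        est.probabilities["p_graft_loss_year1"] = _binomial(
            int(first_year["graft_failure"].sum()), len(first_year)
        )
    later = survivors[survivors["state"].isin([POST1, SUBSEQUENT])]
    if len(later):
        est.probabilities["p_graft_loss_subsequent"] = _binomial(
            int(later["graft_failure"].sum()), len(later)
        )

    # dialysis cost is one shared quantity; transplant-era costs are per strategy
    dial = cohort[cohort["state"] == DIALYSIS]["cost"]
    if len(dial):
        sd = dial.std(ddof=1)
        est.costs["cost_dialysis"] = (
            float(dial.mean()),
            float(sd / math.sqrt(len(dial))) if len(dial) > 1 else math.nan,
            len(dial),
        )
    for strategy in STRATEGIES:
        for state, stem in _STATE_COST_PARAM.items():
            obs = cohort[(cohort["strategy"] == strategy) & (cohort["state"] == state)]["cost"]
            if not len(obs):
                continue
            name = f"{stem}_{_STRATEGY_KEY[strategy]}"
            sd = obs.std(ddof=1)
            est.costs[name] = (
                float(obs.mean()),
                float(sd / math.sqrt(len(obs))) if len(obs) > 1 else math.nan,
                len(obs),
            )
    return est
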