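"""Independent oracles used by the acceptance suite.

The microsimulation propagates individual patients with the same structural
rules as the cohort engine (death first, then transplant access or graft
failure; cycle-start accrual; per-entrant transplant cost; entry-time waiting
cost) but via per-patient Monte Carlo draws rather than expected-value
bookkeeping, giving an independent estimate of the cohort totals.
"""

from __future__ import annotations

import numpy as np

from ktcea.life_tables import DIALYSIS, KT, POST1, SUBSEQUENT


def microsimulate(params, mortality, strategy, n: int, seed: int):
    """Simulate ``n`` patients; return means and standard errors of
    (discounted cost, life-years, QALYs)."""
    rng = np.random.default_rng(seed)
    # compartments: 0 dialysis pre-KT, 1 KT, 2 first post-KT year,
    # 3 subsequent years, 4 dead, 5 dialysis after graft failure
    state = np.full(n, 1 if strategy.entry_state == KT else 0, dtype=np.int8)
    pg1 = params.value("p_graft_loss_year1")
    pgs = params.value("p_graft_loss_subsequent")
    utilities = np.array(
        [
            params.value("utility_dialysis"),
            params.value("utility_kt"),
            params.value("utility_post1"),
            params.value("utility_subsequent"),
            0.0,
            params.value("utility_dialysis"),
        ]
    )
    ac = strategy.annual_costs
    state_costs = np.array(
        [ac[DIALYSIS], ac[KT], ac[POST1], ac[SUBSEQUENT], 0.0, ac[DIALYSIS]]
    )
    kt_cost = strategy.one_off_costs["kt_event"]
    cost = np.full(n, float(strategy.one_off_costs["waiting"]))
    ly = np.zeros(n)
    qaly = np.zeros(n)
    entrant = state == 1
    rate = params.discount_rate

    for t in range(params.max_age - params.start_age + 1):
        age = params.start_age + t
        alive = state != 4
        if not alive.any():
            break
        df = (1.0 + rate) ** (-t)
        cost += df * (state_costs[state] * alive + kt_cost * entrant)
        ly += df * alive
        qaly += df * utilities[state] * alive

        on_dialysis = (state == 0) | (state == 5)
        q = np.where(
            on_dialysis,
            mortality.death_prob(age, DIALYSIS),
            mortality.death_prob(age, KT),
        )
        dies = alive & (rng.random(n) < q)
        survives = alive & ~dies

        p_first = strategy.p_dialysis_to_kt if age <= params.kt_stop_age else 0.0
        p_re = p_first if strategy.allow_retransplant else 0.0
        access = rng.random(n)
        to_kt = survives & (
            ((state == 0) & (access < p_first)) | ((state == 5) & (access < p_re))
        )
        failure = rng.random(n)
        lose_first = survives & (state == 1) & (failure < pg1)
        keep_first = survives & (state == 1) & ~(failure < pg1)
        lose_later = survives & ((state == 2) | (state == 3)) & (failure < pgs)
        keep_later = survives & ((state == 2) | (state == 3)) & ~(failure < pgs)

        state = state.copy()
        state[dies] = 4
        state[lose_first | lose_later] = 5
        state[keep_first] = 2
        state[keep_later] = 3
        state[to_kt] = 1
        entrant = to_kt

    sqrt_n = np.sqrt(n)
    return (
        (cost.mean(), ly.mean(), qaly.mean()),
        (cost.std(ddof=1) / sqrt_n, ly.std(ddof=1) / sqrt_n, qaly.std(ddof=1) / sqrt_n),
    )
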