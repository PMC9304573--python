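"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs a strategy pair with each parameter pushed to its
lower and upper deterministic-sensitivity bound (everything else at base
case) and records the swing in an incremental outcome (tornado diagram).

The probabilistic analysis draws every uncertain parameter from its
moment-matched distribution — beta for probabilities and utilities, gamma
for costs — evaluates all strategies under the same joint draw (common
random numbers), and summarises the draws as a cost-effectiveness plane and
acceptability curves.  Mortality ratios are held fixed between draws unless
``vary_mortality_in_psa`` is enabled, in which case they are drawn gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import StrategyOutcome, nmb
from .life_tables import LifeTable, MortalityModel, make_gompertz_life_table
from .markov import STRATEGIES, run_cohort, strategy_from_parameters
from .parameters import (
    ParameterSet,
    dsa_bounds,
    effective_beta_se,
    fit_beta_moments,
    fit_gamma_moments,
)

__all__ = [
    "evaluate_strategies",
    "one_way_dsa",
    "run_psa",
    "PsaResult",
    "ce_plane",
    "ceac",
    "default_wtp_grid",
]

_MORTALITY_PARAMS = (
    "smr_50_59",
    "smr_60_69",
    "smr_70_79",
    "smr_80_plus",
    "eskd_vs_kt_mortality_ratio",
)


def evaluate_strategies(
    params: ParameterSet,
    life_table: LifeTable | None = None,
    strategy_names=STRATEGIES,
    discount_rate: float | None = None,
) -> dict[str, StrategyOutcome]:
    """Run the cohort model for each strategy and return discounted totals."""
    mortality = MortalityModel.from_parameters(params, life_table)
    out = {}
    for name in strategy_names:
        spec = strategy_from_parameters(params, name)
        tr = run_cohort(params, mortality, spec, discount_rate=discount_rate)
        out[name] = StrategyOutcome(name=name, cost=tr.total_cost, qaly=tr.total_qaly, ly=tr.total_ly)
    return out


def _incremental(outcomes, reference, comparator, wtp, metric):
    ref, comp = outcomes[reference], outcomes[comparator]
    if metric == "incremental_cost":
        return ref.cost - comp.cost
    if metric == "nmb":
        return nmb(ref, wtp) - nmb(comp, wtp)
    raise ValueError(f"unknown tornado metric {metric!r}")


def one_way_dsa(
    params: ParameterSet,
    reference: str = "P-LRKT",
    comparator: str = "NP-DDKT",
    metric: str = "incremental_cost",
    life_table: LifeTable | None = None,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by descending spread.

    ``metric`` is the incremental outcome recorded at each bound:
    ``incremental_cost`` (default; the base-case comparison is cost-saving, so
    an ICER is undefined) or ``nmb`` (incremental net monetary benefit, which
    also registers utility parameters).
    """
    if parameters is None:
        parameters = [
            s.name
            for s in params.specs.values()
            if s.role in ("probability", "cost", "utility", "ratio")
        ] + ["discount_rate"]
    names = (reference, comparator)
    rows = []
    for pname in parameters:
        if pname == "discount_rate":
            low = float(params.settings.get("discount_rate_low", 0.0))
            high = float(params.settings.get("discount_rate_high", 0.06))
            runs = {
                side: evaluate_strategies(params, life_table, names, discount_rate=val)
                for side, val in (("low", low), ("high", high))
            }
        else:
            spec = params.spec(pname)
            low, high = dsa_bounds(spec)
            runs = {
                side: evaluate_strategies(
                    params.with_values({pname: val}), life_table, names
                )
                for side, val in (("low", low), ("high", high))
            }
        at_low = _incremental(runs["low"], reference, comparator, params.wtp, metric)
        at_high = _incremental(runs["high"], reference, comparator, params.wtp, metric)
        rows.append(
            {
                "parameter": pname,
                "low_input": low,
                "high_input": high,
                "outcome_at_low": at_low,
                "outcome_at_high": at_high,
                "spread": abs(at_high - at_low),
            }
        )
    df = pd.DataFrame(rows).sort_values("spread", ascending=False, kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _build_samplers(params: ParameterSet, vary_mortality: bool):
    """(name, family, dist-args) for every parameter drawn in the PSA."""
    samplers = []
    for s in params.specs.values():
        if s.name in _MORTALITY_PARAMS:
            if vary_mortality and s.se:
                samplers.append((s.name, "gamma", fit_gamma_moments(s.value, s.se)))
            continue
        if s.family == "beta" and s.se:
            se = effective_beta_se(s.value, s.se, s.name)
            samplers.append((s.name, "beta", fit_beta_moments(s.value, se)))
        elif s.family == "gamma" and s.se:
            samplers.append((s.name, "gamma", fit_gamma_moments(s.value, s.se)))
    return samplers


@dataclass
class PsaResult:
    """Monte Carlo draws with per-strategy discounted outcomes."""

    samples: pd.DataFrame  # one row per draw: cost_<s>, qaly_<s>, ly_<s>
    draws: pd.DataFrame  # the parameter values behind each row
    wtp: float
    seed: int | None
    strategies: tuple[str, ...]

    def outcome(self, strategy: str, draw: int) -> StrategyOutcome:
        row = self.samples.iloc[draw]
        return StrategyOutcome(
            name=strategy,
            cost=row[f"cost_{strategy}"],
            qaly=row[f"qaly_{strategy}"],
            ly=row[f"ly_{strategy}"],
        )


def run_psa(
    params: ParameterSet,
    n: int = 1000,
    seed: int | None = None,
    life_table: LifeTable | None = None,
    strategy_names=STRATEGIES,
) -> PsaResult:
    """``n`` joint Monte Carlo draws, all strategies evaluated per draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    vary_mortality = bool(params.settings.get("vary_mortality_in_psa", False))
    samplers = _build_samplers(params, vary_mortality)
    lt = life_table if life_table is not None else make_gompertz_life_table()
    base_mortality = MortalityModel.from_parameters(params, lt)
    rng = np.random.default_rng(seed)

    draw_rows, sample_rows = [], []
    for i in range(n):
        overrides = {}
        for name, family, args in samplers:
            if family == "beta":
                overrides[name] = rng.beta(*args)
            else:
                shape, scale = args
                overrides[name] = rng.gamma(shape, scale)
        ps = params.with_values(overrides)
        mortality = (
            MortalityModel.from_parameters(ps, lt) if vary_mortality else base_mortality
        )
        row = {"draw": i}
        for sname in strategy_names:
            spec = strategy_from_parameters(ps, sname)
            tr = run_cohort(ps, mortality, spec)
            row[f"cost_{sname}"] = tr.total_cost
            row[f"qaly_{sname}"] = tr.total_qaly
            row[f"ly_{sname}"] = tr.total_ly
        sample_rows.append(row)
        draw_rows.append({"draw": i, **overrides})
    return PsaResult(
        samples=pd.DataFrame(sample_rows),
        draws=pd.DataFrame(draw_rows),
        wtp=params.wtp,
        seed=seed,
        strategies=tuple(strategy_names),
    )


def ce_plane(
    psa: PsaResult, reference: str, comparator: str, wtp: float | None = None
) -> dict:
    """Quadrant and threshold summary of (dQALY, dCost) per draw.

    Quadrants follow the cost-effectiveness plane convention with the QALY
    difference on the x axis: the south-east quadrant (more QALYs, lower
    cost) is dominant.  ``below_line`` counts draws with
    dCost < wtp * dQALY.
    """
    w = psa.wtp if wtp is None else wtp
    d_cost = (psa.samples[f"cost_{reference}"] - psa.samples[f"cost_{comparator}"]).to_numpy()
    d_qaly = (psa.samples[f"qaly_{reference}"] - psa.samples[f"qaly_{comparator}"]).to_numpy()
    quadrant = np.where(
        d_qaly > 0,
        np.where(d_cost < 0, "SE", "NE"),
        np.where(d_cost < 0, "SW", "NW"),
    )
    below = d_cost < w * d_qaly
    n = len(d_cost)
    per_draw = pd.DataFrame(
        {"delta_qaly": d_qaly, "delta_cost": d_cost, "quadrant": quadrant, "below_line": below}
    )
    return {
        "reference": reference,
        "comparator": comparator,
        "wtp": w,
        "n": n,
        "fraction_se": float(np.mean(quadrant == "SE")),
        "fraction_ne": float(np.mean(quadrant == "NE")),
        "fraction_sw": float(np.mean(quadrant == "SW")),
        "fraction_nw": float(np.mean(quadrant == "NW")),
        "fraction_below_line": float(np.mean(below)),
        "fraction_above_line": float(np.mean(~below)),
        "per_draw": per_draw,
    }


def default_wtp_grid() -> np.ndarray:
    return np.arange(0.0, 20000.0 + 1e-9, 250.0)


def ceac(psa: PsaResult, wtp_grid=None) -> pd.DataFrame:
    """Probability each strategy has maximal net monetary benefit per WTP.

    Ties split their probability mass equally.  Rows sum to one across
    strategies at every grid point.
    """
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    costs = np.column_stack([psa.samples[f"cost_{s}"] for s in psa.strategies])
    qalys = np.column_stack([psa.samples[f"qaly_{s}"] for s in psa.strategies])
    n = costs.shape[0]
    probs = np.zeros((len(grid), len(psa.strategies)))
    for k, w in enumerate(grid):
        benefit = w * qalys - costs
        best = benefit.max(axis=1, keepdims=True)
        winners = np.isclose(benefit, best, rtol=0.0, atol=1e-9)
        probs[k] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n
    out = pd.DataFrame(probs, columns=list(psa.strategies))
    out.insert(0, "wtp", grid)
    return out
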