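"""Pipeline orchestration and tabular report generation.

Ties the modules together into the full analysis: base-case totals and
dominance table, scenario comparisons, one-way (tornado) sensitivity,
probabilistic sensitivity with cost-effectiveness plane and acceptability
curves, and an optional synthetic-cohort parameter-recovery round trip.
Every output directory receives a ``summary.json`` carrying the headline
numbers, the seed, and a hash of the configuration actually used, making
runs auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import StrategyOutcome, classify, frontier
from .life_tables import LifeTable, load_life_table
from .markov import NP_DDKT, NP_LRKT, P_LRKT, STRATEGIES
from .parameters import ParameterSet, load_parameters
from .sensitivity import ce_plane, ceac, evaluate_strategies, one_way_dsa, run_psa
from .synthetic import estimate_inputs, generate_cohort

__all__ = ["RunConfig", "run_base_case", "run_full_pipeline"]

log = logging.getLogger("ktcea")

_SCENARIOS = ((P_LRKT, NP_DDKT), (P_LRKT, NP_LRKT), (NP_LRKT, NP_DDKT))


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    params_path: str | None = None  # None -> packaged default
    life_table_path: str | None = None  # None -> builtin synthetic table
    strategies: tuple[str, ...] = STRATEGIES
    analyses: tuple[str, ...] = ("base",)
    n_psa: int = 1000
    seed: int | None = 20220708
    out_dir: str | None = None
    wtp: float | None = None
    discount: float | None = None
    n_synthetic: dict[str, int] | None = None
    figures: bool = False

    def load(self) -> tuple[ParameterSet, LifeTable | None]:
        params = load_parameters(self.params_path)
        if self.wtp is not None:
            params.wtp = float(self.wtp)
        if self.discount is not None:
            params.discount_rate = float(self.discount)
        lt = None
        if self.life_table_path and self.life_table_path != "builtin":
            lt = load_life_table(self.life_table_path)
        if "psa" in self.analyses or "ceac" in self.analyses:
            if self.n_psa < 1:
                raise ValueError("n_psa must be >= 1 when a probabilistic analysis is requested")
        return params, lt

    def config_hash(self, params: ParameterSet) -> str:
        payload = json.dumps(
            {"params": params.to_dict(), "seed": self.seed, "n_psa": self.n_psa},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _outcomes_frame(outcomes: dict[str, StrategyOutcome]) -> pd.DataFrame:
    rows = [
        {
            "strategy": o.name,
            "total_cost": o.cost,
            "life_expectancy": o.ly,
            "qaly": o.qaly,
            "cost_per_ly": o.cost / o.ly,
        }
        for o in outcomes.values()
    ]
    return pd.DataFrame(rows)


def _scenario_frame(outcomes: dict[str, StrategyOutcome], wtp: float) -> pd.DataFrame:
    rows = []
    for ref, comp in _SCENARIOS:
        if ref not in outcomes or comp not in outcomes:
            continue
        r = classify(outcomes[ref], outcomes[comp], wtp)
        rows.append(
            {
                "reference": r.reference,
                "comparator": r.comparator,
                "incremental_cost": r.incremental_cost,
                "qaly_gained": r.qaly_gained,
                "icer": np.nan if r.icer is None else r.icer,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)


def run_base_case(config: RunConfig) -> dict:
    """Base-case totals, dominance table and pairwise scenario comparisons."""
    params, lt = config.load()
    outcomes = evaluate_strategies(params, lt, config.strategies)
    results = {
        "outcomes": _outcomes_frame(outcomes),
        "frontier": frontier(list(outcomes.values()), params.wtp),
        "scenarios": _scenario_frame(outcomes, params.wtp),
        "_outcome_objects": outcomes,
    }
    if config.out_dir:
        _write(config, params, results)
    return results


def run_full_pipeline(config: RunConfig) -> dict:
    """Base case plus any of dsa / psa / ceac / synthetic, with stage logging."""
    params, lt = config.load()
    results: dict = {}
    failed = False
    stages = ["base"] + [a for a in ("dsa", "psa", "ceac", "synthetic") if a in config.analyses]
    for stage in stages:
        if failed:
            log.warning("skipping stage %s after earlier failure", stage)
            continue
        try:
            if stage == "base":
                outcomes = evaluate_strategies(params, lt, config.strategies)
                results["outcomes"] = _outcomes_frame(outcomes)
                results["frontier"] = frontier(list(outcomes.values()), params.wtp)
                results["scenarios"] = _scenario_frame(outcomes, params.wtp)
                results["_outcome_objects"] = outcomes
            elif stage == "dsa":
                results["tornado"] = one_way_dsa(params, life_table=lt)
                results["tornado_nmb"] = one_way_dsa(params, metric="nmb", life_table=lt)
            elif stage == "psa":
                psa = run_psa(params, n=config.n_psa, seed=config.seed, life_table=lt)
                results["psa"] = psa
                plane = ce_plane(psa, P_LRKT, NP_DDKT)
                results["ce_plane"] = plane
                results["ce_plane_nplrkt"] = ce_plane(psa, NP_LRKT, NP_DDKT)
            elif stage == "ceac":
                if "psa" not in results:
                    results["psa"] = run_psa(params, n=config.n_psa, seed=config.seed, life_table=lt)
                results["ceac"] = ceac(results["psa"])
            elif stage == "synthetic":
                cohort = generate_cohort(params, n_per_strategy=config.n_synthetic, seed=config.seed)
                est = estimate_inputs(cohort)
                results["synthetic_cohort"] = cohort
                results["synthetic_estimates"] = est
        except Exception:
            log.exception("stage %s failed", stage)
            failed = True
    if config.out_dir:
        _write(config, params, results)
    return results


def _summary(config: RunConfig, params: ParameterSet, results: dict) -> dict:
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(params),
        "wtp": params.wtp,
        "discount_rate": params.discount_rate,
        "settings": dict(params.settings),
    }
    if "outcomes" in results:
        for row in results["outcomes"].to_dict("records"):
            key = row["strategy"].lower().replace("-", "_")
            summary[f"{key}_total_cost"] = row["total_cost"]
            summary[f"{key}_qaly"] = row["qaly"]
            summary[f"{key}_ly"] = row["life_expectancy"]
            summary[f"{key}_cost_per_ly"] = row["cost_per_ly"]
    if "ce_plane" in results:
        p = results["ce_plane"]
        summary["psa_fraction_cost_saving"] = p["fraction_se"]
        summary["psa_fraction_below_wtp"] = p["fraction_below_line"]
    if "ce_plane_nplrkt" in results:
        summary["psa_nplrkt_fraction_above_wtp"] = results["ce_plane_nplrkt"]["fraction_above_line"]
    return summary


def _write(config: RunConfig, params: ParameterSet, results: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("outcomes", "frontier", "scenarios", "tornado", "tornado_nmb", "ceac"):
        if name in results:
            results[name].to_csv(out / f"{name}.csv", index=False)
    if "psa" in results:
        results["psa"].samples.to_csv(out / "psa_samples.csv", index=False)
        results["psa"].draws.to_csv(out / "psa_draws.csv", index=False)
    if "ce_plane" in results:
        results["ce_plane"]["per_draw"].to_csv(out / "ce_plane.csv", index=False)
    if "synthetic_cohort" in results:
        results["synthetic_cohort"].to_csv(out / "synthetic_cohort.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(_summary(config, params, results), fh, indent=2, default=float)
    if config.figures:
        from . import plots

        if "tornado" in results:
            plots.tornado_plot(results["tornado"], out / "tornado.png")
        if "ce_plane" in results:
            plots.ce_plane_plot(results["ce_plane"], out / "ce_plane.png")
        if "ceac" in results:
            plots.ceac_plot(results["ceac"], out / "ceac.png")
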