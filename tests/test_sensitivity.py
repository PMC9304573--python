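import copy

import numpy as np
import pandas as pd
import pytest

from ktcea.parameters import ParameterSet, fit_beta_moments, fit_gamma_moments
from ktcea.sensitivity import (
    PsaResult,
    ce_plane,
    ceac,
    default_wtp_grid,
    evaluate_strategies,
    one_way_dsa,
    run_psa,
)


def all_fixed(params: ParameterSet) -> ParameterSet:
    """Copy of a parameter set with every distribution degenerate."""
    data = params.to_dict()
    for block in data["parameters"]:
        block["family"] = "fixed"
    return ParameterSet.from_dict(data)


def fake_psa(rows: dict, wtp=5113.0, strategies=("A", "B")) -> PsaResult:
    df = pd.DataFrame(rows)
    df.insert(0, "draw", range(len(df)))
    return PsaResult(samples=df, draws=df[["draw"]].copy(), wtp=wtp, seed=0, strategies=strategies)


class TestOneWayDsa:
    def test_unread_parameter_has_exactly_zero_spread(self, params):
        # the literature dialysis costing is inert under the cohort profile
        df = one_way_dsa(params, parameters=["cost_dialysis_literature"])
        assert df.loc[0, "spread"] == 0.0

    def test_zero_width_bounds_give_zero_spread(self, params):
        data = params.to_dict()
        for block in data["parameters"]:
            if block["name"] == "cost_kt_plrkt":
                block["low"] = block["high"] = block["value"]
                block.pop("se", None)
        p2 = ParameterSet.from_dict(data)
        df = one_way_dsa(p2, parameters=["cost_kt_plrkt"])
        assert df.loc[0, "spread"] == 0.0

    def test_widening_bounds_widens_spread(self, params):
        spreads = []
        for se in (300.0, 600.0, 1200.0):
            data = params.to_dict()
            for block in data["parameters"]:
                if block["name"] == "cost_subsequent_plrkt":
                    block["se"] = se
            p2 = ParameterSet.from_dict(data)
            df = one_way_dsa(p2, parameters=["cost_subsequent_plrkt"])
            spreads.append(df.loc[0, "spread"])
        assert spreads[0] < spreads[1] < spreads[2]

    def test_discount_rate_uses_explicit_range(self, params):
        df = one_way_dsa(params, parameters=["discount_rate"])
        assert df.loc[0, "low_input"] == 0.0
        assert df.loc[0, "high_input"] == 0.06
        assert df.loc[0, "spread"] > 0.0

    def test_sorted_by_descending_spread(self, params):
        df = one_way_dsa(
            params,
            parameters=["cost_subsequent_plrkt", "cost_kt_plrkt", "utility_subsequent"],
            metric="nmb",
        )
        assert list(df["spread"]) == sorted(df["spread"], reverse=True)


class TestRunPsa:
    def test_same_seed_reproduces_samples_exactly(self, params):
        a = run_psa(params, n=25, seed=123)
        b = run_psa(params, n=25, seed=123)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_different_seed_differs(self, params):
        a = run_psa(params, n=5, seed=1)
        b = run_psa(params, n=5, seed=2)
        assert not a.samples.equals(b.samples)

    def test_all_fixed_families_reproduce_base_case(self, params):
        p2 = all_fixed(params)
        psa = run_psa(p2, n=4, seed=9)
        base = evaluate_strategies(params)
        for name, outcome in base.items():
            assert np.allclose(psa.samples[f"cost_{name}"], outcome.cost)
            assert np.allclose(psa.samples[f"qaly_{name}"], outcome.qaly)

    def test_draws_stay_within_distribution_support(self, params):
        psa = run_psa(params, n=50, seed=5)
        for col in psa.draws.columns:
            if col.startswith("utility") or col.startswith("p_"):
                assert ((psa.draws[col] >= 0) & (psa.draws[col] <= 1)).all()
            elif col.startswith("cost"):
                assert (psa.draws[col] >= 0).all()

    def test_invalid_n_rejected(self, params):
        with pytest.raises(ValueError):
            run_psa(params, n=0)

    def test_sampled_means_recover_inputs(self, params):
        """Monte Carlo means of each fitted distribution match the printed
        mean within 4 standard errors of the estimate (law of large numbers)."""
        rng = np.random.default_rng(2024)
        n = 100_000
        for spec in params.specs.values():
            if spec.family == "beta" and spec.se:
                a, b = fit_beta_moments(spec.value, spec.se)
                draws = rng.beta(a, b, size=n)
            elif spec.family == "gamma" and spec.se:
                k, s = fit_gamma_moments(spec.value, spec.se)
                draws = rng.gamma(k, s, size=n)
            else:
                continue
            z = (draws.mean() - spec.value) / (spec.se / np.sqrt(n))
            assert abs(z) < 4.0, spec.name


class TestCePlane:
    def test_dominant_draw_is_southeast_and_below_line(self):
        psa = fake_psa(
            {"cost_A": [90.0], "qaly_A": [2.0], "cost_B": [100.0], "qaly_B": [1.0]}
        )
        plane = ce_plane(psa, "A", "B", wtp=0.0)
        assert plane["fraction_se"] == 1.0
        assert plane["fraction_below_line"] == 1.0

    def test_quadrant_fractions_partition(self, params):
        psa = run_psa(params, n=40, seed=11)
        plane = ce_plane(psa, "P-LRKT", "NP-DDKT")
        total = (
            plane["fraction_se"]
            + plane["fraction_ne"]
            + plane["fraction_sw"]
            + plane["fraction_nw"]
        )
        assert total == pytest.approx(1.0)
        assert plane["fraction_below_line"] + plane["fraction_above_line"] == pytest.approx(1.0)

    def test_huge_wtp_counts_positive_qaly_gains(self):
        psa = fake_psa(
            {
                "cost_A": [100.0, 100.0],
                "qaly_A": [2.0, 0.5],
                "cost_B": [10.0, 10.0],
                "qaly_B": [1.0, 1.0],
            }
        )
        plane = ce_plane(psa, "A", "B", wtp=1e12)
        assert plane["fraction_below_line"] == 0.5


class TestCeac:
    def test_probabilities_sum_to_one_at_every_wtp(self, params):
        psa = run_psa(params, n=60, seed=3)
        curve = ceac(psa, np.arange(0, 20001, 2500))
        sums = curve.drop(columns="wtp").sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_degenerate_distributions_give_indicator_curve(self, params):
        p2 = all_fixed(params)
        psa = run_psa(p2, n=3, seed=1)
        curve = ceac(psa, [0.0, 5113.0, 20000.0]).set_index("wtp")
        for _, row in curve.iterrows():
            assert sorted(row.values) == [0.0, 0.0, 1.0]

    def test_zero_wtp_selects_cheapest(self):
        psa = fake_psa(
            {
                "cost_A": [10.0, 30.0],
                "qaly_A": [1.0, 1.0],
                "cost_B": [20.0, 20.0],
                "qaly_B": [9.0, 9.0],
            }
        )
        curve = ceac(psa, [0.0]).set_index("wtp")
        assert curve.loc[0.0, "A"] == 0.5
        assert curve.loc[0.0, "B"] == 0.5

    def test_ties_split_probability_mass(self):
        psa = fake_psa({"cost_A": [50.0], "qaly_A": [1.0], "cost_B": [50.0], "qaly_B": [1.0]})
        curve = ceac(psa, [1000.0]).set_index("wtp")
        assert curve.loc[1000.0, "A"] == 0.5
        assert curve.loc[1000.0, "B"] == 0.5

    def test_default_grid(self):
        grid = default_wtp_grid()
        assert grid[0] == 0.0 and grid[-1] == 20000.0
        assert np.all(np.diff(grid) == 250.0)

    def test_empty_grid_rejected(self, params):
        psa = run_psa(params, n=2, seed=1)
        with pytest.raises(ValueError):
            ceac(psa, [])
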