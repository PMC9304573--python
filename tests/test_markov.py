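import math

import numpy as np
import pytest

from conftest import flat_life_table
from ktcea.life_tables import DIALYSIS, KT, MortalityModel, STATES
from ktcea.markov import (
    STRATEGIES,
    StrategySpec,
    build_transition_matrix,
    cost_per_ly,
    discount_factor,
    run_cohort,
    strategy_from_parameters,
)


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate, cycle, expected", [(0.03, 0, 1.0), (0.03, 2, 0.942596), (0.0, 17, 1.0)]
    )
    def test_discount_factor(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


class TestTransitionMatrix:
    def test_ddkt_dialysis_row_with_zero_mortality(self, params, zero_mortality):
        spec = strategy_from_parameters(params, "NP-DDKT")
        m = build_transition_matrix(params, zero_mortality, spec, age=55)
        assert m[0] == pytest.approx([0.82, 0.18, 0.0, 0.0, 0.0])

    def test_kt_row_with_zero_mortality(self, params, zero_mortality):
        spec = strategy_from_parameters(params, "P-LRKT")
        m = build_transition_matrix(params, zero_mortality, spec, age=55)
        assert m[1] == pytest.approx([0.04, 0.0, 0.96, 0.0, 0.0])

    def test_death_row_is_absorbing(self, params, mortality):
        spec = strategy_from_parameters(params, "NP-LRKT")
        m = build_transition_matrix(params, mortality, spec, age=60)
        assert m[4] == pytest.approx([0.0, 0.0, 0.0, 0.0, 1.0])

    @pytest.mark.parametrize("strategy", STRATEGIES)
    @pytest.mark.parametrize("age", [50, 64, 65, 66, 80, 100])
    def test_rows_sum_to_one(self, params, mortality, strategy, age):
        spec = strategy_from_parameters(params, strategy)
        m = build_transition_matrix(params, mortality, spec, age=age)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((m >= 0) & (m <= 1))

    def test_no_transplant_after_stop_age(self, params, zero_mortality):
        spec = strategy_from_parameters(params, "NP-DDKT")
        m = build_transition_matrix(params, zero_mortality, spec, age=66)
        assert m[0, 1] == 0.0
        assert m[0, 0] == 1.0

    def test_retransplant_flag_controls_dialysis_exit(self, params, zero_mortality):
        no_retx = dict(params.settings, allow_retransplant=False)
        import copy

        p2 = copy.copy(params)
        p2.settings = no_retx
        spec = strategy_from_parameters(p2, "NP-DDKT")
        m = build_transition_matrix(p2, zero_mortality, spec, age=55, retransplant_eligible=False)
        assert m[0, 1] == 0.0


def two_cycle_toy():
    """Everyone survives two cycles on dialysis, then dies."""
    qx = np.zeros(111)
    qx[51:] = 1.0 - 1e-12
    lt_model = MortalityModel(
        life_table=flat_life_table(0.0),
        smr_bands=((0.0, math.inf, 1.0),),
        eskd_vs_kt_ratio=1.0,
    )
    from ktcea.life_tables import LifeTable

    lt_model = MortalityModel(
        life_table=LifeTable(ages=np.arange(111), qx=qx),
        smr_bands=((0.0, math.inf, 1.0),),
        eskd_vs_kt_ratio=1.0,
    )
    spec = StrategySpec(
        name="NP-DDKT",
        entry_state=DIALYSIS,
        p_dialysis_to_kt=0.0,
        annual_costs={s: 100.0 for s in STATES[:4]},
        one_off_costs={"kt_event": 0.0, "waiting": 0.0},
    )
    return lt_model, spec


class TestRunCohort:
    def test_two_cycle_hand_computation(self, params):
        mort, spec = two_cycle_toy()
        p = params.with_values(
            {f"utility_{k}": 0.5 for k in ("dialysis", "kt", "post1", "subsequent")}
        )
        trace = run_cohort(p, mort, spec, discount_rate=0.0)
        assert trace.total_cost == pytest.approx(200.0, abs=1e-6)
        assert trace.total_ly == pytest.approx(2.0, abs=1e-6)
        assert trace.total_qaly == pytest.approx(1.0, abs=1e-6)

    def test_unit_utilities_make_qaly_equal_ly(self, params, mortality):
        p = params.with_values(
            {f"utility_{k}": 1.0 for k in ("dialysis", "kt", "post1", "subsequent")}
        )
        for name in STRATEGIES:
            trace = run_cohort(p, mortality, strategy_from_parameters(p, name))
            assert trace.total_qaly == pytest.approx(trace.total_ly, abs=1e-9)

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_occupancy_is_conserved_each_cycle(self, params, mortality, strategy):
        trace = run_cohort(params, mortality, strategy_from_parameters(params, strategy)).trace
        occ = trace[
            [
                "occ_dialysis",
                "occ_kt",
                "occ_post_kt_year1",
                "occ_post_kt_subsequent",
                "occ_death",
            ]
        ].sum(axis=1)
        assert np.allclose(occ, 1.0, atol=1e-9)

    def test_no_graft_loss_keeps_preemptive_cohort_off_dialysis(self, params, mortality):
        p = params.with_values({"p_graft_loss_year1": 0.0, "p_graft_loss_subsequent": 0.0})
        trace = run_cohort(p, mortality, strategy_from_parameters(p, "P-LRKT")).trace
        assert np.all(trace["occ_dialysis"] == 0.0)

    def test_discount_monotonicity(self, params, mortality):
        spec = strategy_from_parameters(params, "NP-LRKT")
        prev = None
        for rate in (0.0, 0.01, 0.03, 0.06):
            tr = run_cohort(params, mortality, spec, discount_rate=rate)
            totals = (tr.total_cost, tr.total_ly, tr.total_qaly)
            if prev is not None:
                assert all(t <= pt + 1e-9 for t, pt in zip(totals, prev))
            prev = totals

    def test_discounted_totals_bounded_by_undiscounted(self, params, mortality):
        tr = run_cohort(params, mortality, strategy_from_parameters(params, "P-LRKT"))
        assert tr.total_cost <= tr.undiscounted_cost
        assert tr.total_ly <= tr.undiscounted_ly
        assert tr.total_qaly <= tr.undiscounted_qaly

    def test_base_case_strategy_ordering(self, params, mortality):
        """Preemptive transplantation costs least and yields the most QALYs."""
        totals = {
            name: run_cohort(params, mortality, strategy_from_parameters(params, name))
            for name in STRATEGIES
        }
        p = totals["P-LRKT"]
        for other in ("NP-LRKT", "NP-DDKT"):
            assert p.total_cost < totals[other].total_cost
            assert p.total_qaly >= totals[other].total_qaly

    def test_waiting_cost_charged_once_at_entry(self, params, mortality):
        spec = strategy_from_parameters(params, "P-LRKT")
        trace = run_cohort(params, mortality, spec).trace
        base = strategy_from_parameters(
            params.with_values({"cost_waiting_plrkt": 0.0}), "P-LRKT"
        )
        trace0 = run_cohort(params, mortality, base).trace
        diff = trace["cycle_cost"] - trace0["cycle_cost"]
        assert diff.iloc[0] == pytest.approx(6879.0)
        assert np.allclose(diff.iloc[1:], 0.0)


class TestCostPerLy:
    @pytest.mark.parametrize(
        "cost, ly, expected",
        [
            (170355.79, 16.00, 10647.24),
            (180338.83, 15.70, 11486.55),
            (0.0, 5.0, 0.0),
        ],
    )
    def test_examples(self, cost, ly, expected):
        assert cost_per_ly(cost, ly) == pytest.approx(expected, abs=0.005)

    def test_zero_ly_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cost_per_ly(100.0, 0.0)


class TestCostAttachment:
    def test_literal_mapping_charges_states_their_named_costs(self, params):
        spec = strategy_from_parameters(params, "NP-DDKT")
        assert spec.annual_costs["kt"] == 0.0
        assert spec.annual_costs["post_kt_year1"] == 19520.0
        assert spec.one_off_costs["kt_event"] == 13908.0

    def test_alternative_mapping_loads_first_year_onto_transplant_cycle(self, params):
        import copy

        p2 = copy.copy(params)
        p2.settings = dict(params.settings, cost_attachment="first_year_at_kt")
        spec = strategy_from_parameters(p2, "NP-DDKT")
        assert spec.annual_costs["kt"] == 19520.0
        assert spec.annual_costs["post_kt_year1"] == 10478.0

    def test_literature_costing_profile(self, params):
        import copy

        p2 = copy.copy(params)
        p2.settings = dict(params.settings, dialysis_costing="literature")
        spec = strategy_from_parameters(p2, "NP-DDKT")
        assert spec.annual_costs["dialysis"] == pytest.approx(12193 + 12 * 481 + 1059)
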