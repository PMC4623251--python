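"""Costing: ingredient bundles, prevention/treatment totals, human-capital value."""

import dataclasses

import pytest

from footcea import (
    CostBundle,
    IngredientLine,
    Strategy,
    compute_flows,
    indirect_cost_per_death,
    prevention_cost,
    total_direct_cost,
    treatment_cost,
    unit_cost_from_bundle,
)
from footcea.parameters import with_values
from footcea.synthetic import ScenarioSpec, generate_parameter_set


class TestBundles:
    def test_empty_bundle_costs_nothing(self):
        assert unit_cost_from_bundle(CostBundle("empty")) == 0.0

    def test_single_line(self):
        b = CostBundle("x", [IngredientLine("dressing", 3, 10.0)])
        assert unit_cost_from_bundle(b) == 30.0

    def test_debridement_fixture_reproduces_aggregate(self, peru):
        # synthetic ingredient lines calibrated so the bundle sums to the
        # published aggregate unit cost; the aggregate is the model input
        bundle = CostBundle(
            "debridement",
            [
                IngredientLine("hospitalization, 6 days", 6, 120.0),
                IngredientLine("debridement procedure", 1, 180.0),
                IngredientLine("tests and antibiotics", 1, 92.0),
                IngredientLine("wound-healing procedures", 6, 5.0),
            ],
        )
        assert unit_cost_from_bundle(bundle) == peru.cost_debridement == 1_022

    def test_negative_quantities_rejected(self):
        with pytest.raises(ValueError):
            IngredientLine("bad", -1, 5.0)


class TestPreventionCost:
    @pytest.mark.parametrize(
        "strategy, expected",
        [
            (Strategy.SUB_OPTIMAL, 13_350_763),
            (Strategy.STANDARD, 38_129_966),
            (Strategy.STANDARD_PLUS_TEMP, 83_849_832),
        ],
    )
    def test_published_totals(self, peru, strategy, expected):
        assert prevention_cost(peru, strategy) == pytest.approx(expected, abs=1.0)

    def test_zero_population(self, peru):
        empty = with_values(peru, total_diabetes_population=0.0)
        assert prevention_cost(empty, Strategy.STANDARD) == 0.0


class TestTreatmentCost:
    def test_debridement_endpoint_sub_optimal(self, peru):
        flows = compute_flows(peru, Strategy.SUB_OPTIMAL)
        cost = treatment_cost(flows, peru)["debridement"]
        assert cost == pytest.approx(5_535_166, rel=1e-3)

    def test_treatment_total_temp_monitoring(self, peru):
        bd = total_direct_cost(peru, Strategy.STANDARD_PLUS_TEMP)
        assert bd.treatment_total == pytest.approx(12_950_435, rel=1e-3)

    def test_deaths_costed_at_their_amputation(self, peru):
        flows = compute_flows(peru, Strategy.SUB_OPTIMAL)
        costs = treatment_cost(flows, peru)
        assert costs["death_major"] == pytest.approx(
            flows.n_death_major_amputation * peru.cost_major_amputation
        )
        assert costs["death_minor"] == pytest.approx(
            flows.n_death_minor_amputation * peru.cost_minor_amputation
        )

    def test_zero_ulcers_zero_treatment(self, peru):
        ps = with_values(peru, baseline_ulcer_prevalence=0.0, ranges={})
        flows = compute_flows(ps, Strategy.SUB_OPTIMAL)
        assert all(v == 0.0 for v in treatment_cost(flows, ps).values())


class TestIndirectCost:
    def test_published_value(self, peru):
        # PEN 750 / 2.64 x 12 x (1 + 1/1.03) = 6,718.9, quoted as US$6,719
        assert indirect_cost_per_death(peru.economic) == pytest.approx(6_718.9, abs=0.05)

    def test_no_discounting_is_full_wage_bill(self, peru):
        econ = dataclasses.replace(peru.economic, discount_rate=0.0)
        monthly_usd = peru.economic.minimum_wage_local / peru.economic.exchange_rate
        assert indirect_cost_per_death(econ) == pytest.approx(24 * monthly_usd)

    def test_single_year_undiscounted(self, peru):
        econ = dataclasses.replace(peru.economic, mean_age_at_death=64.0)
        monthly_usd = peru.economic.minimum_wage_local / peru.economic.exchange_rate
        assert indirect_cost_per_death(econ) == pytest.approx(12 * monthly_usd)

    def test_no_years_left_warns_and_returns_zero(self, peru):
        econ = dataclasses.replace(peru.economic, mean_age_at_death=66.0,
                                   retirement_age=65.0)
        with pytest.warns(UserWarning):
            assert indirect_cost_per_death(econ) == 0.0

    def test_discount_limit_matches_undiscounted(self, peru):
        tiny = dataclasses.replace(peru.economic, discount_rate=1e-12)
        zero = dataclasses.replace(peru.economic, discount_rate=0.0)
        assert indirect_cost_per_death(tiny) == pytest.approx(
            indirect_cost_per_death(zero), rel=1e-9
        )

    def test_currency_invariance(self, peru):
        base = indirect_cost_per_death(peru.economic)
        scaled = dataclasses.replace(
            peru.economic,
            minimum_wage_local=peru.economic.minimum_wage_local * 7.3,
            exchange_rate=peru.economic.exchange_rate * 7.3,
        )
        assert indirect_cost_per_death(scaled) == pytest.approx(base, rel=1e-12)


class TestTotals:
    @pytest.mark.parametrize(
        "strategy, millions",
        [(Strategy.SUB_OPTIMAL, 74.5), (Strategy.STANDARD, 71.8)],
    )
    def test_direct_totals_in_millions(self, peru, strategy, millions):
        bd = total_direct_cost(peru, strategy)
        assert round(bd.direct_total / 1e6, 1) == millions

    def test_zero_scenario(self, peru):
        prevention = {s: 0.0 for s in Strategy}
        ps = with_values(
            peru,
            baseline_ulcer_prevalence=0.0,
            prevention_cost_per_person=prevention,
            ranges={},
        )
        bd = total_direct_cost(ps, Strategy.SUB_OPTIMAL)
        assert bd.direct_total == 0.0

    def test_direct_total_is_prevention_plus_treatment_on_random_scenarios(self):
        for seed in range(200):
            ps = generate_parameter_set(ScenarioSpec(seed=seed))
            for strategy in Strategy:
                bd = total_direct_cost(ps, strategy)
                assert bd.direct_total == pytest.approx(
                    bd.prevention_total + bd.treatment_total, rel=1e-9
                )
                assert bd.treatment_total == pytest.approx(
                    sum(bd.treatment_by_endpoint.values()), rel=1e-9
                )
                assert min(bd.treatment_by_endpoint.values()) >= 0

    def test_treatment_total_monotone_in_prevalence(self, peru):
        low = total_direct_cost(
            with_values(peru, baseline_ulcer_prevalence=0.15, ranges={}),
            Strategy.SUB_OPTIMAL,
        )
        high = total_direct_cost(
            with_values(peru, baseline_ulcer_prevalence=0.29, ranges={}),
            Strategy.SUB_OPTIMAL,
        )
        assert high.treatment_total > low.treatment_total

    def test_treatment_linear_in_unit_cost(self, peru):
        bumped = with_values(peru, cost_debridement=2 * peru.cost_debridement,
                             ranges={})
        base = total_direct_cost(peru, Strategy.SUB_OPTIMAL)
        up = total_direct_cost(bumped, Strategy.SUB_OPTIMAL)
        assert up.treatment_by_endpoint["debridement"] == pytest.approx(
            2 * base.treatment_by_endpoint["debridement"], rel=1e-12
        )
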