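"""Decision-tree flows: reported person counts, conservation, oracle equivalence."""

import dataclasses

import pytest

from footcea import (
    Strategy,
    compute_flows,
    enumerate_tree_paths,
    summarize_outcomes,
)
from footcea.parameters import with_values
from footcea.report import round_half_up
from footcea.synthetic import ScenarioSpec, generate_parameter_set


# published person counts per strategy (rounded presentation values)
TABLE_COUNTS = {
    Strategy.SUB_OPTIMAL: dict(
        n_ulcerated=45_761,
        n_hospital=13_728,
        n_debridement_heal=5_416,
        n_heal_major_amputation=3_658,
        n_heal_minor_amputation=2_897,
        n_death_major_amputation=981,
        n_death_minor_amputation=777,
        n_outpatient_heal=32_032,
    ),
    Strategy.STANDARD: dict(
        n_ulcerated=25_168,
        n_hospital=7_551,
        n_debridement_heal=2_979,
        n_heal_major_amputation=2_012,
        n_heal_minor_amputation=1_594,
        n_death_major_amputation=539,
        n_death_minor_amputation=427,
        n_outpatient_heal=17_618,
    ),
    Strategy.STANDARD_PLUS_TEMP: dict(
        n_ulcerated=9_696,
        n_hospital=2_909,
        n_debridement_heal=1_148,
        n_heal_major_amputation=775,
        n_heal_minor_amputation=614,
        n_death_major_amputation=208,
        n_death_minor_amputation=165,
        n_outpatient_heal=6_787,
    ),
}


@pytest.mark.parametrize("strategy", list(Strategy))
def test_person_counts_match_published_tables(peru, strategy):
    flows = compute_flows(peru, strategy)
    for field, expected in TABLE_COUNTS[strategy].items():
        assert round_half_up(getattr(flows, field)) == expected, field


def test_outcome_summaries(peru):
    deaths = {
        s: summarize_outcomes(compute_flows(peru, s)).deaths for s in Strategy
    }
    assert round_half_up(deaths[Strategy.SUB_OPTIMAL]) == 1_757
    # hand-computed: 206,298 x 0.047 x 0.3 x 0.128 = 372.33
    assert round_half_up(deaths[Strategy.STANDARD_PLUS_TEMP]) == 372
    majors = summarize_outcomes(
        compute_flows(peru, Strategy.STANDARD_PLUS_TEMP)
    ).major_amputations
    # hand-computed: 2,908.80 x (0.4775 + 0.128) x 0.558 = 982.79
    assert round_half_up(majors) == 983


def test_zero_prevalence_sends_everyone_to_no_ulcer(peru):
    ps = with_values(peru, baseline_ulcer_prevalence=0.0, ranges={})
    flows = compute_flows(ps, Strategy.SUB_OPTIMAL)
    assert flows.n_ulcerated == 0
    assert flows.n_no_ulcer == flows.population_high_risk
    out = summarize_outcomes(flows)
    assert out.deaths == out.major_amputations == out.minor_amputations == 0


def _assert_conserved(flows, tol=1e-6):
    assert flows.n_ulcerated + flows.n_no_ulcer == pytest.approx(
        flows.population_high_risk, abs=tol
    )
    assert flows.n_outpatient_heal + flows.n_hospital == pytest.approx(
        flows.n_ulcerated, abs=tol
    )
    terminal = (
        flows.n_debridement_heal
        + flows.n_heal_major_amputation
        + flows.n_heal_minor_amputation
        + flows.n_death_major_amputation
        + flows.n_death_minor_amputation
    )
    assert terminal == pytest.approx(flows.n_hospital, abs=tol)
    for f in dataclasses.fields(flows):
        if f.name != "strategy":
            assert getattr(flows, f.name) >= 0


def test_conservation_and_oracle_equivalence_on_random_scenarios():
    """Node conservation and path-enumeration agreement on 1,000 seeded scenarios."""
    for seed in range(1000):
        _check_one_scenario(generate_parameter_set(ScenarioSpec(seed=seed)))


def _check_one_scenario(ps):
    for strategy in Strategy:
        flows = compute_flows(ps, strategy)
        _assert_conserved(flows)
        paths = enumerate_tree_paths(ps, strategy)
        assert sum(p for _, p, _ in paths) == pytest.approx(1.0, abs=1e-12)
        by_path = {path: persons for path, _, persons in paths}
        pop = flows.population_high_risk
        rel = lambda x: max(1e-9 * max(abs(x), 1.0), 1e-9 * pop)  # noqa: E731
        checks = {
            ("no_ulcer",): flows.n_no_ulcer,
            ("ulcer", "outpatient_heal"): flows.n_outpatient_heal,
            ("ulcer", "hospital", "debridement_heal"): flows.n_debridement_heal,
            ("ulcer", "hospital", "amputation_heal", "major"): flows.n_heal_major_amputation,
            ("ulcer", "hospital", "amputation_heal", "minor"): flows.n_heal_minor_amputation,
            ("ulcer", "hospital", "death", "major"): flows.n_death_major_amputation,
            ("ulcer", "hospital", "death", "minor"): flows.n_death_minor_amputation,
        }
        for path, expected in checks.items():
            assert by_path[path] == pytest.approx(expected, abs=rel(expected)), path


def test_degenerate_tree_has_single_unit_path(peru):
    ps = with_values(
        peru,
        baseline_ulcer_prevalence=1.0,
        p_hospital=1.0,
        p_outpatient=0.0,
        p_amputation_heal=0.0,
        p_debridement_heal=0.0,
        p_death=1.0,
        p_major_given_amputation=1.0,
        p_minor_given_amputation=0.0,
        ranges={},
    )
    paths = enumerate_tree_paths(ps, Strategy.SUB_OPTIMAL)
    live = [(path, p) for path, p, _ in paths if p > 0]
    assert live == [(("ulcer", "hospital", "death", "major"), 1.0)]


def test_monotonicity_in_prevalence_and_effectiveness(peru):
    base_deaths = summarize_outcomes(compute_flows(peru, Strategy.STANDARD)).deaths
    higher_prev = with_values(peru, baseline_ulcer_prevalence=0.28, ranges={})
    assert (
        summarize_outcomes(compute_flows(higher_prev, Strategy.STANDARD)).deaths
        > base_deaths
    )
    more_effective = with_values(peru, effectiveness_standard=0.60, ranges={})
    assert (
        summarize_outcomes(compute_flows(more_effective, Strategy.STANDARD)).deaths
        < base_deaths
    )


def test_linearity_in_population(peru):
    doubled = with_values(
        peru, total_diabetes_population=2 * peru.total_diabetes_population
    )
    f1 = compute_flows(peru, Strategy.SUB_OPTIMAL)
    f2 = compute_flows(doubled, Strategy.SUB_OPTIMAL)
    for f in dataclasses.fields(f1):
        if f.name == "strategy":
            continue
        assert getattr(f2, f.name) == pytest.approx(
            2 * getattr(f1, f.name), rel=1e-12
        )


def test_unknown_strategy_rejected(peru):
    with pytest.raises(ValueError):
        compute_flows(peru, "aggressive")
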