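"""Decision-tree cohort flows.

One strategy, one year. The high-risk cohort splits on ulceration, then
ulcerated patients split between outpatient wound management (heal) and
hospital care, and hospitalized patients reach one of five terminal
endpoints: healing after debridement, healing after a major or minor
amputation, or death after a major or minor amputation (every in-hospital
death follows an amputation in the same year).

Counts are carried as fractional persons at full precision; rounding to
whole persons is a presentation concern (see :mod:`footcea.report`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet, Strategy, high_risk_population

__all__ = [
    "CohortFlows",
    "OutcomeSummary",
    "compute_flows",
    "summarize_outcomes",
    "enumerate_tree_paths",
]


@dataclass(frozen=True)
class CohortFlows:
    """Person counts at every node and terminal of the tree for one strategy."""

    strategy: Strategy
    population_high_risk: float
    n_ulcerated: float
    n_no_ulcer: float
    n_outpatient_heal: float
    n_hospital: float
    n_debridement_heal: float
    n_heal_major_amputation: float
    n_heal_minor_amputation: float
    n_death_major_amputation: float
    n_death_minor_amputation: float


@dataclass(frozen=True)
class OutcomeSummary:
    """Health outcomes aggregated over terminal nodes.

    ``major_amputations`` counts everyone who underwent a major amputation,
    whether they survived it or not; likewise for minor amputations.
    """

    deaths: float
    major_amputations: float
    minor_amputations: float


def compute_flows(ps: ParameterSet, strategy: Strategy) -> CohortFlows:
    """Propagate the high-risk cohort through the tree for *strategy*."""
    strategy = Strategy(strategy)
    pop = high_risk_population(ps)
    prevalence = ps.ulcer_prevalence(strategy)

    n_ulcer = pop * prevalence
    n_hospital = n_ulcer * ps.p_hospital
    n_amp_heal = n_hospital * ps.p_amputation_heal
    n_death = n_hospital * ps.p_death
    return CohortFlows(
        strategy=strategy,
        population_high_risk=pop,
        n_ulcerated=n_ulcer,
        n_no_ulcer=pop - n_ulcer,
        n_outpatient_heal=n_ulcer * ps.p_outpatient,
        n_hospital=n_hospital,
        n_debridement_heal=n_hospital * ps.p_debridement_heal,
        n_heal_major_amputation=n_amp_heal * ps.p_major_given_amputation,
        n_heal_minor_amputation=n_amp_heal * ps.p_minor_given_amputation,
        n_death_major_amputation=n_death * ps.p_major_given_amputation,
        n_death_minor_amputation=n_death * ps.p_minor_given_amputation,
    )


def summarize_outcomes(flows: CohortFlows) -> OutcomeSummary:
    """Deaths and amputations (full precision) for one strategy's flows."""
    return OutcomeSummary(
        deaths=flows.n_death_major_amputation + flows.n_death_minor_amputation,
        major_amputations=flows.n_heal_major_amputation
        + flows.n_death_major_amputation,
        minor_amputations=flows.n_heal_minor_amputation
        + flows.n_death_minor_amputation,
    )


def enumerate_tree_paths(
    ps: ParameterSet, strategy: Strategy
) -> list[tuple[tuple[str, ...], float, float]]:
    """Every root-to-terminal path with its probability and person count.

    A brute-force expansion of the tree used as an independent oracle for
    :func:`compute_flows`: path probabilities are products of branch
    probabilities and sum to one by the law of total probability.
    """
    strategy = Strategy(strategy)
    prevalence = ps.ulcer_prevalence(strategy)
    pop = high_risk_population(ps)

    # nested branch structure: (label, probability, children)
    tree = [
        ("no_ulcer", 1.0 - prevalence, None),
        (
            "ulcer",
            prevalence,
            [
                ("outpatient_heal", ps.p_outpatient, None),
                (
                    "hospital",
                    ps.p_hospital,
                    [
                        ("debridement_heal", ps.p_debridement_heal, None),
                        (
                            "amputation_heal",
                            ps.p_amputation_heal,
                            [
                                ("major", ps.p_major_given_amputation, None),
                                ("minor", ps.p_minor_given_amputation, None),
                            ],
                        ),
                        (
                            "death",
                            ps.p_death,
                            [
                                ("major", ps.p_major_given_amputation, None),
                                ("minor", ps.p_minor_given_amputation, None),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ]

    paths: list[tuple[tuple[str, ...], float, float]] = []

    def walk(node_list, prefix: tuple[str, ...], prob: float) -> None:
        for label, p, children in node_list:
            if children is None:
                paths.append((prefix + (label,), prob * p, pop * prob * p))
            else:
                walk(children, prefix + (label,), prob * p)

    walk(tree, (), 1.0)
    return paths
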