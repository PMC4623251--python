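"""Incremental cost-effectiveness analysis between prevention strategies.

For a pair (intervention, comparator) the model reports incremental direct
cost, incremental cost including indirect (productivity) costs, deaths and
major amputations averted, and either an ICER (incremental cost per death
averted) or a dominance label:

* ``cost_saving`` — the intervention costs less *and* averts deaths; no
  ICER is reported (standard CEA practice);
* ``dominated`` — the intervention costs more without averting deaths;
* ``icer`` — otherwise, ICER = delta cost / deaths averted, computed from
  unrounded quantities.

An ICER is conventionally judged against a willingness-to-pay threshold of
``gdp_multiplier`` (usually 3) times GDP per capita.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort import compute_flows, summarize_outcomes
from .costing import indirect_cost_per_death, total_direct_cost
from .parameters import EconomicAssumptions, ParameterSet, Strategy

__all__ = [
    "DominanceLabel",
    "Comparison",
    "compare",
    "threshold_check",
    "full_comparison_table",
]


class DominanceLabel(str, enum.Enum):
    COST_SAVING = "cost_saving"
    DOMINATED = "dominated"
    ICER = "icer"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _classify(delta_cost: float, delta_effect: float) -> DominanceLabel:
    if delta_cost < 0 and delta_effect > 0:
        return DominanceLabel.COST_SAVING
    if delta_cost > 0 and delta_effect <= 0:
        return DominanceLabel.DOMINATED
    return DominanceLabel.ICER


@dataclass(frozen=True)
class Comparison:
    """Incremental results for intervention vs comparator.

    ``icer_direct`` / ``icer_with_indirect`` are numeric only when the
    corresponding label is ``ICER``; for dominance labels they are ``None``
    (a cost-saving comparison is reported as the label, never as a negative
    ratio). ``deaths_averted`` is comparator deaths minus intervention
    deaths, kept fractional.
    """

    intervention: Strategy
    comparator: Strategy
    delta_cost_direct: float
    delta_cost_with_indirect: float
    deaths_averted: float
    major_amputations_averted: float
    label_direct: DominanceLabel
    icer_direct: float | None
    label_with_indirect: DominanceLabel
    icer_with_indirect: float | None
    cost_effective_at_threshold: bool
    threshold: float


def _icer(delta_cost: float, delta_effect: float) -> tuple[DominanceLabel, float | None]:
    label = _classify(delta_cost, delta_effect)
    if label is not DominanceLabel.ICER:
        return label, None
    if delta_effect == 0:
        # delta cost <= 0 with no effect difference: no meaningful ratio
        return DominanceLabel.ICER, None
    return label, delta_cost / delta_effect


def threshold_check(icer: float, econ: EconomicAssumptions) -> bool:
    """True iff *icer* is at or below ``gdp_multiplier x gdp_per_capita``."""
    return icer <= econ.gdp_multiplier * econ.gdp_per_capita


def compare(
    ps: ParameterSet,
    intervention: Strategy,
    comparator: Strategy,
    include_indirect: bool = True,
) -> Comparison:
    """Incremental analysis of *intervention* against *comparator*.

    Both the direct-cost and the direct-plus-indirect perspectives are
    always computed; *include_indirect* selects which one drives the
    ``cost_effective_at_threshold`` verdict. A cost-saving comparison is
    always deemed cost-effective, a dominated one never.
    """
    intervention = Strategy(intervention)
    comparator = Strategy(comparator)
    if intervention is comparator:
        raise ValueError("intervention and comparator must differ")

    cost_i = total_direct_cost(ps, intervention)
    cost_c = total_direct_cost(ps, comparator)
    out_i = summarize_outcomes(compute_flows(ps, intervention))
    out_c = summarize_outcomes(compute_flows(ps, comparator))

    delta_direct = cost_i.direct_total - cost_c.direct_total
    delta_with_indirect = delta_direct + (cost_i.indirect_total - cost_c.indirect_total)
    deaths_averted = out_c.deaths - out_i.deaths
    majors_averted = out_c.major_amputations - out_i.major_amputations

    label_d, icer_d = _icer(delta_direct, deaths_averted)
    label_i, icer_i = _icer(delta_with_indirect, deaths_averted)

    label, icer = (label_i, icer_i) if include_indirect else (label_d, icer_d)
    if label is DominanceLabel.COST_SAVING:
        cost_effective = True
    elif icer is None:
        cost_effective = False
    else:
        cost_effective = threshold_check(icer, ps.economic)

    return Comparison(
        intervention=intervention,
        comparator=comparator,
        delta_cost_direct=delta_direct,
        delta_cost_with_indirect=delta_with_indirect,
        deaths_averted=deaths_averted,
        major_amputations_averted=majors_averted,
        label_direct=label_d,
        icer_direct=icer_d,
        label_with_indirect=label_i,
        icer_with_indirect=icer_i,
        cost_effective_at_threshold=cost_effective,
        threshold=ps.economic.gdp_multiplier * ps.economic.gdp_per_capita,
    )


#: the three pairwise comparisons reported for the Peru scenario
COMPARISON_PAIRS = (
    (Strategy.STANDARD, Strategy.SUB_OPTIMAL),
    (Strategy.STANDARD_PLUS_TEMP, Strategy.SUB_OPTIMAL),
    (Strategy.STANDARD_PLUS_TEMP, Strategy.STANDARD),
)


def full_comparison_table(ps: ParameterSet) -> list[Comparison]:
    """All three pairwise strategy comparisons, each with both perspectives."""
    return [compare(ps, i, c) for i, c in COMPARISON_PAIRS]


def incremental_indirect_identity(ps: ParameterSet, comparison: Comparison) -> float:
    """Productivity-cost component of the incremental cost (for diagnostics).

    Equals ``delta_cost_with_indirect - delta_cost_direct`` which is
    ``-deaths_averted * indirect_cost_per_death`` by construction.
    """
    return -comparison.deaths_averted * indirect_cost_per_death(ps.economic)
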