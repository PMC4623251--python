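"""Cost-of-illness: direct prevention + treatment costs and indirect costs.

Direct costs follow an ingredients-based approach: a unit cost per resource
bundle (outpatient wound management, debridement, minor/major amputation,
per-person prevention package) multiplied by the number of people reaching
the corresponding endpoint. Deceased patients incur the full cost of the
amputation admission they underwent and no additional death-specific cost.

Indirect costs value premature death with the human-capital approach: the
present value of minimum-wage earnings over the productive years lost
between the mean age at death and retirement, discounted as an annuity-due
(the first year of lost earnings is not discounted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .cohort import CohortFlows, compute_flows, summarize_outcomes
from .parameters import EconomicAssumptions, ParameterSet, Strategy, high_risk_population

__all__ = [
    "IngredientLine",
    "CostBundle",
    "CostBreakdown",
    "ENDPOINTS",
    "ENDPOINT_LABELS",
    "unit_cost_from_bundle",
    "prevention_cost",
    "treatment_cost",
    "indirect_cost_per_death",
    "total_direct_cost",
]

#: treatment endpoints, in reporting order
ENDPOINTS = (
    "debridement",
    "heal_major",
    "heal_minor",
    "death_major",
    "death_minor",
    "outpatient_wound",
)

#: human-readable endpoint labels used in rendered tables
ENDPOINT_LABELS: Mapping[str, str] = {
    "debridement": "Healing with debridement",
    "heal_major": "Healing with major amputation",
    "heal_minor": "Healing with minor amputation",
    "death_major": "Death with major amputation",
    "death_minor": "Death with minor amputation",
    "outpatient_wound": "Healing with outpatient visit",
}


@dataclass(frozen=True)
class IngredientLine:
    """One costed resource: quantity used times unit price (US$)."""

    label: str
    quantity: float
    unit_price: float

    def __post_init__(self) -> None:
        if self.quantity < 0 or self.unit_price < 0:
            raise ValueError("ingredient quantity and unit price must be >= 0")


@dataclass(frozen=True)
class CostBundle:
    """A named bundle of ingredient lines (e.g. the debridement episode)."""

    name: str
    lines: tuple[IngredientLine, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("bundle name must be non-empty")
        object.__setattr__(self, "lines", tuple(self.lines))


@dataclass(frozen=True)
class CostBreakdown:
    """Cost aggregates (US$) for one strategy over one year."""

    strategy: Strategy
    prevention_total: float
    treatment_by_endpoint: Mapping[str, float]
    treatment_total: float
    direct_total: float
    indirect_total: float = 0.0


def unit_cost_from_bundle(bundle: CostBundle) -> float:
    """Aggregate unit cost of a bundle: sum of quantity x unit price."""
    return sum(line.quantity * line.unit_price for line in bundle.lines)


def prevention_cost(ps: ParameterSet, strategy: Strategy) -> float:
    """Annual prevention cost: the whole high-risk cohort receives the package."""
    strategy = Strategy(strategy)
    return high_risk_population(ps) * ps.prevention_cost_per_person[strategy]


def _endpoint_unit_costs(ps: ParameterSet) -> dict[str, float]:
    return {
        "debridement": ps.cost_debridement,
        "heal_major": ps.cost_major_amputation,
        "heal_minor": ps.cost_minor_amputation,
        "death_major": ps.cost_major_amputation,
        "death_minor": ps.cost_minor_amputation,
        "outpatient_wound": ps.cost_wound_management,
    }


def _endpoint_persons(flows: CohortFlows) -> dict[str, float]:
    return {
        "debridement": flows.n_debridement_heal,
        "heal_major": flows.n_heal_major_amputation,
        "heal_minor": flows.n_heal_minor_amputation,
        "death_major": flows.n_death_major_amputation,
        "death_minor": flows.n_death_minor_amputation,
        "outpatient_wound": flows.n_outpatient_heal,
    }


def treatment_cost(flows: CohortFlows, ps: ParameterSet) -> dict[str, float]:
    """Treatment cost per endpoint: unrounded persons x per-episode unit cost."""
    unit = _endpoint_unit_costs(ps)
    persons = _endpoint_persons(flows)
    return {k: persons[k] * unit[k] for k in ENDPOINTS}


def indirect_cost_per_death(econ: EconomicAssumptions) -> float:
    """Present value of earnings lost per premature death (human capital).

    ``years_lost = retirement_age - mean_age_at_death`` years of minimum-wage
    income, valued as an annuity-due: the first lost year is undiscounted,
    each later year is discounted once more. A fractional final year is
    pro-rated. Returns 0 (with a warning) if no productive years remain.
    """
    years_lost = econ.retirement_age - econ.mean_age_at_death
    if years_lost <= 0:
        warnings.warn(
            "mean age at death is at or beyond retirement age; "
            "indirect cost per death is 0",
            stacklevel=2,
        )
        return 0.0
    annual = econ.minimum_wage_local / econ.exchange_rate * 12.0
    r = econ.discount_rate
    full_years = int(years_lost)
    total = sum(annual / (1.0 + r) ** t for t in range(full_years))
    fraction = years_lost - full_years
    if fraction > 0:
        total += fraction * annual / (1.0 + r) ** full_years
    return total


def total_direct_cost(ps: ParameterSet, strategy: Strategy) -> CostBreakdown:
    """Full cost breakdown for one strategy: prevention + treatment + indirect.

    ``direct_total`` is prevention plus treatment; ``indirect_total`` (deaths
    times the human-capital value of one premature death) is carried
    separately so analyses can include or exclude it.
    """
    strategy = Strategy(strategy)
    flows = compute_flows(ps, strategy)
    by_endpoint = treatment_cost(flows, ps)
    prevention = prevention_cost(ps, strategy)
    treatment_total = sum(by_endpoint.values())
    deaths = summarize_outcomes(flows).deaths
    return CostBreakdown(
        strategy=strategy,
        prevention_total=prevention,
        treatment_by_endpoint=by_endpoint,
        treatment_total=treatment_total,
        direct_total=prevention + treatment_total,
        indirect_total=deaths * indirect_cost_per_death(ps.economic),
    )
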