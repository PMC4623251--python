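"""Synthetic scenario generation for property testing.

Every draw is an internally consistent :class:`ParameterSet`: complementary
probability pairs are sampled as complements, the hospital endpoint triplet
(amputation-and-heal, debridement-and-heal, death) is sampled on the
probability simplex with a Dirichlet draw, and sensitivity ranges are built
to bracket the sampled point estimates. By default strategies are ordered
the way the Peru analysis assumes — standard care more effective and more
expensive than sub-optimal care, temperature monitoring more effective and
more expensive than standard care — so that dominance classifications are
exercised in the same regime; set ``enforce_strategy_ordering=False`` to
also generate dominated configurations.

Randomness comes from :func:`numpy.random.default_rng` (PCG64), so a given
seed reproduces the same scenario on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import (
    ParameterSet,
    EconomicAssumptions,
    Strategy,
    bundled_config_path,
    load_parameters,
    validate_parameters,
)

__all__ = ["ScenarioSpec", "generate_parameter_set", "peru_2012"]


def _clip_range(lo: float, hi: float, lower: float, upper: float) -> tuple[float, float]:
    return max(lo, lower), min(hi, upper)


@dataclass(frozen=True)
class ScenarioSpec:
    """Sampling controls for one synthetic scenario."""

    seed: int = 0
    population_range: tuple[float, float] = (100_000, 2_000_000)
    high_risk_range: tuple[float, float] = (0.10, 0.35)
    prevalence_range: tuple[float, float] = (0.05, 0.35)
    effectiveness_range: tuple[float, float] = (0.20, 0.90)
    p_hospital_range: tuple[float, float] = (0.15, 0.50)
    major_given_amputation_range: tuple[float, float] = (0.30, 0.70)
    #: Dirichlet concentration over (amputation-heal, debridement-heal, death)
    branch_probability_concentration: tuple[float, float, float] = (4.8, 3.9, 1.3)
    prevention_cost_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sub_optimal": (30.0, 100.0),
            "standard": (100.0, 300.0),
            "standard_plus_temp": (250.0, 600.0),
        }
    )
    treatment_cost_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wound_management": (40.0, 160.0),
            "debridement": (500.0, 2_000.0),
            "minor_amputation": (2_500.0, 8_000.0),
            "major_amputation": (5_000.0, 15_000.0),
        }
    )
    #: half-width (as a fraction of the point estimate) of auto-generated
    #: sensitivity ranges, mirroring the usual +/-30 % convention
    range_halfwidth: float = 0.30
    enforce_strategy_ordering: bool = True

    def __post_init__(self) -> None:
        pairs = [
            self.population_range,
            self.high_risk_range,
            self.prevalence_range,
            self.effectiveness_range,
            self.p_hospital_range,
            self.major_given_amputation_range,
            *self.prevention_cost_ranges.values(),
            *self.treatment_cost_ranges.values(),
        ]
        if any(lo > hi for lo, hi in pairs):
            raise ValueError("every (min, max) range must satisfy min <= max")


def generate_parameter_set(spec: ScenarioSpec) -> ParameterSet:
    """Draw one valid :class:`ParameterSet`; the seed fixes the entire draw."""
    rng = np.random.default_rng(spec.seed)
    u = lambda pair: float(rng.uniform(*pair))  # noqa: E731

    population = u(spec.population_range)
    high_risk = u(spec.high_risk_range)
    baseline = u(spec.prevalence_range)

    e1, e2 = rng.uniform(*spec.effectiveness_range, size=2)
    if spec.enforce_strategy_ordering:
        e1, e2 = sorted((e1, e2))
    eff_standard, eff_temp = float(e1), float(e2)

    p_hospital = u(spec.p_hospital_range)
    f, g, h = (float(x) for x in rng.dirichlet(spec.branch_probability_concentration))
    f1 = u(spec.major_given_amputation_range)

    prevention = {
        Strategy(name): u(r) for name, r in spec.prevention_cost_ranges.items()
    }
    if spec.enforce_strategy_ordering:
        ordered = sorted(prevention.values())
        prevention = dict(
            zip(
                (Strategy.SUB_OPTIMAL, Strategy.STANDARD, Strategy.STANDARD_PLUS_TEMP),
                ordered,
            )
        )
    treatment = {name: u(r) for name, r in spec.treatment_cost_ranges.items()}
    # major amputation at least as costly as minor (keeps the cost structure
    # of the disease realistic)
    if treatment["major_amputation"] < treatment["minor_amputation"]:
        treatment["major_amputation"], treatment["minor_amputation"] = (
            treatment["minor_amputation"],
            treatment["major_amputation"],
        )

    mean_age_death = float(rng.uniform(50.0, 64.0))
    econ = EconomicAssumptions(
        minimum_wage_local=float(rng.uniform(300.0, 2_000.0)),
        exchange_rate=float(rng.uniform(0.5, 10.0)),
        discount_rate=float(rng.uniform(0.0, 0.08)),
        retirement_age=65.0,
        mean_age_at_death=mean_age_death,
        gdp_per_capita=float(rng.uniform(1_000.0, 20_000.0)),
        gdp_multiplier=3.0,
    )

    w = spec.range_halfwidth
    prop = lambda x: _clip_range(x * (1 - w), x * (1 + w), 0.0, 1.0)  # noqa: E731
    money = lambda x: (x * (1 - w), x * (1 + w))  # noqa: E731
    ranges = {
        "baseline_ulcer_prevalence": prop(baseline),
        "effectiveness_standard": prop(eff_standard),
        "effectiveness_standard_plus_temp": prop(eff_temp),
        "p_hospital": prop(p_hospital),
        "p_outpatient": (
            1.0 - prop(p_hospital)[1],
            1.0 - prop(p_hospital)[0],
        ),
        "p_amputation_heal": prop(f),
        "p_debridement_heal": prop(g),
        "prevention_cost.sub_optimal": money(prevention[Strategy.SUB_OPTIMAL]),
        "prevention_cost.standard": money(prevention[Strategy.STANDARD]),
        "prevention_cost.standard_plus_temp": money(
            prevention[Strategy.STANDARD_PLUS_TEMP]
        ),
        "cost_major_amputation": money(treatment["major_amputation"]),
    }

    ps = ParameterSet(
        total_diabetes_population=population,
        high_risk_fraction=high_risk,
        baseline_ulcer_prevalence=baseline,
        effectiveness_standard=eff_standard,
        effectiveness_standard_plus_temp=eff_temp,
        p_hospital=p_hospital,
        p_outpatient=1.0 - p_hospital,
        p_amputation_heal=f,
        p_debridement_heal=g,
        p_death=h,
        p_major_given_amputation=f1,
        p_minor_given_amputation=1.0 - f1,
        prevention_cost_per_person=prevention,
        cost_wound_management=treatment["wound_management"],
        cost_debridement=treatment["debridement"],
        cost_minor_amputation=treatment["minor_amputation"],
        cost_major_amputation=treatment["major_amputation"],
        economic=econ,
        ranges=ranges,
    )
    return validate_parameters(ps)


def peru_2012() -> ParameterSet:
    """The bundled Peru-2012 scenario, identical on every call."""
    return load_parameters(bundled_config_path())
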