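"""Model parameters: definition, loading, validation and simple derivations.

The model is a one-year, prevalence-based decision tree for a cohort of
Type 2 diabetics at high risk of foot ulceration. A :class:`ParameterSet`
holds every input the tree needs: the cohort size, the ulceration prevalence
under each prevention strategy, the care-setting and clinical-endpoint branch
probabilities, per-person prevention costs, per-episode treatment costs, and
the economic assumptions used to value premature death.

Two small derivations link the strategies together:

* ``baseline = reference_prevalence / (1 - reference_effectiveness)`` —
  back-calculates the ulceration prevalence under the do-little comparator
  from a trial prevalence observed under an effective strategy;
* ``prevalence(strategy) = baseline * (1 - effectiveness)`` — the forward
  direction.

Probabilities that must sum to one (hospital/outpatient, the hospital
endpoint triplet, major/minor amputation shares) are stored explicitly and
validated at load time; any single missing complement is filled in.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "Strategy",
    "EconomicAssumptions",
    "ParameterSet",
    "ConfigurationError",
    "ParameterValidationError",
    "load_parameters",
    "dump_parameters",
    "validate_parameters",
    "derive_baseline_prevalence",
    "strategy_prevalence",
    "high_risk_population",
    "bundled_config_path",
]

_SUM_TOL = 1e-9


class Strategy(str, enum.Enum):
    """The three secondary-prevention strategies compared by the model."""

    SUB_OPTIMAL = "sub_optimal"
    STANDARD = "standard"
    STANDARD_PLUS_TEMP = "standard_plus_temp"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ConfigurationError(ValueError):
    """A required configuration field is missing or unparseable."""


class ParameterValidationError(ValueError):
    """One or more parameter constraints are violated.

    Carries the complete list of violations, not just the first one found.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid parameter set:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass(frozen=True)
class EconomicAssumptions:
    """Wage, discounting and threshold assumptions for costing.

    Attributes
    ----------
    minimum_wage_local:
        Monthly minimum wage in local currency (PEN/month for Peru).
    exchange_rate:
        Local currency units per US$ (annual average).
    discount_rate:
        Annual discount rate applied to future productivity losses.
    retirement_age, mean_age_at_death:
        Years; their difference is the productive years lost per premature
        death under the human-capital approach.
    gdp_per_capita:
        US$; with ``gdp_multiplier`` defines the cost-effectiveness
        willingness-to-pay threshold (conventionally 3x GDP per capita).
    """

    minimum_wage_local: float
    exchange_rate: float
    discount_rate: float
    retirement_age: float
    mean_age_at_death: float
    gdp_per_capita: float
    gdp_multiplier: float = 3.0


@dataclass(frozen=True)
class ParameterSet:
    """Complete input set for one run of the decision-tree model."""

    total_diabetes_population: float
    high_risk_fraction: float
    baseline_ulcer_prevalence: float
    effectiveness_standard: float
    effectiveness_standard_plus_temp: float
    p_hospital: float
    p_outpatient: float
    p_amputation_heal: float
    p_debridement_heal: float
    p_death: float
    p_major_given_amputation: float
    p_minor_given_amputation: float
    prevention_cost_per_person: Mapping[Strategy, float]
    cost_wound_management: float
    cost_debridement: float
    cost_minor_amputation: float
    cost_major_amputation: float
    economic: EconomicAssumptions
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    display: Mapping[str, float] = field(default_factory=dict)

    def effectiveness(self, strategy: Strategy) -> float:
        """Prevalence reduction of *strategy* relative to the comparator.

        The sub-optimal comparator has, by definition, zero effectiveness.
        """
        strategy = Strategy(strategy)
        if strategy is Strategy.SUB_OPTIMAL:
            return 0.0
        if strategy is Strategy.STANDARD:
            return self.effectiveness_standard
        return self.effectiveness_standard_plus_temp

    def ulcer_prevalence(self, strategy: Strategy) -> float:
        """One-year ulceration prevalence in the high-risk cohort."""
        return strategy_prevalence(
            self.baseline_ulcer_prevalence, self.effectiveness(strategy)
        )


def derive_baseline_prevalence(
    reference_prevalence: float, reference_effectiveness: float
) -> float:
    """Back-calculate the comparator's ulcer prevalence.

    If a strategy with effectiveness ``e`` (fractional prevalence reduction)
    achieves prevalence ``p``, the prevalence without it is ``p / (1 - e)``.
    Full precision is kept; do not round to the two decimals usually quoted.
    """
    if not 0.0 <= reference_prevalence <= 1.0:
        raise ValueError("reference_prevalence must be in [0, 1]")
    if not 0.0 <= reference_effectiveness < 1.0:
        raise ValueError("reference_effectiveness must be in [0, 1)")
    return reference_prevalence / (1.0 - reference_effectiveness)


def strategy_prevalence(baseline: float, effectiveness: float) -> float:
    """Forward direction: prevalence under a strategy = baseline * (1 - e)."""
    if not 0.0 <= baseline <= 1.0 or not 0.0 <= effectiveness <= 1.0:
        raise ValueError("baseline and effectiveness must be in [0, 1]")
    return baseline * (1.0 - effectiveness)


def high_risk_population(ps: ParameterSet) -> float:
    """Number of persons at high risk of ulceration (fractional, unrounded)."""
    return ps.total_diabetes_population * ps.high_risk_fraction


def bundled_config_path() -> Path:
    """Path of the bundled Peru-2012 scenario configuration."""
    return Path(resources.files("footcea").joinpath("data/peru_2012.yaml"))


# ---------------------------------------------------------------------------
# loading


def _require(section: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in section:
        raise ConfigurationError(f"missing required field '{where}.{key}'")
    return section[key]


def _fill_complement(epi: dict, a: str, b: str) -> None:
    """Fill whichever of the complementary pair *a*, *b* is missing."""
    if a in epi and b not in epi:
        epi[b] = 1.0 - float(epi[a])
    elif b in epi and a not in epi:
        epi[a] = 1.0 - float(epi[b])


def load_parameters(source: Any) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from a configuration.

    Parameters
    ----------
    source:
        A mapping, a path to a YAML file, a YAML string, or an open file
        object. The document must contain the sections ``epidemiology``,
        ``strategies``, ``treatment_costs`` and ``economics``; ``ranges``
        is optional.

    Raises
    ------
    ConfigurationError
        If the source does not parse or a required field is absent.
    ParameterValidationError
        If any constraint is violated; the error lists every violation.
    """
    if isinstance(source, Mapping):
        doc: Any = dict(source)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        p = Path(source) if not isinstance(source, Path) else source
        try:
            exists = p.exists()
        except OSError:
            exists = False
        text = p.read_text() if exists else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigurationError("configuration did not parse to a mapping")

    for section in ("epidemiology", "strategies", "treatment_costs", "economics"):
        if section not in doc:
            raise ConfigurationError(f"missing required section '{section}'")

    epi = dict(doc["epidemiology"])
    _fill_complement(epi, "p_hospital", "p_outpatient")
    _fill_complement(epi, "p_major_given_amputation", "p_minor_given_amputation")
    # hospital endpoint triplet: fill a single missing member
    triplet = ("p_amputation_heal", "p_debridement_heal", "p_death")
    missing = [k for k in triplet if k not in epi]
    if len(missing) == 1:
        others = [float(epi[k]) for k in triplet if k != missing[0]]
        epi[missing[0]] = 1.0 - sum(others)

    baseline = _require(epi, "baseline_ulcer_prevalence", "epidemiology")
    if isinstance(baseline, Mapping):
        baseline = derive_baseline_prevalence(
            float(_require(baseline, "reference_prevalence", "baseline_ulcer_prevalence")),
            float(
                _require(
                    baseline, "reference_effectiveness", "baseline_ulcer_prevalence"
                )
            ),
        )
    baseline = float(baseline)

    strategies = doc["strategies"]
    eff: dict[Strategy, float] = {}
    prevention: dict[Strategy, float] = {}
    display: dict[str, float] = {}
    for strat in Strategy:
        section = _require(strategies, strat.value, "strategies")
        e = section.get("effectiveness", 0.0)
        if isinstance(e, Mapping):
            # derived from the ulceration prevalence the strategy achieves
            target = float(_require(e, "target_prevalence", f"strategies.{strat.value}"))
            if baseline <= 0:
                raise ConfigurationError(
                    "cannot derive effectiveness from target_prevalence when the "
                    "baseline prevalence is zero"
                )
            e = 1.0 - target / baseline
        eff[strat] = float(e)
        prevention[strat] = float(
            _require(section, "prevention_cost_per_person", f"strategies.{strat.value}")
        )
        if "display_cost" in section:
            display[f"prevention_cost.{strat.value}"] = float(section["display_cost"])

    tc = doc["treatment_costs"]
    econ_doc = doc["economics"]
    econ = EconomicAssumptions(
        minimum_wage_local=float(_require(econ_doc, "minimum_wage_local", "economics")),
        exchange_rate=float(_require(econ_doc, "exchange_rate", "economics")),
        discount_rate=float(_require(econ_doc, "discount_rate", "economics")),
        retirement_age=float(_require(econ_doc, "retirement_age", "economics")),
        mean_age_at_death=float(_require(econ_doc, "mean_age_at_death", "economics")),
        gdp_per_capita=float(_require(econ_doc, "gdp_per_capita", "economics")),
        gdp_multiplier=float(econ_doc.get("gdp_multiplier", 3.0)),
    )

    ranges = {
        str(k): (float(v[0]), float(v[1])) for k, v in (doc.get("ranges") or {}).items()
    }

    ps = ParameterSet(
        total_diabetes_population=float(
            _require(epi, "total_diabetes_population", "epidemiology")
        ),
        high_risk_fraction=float(_require(epi, "high_risk_fraction", "epidemiology")),
        baseline_ulcer_prevalence=baseline,
        effectiveness_standard=eff[Strategy.STANDARD],
        effectiveness_standard_plus_temp=eff[Strategy.STANDARD_PLUS_TEMP],
        p_hospital=float(_require(epi, "p_hospital", "epidemiology")),
        p_outpatient=float(_require(epi, "p_outpatient", "epidemiology")),
        p_amputation_heal=float(_require(epi, "p_amputation_heal", "epidemiology")),
        p_debridement_heal=float(_require(epi, "p_debridement_heal", "epidemiology")),
        p_death=float(_require(epi, "p_death", "epidemiology")),
        p_major_given_amputation=float(
            _require(epi, "p_major_given_amputation", "epidemiology")
        ),
        p_minor_given_amputation=float(
            _require(epi, "p_minor_given_amputation", "epidemiology")
        ),
        prevention_cost_per_person=prevention,
        cost_wound_management=float(_require(tc, "wound_management", "treatment_costs")),
        cost_debridement=float(_require(tc, "debridement", "treatment_costs")),
        cost_minor_amputation=float(_require(tc, "minor_amputation", "treatment_costs")),
        cost_major_amputation=float(_require(tc, "major_amputation", "treatment_costs")),
        economic=econ,
        ranges=ranges,
        display=display,
    )
    if eff[Strategy.SUB_OPTIMAL] != 0.0:
        raise ParameterValidationError(
            ["strategies.sub_optimal.effectiveness: the comparator must have "
             "effectiveness 0 (it defines the baseline)"]
        )
    validate_parameters(ps)
    return ps


def dump_parameters(ps: ParameterSet) -> dict:
    """Serialize a :class:`ParameterSet` to a plain configuration mapping.

    ``load_parameters(dump_parameters(ps)) == ps`` holds exactly.
    """
    strategies = {}
    for strat in Strategy:
        entry: dict[str, Any] = {
            "effectiveness": ps.effectiveness(strat),
            "prevention_cost_per_person": ps.prevention_cost_per_person[strat],
        }
        key = f"prevention_cost.{strat.value}"
        if key in ps.display:
            entry["display_cost"] = ps.display[key]
        strategies[strat.value] = entry
    return {
        "epidemiology": {
            "total_diabetes_population": ps.total_diabetes_population,
            "high_risk_fraction": ps.high_risk_fraction,
            "baseline_ulcer_prevalence": ps.baseline_ulcer_prevalence,
            "p_hospital": ps.p_hospital,
            "p_outpatient": ps.p_outpatient,
            "p_amputation_heal": ps.p_amputation_heal,
            "p_debridement_heal": ps.p_debridement_heal,
            "p_death": ps.p_death,
            "p_major_given_amputation": ps.p_major_given_amputation,
            "p_minor_given_amputation": ps.p_minor_given_amputation,
        },
        "strategies": strategies,
        "treatment_costs": {
            "wound_management": ps.cost_wound_management,
            "debridement": ps.cost_debridement,
            "minor_amputation": ps.cost_minor_amputation,
            "major_amputation": ps.cost_major_amputation,
        },
        "economics": {
            "minimum_wage_local": ps.economic.minimum_wage_local,
            "exchange_rate": ps.economic.exchange_rate,
            "discount_rate": ps.economic.discount_rate,
            "retirement_age": ps.economic.retirement_age,
            "mean_age_at_death": ps.economic.mean_age_at_death,
            "gdp_per_capita": ps.economic.gdp_per_capita,
            "gdp_multiplier": ps.economic.gdp_multiplier,
        },
        "ranges": {k: [v[0], v[1]] for k, v in ps.ranges.items()},
    }


# ---------------------------------------------------------------------------
# validation


def _point_estimate(ps: ParameterSet, name: str) -> float | None:
    """Look up the point estimate a sensitivity range refers to, if known."""
    if name.startswith("prevention_cost."):
        try:
            return ps.prevention_cost_per_person[Strategy(name.split(".", 1)[1])]
        except (ValueError, KeyError):
            return None
    return getattr(ps, name, None)


def validate_parameters(ps: ParameterSet) -> ParameterSet:
    """Check every constraint; raise with the full violation list if any fail."""
    v: list[str] = []

    proportions = [
        "high_risk_fraction",
        "baseline_ulcer_prevalence",
        "effectiveness_standard",
        "effectiveness_standard_plus_temp",
        "p_hospital",
        "p_outpatient",
        "p_amputation_heal",
        "p_debridement_heal",
        "p_death",
        "p_major_given_amputation",
        "p_minor_given_amputation",
    ]
    for name in proportions:
        x = getattr(ps, name)
        if not (0.0 <= x <= 1.0) or not math.isfinite(x):
            v.append(f"{name} = {x!r} is not a proportion in [0, 1]")

    nonneg = [
        "total_diabetes_population",
        "cost_wound_management",
        "cost_debridement",
        "cost_minor_amputation",
        "cost_major_amputation",
    ]
    for name in nonneg:
        x = getattr(ps, name)
        if not (x >= 0.0) or not math.isfinite(x):
            v.append(f"{name} = {x!r} must be a finite non-negative number")
    for strat in Strategy:
        c = ps.prevention_cost_per_person.get(strat)
        if c is None:
            v.append(f"prevention_cost_per_person missing strategy '{strat.value}'")
        elif not (c >= 0.0) or not math.isfinite(c):
            v.append(
                f"prevention_cost_per_person[{strat.value}] = {c!r} must be >= 0"
            )

    def check_sum(parts: dict[str, float], total: float = 1.0) -> None:
        s = sum(parts.values())
        if abs(s - total) > _SUM_TOL:
            detail = " + ".join(f"{k} ({x:g})" for k, x in parts.items())
            v.append(f"{detail} = {s:.12g}, expected {total:g}")

    check_sum({"p_hospital": ps.p_hospital, "p_outpatient": ps.p_outpatient})
    check_sum(
        {
            "p_amputation_heal": ps.p_amputation_heal,
            "p_debridement_heal": ps.p_debridement_heal,
            "p_death": ps.p_death,
        }
    )
    check_sum(
        {
            "p_major_given_amputation": ps.p_major_given_amputation,
            "p_minor_given_amputation": ps.p_minor_given_amputation,
        }
    )

    econ = ps.economic
    if not econ.exchange_rate > 0:
        v.append(f"economic.exchange_rate = {econ.exchange_rate!r} must be > 0")
    if not (0.0 <= econ.discount_rate < 1.0):
        v.append(f"economic.discount_rate = {econ.discount_rate!r} must be in [0, 1)")
    if not econ.retirement_age > econ.mean_age_at_death:
        v.append(
            "economic.retirement_age must exceed mean_age_at_death "
            f"({econ.retirement_age!r} vs {econ.mean_age_at_death!r})"
        )
    if econ.minimum_wage_local < 0:
        v.append("economic.minimum_wage_local must be >= 0")

    for name, (lo, hi) in ps.ranges.items():
        point = _point_estimate(ps, name)
        if point is None:
            v.append(f"ranges: '{name}' does not name a known parameter")
        elif not lo <= point <= hi:
            v.append(
                f"ranges[{name}] = ({lo:g}, {hi:g}) does not bracket the "
                f"point estimate {point:g}"
            )

    if v:
        raise ParameterValidationError(v)
    return ps


def with_values(ps: ParameterSet, **changes: Any) -> ParameterSet:
    """Return a copy of *ps* with the given attributes replaced (no revalidation)."""
    return replace(ps, **changes)
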