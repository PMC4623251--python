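"""Multiple one-way (deterministic) sensitivity analysis and tornado ordering.

Each parameter with a configured (low, high) range is varied to each bound
in turn, all other parameters held at base values, and the chosen outcome
(ICER, incremental cost, or deaths averted) is recomputed. Entries are
ordered by descending swing — the absolute difference between the outcomes
at the two bounds — giving the tornado diagram ordering.

Varying one member of a probability pair or triplet would break the
sum-to-one constraints, so linked parameters are adjusted:

* hospital vs outpatient shares are complements of each other;
* varying the amputation-and-heal share holds mortality fixed and gives the
  remainder to debridement-and-heal (and symmetrically);
* varying mortality rescales the two healing shares proportionally;
* major/minor amputation shares are complements.

Varying the baseline ulcer prevalence holds strategy effectiveness fixed
(strategy prevalences follow), and varying an effectiveness holds the
baseline fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .cea import DominanceLabel, compare
from .parameters import ParameterSet, Strategy, validate_parameters

__all__ = [
    "OwsaSpec",
    "TornadoEntry",
    "InfeasiblePerturbation",
    "with_parameter",
    "parameter_value",
    "run_owsa",
    "order_tornado",
    "default_range",
]

OUTCOMES = ("icer_direct", "icer_with_indirect", "delta_cost", "deaths_averted")


class InfeasiblePerturbation(ValueError):
    """A one-way excursion produced an invalid parameter set."""


@dataclass(frozen=True)
class OwsaSpec:
    """What to vary, for which comparison, measuring which outcome.

    ``parameters`` defaults to every key of ``ParameterSet.ranges``.
    ``include_indirect`` only matters for the ``delta_cost`` outcome; the
    two ICER outcomes carry their perspective in their name.
    """

    intervention: Strategy
    comparator: Strategy
    outcome: str = "icer_direct"
    include_indirect: bool = False
    parameters: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's excursion in a one-way sensitivity analysis."""

    parameter: str
    base_value: float
    low_value: float
    high_value: float
    outcome_at_base: float | None
    outcome_at_low: float | None
    outcome_at_high: float | None
    swing: float
    flags: tuple[str, ...] = ()


def default_range(point: float, fraction: float) -> tuple[float, float]:
    """Symmetric +/- *fraction* range around a non-negative point estimate."""
    if point < 0:
        raise ValueError("point must be >= 0")
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    return point * (1.0 - fraction), point * (1.0 + fraction)


# ---------------------------------------------------------------------------
# named parameter access with linked-consistency rules

_SIMPLE_FIELDS = (
    "total_diabetes_population",
    "high_risk_fraction",
    "baseline_ulcer_prevalence",
    "effectiveness_standard",
    "effectiveness_standard_plus_temp",
    "cost_wound_management",
    "cost_debridement",
    "cost_minor_amputation",
    "cost_major_amputation",
)


def parameter_value(ps: ParameterSet, name: str) -> float:
    """Base value of a sensitivity parameter addressed by name."""
    if name.startswith("prevention_cost."):
        return ps.prevention_cost_per_person[Strategy(name.split(".", 1)[1])]
    if hasattr(ps, name):
        return getattr(ps, name)
    raise KeyError(f"unknown sensitivity parameter '{name}'")


def with_parameter(ps: ParameterSet, name: str, value: float) -> ParameterSet:
    """Copy of *ps* with *name* set to *value* and linked parameters adjusted.

    Raises :class:`InfeasiblePerturbation` if the adjusted set violates a
    hard constraint (a probability outside [0, 1], a broken sum-to-one);
    nothing is silently clamped.
    """
    changes: dict[str, object]
    if name.startswith("prevention_cost."):
        strat = Strategy(name.split(".", 1)[1])
        costs = dict(ps.prevention_cost_per_person)
        costs[strat] = value
        changes = {"prevention_cost_per_person": costs}
    elif name == "p_hospital":
        changes = {"p_hospital": value, "p_outpatient": 1.0 - value}
    elif name == "p_outpatient":
        changes = {"p_outpatient": value, "p_hospital": 1.0 - value}
    elif name == "p_amputation_heal":
        changes = {
            "p_amputation_heal": value,
            "p_debridement_heal": 1.0 - value - ps.p_death,
        }
    elif name == "p_debridement_heal":
        changes = {
            "p_debridement_heal": value,
            "p_amputation_heal": 1.0 - value - ps.p_death,
        }
    elif name == "p_death":
        heal = ps.p_amputation_heal + ps.p_debridement_heal
        if heal <= 0:
            raise InfeasiblePerturbation(
                "cannot rescale healing shares: both are zero"
            )
        scale = (1.0 - value) / heal
        changes = {
            "p_death": value,
            "p_amputation_heal": ps.p_amputation_heal * scale,
            "p_debridement_heal": ps.p_debridement_heal * scale,
        }
    elif name == "p_major_given_amputation":
        changes = {
            "p_major_given_amputation": value,
            "p_minor_given_amputation": 1.0 - value,
        }
    elif name == "p_minor_given_amputation":
        changes = {
            "p_minor_given_amputation": value,
            "p_major_given_amputation": 1.0 - value,
        }
    elif name in _SIMPLE_FIELDS:
        changes = {name: value}
    else:
        raise KeyError(f"unknown sensitivity parameter '{name}'")

    perturbed = replace(ps, **changes)
    try:
        # hard invariants only: the perturbed point may leave its own
        # configured sensitivity range, which is expected, so ranges are
        # stripped before validation
        validate_parameters(replace(perturbed, ranges={}))
    except ValueError as err:
        raise InfeasiblePerturbation(
            f"setting {name} = {value:g} yields an invalid parameter set: {err}"
        ) from err
    return perturbed


# ---------------------------------------------------------------------------
# the analysis


def _outcome_fn(spec: OwsaSpec) -> Callable[[ParameterSet], tuple[float | None, list[str]]]:
    def evaluate(ps: ParameterSet) -> tuple[float | None, list[str]]:
        cmp = compare(ps, spec.intervention, spec.comparator)
        flags: list[str] = []
        if spec.outcome == "deaths_averted":
            return cmp.deaths_averted, flags
        if spec.outcome == "delta_cost":
            return (
                cmp.delta_cost_with_indirect
                if spec.include_indirect
                else cmp.delta_cost_direct
            ), flags
        delta = (
            cmp.delta_cost_with_indirect
            if spec.outcome == "icer_with_indirect"
            else cmp.delta_cost_direct
        )
        label = (
            cmp.label_with_indirect
            if spec.outcome == "icer_with_indirect"
            else cmp.label_direct
        )
        if cmp.deaths_averted == 0:
            return None, ["undefined: no difference in deaths"]
        # signed ratio kept even under dominance so tornado bars stay
        # plottable; the label is surfaced as a flag
        if label is not DominanceLabel.ICER:
            flags.append(label.value)
        return delta / cmp.deaths_averted, flags

    return evaluate


def run_owsa(ps: ParameterSet, spec: OwsaSpec) -> list[TornadoEntry]:
    """One-way sensitivity analysis; entries ordered by descending swing."""
    names = list(spec.parameters) if spec.parameters is not None else list(ps.ranges)
    for name in names:
        if name not in ps.ranges:
            raise KeyError(f"parameter '{name}' has no configured range")

    evaluate = _outcome_fn(spec)
    base_outcome, _ = evaluate(ps)

    entries: list[TornadoEntry] = []
    for name in names:
        lo, hi = ps.ranges[name]
        base_value = parameter_value(ps, name)
        results: dict[str, float | None] = {}
        flags: list[str] = []
        for tag, bound in (("low", lo), ("high", hi)):
            try:
                value, f = evaluate(with_parameter(ps, name, bound))
            except InfeasiblePerturbation as err:
                value, f = None, [f"infeasible at {tag}: {err}"]
            results[tag] = value
            flags.extend(f"{tag}: {msg}" for msg in f)
        out_lo, out_hi = results["low"], results["high"]
        if out_lo is not None and out_hi is not None:
            swing = abs(out_hi - out_lo)
        elif base_outcome is not None and (out_lo is not None or out_hi is not None):
            present = out_lo if out_lo is not None else out_hi
            swing = abs(present - base_outcome)
        else:
            swing = 0.0
        entries.append(
            TornadoEntry(
                parameter=name,
                base_value=base_value,
                low_value=lo,
                high_value=hi,
                outcome_at_base=base_outcome,
                outcome_at_low=out_lo,
                outcome_at_high=out_hi,
                swing=swing,
                flags=tuple(flags),
            )
        )
    return order_tornado(entries)


def order_tornado(entries: Sequence[TornadoEntry]) -> list[TornadoEntry]:
    """Sort by descending swing; ties broken by parameter name."""
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))
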