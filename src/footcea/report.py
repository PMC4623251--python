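"""Report rendering: cost-of-illness, cost-effectiveness and tornado tables.

All model quantities are computed and stored at full precision; rounding
(half-up, persons and dollars to integers) happens only when a table is
rendered. CSV and JSON outputs carry plain numbers; the markdown rendering
adds currency symbols and thousands separators for reading.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cea import Comparison, full_comparison_table
from .cohort import compute_flows
from .costing import ENDPOINT_LABELS, ENDPOINTS, total_direct_cost
from .parameters import ParameterSet, Strategy, dump_parameters, high_risk_population
from .sensitivity import TornadoEntry

__all__ = [
    "ReportBundle",
    "round_half_up",
    "coi_table",
    "cea_table",
    "tornado_table",
    "render_reports",
]

STRATEGY_TITLES = {
    Strategy.SUB_OPTIMAL: "Sub-optimal care",
    Strategy.STANDARD: "Standard care",
    Strategy.STANDARD_PLUS_TEMP: "Standard care plus temperature monitoring",
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ReportBundle:
    """Full-precision report tables plus provenance metadata."""

    coi_table: pd.DataFrame
    cea_table: pd.DataFrame
    tornado_tables: Mapping[str, pd.DataFrame]
    metadata: Mapping[str, str] = field(default_factory=dict)


def coi_table(ps: ParameterSet) -> pd.DataFrame:
    """Cost-of-illness table: one row per line item, one strategy pair of
    columns (persons, cost in US$), full precision."""
    pop = high_risk_population(ps)
    rows: dict[str, dict[str, float]] = {}

    def put(row: str, strategy: Strategy, persons: float | None, cost: float | None):
        cell = rows.setdefault(row, {})
        if persons is not None:
            cell[f"{strategy.value}_persons"] = persons
        if cost is not None:
            cell[f"{strategy.value}_cost"] = cost

    for strategy in Strategy:
        flows = compute_flows(ps, strategy)
        breakdown = total_direct_cost(ps, strategy)
        put("Prevention cost per person", strategy, None,
            ps.prevention_cost_per_person[strategy])
        put("Total people", strategy, pop, None)
        put("Total cost of prevention", strategy, None, breakdown.prevention_total)

        persons_by_endpoint = {
            "debridement": flows.n_debridement_heal,
            "heal_major": flows.n_heal_major_amputation,
            "heal_minor": flows.n_heal_minor_amputation,
            "death_major": flows.n_death_major_amputation,
            "death_minor": flows.n_death_minor_amputation,
            "outpatient_wound": flows.n_outpatient_heal,
        }
        hospital_cost = 0.0
        for endpoint in ENDPOINTS:
            cost = breakdown.treatment_by_endpoint[endpoint]
            put(ENDPOINT_LABELS[endpoint], strategy, persons_by_endpoint[endpoint], cost)
            if endpoint != "outpatient_wound":
                hospital_cost += cost
        put("Hospital subtotal", strategy, flows.n_hospital, hospital_cost)
        put("Total No. of people / Total cost of treatment", strategy,
            flows.n_ulcerated, breakdown.treatment_total)
        put("Total cost", strategy, None, breakdown.direct_total)

    order = [
        "Prevention cost per person",
        "Total people",
        "Total cost of prevention",
        *(ENDPOINT_LABELS[e] for e in ENDPOINTS if e != "outpatient_wound"),
        "Hospital subtotal",
        ENDPOINT_LABELS["outpatient_wound"],
        "Total No. of people / Total cost of treatment",
        "Total cost",
    ]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(order)
    df.index.name = "description"
    return df


def _icer_cell(label, icer) -> float | str:
    return label.value if icer is None else icer


def cea_table(ps: ParameterSet, comparisons: Sequence[Comparison] | None = None) -> pd.DataFrame:
    """Incremental comparison table, one column per strategy pair."""
    comparisons = list(comparisons) if comparisons is not None else full_comparison_table(ps)
    data = {}
    for c in comparisons:
        col = f"{c.intervention.value} vs {c.comparator.value}"
        data[col] = {
            "delta_cost_direct": c.delta_cost_direct,
            "delta_cost_direct_plus_indirect": c.delta_cost_with_indirect,
            "deaths_averted": c.deaths_averted,
            "major_amputations_averted": c.major_amputations_averted,
            "icer_direct": _icer_cell(c.label_direct, c.icer_direct),
            "icer_direct_plus_indirect": _icer_cell(
                c.label_with_indirect, c.icer_with_indirect
            ),
            "cost_effective_at_threshold": c.cost_effective_at_threshold,
            "threshold": c.threshold,
        }
    df = pd.DataFrame(data)
    df.index.name = "quantity"
    return df


def tornado_table(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    """One-way sensitivity entries as a flat table (tornado order preserved)."""
    df = pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "base_value": e.base_value,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "outcome_at_base": e.outcome_at_base,
                "outcome_at_low": e.outcome_at_low,
                "outcome_at_high": e.outcome_at_high,
                "swing": e.swing,
                "flags": "; ".join(e.flags),
            }
            for e in entries
        ]
    )
    return df


# ---------------------------------------------------------------------------
# rendering


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    """Half-up integer rounding of every numeric cell (rendered view)."""

    def cell(x):
        if isinstance(x, float) and not math.isnan(x):
            return round_half_up(x)
        return x

    return df.map(cell)


def _markdown_table(df: pd.DataFrame, money_cols: bool = True) -> str:
    """Minimal GitHub-style markdown table with thousands separators."""
    df = df.reset_index()

    def fmt(x, col: str) -> str:
        if isinstance(x, bool):
            return "yes" if x else "no"
        if isinstance(x, float) and math.isnan(x):
            return ""
        if isinstance(x, (int, float)):
            n = round_half_up(float(x))
            text = f"{n:,}"
            if money_cols and ("cost" in col.lower() or "icer" in col.lower()):
                text = f"US${text}" if n >= 0 else f"-US${-n:,}"
            return text
        return str(x)

    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    rule = "|" + "|".join(" --- " for _ in df.columns) + "|"
    body = [
        "| " + " | ".join(fmt(v, str(c)) for c, v in zip(df.columns, row)) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, rule, *body])


def render_reports(
    ps: ParameterSet,
    out_dir: str | Path,
    formats: Iterable[str] = ("csv", "json", "markdown"),
    tornado: Mapping[str, Sequence[TornadoEntry]] | None = None,
) -> ReportBundle:
    """Compute all report tables and write them under *out_dir*.

    Writes ``coi.<ext>`` and ``cea.<ext>`` for each requested format plus
    one ``tornado_<name>.<ext>`` per supplied tornado analysis; markdown is
    combined into a single ``report.md``.
    """
    formats = set(formats)
    unknown = formats - {"csv", "json", "markdown"}
    if unknown:
        raise ValueError(f"unknown report formats: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    coi = coi_table(ps)
    cea = cea_table(ps)
    tornado_frames = {
        name: tornado_table(entries) for name, entries in (tornado or {}).items()
    }
    config_yaml = yaml.safe_dump(dump_parameters(ps), sort_keys=True)
    metadata = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "generated_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }

    named = {"coi": coi, "cea": cea}
    named.update({f"tornado_{k}": v for k, v in tornado_frames.items()})

    if "csv" in formats:
        for name, df in named.items():
            _rounded(df).to_csv(out / f"{name}.csv")
    if "json" in formats:
        doc = {
            "metadata": metadata,
            **{
                name: json.loads(_rounded(df).to_json(orient="index"))
                for name, df in named.items()
            },
        }
        (out / "report.json").write_text(json.dumps(doc, indent=2))
    if "markdown" in formats:
        parts = [
            "# Diabetic-foot prevention: cost-of-illness and cost-effectiveness",
            "",
            f"Package version {metadata['package_version']}; "
            f"configuration sha256 `{metadata['config_sha256'][:12]}`.",
            "",
            "## Cost of illness (direct costs)",
            "",
            _markdown_table(coi),
            "",
            "## Incremental cost-effectiveness",
            "",
            _markdown_table(cea),
        ]
        for name, df in tornado_frames.items():
            parts += ["", f"## One-way sensitivity: {name}", "", _markdown_table(df)]
        (out / "report.md").write_text("\n".join(parts) + "\n")

    return ReportBundle(
        coi_table=coi, cea_table=cea, tornado_tables=tornado_frames, metadata=metadata
    )
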