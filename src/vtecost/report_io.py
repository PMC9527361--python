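"""Configuration, file I/O and the end-to-end break-even pipeline.

Drug costs come in as a CSV with header
``name,dose,route,course_cost_usd,monitoring_cost_usd``; currency cells are
parsed as exact decimal dollars so prices like $504.23 round-trip without
float contamination.  A flat YAML config describes a run (treatment cost,
initial rates, optional treatment-cost grid, output directory) and
:func:`run_breakeven` writes the rate-sweep and cost-sweep tables as CSV and
markdown plus a JSON manifest recording every resolved input and the
package version, so two surgeons running the model with the same local
prices produce byte-identical artifacts.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .econ_model import DrugCourse
from .sensitivity import (
    SweepTable,
    TableFormat,
    render_table,
    sweep_initial_rates,
    sweep_treatment_costs,
)

__all__ = [
    "RunConfig",
    "read_drug_table",
    "packaged_drug_table",
    "load_config",
    "run_breakeven",
    "parse_rendered_csv",
]

_DRUG_COLUMNS = ("name", "dose", "route", "course_cost_usd", "monitoring_cost_usd")

#: Lowest published cost of INR monitoring for a warfarin course (USD);
#: used when a run adds the warfarin-with-monitoring variant.
INR_MONITORING_USD = Decimal("6.19")


@dataclass(frozen=True)
class RunConfig:
    """Resolved inputs for one end-to-end run."""

    drug_table_path: str
    treatment_cost: Decimal
    initial_rates: tuple[float, ...]
    output_dir: str
    treatment_cost_grid: tuple[Decimal, ...] = ()
    annual_surgeries: int = 1
    include_inr_variant: bool = True
    seed: int | None = None


def _parse_money(cell: str, row: int, column: str) -> Decimal:
    try:
        value = Decimal(cell.strip().replace("$", "").replace(" ", ""))
    except InvalidOperation:
        raise ValueError(f"row {row}, column {column!r}: not a currency amount: {cell!r}") from None
    return value


def read_drug_table(source) -> list[DrugCourse]:
    """Read regimens from a drug-cost CSV (path or open text file).

    Course costs must be positive; monitoring costs non-negative.  Errors
    name the offending row and column.
    """
    if hasattr(source, "read"):
        fh = io.StringIO(source.read())
        close = False
    else:
        fh = open(source, "r", encoding="utf-8", newline="")
        close = True
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError("drug table is empty (no header row)")
        missing = [c for c in _DRUG_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"drug table is missing column(s): {', '.join(missing)}")
        drugs: list[DrugCourse] = []
        for i, row in enumerate(reader, start=2):
            cost = _parse_money(row["course_cost_usd"], i, "course_cost_usd")
            if cost <= 0:
                raise ValueError(f"row {i}, column 'course_cost_usd': must be positive, got {cost}")
            monitoring = _parse_money(row["monitoring_cost_usd"] or "0", i, "monitoring_cost_usd")
            drugs.append(
                DrugCourse(
                    name=row["name"].strip(),
                    course_cost=cost,
                    monitoring_cost=monitoring,
                    dose_label=row["dose"].strip(),
                    route=row["route"].strip(),
                )
            )
        if not drugs:
            raise ValueError("drug table contains no data rows")
        return drugs
    finally:
        if close:
            fh.close()


def packaged_drug_table() -> list[DrugCourse]:
    """The packaged drug-cost fixture: retail prices of a 1-month course of
    the five commonly prescribed regimens (aspirin 81/325 mg, enoxaparin
    40 mg, rivaroxaban 20 mg, warfarin 5 mg)."""
    with resources.files("vtecost.data").joinpath("drug_costs.csv").open("r", encoding="utf-8") as fh:
        return read_drug_table(fh)


def load_config(path) -> RunConfig:
    """Load a flat key-value YAML run config."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r} must be a flat mapping")
    known = {
        "drug_table_path", "treatment_cost", "initial_rates", "output_dir",
        "treatment_cost_grid", "annual_surgeries", "include_inr_variant", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(
        drug_table_path=str(raw["drug_table_path"]),
        treatment_cost=Decimal(str(raw["treatment_cost"])),
        initial_rates=tuple(float(r) for r in raw["initial_rates"]),
        output_dir=str(raw["output_dir"]),
        treatment_cost_grid=tuple(Decimal(str(c)) for c in raw.get("treatment_cost_grid", ())),
        annual_surgeries=int(raw.get("annual_surgeries", 1)),
        include_inr_variant=bool(raw.get("include_inr_variant", True)),
        seed=None if raw.get("seed") is None else int(raw["seed"]),
    )


def _resolve_drugs(config: RunConfig) -> list[DrugCourse]:
    drugs = packaged_drug_table() if config.drug_table_path == "packaged" \
        else read_drug_table(config.drug_table_path)
    if config.include_inr_variant:
        for drug in list(drugs):
            if drug.name.lower() == "warfarin":
                drugs.append(drug.with_monitoring(INR_MONITORING_USD))
    return drugs


def _write(path: Path, text: str) -> str:
    path.write_text(text, encoding="utf-8")
    return path.name


def run_breakeven(config: RunConfig) -> dict:
    """Run the full pipeline and write its artifacts.

    Writes ``rate_table.csv``/``.md`` (drugs x initial rates), and when a
    treatment-cost grid is configured ``cost_table.csv``/``.md`` (every
    drug along the grid), plus ``manifest.json`` and ``run.log``.  Output
    is deterministic: rerunning an identical config reproduces every file
    byte for byte.  Returns the manifest dict.
    """
    drugs = _resolve_drugs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    written: list[str] = []
    rate_fmt = TableFormat(final_rate_dp=3, arr_dp=3, axis_dp=2)
    rate_table = sweep_initial_rates(drugs, sorted(config.initial_rates), config.treatment_cost)
    rate_table = SweepTable(rate_table.axis_name, rate_table.rows, rate_fmt)
    written.append(_write(outdir / "rate_table.csv", render_table(rate_table, "csv")))
    written.append(_write(outdir / "rate_table.md", render_table(rate_table, "markdown")))

    if config.treatment_cost_grid:
        pieces = [
            sweep_treatment_costs(drug, config.initial_rates[0], list(config.treatment_cost_grid))
            for drug in drugs
        ]
        cost_table = SweepTable(
            axis_name="treatment_cost",
            rows=tuple(row for piece in pieces for row in piece.rows),
            format_spec=TableFormat(final_rate_dp=3, arr_dp=2, axis_dp=2),
        )
        written.append(_write(outdir / "cost_table.csv", render_table(cost_table, "csv")))
        written.append(_write(outdir / "cost_table.md", render_table(cost_table, "markdown")))

    manifest = {
        "package": "vtecost",
        "version": __version__,
        "config": {
            "drug_table_path": config.drug_table_path,
            "treatment_cost_usd": str(config.treatment_cost),
            "initial_rates": list(config.initial_rates),
            "treatment_cost_grid_usd": [str(c) for c in config.treatment_cost_grid],
            "annual_surgeries": config.annual_surgeries,
            "include_inr_variant": config.include_inr_variant,
            "seed": config.seed,
        },
        "drugs": [
            {
                "label": d.label,
                "course_cost_usd": str(d.course_cost),
                "monitoring_cost_usd": str(d.monitoring_cost),
                "route": d.route,
            }
            for d in drugs
        ],
        "outputs": written,
    }
    _write(outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    log_lines = [f"vtecost {__version__} break-even run"]
    log_lines += [f"input {k} = {v}" for k, v in sorted(manifest["config"].items())]
    log_lines += [f"wrote {name}" for name in written + ["manifest.json"]]
    _write(outdir / "run.log", "\n".join(log_lines) + "\n")
    return manifest


def parse_rendered_csv(text: str) -> list[dict]:
    """Parse a rendered sweep CSV back into typed rows (floats for the
    percent columns, int NNT, bool verdict); inverse of the CSV dialect of
    :func:`~vtecost.sensitivity.render_table` at the rendered precision."""
    reader = csv.DictReader(io.StringIO(text))
    rows = []
    for row in reader:
        rows.append(
            {
                "drug": row["drug"],
                "axis": float(row["axis"]),
                "final_rate_pct": float(row["final_rate_pct"]),
                "arr_pct": float(row["arr_pct"]),
                "nnt": int(row["nnt"]),
                "cost_effective": row["cost_effective"] == "true",
            }
        )
    return rows
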