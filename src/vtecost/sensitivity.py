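"""Deterministic one-way sensitivity sweeps over the break-even model.

Two sweeps reproduce the published sensitivity structure of the analysis:

* :func:`sweep_initial_rates` — every drug at each initial symptomatic VTE
  rate (low literature rate 0.46%, registry rate 1.01%, high literature
  rate 9.8%) at a fixed treatment cost.  ARR and NNT are price ratios and
  therefore constant along this axis; only the final rate moves.
* :func:`sweep_treatment_costs` — one drug along an escalating grid of
  per-event treatment costs, showing where an expensive drug first breaks
  even (the final rate's sign change).

Results are carried as a :class:`SweepTable` — an ordered grid of
:class:`~vtecost.econ_model.BreakEvenResult` rows plus the display rounding
the rendered table should use — and rendered to CSV or markdown by
:func:`render_table` with byte-deterministic output.

The package also ships the published reference cells for both sweeps
(printed strings with their per-cell decimal places); a handful of
final-rate cells in the published rate sweep are internally inconsistent
with the model's own arithmetic and carry ``final_rate_excluded = 1`` so
they stay visible as documented anomalies without being asserted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources

import pandas as pd

from .econ_model import BreakEvenResult, CostScenario, DrugCourse, break_even_rate, round_half_away

__all__ = [
    "TableFormat",
    "SweepTable",
    "sweep_initial_rates",
    "sweep_treatment_costs",
    "render_table",
    "load_reference_rate_table",
    "load_reference_cost_table",
]


@dataclass(frozen=True)
class TableFormat:
    """Per-column display rounding for a rendered sweep table.

    ``None`` for a dp means full float precision (``repr``), which makes a
    write-then-parse round trip exact.  The published cost-escalation table
    uses final rate 3 dp / ARR 2 dp / integer NNT.
    """

    final_rate_dp: int | None = 3
    arr_dp: int | None = 2
    axis_dp: int = 2


@dataclass(frozen=True)
class SweepTable:
    """Ordered sweep results: one row per (drug label, axis value).

    ``axis_name`` is ``"initial_rate"`` (axis values are percent) or
    ``"treatment_cost"`` (axis values are exact Decimal dollars).
    """

    axis_name: str
    rows: tuple[tuple[str, object, BreakEvenResult], ...]
    format_spec: TableFormat = field(default_factory=TableFormat)

    def __post_init__(self) -> None:
        if self.axis_name not in ("initial_rate", "treatment_cost"):
            raise ValueError(f"unknown axis_name {self.axis_name!r}")


def _check_strictly_increasing(values, what: str) -> None:
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError(f"{what} must be strictly increasing, got {values!r}")


def sweep_initial_rates(
    drugs: list[DrugCourse],
    rates: list[float],
    treatment_cost,
) -> SweepTable:
    """Break-even results for every drug at each initial rate (fractions).

    Rates must be strictly increasing; one row per drug x rate, drugs in
    the order given.  ARR and NNT are constant across rates for each drug.
    """
    if not drugs or not rates:
        raise ValueError("drugs and rates must be non-empty")
    if any(not 0.0 < r <= 1.0 for r in rates):
        raise ValueError(f"rates must lie in (0, 1], got {rates!r}")
    _check_strictly_increasing(rates, "rates")
    rows = []
    for drug in drugs:
        for rate in rates:
            scenario = CostScenario(treatment_cost=treatment_cost, initial_rate=rate)
            rows.append((drug.label, rate, break_even_rate(drug, scenario)))
    return SweepTable(axis_name="initial_rate", rows=tuple(rows))


def sweep_treatment_costs(
    drug: DrugCourse,
    initial_rate: float,
    costs: list,
) -> SweepTable:
    """Break-even results for one drug along an escalating treatment-cost grid.

    Costs must be positive and strictly increasing (callers sort; the
    contract is explicit).  Along the grid the final rate rises toward the
    initial rate and the NNT grows: a costlier event makes prevention easier
    to justify but each prevented event buys more courses.
    """
    if not costs:
        raise ValueError("costs must be non-empty")
    costs_dec = [Decimal(str(c)) for c in costs]
    if any(c <= 0 for c in costs_dec):
        raise ValueError(f"costs must be positive, got {costs!r}")
    _check_strictly_increasing(costs_dec, "costs")
    rows = []
    for cost in costs_dec:
        scenario = CostScenario(treatment_cost=cost, initial_rate=initial_rate)
        rows.append((drug.label, cost, break_even_rate(drug, scenario)))
    return SweepTable(axis_name="treatment_cost", rows=tuple(rows))


def _fmt(value: float, dp: int | None) -> str:
    if dp is None:
        return repr(value)
    return f"{round_half_away(value, dp):.{dp}f}"


def _table_cells(table: SweepTable) -> tuple[list[str], list[list[str]]]:
    header = ["drug", "axis", "final_rate_pct", "arr_pct", "nnt", "cost_effective"]
    spec = table.format_spec
    body = []
    for drug, axis, res in table.rows:
        if table.axis_name == "treatment_cost":
            axis_cell = f"{Decimal(str(axis)):.{spec.axis_dp}f}"
        else:
            axis_cell = _fmt(float(axis) * 100.0, spec.axis_dp)
        body.append([
            drug,
            axis_cell,
            _fmt(res.final_rate * 100.0, spec.final_rate_dp),
            _fmt(res.arr * 100.0, spec.arr_dp),
            str(res.nnt),
            "true" if res.cost_effective else "false",
        ])
    return header, body


def render_table(table: SweepTable, dialect: str = "csv") -> str:
    """Render a sweep table as ``csv`` or ``markdown`` text.

    Output is deterministic (byte-identical for identical inputs); both
    dialects carry identical cell strings, so they parse to identical
    numbers.  Negative rates use the ASCII minus sign.
    """
    header, body = _table_cells(table)
    if dialect == "csv":
        buf = io.StringIO()
        buf.write(",".join(header) + "\n")
        for row in body:
            buf.write(",".join(row) + "\n")
        return buf.getvalue()
    if dialect == "markdown":
        widths = [max(len(h), *(len(r[i]) for r in body)) if body else len(h)
                  for i, h in enumerate(header)]
        lines = [
            "| " + " | ".join(h.ljust(w) for h, w in zip(header, widths)) + " |",
            "| " + " | ".join("-" * w for w in widths) + " |",
        ]
        for row in body:
            lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(row, widths)) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'markdown')")


def _load_packaged(name: str, dtype: dict) -> pd.DataFrame:
    with resources.files("vtecost.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype=dtype)


def load_reference_rate_table() -> pd.DataFrame:
    """Published drug x initial-rate reference cells.

    Columns: drug, monitoring_usd, initial_rate_pct, final_rate_printed,
    final_rate_dp, arr_printed, arr_dp, nnt, final_rate_excluded.  Printed
    values keep their original per-cell decimal places; rows with
    ``final_rate_excluded = 1`` are final-rate cells whose printed value is
    inconsistent with the model arithmetic (documented anomalies — their
    ARR and NNT cells remain valid).
    """
    # printed cells stay strings to preserve their published precision
    return _load_packaged(
        "rate_table_reference.csv",
        {"drug": str, "final_rate_printed": str, "arr_printed": str},
    )


def load_reference_cost_table() -> pd.DataFrame:
    """Published treatment-cost-escalation reference cells (final rate 3 dp,
    ARR 2 dp, integer NNT) for enoxaparin 40 and rivaroxaban 20 at the low
    0.46% initial rate."""
    return _load_packaged("cost_table_reference.csv", {"drug": str})
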