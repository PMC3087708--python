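"""Aggregate clone evaluations into summary tables and plate maps.

Three deliverables: a per-category summary (counts, percentages, and how
many clones in each category need re-annotation), a cross-tabulation of
predicted category against direct-sequencing outcome, and per-plate
16x24 well maps using the road-traffic glyph convention (G/Y/R for
green/yellow/red, an ``R`` suffix for clones needing remapping, a tick
or cross where sequencing confirmed or refuted the prediction).

All percentages are computed exactly on integer counts and rounded
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from cloneaudit.io_formats import PLATE_COLS, PLATE_ROWS
from cloneaudit.scoring import Category, CloneEvaluation, NO_TARGET, REMAPPED

OUTCOME_RELIABLE = "RELIABLE"
OUTCOME_REMAPPED_RETIRED = "REMAPPED_RETIRED"
OUTCOME_REMAPPED_WRONG_INSERT = "REMAPPED_WRONG_INSERT"
OUTCOME_UNRELIABLE = "UNRELIABLE"
OUTCOMES = (
    OUTCOME_RELIABLE,
    OUTCOME_REMAPPED_RETIRED,
    OUTCOME_REMAPPED_WRONG_INSERT,
    OUTCOME_UNRELIABLE,
)

_CATEGORY_ROW = {
    Category.RELIABLE: "Green",
    Category.MARGINAL: "Yellow",
    Category.UNRELIABLE: "Red",
}

_GLYPH = {
    Category.RELIABLE: "G",
    Category.MARGINAL: "Y",
    Category.UNRELIABLE: "R",
}


@dataclass(frozen=True)
class ValidationRecord:
    """Direct-sequencing outcome for one clone."""

    clone_name: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown validation outcome {self.outcome!r}")


def round_pct(count: int, total: int) -> float:
    """Exact percentage of ``count`` in ``total``, rounded half-up to two
    decimals (0.0 when the total is zero)."""
    if total == 0:
        return 0.0
    pct = Decimal(count * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summary_from_counts(
    category_counts: Mapping[str, int],
    sequenced_counts: Mapping[str, int] | None = None,
    remapped_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Category summary table from bare counts.

    ``category_counts`` maps ``Reliable``/``Marginal``/``Unreliable`` to
    clone counts. Category percentages are of the library total;
    sequenced and remapped percentages are of their own category row.
    """
    order = ["Reliable", "Marginal", "Unreliable"]
    total = sum(category_counts.get(k, 0) for k in order)
    rows = []
    for name in order:
        n = category_counts.get(name, 0)
        row = {"group": name, "count": n, "pct": round_pct(n, total)}
        if sequenced_counts is not None:
            row["sequenced"] = sequenced_counts.get(name, 0)
            row["sequenced_pct"] = round_pct(row["sequenced"], n)
        if remapped_counts is not None:
            row["remapped"] = remapped_counts.get(name, 0)
            row["remapped_pct"] = round_pct(row["remapped"], n)
        rows.append(row)
    total_row = {"group": "Total", "count": total, "pct": round_pct(total, total)}
    if sequenced_counts is not None:
        s = sum(r["sequenced"] for r in rows)
        total_row["sequenced"] = s
        total_row["sequenced_pct"] = round_pct(s, total)
    if remapped_counts is not None:
        m = sum(r["remapped"] for r in rows)
        total_row["remapped"] = m
        total_row["remapped_pct"] = round_pct(m, total)
    rows.append(total_row)
    return pd.DataFrame(rows).set_index("group")


def summary_table(
    evaluations: Sequence[CloneEvaluation],
    validations: Sequence[ValidationRecord] | None = None,
) -> pd.DataFrame:
    """Category summary of a library evaluation.

    Counts clones per category with percentages of the total, plus per
    category how many carry the remap flag (``REMAPPED`` or no target at
    all) and, when validation records are supplied, how many were
    sequenced.
    """
    cat_counts: dict[str, int] = {}
    remap_counts: dict[str, int] = {}
    seq_counts: dict[str, int] = {}
    sequenced = {v.clone_name for v in validations} if validations else set()
    for e in evaluations:
        name = _CATEGORY_ROW[e.category].replace("Green", "Reliable").replace(
            "Yellow", "Marginal").replace("Red", "Unreliable")
        cat_counts[name] = cat_counts.get(name, 0) + 1
        if REMAPPED in e.flags or NO_TARGET in e.flags:
            remap_counts[name] = remap_counts.get(name, 0) + 1
        if e.clone_name in sequenced:
            seq_counts[name] = seq_counts.get(name, 0) + 1
    return summary_from_counts(
        cat_counts,
        seq_counts if validations else None,
        remap_counts,
    )


def crosstab_from_counts(rows: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Validation cross-tab from bare counts.

    ``rows`` maps row labels (``Green``/``Yellow``/``Red``) to outcome
    counts keyed by the four validation outcomes. Adds a ``Summary`` row
    and per-cell percentages of each row's total.
    """
    order = [r for r in ("Green", "Yellow", "Red") if r in rows]
    records = []
    totals = {o: 0 for o in OUTCOMES}
    grand = 0
    for label in order:
        counts = rows[label]
        n = sum(counts.get(o, 0) for o in OUTCOMES)
        rec: dict[str, object] = {"category": label, "n": n}
        for outcome in OUTCOMES:
            c = counts.get(outcome, 0)
            rec[outcome] = c
            rec[outcome + "_pct"] = round_pct(c, n)
            totals[outcome] += c
        grand += n
        records.append(rec)
    summary: dict[str, object] = {"category": "Summary", "n": grand}
    for outcome in OUTCOMES:
        summary[outcome] = totals[outcome]
        summary[outcome + "_pct"] = round_pct(totals[outcome], grand)
    records.append(summary)
    return pd.DataFrame(records).set_index("category")


def validation_crosstab(
    evaluations: Sequence[CloneEvaluation],
    validation_records: Sequence[ValidationRecord],
) -> pd.DataFrame:
    """Cross-tabulate predicted category against sequencing outcome."""
    by_name = {e.clone_name: e for e in evaluations}
    rows: dict[str, dict[str, int]] = {
        "Green": {}, "Yellow": {}, "Red": {},
    }
    for record in validation_records:
        ev = by_name.get(record.clone_name)
        if ev is None:
            raise ValueError(
                f"validation record for unknown clone {record.clone_name!r}"
            )
        row = rows[_CATEGORY_ROW[ev.category]]
        row[record.outcome] = row.get(record.outcome, 0) + 1
    return crosstab_from_counts(rows)


def _glyph(e: CloneEvaluation, outcome: str | None) -> str:
    glyph = _GLYPH[e.category]
    if REMAPPED in e.flags or NO_TARGET in e.flags:
        glyph += "R"
    if outcome is not None:
        glyph += "✓" if outcome == OUTCOME_RELIABLE else (
            "✗" if outcome == OUTCOME_UNRELIABLE else "")
    return glyph


def _plate_wells(
    evaluations: Sequence[CloneEvaluation],
    plate: str,
    validations: Sequence[ValidationRecord] | None,
) -> dict[tuple[str, int], str]:
    outcome_by_name = {v.clone_name: v.outcome for v in validations or ()}
    wells: dict[tuple[str, int], str] = {}
    found = False
    for e in evaluations:
        if f"{e.location.chrom_label}-{e.location.plate_no}" != plate:
            continue
        found = True
        wells[(e.location.row, e.location.col)] = _glyph(
            e, outcome_by_name.get(e.clone_name)
        )
    if not found:
        raise ValueError(f"no clones on plate {plate!r}")
    return wells


def plate_map(
    evaluations: Sequence[CloneEvaluation],
    plate: str,
    validations: Sequence[ValidationRecord] | None = None,
) -> str:
    """Text rendering of one 384-well plate, e.g. plate ``"IV-2"``.

    Wells show G/Y/R by category with an ``R`` suffix for clones needing
    remapping and a tick/cross where sequencing confirmed/refuted; blank
    wells show a middle dot.
    """
    wells = _plate_wells(evaluations, plate, validations)
    width = max(3, max((len(g) for g in wells.values()), default=3) + 1)
    header = "    " + "".join(f"{c:>{width}}" for c in range(1, PLATE_COLS + 1))
    lines = [f"Plate {plate}", header]
    for row in PLATE_ROWS:
        cells = "".join(
            f"{wells.get((row, c), chr(0xB7)):>{width}}" for c in range(1, PLATE_COLS + 1)
        )
        lines.append(f"  {row} {cells}")
    return "\n".join(lines) + "\n"


_HTML_COLOR = {"G": "#7bd47b", "Y": "#f2e35a", "R": "#e66a6a"}


def plate_map_html(
    evaluations: Sequence[CloneEvaluation],
    plate: str,
    validations: Sequence[ValidationRecord] | None = None,
) -> str:
    """HTML rendering of one plate with colored well backgrounds."""
    wells = _plate_wells(evaluations, plate, validations)
    parts = [
        f"<table border='1' style='border-collapse:collapse'><caption>Plate {plate}"
        "</caption><tr><th></th>"
    ]
    parts += [f"<th>{c}</th>" for c in range(1, PLATE_COLS + 1)]
    parts.append("</tr>")
    for row in PLATE_ROWS:
        parts.append(f"<tr><th>{row}</th>")
        for col in range(1, PLATE_COLS + 1):
            glyph = wells.get((row, col), "")
            color = _HTML_COLOR.get(glyph[:1], "#ffffff")
            parts.append(f"<td style='background:{color};text-align:center'>{glyph}</td>")
        parts.append("</tr>")
    parts.append("</table>")
    return "".join(parts)
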