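"""Corpus-level aggregation and report writing.

Aggregates per-row validation reports into occurrence / distinct-name
counts per match-provenance category and writes deterministic TSV, JSON
and plain-text summaries. The JSON document is validated against the
pydantic schema in :mod:`cellgate.schema`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from ._text import canon
from .gate_parser import Provenance
from .validator import GateStatus, ValidationReport, Verdict

CATEGORIES = (
    Provenance.PRO_SHORT_LABEL,
    Provenance.EXACT_SYNONYM,
    Provenance.MANUAL,
    Provenance.NOT_MATCHED,
)

_CATEGORY_TITLES = {
    Provenance.PRO_SHORT_LABEL: "PRO short label",
    Provenance.EXACT_SYNONYM: "exact synonym",
    Provenance.MANUAL: "manual",
    Provenance.NOT_MATCHED: "not matched",
}


@dataclass
class CorpusSummary:
    total_gate_occurrences: int = 0
    occurrences_by_provenance: dict[str, int] = field(default_factory=dict)
    occurrence_pct_by_provenance: dict[str, int] = field(default_factory=dict)
    distinct_gate_names: int = 0
    distinct_by_provenance: dict[str, int] = field(default_factory=dict)
    distinct_pct_by_provenance: dict[str, int] = field(default_factory=dict)
    rows_processed: int = 0
    conflict_rows: int = 0


def _pct(count: int, total: int) -> int:
    # Whole-percent presentation; counts are always carried alongside.
    return round(100 * count / total) if total else 0


def summarize_corpus(reports) -> CorpusSummary:
    """Single pass over validation reports.

    Occurrences count every gating-definition gate; distinct names are
    case-folded raw tokens (not intensity-stripped), each carrying the
    provenance of its normalized resolution.
    """
    occurrences = {p.value: 0 for p in CATEGORIES}
    distinct: dict[str, str] = {}
    rows = 0
    conflict_rows = 0
    for report in reports:
        rows += 1
        if report.verdict is Verdict.HAS_CONFLICTS:
            conflict_rows += 1
        for assessment in report.assessments:
            if assessment.source != "gating":
                continue
            provenance = assessment.gate.provenance.value
            occurrences[provenance] += 1
            distinct.setdefault(canon(assessment.gate.raw), provenance)
    total = sum(occurrences.values())
    distinct_counts = {p.value: 0 for p in CATEGORIES}
    for provenance in distinct.values():
        distinct_counts[provenance] += 1
    n_distinct = len(distinct)
    summary = CorpusSummary(
        total_gate_occurrences=total,
        occurrences_by_provenance=occurrences,
        occurrence_pct_by_provenance={k: _pct(v, total) for k, v in occurrences.items()},
        distinct_gate_names=n_distinct,
        distinct_by_provenance=distinct_counts,
        distinct_pct_by_provenance={
            k: _pct(v, n_distinct) for k, v in distinct_counts.items()
        },
        rows_processed=rows,
        conflict_rows=conflict_rows,
    )
    assert sum(summary.occurrences_by_provenance.values()) == total
    assert sum(summary.distinct_by_provenance.values()) == n_distinct
    return summary


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def report_to_dict(report: ValidationReport) -> dict:
    return {
        "row_id": report.row_id,
        "population_raw": report.population.raw,
        "base_label": report.population.base_label,
        "cl_id": report.population.cl_id,
        "resolved": report.population.resolved,
        "verdict": report.verdict.value,
        "assessments": [
            {
                "source": a.source,
                "raw": a.gate.raw,
                "kind": a.gate.kind.value,
                "marker_id": a.gate.marker_id,
                "canonical_label": a.gate.canonical_label,
                "intensity": a.gate.intensity.symbol if a.gate.intensity else None,
                "provenance": a.gate.provenance.value,
                "status": a.status.value,
                "constraint": a.constraint.serialize() if a.constraint else None,
                "message": a.message,
            }
            for a in report.assessments
        ],
    }


def summary_to_dict(summary: CorpusSummary) -> dict:
    return {
        "total_gate_occurrences": summary.total_gate_occurrences,
        "occurrences_by_provenance": dict(sorted(summary.occurrences_by_provenance.items())),
        "occurrence_pct_by_provenance": dict(
            sorted(summary.occurrence_pct_by_provenance.items())
        ),
        "distinct_gate_names": summary.distinct_gate_names,
        "distinct_by_provenance": dict(sorted(summary.distinct_by_provenance.items())),
        "distinct_pct_by_provenance": dict(
            sorted(summary.distinct_pct_by_provenance.items())
        ),
        "rows_processed": summary.rows_processed,
        "conflict_rows": summary.conflict_rows,
    }


def summary_from_dict(data: dict) -> CorpusSummary:
    return CorpusSummary(
        total_gate_occurrences=data["total_gate_occurrences"],
        occurrences_by_provenance=dict(data["occurrences_by_provenance"]),
        occurrence_pct_by_provenance=dict(data["occurrence_pct_by_provenance"]),
        distinct_gate_names=data["distinct_gate_names"],
        distinct_by_provenance=dict(data["distinct_by_provenance"]),
        distinct_pct_by_provenance=dict(data["distinct_pct_by_provenance"]),
        rows_processed=data["rows_processed"],
        conflict_rows=data["conflict_rows"],
    )


def report_document(summary: CorpusSummary, reports: list[ValidationReport]) -> dict:
    return {
        "summary": summary_to_dict(summary),
        "rows": [report_to_dict(r) for r in reports],
    }


def summary_to_tsv(summary: CorpusSummary) -> str:
    lines = [
        "category\toccurrences\toccurrence_pct\tdistinct_names\tdistinct_pct"
    ]
    for provenance in CATEGORIES:
        key = provenance.value
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    _CATEGORY_TITLES[provenance],
                    summary.occurrences_by_provenance.get(key, 0),
                    summary.occurrence_pct_by_provenance.get(key, 0),
                    summary.distinct_by_provenance.get(key, 0),
                    summary.distinct_pct_by_provenance.get(key, 0),
                )
            )
        )
    lines.append(
        "\t".join(
            str(v)
            for v in (
                "Total",
                summary.total_gate_occurrences,
                _pct(summary.total_gate_occurrences, summary.total_gate_occurrences),
                summary.distinct_gate_names,
                _pct(summary.distinct_gate_names, summary.distinct_gate_names),
            )
        )
    )
    return "\n".join(lines) + "\n"


def render_text(summary: CorpusSummary, reports: list[ValidationReport] | None = None) -> str:
    """Human-readable summary block; conflicting rows get a CONFLICT tag."""
    width = max(len(t) for t in _CATEGORY_TITLES.values())
    lines = [
        f"rows processed: {summary.rows_processed}",
        f"rows with conflicts: {summary.conflict_rows}",
        "",
        f"{'category'.ljust(width)}  occurrences  occ%  distinct  dist%",
    ]
    for provenance in CATEGORIES:
        key = provenance.value
        lines.append(
            f"{_CATEGORY_TITLES[provenance].ljust(width)}"
            f"  {summary.occurrences_by_provenance.get(key, 0):>11}"
            f"  {summary.occurrence_pct_by_provenance.get(key, 0):>3}%"
            f"  {summary.distinct_by_provenance.get(key, 0):>8}"
            f"  {summary.distinct_pct_by_provenance.get(key, 0):>4}%"
        )
    lines.append(
        f"{'Total'.ljust(width)}  {summary.total_gate_occurrences:>11}"
        f"  {'100' if summary.total_gate_occurrences else '  0':>3}%"
        f"  {summary.distinct_gate_names:>8}"
        f"  {'100' if summary.distinct_gate_names else '  0':>4}%"
    )
    if reports:
        conflict_lines = [
            f"CONFLICT row {r.row_id}: {r.population.raw!r}"
            for r in reports
            if r.verdict is Verdict.HAS_CONFLICTS
        ]
        if conflict_lines:
            lines.append("")
            lines.extend(conflict_lines)
    return "\n".join(lines) + "\n"


def write_report(
    summary: CorpusSummary,
    reports: list[ValidationReport],
    fmt: str,
    path: str | os.PathLike,
) -> None:
    """Write a summary (and rows, for JSON) in ``tsv``, ``json`` or ``text``.

    Output is byte-stable for identical inputs; JSON is validated against
    the shipped schema before writing.
    """
    if fmt == "tsv":
        payload = summary_to_tsv(summary)
    elif fmt == "json":
        from .schema import validate_report_document

        document = report_document(summary, reports)
        validate_report_document(document)
        payload = json.dumps(document, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    elif fmt == "text":
        payload = render_text(summary, reports)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(payload)
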