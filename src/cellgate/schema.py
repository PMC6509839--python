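"""Pydantic schema for the machine-readable JSON report."""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator


class AssessmentModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: Literal["gating", "population_extra"]
    raw: str
    kind: Literal["protein_marker", "scatter", "dye", "unmatched"]
    marker_id: Optional[str]
    canonical_label: str
    intensity: Optional[Literal["−", "+", "+−", "+~", "++"]]
    provenance: Literal["pro_short_label", "exact_synonym", "manual", "not_matched"]
    status: Literal["consistent", "conflict", "not_covered", "unresolvable"]
    constraint: Optional[str]
    message: str


class RowModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    row_id: str
    population_raw: str
    base_label: str
    cl_id: Optional[str]
    resolved: bool
    verdict: Literal["valid", "has_conflicts", "unresolvable"]
    assessments: list[AssessmentModel]

    @model_validator(mode="after")
    def _verdict_matches_assessments(self) -> "RowModel":
        has_conflict = any(a.status == "conflict" for a in self.assessments)
        if has_conflict != (self.verdict == "has_conflicts"):
            raise ValueError("verdict inconsistent with assessment statuses")
        return self


class SummaryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    total_gate_occurrences: int
    occurrences_by_provenance: dict[str, int]
    occurrence_pct_by_provenance: dict[str, int]
    distinct_gate_names: int
    distinct_by_provenance: dict[str, int]
    distinct_pct_by_provenance: dict[str, int]
    rows_processed: int
    conflict_rows: int

    @model_validator(mode="after")
    def _counts_conserve(self) -> "SummaryModel":
        if sum(self.occurrences_by_provenance.values()) != self.total_gate_occurrences:
            raise ValueError("occurrence counts do not sum to total")
        if sum(self.distinct_by_provenance.values()) != self.distinct_gate_names:
            raise ValueError("distinct counts do not sum to total")
        return self


class ReportDocument(BaseModel):
    model_config = ConfigDict(extra="forbid")

    summary: SummaryModel
    rows: list[RowModel]


def validate_report_document(document: dict) -> ReportDocument:
    """Raise pydantic.ValidationError if the document is malformed."""
    return ReportDocument.model_validate(document)
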