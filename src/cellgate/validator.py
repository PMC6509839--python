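"""Cross-check parsed populations against parsed gating definitions.

Each gate is compared to the population's marker-constraint closure:
a gate whose intensity contradicts a presence/absence/amount requirement
is a conflict; a gate on a marker the closure never mentions is simply
not covered (never a conflict); scatter/dye and unmatched gates cannot be
checked against protein constraints.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .gate_parser import Dialect, Gate, GateKind, parse_gating_definition
from .ontology_catalog import (
    CellIndex,
    ConstraintRelation,
    IntensityLevel,
    MarkerConstraint,
    MarkerIndex,
    constraint_closure,
)
from .population_parser import PopulationDescriptor, parse_population


class GateStatus(str, enum.Enum):
    CONSISTENT = "consistent"
    CONFLICT = "conflict"
    NOT_COVERED = "not_covered"
    UNRESOLVABLE = "unresolvable"


class Verdict(str, enum.Enum):
    VALID = "valid"
    HAS_CONFLICTS = "has_conflicts"
    UNRESOLVABLE = "unresolvable"


@dataclass(frozen=True)
class GateAssessment:
    gate: Gate
    status: GateStatus
    constraint: MarkerConstraint | None = None
    message: str = ""
    source: str = "gating"  # "gating" or "population_extra"


@dataclass
class ValidationReport:
    row_id: str
    population: PopulationDescriptor
    assessments: list[GateAssessment] = field(default_factory=list)
    verdict: Verdict = Verdict.VALID


def _conflicts(intensity: IntensityLevel | None, relation: ConstraintRelation) -> bool:
    """Conflict table. A gate with no intensity suffix is read as
    'present, level unspecified' and never conflicts."""
    if intensity is None:
        return False
    if relation is ConstraintRelation.REQUIRES_PRESENT:
        return intensity is IntensityLevel.NEGATIVE
    if relation is ConstraintRelation.REQUIRES_ABSENT:
        return intensity.present
    if relation is ConstraintRelation.REQUIRES_HIGH:
        return intensity in (IntensityLevel.NEGATIVE, IntensityLevel.LOW)
    if relation is ConstraintRelation.REQUIRES_LOW:
        return intensity is IntensityLevel.HIGH
    raise AssertionError(f"unhandled relation {relation}")


def assess_gate(
    gate: Gate, closure: list[MarkerConstraint], source: str = "gating"
) -> GateAssessment:
    """Classify one gate against a constraint closure."""
    if gate.kind is GateKind.UNMATCHED:
        return GateAssessment(
            gate=gate,
            status=GateStatus.UNRESOLVABLE,
            message=gate.message or f"gate {gate.raw!r} did not match any catalog entry",
            source=source,
        )
    if gate.kind in (GateKind.SCATTER, GateKind.DYE):
        return GateAssessment(
            gate=gate,
            status=GateStatus.NOT_COVERED,
            message="scatter/dye gates carry no protein-marker constraint",
            source=source,
        )
    constraint = next(
        (c for c in closure if c.marker_key == gate.marker_key), None
    )
    if constraint is None:
        return GateAssessment(
            gate=gate,
            status=GateStatus.NOT_COVERED,
            message=f"no constraint on {gate.canonical_label!r} in the cell definition",
            source=source,
        )
    if _conflicts(gate.intensity, constraint.relation):
        symbol = gate.intensity.symbol if gate.intensity else ""
        return GateAssessment(
            gate=gate,
            status=GateStatus.CONFLICT,
            constraint=constraint,
            message=(
                f"gate {gate.canonical_label}{symbol} violates "
                f"{constraint.serialize()!r}"
            ),
            source=source,
        )
    return GateAssessment(
        gate=gate,
        status=GateStatus.CONSISTENT,
        constraint=constraint,
        message=f"gate agrees with {constraint.serialize()!r}",
        source=source,
    )


def _assess_unresolved(gate: Gate, source: str) -> GateAssessment:
    if gate.kind in (GateKind.SCATTER, GateKind.DYE):
        return GateAssessment(
            gate=gate,
            status=GateStatus.NOT_COVERED,
            message="scatter/dye gates carry no protein-marker constraint",
            source=source,
        )
    return GateAssessment(
        gate=gate,
        status=GateStatus.UNRESOLVABLE,
        message="population name did not resolve to a catalogued cell type",
        source=source,
    )


def validate_row(
    population_text: str,
    gating_text: str,
    dialect: Dialect,
    marker_catalog: MarkerIndex,
    cell_catalog: CellIndex,
    row_id: str = "0",
    inherit: bool = True,
) -> ValidationReport:
    """Parse both fields for one study row and assess every gate.

    Population extras that parsed as gates are validated against the same
    closure as the gating-definition gates. With ``inherit=False`` only the
    named cell's own constraints are used (no ancestor axioms).
    """
    population = parse_population(population_text, cell_catalog, marker_catalog)
    gates = parse_gating_definition(gating_text, dialect, marker_catalog)
    extra_gates = [extra for extra in population.extras if isinstance(extra, Gate)]

    assessments: list[GateAssessment] = []
    if population.resolved:
        closure = (
            constraint_closure(population.cell)
            if inherit
            else list(population.cell.own_constraints)
        )
        assessments.extend(assess_gate(g, closure, source="gating") for g in gates)
        assessments.extend(
            assess_gate(g, closure, source="population_extra") for g in extra_gates
        )
        verdict = (
            Verdict.HAS_CONFLICTS
            if any(a.status is GateStatus.CONFLICT for a in assessments)
            else Verdict.VALID
        )
    else:
        assessments.extend(_assess_unresolved(g, source="gating") for g in gates)
        assessments.extend(
            _assess_unresolved(g, source="population_extra") for g in extra_gates
        )
        verdict = Verdict.UNRESOLVABLE
    return ValidationReport(
        row_id=row_id, population=population, assessments=assessments, verdict=verdict
    )
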