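"""Population-name parsing: a cell-type label plus '&'-separated extras.

The convention is that the population field names a catalogued cell type
(optionally wrapped in single quotes) and appends additional markers or
subtype qualifiers after '&' symbols, e.g.::

    'plasmacytoid dendritic cell' & BDCA3+
    'effector memory CD4-positive, alpha-beta T cell' & Temra
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CellgateError
from .gate_parser import Gate, GateKind, GateToken, _gate_from_token
from .ontology_catalog import CellDefinition, CellIndex, MarkerIndex


@dataclass
class PopulationDescriptor:
    base_label: str
    cl_id: str | None = None
    cell: CellDefinition | None = None
    extras: list[Gate | str] = field(default_factory=list)
    resolved: bool = False
    raw: str = ""


def resolve_cell_type(label: str, cell_catalog: CellIndex) -> CellDefinition | None:
    """Case-insensitive, NFC-normalized exact match against catalog labels.

    Not-found is a value (None), never an error; no partial matching.
    """
    if not label:
        return None
    return cell_catalog.by_label(label)


def _strip_single_quotes(text: str) -> str:
    if len(text) >= 2 and text[0] == "'" and text[-1] == "'":
        return text[1:-1].strip()
    return text


def _parse_extra(text: str, marker_catalog: MarkerIndex) -> Gate | str:
    """An extra is kept as a gate when its marker resolves or when it
    carries an explicit intensity suffix; otherwise it stays free text."""
    gate = _gate_from_token(GateToken(raw=text, position=0), marker_catalog)
    if gate.kind is not GateKind.UNMATCHED or gate.intensity is not None:
        return gate
    return text


def parse_population(
    text: str, cell_catalog: CellIndex, marker_catalog: MarkerIndex
) -> PopulationDescriptor:
    """Split on '&', resolve the base label, parse extras as gates when possible.

    An unresolvable base yields ``resolved=False`` rather than an error so
    corpus processing can continue.
    """
    if not text or not text.strip():
        raise CellgateError("empty population name")
    segments = [s.strip() for s in text.split("&")]
    base = _strip_single_quotes(segments[0])
    if not base:
        raise CellgateError(f"population {text!r} has an empty base segment")
    cell = resolve_cell_type(base, cell_catalog)
    extras: list[Gate | str] = [
        _parse_extra(segment, marker_catalog) for segment in segments[1:] if segment
    ]
    return PopulationDescriptor(
        base_label=base,
        cl_id=cell.cl_id if cell else None,
        cell=cell,
        extras=extras,
        resolved=cell is not None,
        raw=text,
    )
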