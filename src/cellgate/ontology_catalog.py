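"""Marker and cell-type catalogs.

Loads flat TSV extracts of a protein-marker catalog (preferred labels,
short labels, exact synonyms, manually curated flow-cytometry synonyms),
a scatter/dye gate catalog, and a cell-type catalog whose logical
definitions are Manchester-style conjunction strings, e.g.::

    CD4-positive, alpha-beta memory T cell
        and lacks_plasma_membrane_part some C-C chemokine receptor type 7

Provides case-insensitive tiered lookup and computation of a cell type's
inherited marker-constraint closure.
"""

from __future__ import annotations

import csv
import enum
import os
import re
from dataclasses import dataclass, field

from ._text import canon
from .errors import CatalogError, ClosureError, DefinitionError

# ---------------------------------------------------------------------------
# Intensity scale
# ---------------------------------------------------------------------------


class IntensityLevel(enum.Enum):
    """Detected marker intensity; values are the preferred symbols."""

    NEGATIVE = "−"
    POSITIVE = "+"
    LOW = "+−"
    INTERMEDIATE = "+~"
    HIGH = "++"

    @property
    def symbol(self) -> str:
        return self.value

    @property
    def present(self) -> bool:
        """True for every state except negative."""
        return self is not IntensityLevel.NEGATIVE


# ---------------------------------------------------------------------------
# Marker entries
# ---------------------------------------------------------------------------


class MarkerClass(str, enum.Enum):
    PROTEIN = "protein"
    PROTEIN_COMPLEX = "protein_complex"
    PHOSPHO_PROTEIN = "phospho_protein"
    DISALLOWED = "disallowed"


DISALLOWED_MESSAGE = (
    "mixtures of lineage markers are disallowed as a single gate; "
    "spell out the specific marker cocktail used"
)

#: Synonym tiers in cascade order (first match wins).
TIERS = ("short_label", "exact_synonym", "manual")


@dataclass
class MarkerEntry:
    """One catalog record for a protein, complex or modified-form marker."""

    id: str
    preferred_label: str
    marker_class: MarkerClass = MarkerClass.PROTEIN
    short_labels: set[str] = field(default_factory=set)
    exact_synonyms: set[str] = field(default_factory=set)
    manual_synonyms: set[str] = field(default_factory=set)
    message: str = ""

    def tier(self, name: str) -> set[str]:
        return {
            "short_label": self.short_labels,
            "exact_synonym": self.exact_synonyms,
            "manual": self.manual_synonyms,
        }[name]


class ScatterBasis(str, enum.Enum):
    SIZE_FSC_SSC = "size_fsc_ssc"
    RELATIVE_DIMENSIONS = "relative_dimensions"
    DYE = "dye"


@dataclass
class ScatterGateEntry:
    """A non-protein gate: size/scatter geometry or a dye stain."""

    preferred_label: str
    basis: ScatterBasis
    alternative_spellings: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class CascadeHit:
    """Result of one tiered lookup: either marker entries or a scatter gate."""

    tier: str  # one of TIERS or "scatter"
    entries: tuple[MarkerEntry, ...] = ()
    scatter: ScatterGateEntry | None = None


class MarkerIndex:
    """Case-insensitive tiered index over marker and scatter-gate entries.

    Preferred labels are indexed in the short-label tier so every canonical
    label resolves back to its own entry.
    """

    def __init__(self) -> None:
        self.entries: dict[str, MarkerEntry] = {}
        self.scatter_entries: dict[str, ScatterGateEntry] = {}
        self._tier_maps: dict[str, dict[str, list[str]]] = {t: {} for t in TIERS}
        self._scatter_map: dict[str, str] = {}
        self.ambiguities: list[tuple[str, str, tuple[str, ...]]] = []

    # -- construction -------------------------------------------------------

    def add_entry(self, entry: MarkerEntry) -> None:
        if not entry.id:
            raise CatalogError("marker entry with empty id")
        if entry.id in self.entries:
            raise CatalogError(f"duplicate marker id {entry.id!r}")
        self._check_tier_disjointness(entry)
        if entry.marker_class is MarkerClass.DISALLOWED and not entry.message:
            entry.message = DISALLOWED_MESSAGE
        self.entries[entry.id] = entry
        self._index_text("short_label", entry.preferred_label, entry.id)
        for tier in TIERS:
            for text in entry.tier(tier):
                self._index_text(tier, text, entry.id)

    def add_scatter(self, entry: ScatterGateEntry) -> None:
        if not entry.alternative_spellings:
            raise CatalogError(
                f"scatter gate {entry.preferred_label!r} has no alternative spellings"
            )
        self.scatter_entries[entry.preferred_label] = entry
        self._scatter_map[canon(entry.preferred_label)] = entry.preferred_label
        for text in entry.alternative_spellings:
            self._scatter_map.setdefault(canon(text), entry.preferred_label)

    @staticmethod
    def _check_tier_disjointness(entry: MarkerEntry) -> None:
        seen: dict[str, str] = {}
        for tier in TIERS:
            for text in entry.tier(tier):
                key = canon(text)
                if key in seen and seen[key] != tier:
                    raise CatalogError(
                        f"entry {entry.id}: synonym {text!r} appears in both "
                        f"{seen[key]!r} and {tier!r} tiers"
                    )
                seen[key] = tier

    def _index_text(self, tier: str, text: str, entry_id: str) -> None:
        if not text:
            return
        key = canon(text)
        ids = self._tier_maps[tier].setdefault(key, [])
        if entry_id not in ids:
            ids.append(entry_id)
            if len(ids) > 1:
                self.ambiguities.append((tier, text, tuple(ids)))

    # -- lookup -------------------------------------------------------------

    def lookup(self, tier: str, text: str) -> list[MarkerEntry]:
        ids = self._tier_maps[tier].get(canon(text), [])
        return [self.entries[i] for i in ids]

    def lookup_scatter(self, text: str) -> ScatterGateEntry | None:
        name = self._scatter_map.get(canon(text))
        return self.scatter_entries[name] if name else None

    def cascade(self, text: str) -> CascadeHit | None:
        """Tiered first-match-wins lookup: short label, exact synonym, manual
        (manually curated synonyms, then scatter/dye spellings)."""
        for tier in TIERS:
            entries = self.lookup(tier, text)
            if entries:
                return CascadeHit(tier=tier, entries=tuple(entries))
        scatter = self.lookup_scatter(text)
        if scatter is not None:
            return CascadeHit(tier="scatter", scatter=scatter)
        return None


# ---------------------------------------------------------------------------
# Marker catalog loading
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ("id", "preferred_label", "tier", "synonym", "marker_class")
_SCATTER_COLUMNS = ("preferred_label", "basis", "spelling")
_CELL_COLUMNS = ("cl_id", "label", "parent_id", "definition")


def _read_tsv(path: str | os.PathLike, required: tuple[str, ...]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty file")
        for column in required:
            if column not in reader.fieldnames:
                raise CatalogError(f"{path}: missing required column {column!r}")
        rows = [row for row in reader if any((v or "").strip() for v in row.values())]
    if not rows:
        raise CatalogError(f"{path}: no data rows")
    return rows


def load_marker_catalog(
    markers_path: str | os.PathLike,
    scatter_path: str | os.PathLike | None = None,
) -> MarkerIndex:
    """Load markers.tsv (and optionally scatter_gates.tsv) into an index.

    markers.tsv has one row per (entry, tier, synonym); rows with an empty
    tier/synonym just declare the entry. scatter_gates.tsv has one row per
    alternative spelling.
    """
    index = MarkerIndex()
    staged: dict[str, MarkerEntry] = {}
    for row in _read_tsv(markers_path, _MARKER_COLUMNS):
        entry_id = row["id"].strip()
        if not entry_id:
            raise CatalogError(f"{markers_path}: row with empty id")
        entry = staged.get(entry_id)
        if entry is None:
            try:
                marker_class = MarkerClass(row["marker_class"].strip() or "protein")
            except ValueError:
                raise CatalogError(
                    f"{markers_path}: unknown marker_class {row['marker_class']!r}"
                ) from None
            entry = MarkerEntry(
                id=entry_id,
                preferred_label=row["preferred_label"].strip(),
                marker_class=marker_class,
            )
            staged[entry_id] = entry
        tier = row["tier"].strip()
        synonym = row["synonym"].strip()
        if tier:
            if tier not in TIERS:
                raise CatalogError(f"{markers_path}: unknown tier {tier!r}")
            if synonym:
                entry.tier(tier).add(synonym)
    for entry in staged.values():
        index.add_entry(entry)
    if scatter_path is not None:
        load_scatter_gates(scatter_path, index)
    return index


def load_scatter_gates(path: str | os.PathLike, index: MarkerIndex) -> MarkerIndex:
    staged: dict[str, ScatterGateEntry] = {}
    for row in _read_tsv(path, _SCATTER_COLUMNS):
        label = row["preferred_label"].strip()
        entry = staged.get(label)
        if entry is None:
            try:
                basis = ScatterBasis(row["basis"].strip())
            except ValueError:
                raise CatalogError(f"{path}: unknown basis {row['basis']!r}") from None
            entry = ScatterGateEntry(preferred_label=label, basis=basis)
            staged[label] = entry
        spelling = row["spelling"].strip()
        if spelling:
            entry.alternative_spellings.add(spelling)
    for entry in staged.values():
        index.add_scatter(entry)
    return index


# ---------------------------------------------------------------------------
# Marker constraints and logical definitions
# ---------------------------------------------------------------------------


class ConstraintRelation(str, enum.Enum):
    REQUIRES_PRESENT = "requires_present"
    REQUIRES_ABSENT = "requires_absent"
    REQUIRES_HIGH = "requires_high"
    REQUIRES_LOW = "requires_low"


#: Relation names as they appear in logical definition strings.
RELATION_NAMES = {
    "has_plasma_membrane_part": ConstraintRelation.REQUIRES_PRESENT,
    "lacks_plasma_membrane_part": ConstraintRelation.REQUIRES_ABSENT,
    "has_high_plasma_membrane_amount": ConstraintRelation.REQUIRES_HIGH,
    "has_low_plasma_membrane_amount": ConstraintRelation.REQUIRES_LOW,
}

_RELATION_TO_NAME = {v: k for k, v in RELATION_NAMES.items()}


@dataclass(frozen=True)
class MarkerConstraint:
    """One has/lacks-plasma-membrane-part style requirement on a marker."""

    relation: ConstraintRelation
    marker_text: str
    marker_id: str | None = None

    @property
    def marker_key(self) -> str:
        """Identity used to match constraints against gates."""
        return self.marker_id if self.marker_id is not None else canon(self.marker_text)

    @property
    def relation_name(self) -> str:
        return _RELATION_TO_NAME[self.relation]

    def serialize(self) -> str:
        return f"{self.relation_name} some {self.marker_text}"


_CLAUSE_RE = re.compile(r"^(\w+)\s+some\s+(.+)$", re.DOTALL)


def parse_logical_definition(
    text: str, catalog: MarkerIndex | None = None
) -> tuple[str, list[MarkerConstraint]]:
    """Parse a conjunction of one named class and relation clauses.

    Returns ``(parent_label, constraints)``. Marker names are resolved
    through the catalog cascade when possible and kept verbatim otherwise.
    """
    conjuncts = [c.strip() for c in re.split(r"\s+and\s+", text.strip()) if c.strip()]
    if not conjuncts:
        raise DefinitionError("empty logical definition")
    parent: str | None = None
    constraints: list[MarkerConstraint] = []
    for conjunct in conjuncts:
        match = _CLAUSE_RE.match(conjunct)
        if match:
            relation_name, marker_text = match.group(1), match.group(2).strip()
            relation = RELATION_NAMES.get(relation_name)
            if relation is None:
                raise DefinitionError(f"unknown relation {relation_name!r}")
            marker_id = None
            if catalog is not None:
                hit = catalog.cascade(marker_text)
                if hit is not None and len(hit.entries) == 1:
                    marker_id = hit.entries[0].id
            constraints.append(
                MarkerConstraint(relation=relation, marker_text=marker_text, marker_id=marker_id)
            )
        else:
            if parent is not None:
                raise DefinitionError(
                    f"two non-relation conjuncts: {parent!r} and {conjunct!r}"
                )
            parent = conjunct
    if parent is None:
        raise DefinitionError("logical definition has no named parent class")
    return parent, constraints


# ---------------------------------------------------------------------------
# Cell definitions
# ---------------------------------------------------------------------------


@dataclass
class CellDefinition:
    """A cell type: label, optional parent, and its own marker constraints."""

    cl_id: str
    label: str
    parent: "CellDefinition | None" = None
    own_constraints: list[MarkerConstraint] = field(default_factory=list)
    definition_source: str = ""

    def ancestors_root_first(self) -> list["CellDefinition"]:
        chain: list[CellDefinition] = []
        node = self
        while node is not None:
            chain.append(node)
            node = node.parent
        chain.reverse()
        return chain


class CellIndex:
    """Cell-type catalog indexed by id and case-insensitive label."""

    def __init__(self) -> None:
        self.by_id: dict[str, CellDefinition] = {}
        self._by_label: dict[str, CellDefinition] = {}

    def add(self, cell: CellDefinition) -> None:
        if cell.cl_id in self.by_id:
            raise CatalogError(f"duplicate cell id {cell.cl_id!r}")
        self.by_id[cell.cl_id] = cell
        self._by_label[canon(cell.label)] = cell

    def by_label(self, label: str) -> CellDefinition | None:
        return self._by_label.get(canon(label))

    def __iter__(self):
        return iter(self.by_id.values())


def _check_own_constraints(cell: CellDefinition) -> None:
    by_marker: dict[str, ConstraintRelation] = {}
    for constraint in cell.own_constraints:
        prior = by_marker.get(constraint.marker_key)
        if prior is not None and prior != constraint.relation:
            raise CatalogError(
                f"cell {cell.cl_id}: contradictory constraints on marker "
                f"{constraint.marker_text!r}"
            )
        by_marker[constraint.marker_key] = constraint.relation


def load_cell_catalog(
    path: str | os.PathLike, marker_index: MarkerIndex | None = None
) -> CellIndex:
    """Load cells.tsv; parse logical definitions; link and verify parents."""
    rows = _read_tsv(path, _CELL_COLUMNS)
    index = CellIndex()
    parent_ids: dict[str, str] = {}
    parent_labels: dict[str, str] = {}
    for row in rows:
        cl_id = row["cl_id"].strip()
        definition = row["definition"].strip()
        cell = CellDefinition(cl_id=cl_id, label=row["label"].strip(),
                              definition_source=definition)
        if definition:
            parent_label, constraints = parse_logical_definition(definition, marker_index)
            cell.own_constraints = constraints
            parent_labels[cl_id] = parent_label
        _check_own_constraints(cell)
        index.add(cell)
        parent_id = row["parent_id"].strip()
        if parent_id:
            parent_ids[cl_id] = parent_id
    for cell in index:
        parent_id = parent_ids.get(cell.cl_id)
        if parent_id is not None:
            parent = index.by_id.get(parent_id)
            if parent is None:
                raise ClosureError(f"cell {cell.cl_id}: unknown parent id {parent_id!r}")
            cell.parent = parent
        elif cell.cl_id in parent_labels:
            parent = index.by_label(parent_labels[cell.cl_id])
            if parent is not None:
                cell.parent = parent
    _check_acyclic(index)
    return index


def _check_acyclic(index: CellIndex) -> None:
    for cell in index:
        seen = set()
        node = cell
        while node is not None:
            if node.cl_id in seen:
                raise CatalogError(f"cycle in parent chain at {node.cl_id!r}")
            seen.add(node.cl_id)
            node = node.parent


def constraint_closure(cell: CellDefinition) -> list[MarkerConstraint]:
    """Union of the cell's own constraints with all ancestors' constraints.

    Walks root-first in document order; a descendant's constraint on a
    marker replaces an ancestor's constraint on the same marker, keeping
    the ancestor's position (so the order is deterministic).
    """
    ordered: dict[str, MarkerConstraint] = {}
    for node in cell.ancestors_root_first():
        for constraint in node.own_constraints:
            ordered[constraint.marker_key] = constraint
    return list(ordered.values())
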