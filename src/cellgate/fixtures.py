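"""Bundled catalog fixtures and the synthetic study-corpus generator.

The catalogs transcribe the curated synonym tables (alternative protein
labels, unmappable/complex markers, non-protein gates) and a small cell
type hierarchy with Manchester-style logical definitions. The corpus
generator emits seeded study tables with per-row ground truth (intended
cell, per-gate provenance, planted conflicts) so the whole pipeline can
be tested end-to-end without any external downloads.
"""

from __future__ import annotations

import csv
import io
import json
import os
import random
from dataclasses import dataclass, field
from pathlib import Path

from ._text import canon
from .ontology_catalog import (
    CellIndex,
    MarkerIndex,
    TIERS,
    constraint_closure,
    load_cell_catalog,
    load_marker_catalog,
)

# ---------------------------------------------------------------------------
# Transcribed tables
# ---------------------------------------------------------------------------

#: Alternative flow-cytometry labels to be curated as synonyms:
#: (preferred label, alternative label).
TABLE_SYNONYMS = (
    ("BDCA-2", "BDCA2"),
    ("KLRB1", "CD161"),
    ("MKI67", "KI67"),
    ("PDCD1", "PD1"),
    ("TNF-a", "TNFa"),
)

#: Intensity states: (state, preferred symbol, alternative labels).
TABLE_INTENSITIES = (
    ("negative", "−", ("neg",)),
    ("positive", "+", ("Pos",)),
    ("low", "+−", ("dim", "lo")),
    ("intermediate", "+~", ("int", "medium", "med")),
    ("high", "++", ("bright", "hi")),
)

#: Non-protein gates: (preferred label, basis, alternative spellings).
TABLE_SCATTER_GATES = (
    ("lymphocyte", "size_fsc_ssc",
     ("ly", "lymp", "lymph", "lymphocyte", "Lymph", "Lymphs", "Lymp", "Lymphocytes")),
    ("monocyte", "size_fsc_ssc", ("mo", "mono", "monos", "MNC", "Monocytes", "Mono")),
    ("granulocyte", "size_fsc_ssc", ("Gran",)),
    ("intact", "size_fsc_ssc", ("Intact_cells", "Intact_cells_population")),
    ("singlet", "relative_dimensions",
     ("sing", "singlets", "Singlet", "Singlets", "doublet_excluded", "sing-F",
      "intact_singlet")),
    ("viable", "dye", ("live", "Annexin-", "live/dead stain-?")),
    ("proliferated", "dye", ("CFSE-", "TracerViolet-")),
)

# (id, preferred_label, marker_class, short_labels, exact_synonyms, manual_synonyms)
# Accessions other than the four complex/phospho targets are fixture-local.
MARKER_ROWS = (
    ("PRX:BDCA2", "BDCA-2", "protein", (), ("CD303",), ("BDCA2",)),
    ("PRX:KLRB1", "KLRB1", "protein", ("KLRB1",), (), ("CD161",)),
    ("PRX:MKI67", "MKI67", "protein", ("MKI67",), ("Ki-67",), ("KI67",)),
    ("PRX:PDCD1", "PDCD1", "protein", ("PDCD1",), ("CD279",), ("PD1",)),
    ("PRX:TNFA", "TNF-a", "protein", (), (), ("TNFa",)),
    ("PR:000025402", "CD8 protein complex", "protein_complex", (), (), ("CD8",)),
    ("PR:000001020", "CD3e", "protein", ("CD3E",), (), ("CD3",)),
    ("PR:000036952", "HLA-DRB", "protein", (), (), ("HLA-DR",)),
    ("PR:000003075", "STAT1 phosphorylated form", "phospho_protein", (), (), ("pSTAT1",)),
    ("PRX:PSTAT3", "STAT3 phosphorylated form", "phospho_protein", (), (), ("pSTAT3",)),
    ("PRX:PSTAT5", "STAT5 phosphorylated form", "phospho_protein", (), (), ("pSTAT5",)),
    ("PRX:LIN", "lineage cocktail", "disallowed", (), (), ("LIN",)),
    ("PRX:CD4", "CD4", "protein", ("CD4",), ("CD4 molecule",), ()),
    ("PRX:CD14", "CD14", "protein", ("CD14",), (), ()),
    ("PRX:CD19", "CD19", "protein", ("CD19",), (), ()),
    ("PRX:MS4A1", "MS4A1", "protein", ("MS4A1",), ("CD20",), ()),
    ("PRX:CD27", "CD27", "protein", ("CD27",), (), ()),
    ("PRX:CD38", "CD38", "protein", ("CD38",), (), ()),
    ("PRX:CD45RA", "CD45RA", "protein",
     ("CD45RA",), ("receptor-type tyrosine-protein phosphatase C isoform CD45RA",), ()),
    ("PRX:CCR7", "CCR7", "protein",
     ("CCR7",), ("C-C chemokine receptor type 7", "CD197"), ()),
    ("PRX:IL2RA", "IL2RA", "protein",
     ("IL2RA",), ("interleukin-2 receptor subunit alpha", "CD25"), ()),
    ("PRX:BDCA3", "BDCA-3", "protein", (), ("CD141",), ("BDCA3",)),
)

EFFECTOR_MEMORY_DEFINITION = (
    "CD4-positive, alpha-beta memory T cell"
    " and lacks_plasma_membrane_part some"
    " receptor-type tyrosine-protein phosphatase C isoform CD45RA"
    " and lacks_plasma_membrane_part some C-C chemokine receptor type 7"
    " and lacks_plasma_membrane_part some interleukin-2 receptor subunit alpha"
)

# (cl_id, label, parent_id, definition)
CELL_ROWS = (
    ("CL:0000084", "T cell", "", ""),
    ("CL:0000789", "alpha-beta T cell", "CL:0000084", ""),
    ("CL:0000624", "CD4-positive, alpha-beta T cell", "CL:0000789",
     "alpha-beta T cell and has_plasma_membrane_part some CD4 molecule"),
    ("CL:0000897", "CD4-positive, alpha-beta memory T cell", "CL:0000624", ""),
    ("CL:0000905", "effector memory CD4-positive, alpha-beta T cell", "CL:0000897",
     EFFECTOR_MEMORY_DEFINITION),
    ("CL:0000236", "B cell", "", ""),
    ("CL:0000784", "plasmacytoid dendritic cell", "", ""),
)


# ---------------------------------------------------------------------------
# Catalog file builders
# ---------------------------------------------------------------------------


def markers_tsv() -> str:
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["id", "preferred_label", "tier", "synonym", "marker_class"])
    for entry_id, preferred, marker_class, short, exact, manual in MARKER_ROWS:
        tiers = (("short_label", short), ("exact_synonym", exact), ("manual", manual))
        wrote_any = False
        for tier, synonyms in tiers:
            for synonym in synonyms:
                writer.writerow([entry_id, preferred, tier, synonym, marker_class])
                wrote_any = True
        if not wrote_any:
            writer.writerow([entry_id, preferred, "", "", marker_class])
    return out.getvalue()


def scatter_gates_tsv() -> str:
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["preferred_label", "basis", "spelling"])
    for preferred, basis, spellings in TABLE_SCATTER_GATES:
        for spelling in spellings:
            writer.writerow([preferred, basis, spelling])
    return out.getvalue()


def cells_tsv() -> str:
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["cl_id", "label", "parent_id", "definition"])
    for row in CELL_ROWS:
        writer.writerow(row)
    return out.getvalue()


def build_fixture_catalog(out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write markers.tsv, cells.tsv and scatter_gates.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": out / "markers.tsv",
        "cells": out / "cells.tsv",
        "scatter_gates": out / "scatter_gates.tsv",
    }
    paths["markers"].write_text(markers_tsv(), encoding="utf-8")
    paths["cells"].write_text(cells_tsv(), encoding="utf-8")
    paths["scatter_gates"].write_text(scatter_gates_tsv(), encoding="utf-8")
    return paths


def load_fixture_indexes(out_dir: str | os.PathLike) -> tuple[MarkerIndex, CellIndex]:
    """Build the fixture catalogs in ``out_dir`` and load them."""
    paths = build_fixture_catalog(out_dir)
    marker_index = load_marker_catalog(paths["markers"], paths["scatter_gates"])
    cell_index = load_cell_catalog(paths["cells"], marker_index)
    return marker_index, cell_index


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    n_rows: int
    dialect_mix: dict[str, float] = field(
        default_factory=lambda: {"standard": 1.0}
    )
    planted_conflict_rate: float = 0.0
    unmatched_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 0:
            raise ValueError("n_rows must be nonnegative")
        for name, rate in (
            ("planted_conflict_rate", self.planted_conflict_rate),
            ("unmatched_rate", self.unmatched_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.dialect_mix:
            raise ValueError("dialect_mix must not be empty")
        if any(w < 0 for w in self.dialect_mix.values()):
            raise ValueError("dialect weights must be nonnegative")
        if not any(self.dialect_mix.values()):
            raise ValueError("dialect weights must not all be zero")


@dataclass
class RowTruth:
    row_id: str
    cl_id: str
    dialect: str
    provenances: list[str]
    planted_conflict: bool
    conflict_marker_id: str | None
    unmatched_count: int


@dataclass
class StudyRow:
    row_id: str
    population_name: str
    gating_definition: str
    dialect: str


_SEPARATOR_CHAR = {
    "standard": ",", "comma": ",", "slash": "/",
    "semicolon": ";", "colon": ":", "whitespace": " ",
}

_SATISFYING = {
    "requires_present": ("+", "pos", "positive"),
    "requires_absent": ("−", "-", "neg", "negative"),
    "requires_high": ("++", "bright", "hi"),
    "requires_low": ("+−", "dim", "lo"),
}

_VIOLATING = {
    "requires_present": ("−", "neg"),
    "requires_absent": ("+", "++", "+−", "pos"),
    "requires_high": ("−", "+−", "dim"),
    "requires_low": ("++", "bright"),
}


def _cascade_provenance(index: MarkerIndex, text: str) -> tuple[str, str] | None:
    """(provenance, entry id or scatter label) of the first cascade hit,
    recomputed from the tier maps for generator bookkeeping."""
    for tier, provenance in zip(
        TIERS, ("pro_short_label", "exact_synonym", "manual")
    ):
        entries = index.lookup(tier, text)
        if len(entries) == 1:
            return provenance, entries[0].id
        if entries:
            return None
    scatter = index.lookup_scatter(text)
    if scatter is not None:
        return "manual", scatter.preferred_label
    return None


def _emit_texts_for_entry(index: MarkerIndex, entry_id: str) -> list[str]:
    """Spellings that deterministically resolve to ``entry_id``."""
    entry = index.entries[entry_id]
    candidates = {entry.preferred_label} | entry.short_labels
    candidates |= entry.exact_synonyms | entry.manual_synonyms
    texts = []
    for text in sorted(candidates):
        hit = _cascade_provenance(index, text)
        if hit is not None and hit[1] == entry_id:
            texts.append(text)
    return texts


def _token_safe(text: str, separator: str) -> bool:
    if '"' in text:
        return False
    if separator == " ":
        return not any(ch.isspace() for ch in text)
    return separator not in text and not any(ch.isspace() for ch in text)


def generate_gating_corpus(
    spec: FixtureSpec, marker_index: MarkerIndex, cell_index: CellIndex
) -> tuple[list[StudyRow], list[RowTruth]]:
    """Seeded pseudo-random study rows with exact ground truth.

    Every row names a catalogued cell type; its gating definition satisfies
    the cell's constraint closure, except that with probability
    ``planted_conflict_rate`` one closure-derived gate's intensity is
    flipped to a violating value (recorded in the truth), and with
    probability ``unmatched_rate`` a nonsense marker token is injected.
    """
    rng = random.Random(spec.seed)
    cells = sorted(cell_index, key=lambda c: c.cl_id)
    closures = {c.cl_id: constraint_closure(c) for c in cells}
    resolvable = {
        cl_id: [c for c in closure if c.marker_id is not None]
        for cl_id, closure in closures.items()
    }
    conflictable = [c for c in cells if resolvable[c.cl_id]]
    closure_ids = {
        cl_id: {c.marker_id for c in constraints}
        for cl_id, constraints in resolvable.items()
    }
    emit_texts = {
        entry_id: _emit_texts_for_entry(marker_index, entry_id)
        for entry_id in sorted(marker_index.entries)
        if marker_index.entries[entry_id].marker_class.value != "disallowed"
    }
    scatter_spellings = sorted(
        spelling
        for entry in marker_index.scatter_entries.values()
        for spelling in entry.alternative_spellings | {entry.preferred_label}
    )
    dialect_names = sorted(spec.dialect_mix)
    weights = [spec.dialect_mix[name] for name in dialect_names]

    rows: list[StudyRow] = []
    truths: list[RowTruth] = []
    for i in range(spec.n_rows):
        row_id = str(i)
        dialect = rng.choices(dialect_names, weights=weights)[0]
        separator = _SEPARATOR_CHAR[dialect]
        plant = rng.random() < spec.planted_conflict_rate
        cell = rng.choice(conflictable if plant else cells)
        constraints = resolvable[cell.cl_id]

        tokens: list[str] = []
        provenances: list[str] = []

        def emit_marker(entry_id: str, suffix: str) -> bool:
            texts = [
                t for t in emit_texts.get(entry_id, []) if _token_safe(t, separator)
            ]
            if not texts:
                return False
            text = rng.choice(texts)
            provenance, _ = _cascade_provenance(marker_index, text)
            tokens.append(text + suffix)
            provenances.append(provenance)
            return True

        if rng.random() < 0.5:
            spelling = rng.choice(
                [s for s in scatter_spellings if _token_safe(s, separator)]
            )
            tokens.append(spelling)
            provenances.append("manual")

        conflict_marker: str | None = None
        conflict_constraint = rng.choice(constraints) if plant and constraints else None
        for constraint in constraints:
            relation = constraint.relation.value
            if constraint is conflict_constraint:
                suffix = rng.choice(_VIOLATING[relation])
                if emit_marker(constraint.marker_id, suffix):
                    conflict_marker = constraint.marker_id
            else:
                suffix = rng.choice(_SATISFYING[relation])
                emit_marker(constraint.marker_id, suffix)

        filler_pool = [
            entry_id
            for entry_id in sorted(emit_texts)
            if entry_id not in closure_ids[cell.cl_id]
        ]
        for entry_id in rng.sample(filler_pool, k=rng.randint(0, 2)):
            emit_marker(entry_id, rng.choice(("+", "−", "")))

        unmatched_count = 0
        if rng.random() < spec.unmatched_rate:
            while True:
                nonsense = f"ZZM{rng.randint(100, 9999)}"
                if marker_index.cascade(nonsense) is None:
                    break
            tokens.append(nonsense + rng.choice(("+", "−")))
            provenances.append("not_matched")
            unmatched_count = 1

        if not tokens:  # cells with empty closures can draw zero gates
            spelling = rng.choice(
                [s for s in scatter_spellings if _token_safe(s, separator)]
            )
            tokens.append(spelling)
            provenances.append("manual")

        population = cell.label
        if rng.random() < 0.2:
            population = f"'{cell.label}'"
        rows.append(
            StudyRow(
                row_id=row_id,
                population_name=population,
                gating_definition=separator.join(tokens),
                dialect=dialect,
            )
        )
        truths.append(
            RowTruth(
                row_id=row_id,
                cl_id=cell.cl_id,
                dialect=dialect,
                provenances=provenances,
                planted_conflict=conflict_marker is not None,
                conflict_marker_id=conflict_marker,
                unmatched_count=unmatched_count,
            )
        )
    return rows, truths


# ---------------------------------------------------------------------------
# Study-table I/O
# ---------------------------------------------------------------------------

STUDY_COLUMNS = ("row_id", "Population name", "Gating definition", "dialect")


def write_study(rows: list[StudyRow], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(STUDY_COLUMNS)
        for row in rows:
            writer.writerow(
                [row.row_id, row.population_name, row.gating_definition, row.dialect]
            )


def read_study(path: str | os.PathLike) -> list[StudyRow]:
    """Read a study table; accepts display or snake_case column headers."""
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty study file")

        def pick(row: dict, *names: str, default: str = "") -> str:
            for name in names:
                if name in row and row[name] is not None:
                    return row[name]
            return default

        rows = []
        for i, raw in enumerate(reader):
            rows.append(
                StudyRow(
                    row_id=pick(raw, "row_id", default=str(i)) or str(i),
                    population_name=pick(raw, "Population name", "population_name"),
                    gating_definition=pick(raw, "Gating definition", "gating_definition"),
                    dialect=pick(raw, "dialect"),
                )
            )
    return rows


def write_truth(truths: list[RowTruth], path: str | os.PathLike) -> None:
    payload = [
        {
            "row_id": t.row_id,
            "cl_id": t.cl_id,
            "dialect": t.dialect,
            "provenances": t.provenances,
            "planted_conflict": t.planted_conflict,
            "conflict_marker_id": t.conflict_marker_id,
            "unmatched_count": t.unmatched_count,
        }
        for t in truths
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(payload, handle, indent=2, ensure_ascii=False)
        handle.write("\n")


def read_truth(path: str | os.PathLike) -> list[RowTruth]:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    return [RowTruth(**item) for item in payload]
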