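# cellgate

Tools for standardizing how flow-cytometry cell populations are reported:
a parser/normalizer for gating-definition strings and population names,
and a validator that cross-checks gating definitions against Cell
Ontology-style logical marker axioms.

A study row has two text fields:

- **Population name** — a catalogued cell-type label, optionally followed by
  extra markers or subtype qualifiers after `&` symbols, e.g.
  `'plasmacytoid dendritic cell' & BDCA3+`.
- **Gating definition** — an ordered list of gates such as
  `singlet/CD14−/CD3+`, split under a per-center *dialect* (comma, slash,
  semicolon, colon, whitespace, or a custom regex; the standard dialect is
  comma-separated with double-quote escaping for marker names that contain
  a comma).

Each gate is normalized into a canonical marker (or scatter/dye gate) plus
an intensity level (`−`, `+`, `+−`, `+~`, `++`; textual variants such as
`neg`, `pos`, `dim`, `lo`, `int`, `med`, `bright`, `hi` are accepted).
Marker names resolve through a fixed case-insensitive cascade — PRO short
labels, exact synonyms, then a manually curated tier (including scatter/dye
gate spellings) — and the winning tier is recorded as the gate's
*provenance*. Hyphen-minus, Unicode minus and en dash are interchangeable;
`CD38 + −` is read as `CD38+−` (low).

The validator computes the named cell type's marker-constraint closure
(its own logical axioms plus inherited ancestor axioms, descendants
overriding ancestors per marker) and classifies every gate as
`consistent`, `conflict`, `not_covered` or `unresolvable`. For example,
population `CD4-positive, alpha-beta T cell` with gating `CD4− …` is
flagged: that cell type is axiomatized as CD4-positive.

## CLI

```sh
# Write the bundled catalogs (markers.tsv, cells.tsv, scatter_gates.tsv)
cellgate fixtures --out catalogs/

# Generate a seeded synthetic study corpus with ground truth
echo '{"n_rows": 200, "dialect_mix": {"standard": 1, "slash": 1},
      "planted_conflict_rate": 0.3, "unmatched_rate": 0.2, "seed": 7}' > spec.json
cellgate synth --spec spec.json --out study.tsv --truth truth.json \
    --catalog-dir catalogs/

# Normalize gating definitions
cellgate parse --dialect standard --markers catalogs/markers.tsv \
    --scatter catalogs/scatter_gates.tsv --in study.tsv --out parsed.tsv

# Cross-check populations against gating definitions
cellgate validate --markers catalogs/markers.tsv --cells catalogs/cells.tsv \
    --scatter catalogs/scatter_gates.tsv --in study.tsv \
    --out report.tsv --json report.json   # add --no-inherit to skip ancestor axioms

# Corpus statistics (occurrences and distinct gate names per provenance)
cellgate summarize --in report.json --out summary.tsv   # or .json / .txt
```

Study tables are TSV with columns `Population name` and `Gating definition`
(snake_case also accepted); an optional `dialect` column overrides the
`--dialect` flag per row.

## Package layout

- `cellgate.ontology_catalog` — marker/cell catalogs, logical-definition
  parsing, constraint closure
- `cellgate.gate_parser` — dialects, tokenization, intensity grammar,
  marker resolution cascade, serialization
- `cellgate.population_parser` — `CL label & extras` population grammar
- `cellgate.validator` — per-gate conflict detection and row verdicts
- `cellgate.reporter` — corpus summaries; TSV/JSON/text reports
  (JSON validated by the pydantic schema in `cellgate.schema`)
- `cellgate.fixtures` — bundled catalog data and the seeded corpus generator
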