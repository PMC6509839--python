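"""Gating-definition parsing and normalization.

A gating definition is split into gate tokens under a dialect (which
separator, which quote character), and each token is normalized into a
canonical marker or scatter/dye gate plus an intensity level, recording
which synonym tier matched (the gate's provenance).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from ._text import MINUS, normalize_minus
from .errors import (
    AmbiguousMarkerError,
    DisallowedMarkerError,
    IntensityError,
    MarkerResolutionError,
    TokenizeError,
)
from .ontology_catalog import (
    CascadeHit,
    IntensityLevel,
    MarkerClass,
    MarkerIndex,
    ScatterBasis,
)

# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

_BUILTIN_SEPARATORS = {
    "standard": ",",
    "comma": ",",
    "slash": "/",
    "semicolon": ";",
    "colon": ":",
    "whitespace": r"\s+",
}


@dataclass(frozen=True)
class Dialect:
    """How one center separates gates inside a gating-definition string."""

    name: str
    separator_pattern: str
    quote_char: str = '"'

    @classmethod
    def named(cls, name: str) -> "Dialect":
        try:
            return cls(name=name, separator_pattern=_BUILTIN_SEPARATORS[name])
        except KeyError:
            raise ValueError(f"unknown dialect {name!r}") from None

    @classmethod
    def custom(cls, pattern: str, name: str = "custom") -> "Dialect":
        re.compile(pattern)  # fail fast on a bad pattern
        return cls(name=name, separator_pattern=pattern)

    @classmethod
    def from_spec(cls, spec: str) -> "Dialect":
        """Accept a builtin name or fall back to a custom regex pattern."""
        if spec in _BUILTIN_SEPARATORS:
            return cls.named(spec)
        return cls.custom(spec, name=spec)


STANDARD = Dialect.named("standard")

#: Builtin dialect names, for CLIs and corpus generation.
BUILTIN_DIALECTS = tuple(_BUILTIN_SEPARATORS)


@dataclass(frozen=True)
class GateToken:
    raw: str
    position: int


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# A segment consisting purely of intensity-symbol characters is glued back
# onto the previous token ("CD38 + −" under the whitespace dialect).
_PURE_SYMBOL_RE = re.compile(r"^[+\-−–~\s]+$")


def _mask_quotes(text: str, quote_char: str) -> tuple[str, list[str]]:
    stored: list[str] = []
    out: list[str] = []
    i = 0
    while i < len(text):
        char = text[i]
        if char == quote_char:
            end = text.find(quote_char, i + 1)
            if end == -1:
                raise TokenizeError(f"unbalanced quote at offset {i}", offset=i)
            stored.append(text[i + 1 : end])
            out.append(f"\x00{len(stored) - 1}\x01")
            i = end + 1
        else:
            out.append(char)
            i += 1
    return "".join(out), stored


def tokenize(definition: str, dialect: Dialect = STANDARD) -> list[GateToken]:
    """Split a gating definition into gate tokens.

    Quoted spans are never split and their quotes are stripped; empty
    segments are dropped; a segment made only of intensity symbols is
    merged into the preceding token.
    """
    if not definition or not definition.strip():
        raise TokenizeError("empty gating definition")
    masked, stored = _mask_quotes(definition, dialect.quote_char)

    def unmask(segment: str) -> str:
        return re.sub(r"\x00(\d+)\x01", lambda m: stored[int(m.group(1))], segment)

    raws: list[str] = []
    for segment in re.split(dialect.separator_pattern, masked):
        text = unmask(segment).strip()
        if not text:
            continue
        if raws and _PURE_SYMBOL_RE.match(text) and "\x00" not in segment:
            raws[-1] = raws[-1] + text
        else:
            raws.append(text)
    return [GateToken(raw=raw, position=i) for i, raw in enumerate(raws)]


# ---------------------------------------------------------------------------
# Intensity grammar
# ---------------------------------------------------------------------------

# Symbolic suffixes, longest first; whitespace between marker and symbols
# (and between the symbols themselves) is tolerated and collapsed.
_SYMBOL_SUFFIX_RE = re.compile(r"\s*(\+\s*\+|\+\s*~|\+\s*−|\+|−)\s*$")

# Textual suffixes, longest first, attached with whitespace or nothing.
_TEXT_SUFFIXES = (
    "positive", "negative", "bright", "medium",
    "dim", "med", "neg", "pos", "int", "hi", "lo",
)
_TEXT_SUFFIX_RE = re.compile(
    r"(?:\s+|(?<=\S))(" + "|".join(_TEXT_SUFFIXES) + r")$", re.IGNORECASE
)

_INTENSITY_TABLE = {
    "−": IntensityLevel.NEGATIVE,
    "+": IntensityLevel.POSITIVE,
    "+−": IntensityLevel.LOW,
    "+~": IntensityLevel.INTERMEDIATE,
    "++": IntensityLevel.HIGH,
    "neg": IntensityLevel.NEGATIVE,
    "negative": IntensityLevel.NEGATIVE,
    "pos": IntensityLevel.POSITIVE,
    "positive": IntensityLevel.POSITIVE,
    "dim": IntensityLevel.LOW,
    "lo": IntensityLevel.LOW,
    "int": IntensityLevel.INTERMEDIATE,
    "medium": IntensityLevel.INTERMEDIATE,
    "med": IntensityLevel.INTERMEDIATE,
    "bright": IntensityLevel.HIGH,
    "hi": IntensityLevel.HIGH,
}


def split_intensity(token: GateToken | str) -> tuple[str, str]:
    """Strip the longest matching intensity suffix off a gate token.

    Returns ``(marker_text, intensity_text)``; ``intensity_text`` is empty
    when no suffix matches. Hyphen-minus, Unicode minus and en dash are
    equivalent negative symbols.
    """
    text = token.raw if isinstance(token, GateToken) else token
    text = text.strip()
    normalized = normalize_minus(text)
    match = _SYMBOL_SUFFIX_RE.search(normalized)
    if match and match.start() > 0:
        marker = text[: match.start()].strip()
        suffix = re.sub(r"\s+", "", match.group(1))
        return marker, suffix
    match = _TEXT_SUFFIX_RE.search(text)
    if match and text[: match.start()].strip():
        return text[: match.start()].strip(), match.group(1)
    return text, ""


def normalize_intensity(intensity_text: str) -> IntensityLevel:
    """Map an intensity label (symbolic or textual, any case) to its level."""
    if not intensity_text:
        raise IntensityError("empty intensity text")
    key = re.sub(r"\s+", "", normalize_minus(intensity_text)).casefold()
    try:
        return _INTENSITY_TABLE[key]
    except KeyError:
        raise IntensityError(f"unknown intensity label {intensity_text!r}") from None


# ---------------------------------------------------------------------------
# Marker resolution
# ---------------------------------------------------------------------------


class GateKind(str, enum.Enum):
    PROTEIN_MARKER = "protein_marker"
    SCATTER = "scatter"
    DYE = "dye"
    UNMATCHED = "unmatched"


class Provenance(str, enum.Enum):
    PRO_SHORT_LABEL = "pro_short_label"
    EXACT_SYNONYM = "exact_synonym"
    MANUAL = "manual"
    NOT_MATCHED = "not_matched"


_TIER_PROVENANCE = {
    "short_label": Provenance.PRO_SHORT_LABEL,
    "exact_synonym": Provenance.EXACT_SYNONYM,
    "manual": Provenance.MANUAL,
}


@dataclass(frozen=True)
class MarkerResolution:
    kind: GateKind
    marker_id: str | None
    canonical_label: str
    provenance: Provenance


def resolve_marker(marker_text: str, catalog: MarkerIndex) -> MarkerResolution:
    """Resolve a marker name through the tier cascade.

    Order is fixed: PRO short labels, exact synonyms, then the manual tier
    (curated synonyms, then scatter/dye spellings); the first hit wins and
    sets the provenance. No hit yields an unmatched resolution.
    """
    hit = catalog.cascade(marker_text)
    if hit is None:
        return MarkerResolution(
            kind=GateKind.UNMATCHED,
            marker_id=None,
            canonical_label=marker_text,
            provenance=Provenance.NOT_MATCHED,
        )
    if hit.scatter is not None:
        kind = GateKind.DYE if hit.scatter.basis is ScatterBasis.DYE else GateKind.SCATTER
        return MarkerResolution(
            kind=kind,
            marker_id=None,
            canonical_label=hit.scatter.preferred_label,
            provenance=Provenance.MANUAL,
        )
    if len(hit.entries) > 1:
        raise AmbiguousMarkerError(marker_text, [e.id for e in hit.entries])
    entry = hit.entries[0]
    if entry.marker_class is MarkerClass.DISALLOWED:
        raise DisallowedMarkerError(marker_text, entry.message)
    return MarkerResolution(
        kind=GateKind.PROTEIN_MARKER,
        marker_id=entry.id,
        canonical_label=entry.preferred_label,
        provenance=_TIER_PROVENANCE[hit.tier],
    )


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gate:
    """One normalized gate with its match provenance and original text."""

    kind: GateKind
    canonical_label: str
    raw: str
    marker_id: str | None = None
    intensity: IntensityLevel | None = None
    provenance: Provenance = Provenance.NOT_MATCHED
    message: str = ""

    @property
    def canonical_key(self) -> tuple:
        """Identity of the normalized gate, independent of raw spelling and
        of which synonym tier happened to match."""
        return (self.kind, self.marker_id, self.canonical_label, self.intensity)

    @property
    def marker_key(self) -> str | None:
        """Identity used to match this gate against closure constraints."""
        if self.kind is not GateKind.PROTEIN_MARKER:
            return None
        return self.marker_id


def _gate_from_token(token: GateToken, catalog: MarkerIndex) -> Gate:
    # Whole-token match first, so scatter/dye spellings that themselves end
    # in '-' or '?' ("Annexin-", "live/dead stain-?") survive intact.
    try:
        resolution = resolve_marker(token.raw, catalog)
    except MarkerResolutionError:
        resolution = None
    if resolution is not None and resolution.kind is not GateKind.UNMATCHED:
        return Gate(
            kind=resolution.kind,
            canonical_label=resolution.canonical_label,
            raw=token.raw,
            marker_id=resolution.marker_id,
            intensity=None,
            provenance=resolution.provenance,
        )
    marker_text, intensity_text = split_intensity(token)
    intensity = normalize_intensity(intensity_text) if intensity_text else None
    try:
        resolution = resolve_marker(marker_text, catalog)
    except MarkerResolutionError as exc:
        return Gate(
            kind=GateKind.UNMATCHED,
            canonical_label=marker_text,
            raw=token.raw,
            intensity=intensity,
            provenance=Provenance.NOT_MATCHED,
            message=str(exc),
        )
    return Gate(
        kind=resolution.kind,
        canonical_label=resolution.canonical_label,
        raw=token.raw,
        marker_id=resolution.marker_id,
        intensity=intensity if resolution.kind is GateKind.PROTEIN_MARKER
        or resolution.kind is GateKind.UNMATCHED else None,
        provenance=resolution.provenance,
    )


def parse_gating_definition(
    definition: str, dialect: Dialect, catalog: MarkerIndex
) -> list[Gate]:
    """tokenize → split_intensity → normalize_intensity → resolve_marker.

    Unmatched tokens become unmatched gates rather than failures; only
    structural problems (unbalanced quote, empty input) abort.
    """
    return [_gate_from_token(token, catalog) for token in tokenize(definition, dialect)]


def serialize_gating_definition(gates: list[Gate]) -> str:
    """Emit canonical labels plus preferred intensity symbols, comma-joined.

    Labels containing a comma are wrapped in double quotes so the result
    re-parses identically under the standard dialect.
    """
    parts = []
    for gate in gates:
        label = gate.canonical_label
        if "," in label or '"' in label:
            label = '"' + label.replace('"', "") + '"'
        suffix = gate.intensity.symbol if gate.intensity is not None else ""
        parts.append(label + suffix)
    return ",".join(parts)
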