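"""Exception hierarchy."""

from __future__ import annotations


class CellgateError(Exception):
    """Base class for all package errors."""


class CatalogError(CellgateError):
    """Raised when a catalog file cannot be loaded or violates an invariant."""


class TokenizeError(CellgateError):
    """Structural failure while splitting a gating definition.

    Carries the character offset of the problem when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class IntensityError(CellgateError):
    """Unknown marker-intensity label."""


class MarkerResolutionError(CellgateError):
    """Base for per-gate marker resolution failures."""


class AmbiguousMarkerError(MarkerResolutionError):
    """A synonym maps to more than one catalog entry within the winning tier."""

    def __init__(self, text: str, candidate_ids: list[str]):
        super().__init__(
            f"marker {text!r} is ambiguous between entries: {', '.join(sorted(candidate_ids))}"
        )
        self.text = text
        self.candidate_ids = list(candidate_ids)


class DisallowedMarkerError(MarkerResolutionError):
    """The marker is catalogued as disallowed (e.g. a lineage cocktail)."""

    def __init__(self, text: str, message: str):
        super().__init__(f"marker {text!r} is disallowed: {message}")
        self.text = text


class DefinitionError(CellgateError):
    """A cell-type logical definition string cannot be parsed."""


class ClosureError(CellgateError):
    """Constraint-closure computation failed (e.g. unknown parent id)."""
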