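"""Text normalization helpers shared across the package.

All label/synonym comparison happens on NFC-normalized, case-folded keys
with the minus-like characters collapsed, so that typographic variants of
the same name (hyphen-minus, Unicode minus, en dash) compare equal.
"""

from __future__ import annotations

import unicodedata

#: Characters treated as interchangeable with the negative-intensity symbol.
MINUS_CHARS = "-−–"

#: Canonical minus used in preferred intensity symbols.
MINUS = "−"

_MINUS_TO_CANONICAL = str.maketrans({c: MINUS for c in MINUS_CHARS})
_MINUS_TO_ASCII = str.maketrans({c: "-" for c in MINUS_CHARS})


def normalize_minus(text: str) -> str:
    """Collapse hyphen-minus / Unicode minus / en dash to U+2212."""
    return text.translate(_MINUS_TO_CANONICAL)


def canon(text: str) -> str:
    """Comparison key: NFC, case-folded, minus-like chars as ASCII hyphen."""
    return unicodedata.normalize("NFC", text).casefold().translate(_MINUS_TO_ASCII)
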