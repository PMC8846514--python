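"""Small shared helpers: text folding, null-token vocabulary, rounding."""

from __future__ import annotations

import unicodedata
from decimal import ROUND_HALF_UP, Decimal

#: INSDC-style null tokens treated as "no value" wherever free-text metadata
#: is interpreted (geography, host). Comparison is case-insensitive on the
#: folded string. Configurable at call sites that accept ``null_tokens``.
NULL_TOKENS: frozenset[str] = frozenset(
    {"", "missing", "not collected", "not applicable", "restricted access", "unknown"}
)


def fold(text: str) -> str:
    """Case-fold, strip diacritics and collapse internal whitespace.

    Used for every dictionary-style lookup on free-text metadata so that
    "Côte d'Ivoire", "COTE D'IVOIRE " and "cote d'ivoire" all hit the same
    gazetteer entry.
    """
    text = unicodedata.normalize("NFKD", text)
    text = "".join(c for c in text if not unicodedata.combining(c))
    return " ".join(text.casefold().split())


def is_null_token(value: str | None, null_tokens: frozenset[str] = NULL_TOKENS) -> bool:
    if value is None:
        return True
    return fold(value) in null_tokens


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (presentation rounding for printed tables).

    Python's built-in ``round`` is banker's rounding; published tables use the
    conventional 0.5-rounds-up-in-magnitude rule, so all printed-style output
    goes through this helper. Internal arithmetic stays in full precision.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
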