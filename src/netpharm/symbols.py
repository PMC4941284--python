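"""Gene-symbol normalization shared by every reader and generator.

Symbol styles in the wild are inconsistent (``PPAR-γ`` vs ``PPARG``,
lower-case aliases, stray whitespace).  Every module funnels identifiers
through :func:`normalize_symbol` so that lookups are case- and
punctuation-insensitive.
"""

from __future__ import annotations

from collections.abc import Iterable

# Greek letters frequently embedded in protein names map onto the latin
# letter used by the official symbol (PPAR-γ -> PPARG, NF-κB -> NFKB...).
_GREEK = str.maketrans(
    {
        "α": "A", "Α": "A",
        "β": "B", "Β": "B",
        "γ": "G", "Γ": "G",
        "δ": "D", "Δ": "D",
        "ε": "E", "Ε": "E",
        "κ": "K", "Κ": "K",
    }
)


def normalize_symbol(symbol: str) -> str:
    """Return the canonical form of a gene/protein symbol.

    Upper-cases, strips surrounding whitespace, removes internal hyphens
    and spaces, and transliterates common Greek letters, so that e.g.
    ``"PPAR-γ"`` and ``"pparg"`` normalize to the same key ``"PPARG"``.
    """
    if not isinstance(symbol, str):
        raise TypeError(f"gene symbol must be a string, got {type(symbol).__name__}")
    s = symbol.strip().translate(_GREEK).upper()
    return s.replace("-", "").replace(" ", "")


def normalize_symbols(symbols: Iterable[str]) -> list[str]:
    """Normalize an iterable of symbols, preserving order."""
    return [normalize_symbol(s) for s in symbols]
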