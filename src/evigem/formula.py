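"""Elemental formulas in Hill notation with integer counts.

Formulas drive the mass-balance check: each metabolite carries an element
count map, and a reaction is balanced when substrate and product element
sums agree. Wildcard elements (R-groups such as ``R`` or ``X``, and the
generic ``*``) are legal — biomass and polymer species rarely have full
formulas — but any participant carrying one makes the balance verdict
"undetermined" rather than balanced/unbalanced.
"""

from __future__ import annotations

import re
from typing import Dict, Tuple

__all__ = ["parse_formula", "format_formula", "has_wildcard", "FormulaError", "WILDCARDS"]

# one- or two-letter element symbol, optionally followed by a count
_TOKEN = re.compile(r"([A-Z][a-z]?|\*)(\d*)")

#: element symbols treated as unspecified R-groups / repeat units
WILDCARDS = frozenset({"R", "X", "*"})


class FormulaError(ValueError):
    """Raised for a string that is not a Hill-notation formula."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse ``"C6H12O6"`` into ``{"C": 6, "H": 12, "O": 6}``.

    Counts default to 1; repeated symbols accumulate. Raises
    :class:`FormulaError` on anything that is not element tokens.
    """
    counts: Dict[str, int] = {}
    pos = 0
    text = formula.strip()
    if not text:
        raise FormulaError("empty formula")
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def has_wildcard(counts: Dict[str, int]) -> bool:
    return any(e in WILDCARDS for e in counts)


def format_formula(counts: Dict[str, int]) -> str:
    """Serialize counts in Hill order (C, H, then alphabetical)."""

    def key(item: Tuple[str, int]) -> Tuple[int, str]:
        e = item[0]
        if "C" in counts:
            if e == "C":
                return (0, e)
            if e == "H":
                return (1, e)
        return (2, e)

    parts = []
    for e, n in sorted(counts.items(), key=key):
        if n == 0:
            continue
        parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)
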