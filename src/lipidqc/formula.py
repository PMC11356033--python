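"""Molecular formula parsing and element feature construction.

Formulas arriving in lipidomics annotation exports are plain Hill-style
strings ("C51H98O6", "C36H61D7O5"). This module turns them into element
count maps — the numeric feature block of the retention-time model — and
defines the deterministic element ordering used to build fixed-width
feature matrices.

Deuterium ("D", common in internal-standard mixes such as EquiSPLASH) is
kept as a distinct element by default so that labelled and unlabelled
species occupy different points in feature space; pass
``merge_deuterium=True`` to fold D into H.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping

__all__ = [
    "FormulaError",
    "AtomComposition",
    "parse_formula",
    "to_hill",
    "hill_sorted",
    "element_universe",
    "composition_vector",
]

# One element token: capital letter, optional lowercase, optional count.
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular formula cannot be parsed."""


#: Element symbol -> positive count. Absent elements are implicitly zero.
AtomComposition = dict[str, int]


def parse_formula(formula: str, merge_deuterium: bool = False) -> AtomComposition:
    """Parse a plain molecular formula into an element -> count map.

    Parameters
    ----------
    formula
        Hill-style formula without brackets, charges or adduct notation,
        e.g. ``"C36H64NO8P"``. A symbol with no trailing digits has an
        implicit count of 1. Repeated symbols are summed.
    merge_deuterium
        If True, any ``D`` count is added to ``H`` instead of being kept
        as its own element.

    Raises
    ------
    FormulaError
        On an empty string, an unrecognisable token (position reported),
        or an explicit zero count.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    counts: AtomComposition = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"unparseable token at position {pos} in {formula!r}: {s[pos:pos + 5]!r}"
            )
        sym, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(
                f"non-positive count for element {sym!r} at position {pos} in {formula!r}"
            )
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if merge_deuterium and "D" in counts:
        counts["H"] = counts.get("H", 0) + counts.pop("D")
    return counts


def hill_sorted(elements: Iterable[str]) -> list[str]:
    """Order element symbols by the Hill convention.

    Carbon first and hydrogen second when carbon is present, the rest
    alphabetical; fully alphabetical for carbon-free sets.
    """
    elems = set(elements)
    if "C" in elems:
        head = [e for e in ("C", "H") if e in elems]
        return head + sorted(elems - {"C", "H"})
    return sorted(elems)


def to_hill(composition: Mapping[str, int]) -> str:
    """Serialize a composition to Hill notation (count 1 left implicit)."""
    parts = []
    for el in hill_sorted(composition):
        n = composition[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def element_universe(compositions: Iterable[Mapping[str, int]]) -> list[str]:
    """Union of elements over a collection of compositions, Hill-ordered.

    The universe fixes the numeric feature columns of the design matrix:
    every composition is embedded as a fixed-width vector with zeros for
    elements it lacks.
    """
    comps = list(compositions)
    if not comps:
        raise ValueError("element_universe of an empty collection")
    seen: set[str] = set()
    for c in comps:
        seen.update(c)
    return hill_sorted(seen)


def composition_vector(
    composition: Mapping[str, int], universe: list[str]
) -> list[int]:
    """Embed one composition as counts over a fixed element universe."""
    return [composition.get(el, 0) for el in universe]
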