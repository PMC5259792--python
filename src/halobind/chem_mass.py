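"""Molecular-formula parsing and isotope-resolved mass / adduct m/z.

Supports the compound-characterization arithmetic used throughout the
project: parse a Hill-notation formula, sum exact isotope masses (with the
chlorine isotope selectable to resolve the M/M+2 pair of a monochloro
compound), and shift by the proton mass for ESI adducts.
"""

from __future__ import annotations

import re
from collections.abc import Mapping

#: Exact isotope masses in Da, keyed element -> {mass number: mass}.
#: First-listed mass number per element is the most abundant isotope.
#: CODATA/AME2020-derived values, truncated to 6 decimals.
ISOTOPE_MASSES: dict[str, dict[int, float]] = {
    "H": {1: 1.007825, 2: 2.014102},
    "C": {12: 12.0, 13: 13.003355},
    "N": {14: 14.003074, 15: 15.000109},
    "O": {16: 15.994915, 17: 16.999132, 18: 17.999160},
    "F": {19: 18.998403},
    "Na": {23: 22.989769},
    "P": {31: 30.973762},
    "S": {32: 31.972071, 33: 32.971459, 34: 33.967867},
    "Cl": {35: 34.968853, 37: 36.965903},
    "K": {39: 38.963706},
    "Br": {79: 78.918338, 81: 80.916290},
    "I": {127: 126.904473},
}

#: Proton mass in Da (H atom minus electron), the ESI charge carrier.
PROTON_MASS = 1.007276

ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M]+": 0.0,
}
# Unicode minus accepted for the deprotonated label.
ADDUCTS["[M−H]-"] = ADDUCTS["[M-H]-"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    pass


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula ('C21H21ClN4O2S') into element counts.

    Counts of repeated element tokens are summed; an omitted count means 1.
    Raises :class:`FormulaError` on unknown element symbols or bad counts.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparseable token at {text[pos:]!r}")
        pos = m.end()
        element, digits = m.groups()
        if element not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element symbol {element!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count for {element} must be positive, got {n}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text):
        raise FormulaError(f"unparseable token at {text[pos:]!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Canonical Hill order: C, then H, then other elements alphabetically."""
    def key(el: str):
        return {"C": (0,), "H": (1,)}.get(el, (2, el))

    parts = []
    for el in sorted(counts, key=key):
        n = counts[el]
        if n < 1:
            raise FormulaError(f"count for {el} must be >= 1, got {n}")
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def isotope_mass(element: str, mass_number: int | None = None) -> float:
    """Exact mass of one isotope; default is the most abundant isotope."""
    try:
        table = ISOTOPE_MASSES[element]
    except KeyError:
        raise FormulaError(f"element {element!r} not in isotope table") from None
    if mass_number is None:
        return next(iter(table.values()))
    try:
        return table[mass_number]
    except KeyError:
        raise FormulaError(
            f"no tabulated isotope {mass_number} for {element} "
            f"(have {sorted(table)})"
        ) from None


def monoisotopic_mass(
    counts: Mapping[str, int], isotopes: Mapping[str, int] | None = None
) -> float:
    """Sum of exact isotope masses; ``isotopes`` overrides per element.

    E.g. ``monoisotopic_mass(parse_formula("C21H21ClN4O2S"), {"Cl": 37})``
    gives the 37Cl isotopologue mass.
    """
    isotopes = isotopes or {}
    return sum(
        n * isotope_mass(el, isotopes.get(el)) for el, n in counts.items()
    )


def adduct_mz(neutral_mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of a singly charged adduct ion of the given neutral mass."""
    try:
        shift = ADDUCTS[adduct]
    except KeyError:
        raise FormulaError(
            f"unknown adduct {adduct!r}; supported: "
            + ", ".join(sorted(set(ADDUCTS) - {'[M−H]-'}))
        ) from None
    if neutral_mass <= 0 and shift != 0:
        raise FormulaError("neutral mass must be positive for ionized adducts")
    return neutral_mass + shift


def formula_mz(
    formula: str,
    isotopes: Mapping[str, int] | None = None,
    adduct: str = "[M+H]+",
) -> float:
    """Convenience: parse, sum isotope masses, apply the adduct shift."""
    return adduct_mz(monoisotopic_mass(parse_formula(formula), isotopes), adduct)
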