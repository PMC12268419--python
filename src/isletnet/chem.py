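"""Monoisotopic mass arithmetic for small molecules.

Masses are computed from elemental formulas using the monoisotopic masses of
the most abundant isotopes, which is what high-resolution LC-MS instruments
measure for the dominant isotopologue peak.
"""

from __future__ import annotations

import re

# Monoisotopic atomic masses (Da), most abundant isotope, 6+ decimals.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Se": 79.9165213,
    "I": 126.904473,
}

PROTON_MASS = 1.007276  # mass of H+ (H atom minus electron)

# Singly charged positive-mode adduct mass shifts (Da).
ADDUCT_SHIFTS = {
    "M+H": 1.007276,
    "M+Na": 22.989218,
    "M+K": 38.963158,
    "M+NH4": 18.033823,
}

PRIMARY_ADDUCT = "M+H"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of an elemental formula such as ``C6H12O6``."""
    pos = 0
    mass = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        mass += MONOISOTOPIC[element] * (int(count) if count else 1)
    if pos != len(formula) or mass == 0.0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass
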