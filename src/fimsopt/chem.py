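"""Elemental mass arithmetic for singly charged small-molecule ions.

Monoisotopic masses, Hill-notation formula parsing, adduct m/z computation
and ppm tolerance math.  All constants are CODATA/NIST monoisotopic values
embedded here; no external lookup is performed.

The ion m/z convention adds or subtracts the mass of a *proton*
(1.007276 Da), i.e. the electron mass is accounted for, which is the
physically correct convention for Orbitrap accurate-mass work.  Only singly
charged adducts are supported, so m/z equals the ion mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_SPACING",
    "Adduct",
    "ADDUCTS",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "formula_mass",
    "adduct_mz",
    "neutral_mass",
    "ppm_diff",
    "within_ppm",
]

#: Monoisotopic masses (Da) of the most abundant isotope, NIST values.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

#: Mass of a proton (Da).
PROTON_MASS = 1.007276466879

#: Mass of an electron (Da).
ELECTRON_MASS = 0.000548579909

#: 13C - 12C mass spacing (Da); the dominant isotopologue offset in
#: carbon-containing metabolites.
C13_C12_SPACING = 1.0033548378

_WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


@dataclass(frozen=True)
class Adduct:
    """A singly charged ionization adduct.

    ``mass_delta`` is the signed mass difference between the ion and the
    neutral molecule, so ``mz = neutral_mass + mass_delta``.
    """

    name: str
    mass_delta: float
    charge_sign: int

    def __post_init__(self) -> None:
        if self.charge_sign not in (+1, -1):
            raise ValueError(f"charge sign must be +1 or -1, got {self.charge_sign}")


#: The four adducts used for annotation and ion clustering.  The sodium
#: adduct uses the theoretical Na - e⁻ mass; note the commonly quoted
#: rounded spacing of ~21.98 vs [M+H]+.
ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +PROTON_MASS, +1),
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1),
    "[M+Na]+": Adduct("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "[M-H2O-H]-": Adduct("[M-H2O-H]-", -_WATER_MASS - PROTON_MASS, -1),
}

# Accept the unicode minus sign used in much of the literature.
for _name, _adduct in list(ADDUCTS.items()):
    ADDUCTS[_name.replace("-", "−")] = _adduct

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    Parameters
    ----------
    formula
        e.g. ``"C6H13O9P"``; element symbols with optional positive
        integer counts (implicit count 1).

    Returns
    -------
    dict
        Element symbol -> count.

    Raises
    ------
    FormulaError
        On empty/malformed strings or element symbols not in
        :data:`MONOISOTOPIC_MASS`; the message names the offending token.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    s = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {formula!r} at {s[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {element!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an element-count map.

    The empty map has mass 0.  Unknown elements raise :class:`FormulaError`.
    """
    total = 0.0
    for element, n in counts.items():
        try:
            total += MONOISOTOPIC_MASS[element] * n
        except KeyError:
            raise FormulaError(f"unsupported element {element!r}") from None
    return total


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) computed directly from a formula string."""
    return monoisotopic_mass(parse_formula(formula))


def _resolve_adduct(adduct: "Adduct | str") -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise KeyError(f"unknown adduct {adduct!r}; known: {sorted(set(a.name for a in ADDUCTS.values()))}") from None


def adduct_mz(neutral: float, adduct: "Adduct | str") -> float:
    """m/z of the singly charged ion formed from a neutral of mass ``neutral``."""
    if neutral < 0:
        raise ValueError("neutral mass must be non-negative")
    return neutral + _resolve_adduct(adduct).mass_delta


def neutral_mass(mz: float, adduct: "Adduct | str") -> float:
    """Invert :func:`adduct_mz`: the neutral mass implied by an observed m/z."""
    return mz - _resolve_adduct(adduct).mass_delta


def ppm_diff(a: float, b: float) -> float:
    """Relative difference of ``a`` vs reference ``b`` in parts per million."""
    if b <= 0:
        raise ValueError("reference m/z must be positive")
    return 1e6 * abs(a - b) / b


def within_ppm(a: float, b: float, tolerance: float) -> bool:
    """True when ``a`` lies within ``tolerance`` ppm of reference ``b``."""
    return ppm_diff(a, b) <= tolerance
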