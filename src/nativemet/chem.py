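"""Molecular-formula arithmetic and mass bookkeeping.

Every other stage of the workflow converts between neutral masses and m/z
values of multiply protonated ions, so the charge-carrier convention lives
here and nowhere else: in positive mode an ion of charge ``z`` carries ``z``
protons, and

    m/z = (M_neutral + z * PROTON_MASS) / z

with the proton mass (not the hydrogen-atom mass), so the electron deficit
of the cation is accounted for exactly.  Printed ion formulas such as
``C61H88N9O15`` for an [M+H]+ species are interpreted as the composition of
the protonated cation; its theoretical m/z is the monoisotopic mass of those
atoms minus one electron mass (equivalently: neutral-M formula with one H
fewer, plus one proton).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "AVERAGINE",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_error",
    "protonated_ion_mz",
    "neutral_mass_from_mh",
]

#: Monoisotopic atomic masses in Da (IUPAC/CODATA, most abundant isotope).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Br": 78.9183371,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "F": 18.99840322,
    "I": 126.904473,
    "Se": 79.9165213,
}

#: Charge-carrier mass in positive mode (Da).
PROTON_MASS: float = 1.00727646677

#: Electron rest mass (Da); PROTON_MASS + ELECTRON_MASS == mass of H atom.
ELECTRON_MASS: float = 0.00054857990907

#: Averagine composition (atoms per residue, residue mass 111.1254 Da);
#: used by the synthetic-data generator to sketch protein compositions.
AVERAGINE: dict[str, float] = {
    "C": 4.9384,
    "H": 7.7583,
    "N": 1.3577,
    "O": 1.4773,
    "S": 0.0417,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition as a mapping of element symbol to count.

    Stored counts are strictly positive; elements with zero count are
    dropped on construction.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
            if n > 0:
                cleaned[el] = n
        object.__setattr__(self, "element_counts", cleaned)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts)

    def __getitem__(self, el: str) -> int:
        return self.element_counts.get(el, 0)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        parts = []
        for el in sorted(self.element_counts, key=lambda e: (e != "C", e != "H", e)):
            n = self.element_counts[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style element-count string, e.g. ``"C48H66BrN8O13"``.

    An omitted count means 1.  Two-letter symbols (Br, Cl, Na...) take
    precedence over one-letter ones by the capitalization convention.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da of a formula (object, mapping, or string)."""
    if isinstance(f, str):
        f = parse_formula(f)
    counts = f.element_counts if isinstance(f, MolecularFormula) else f
    total = 0.0
    for el, n in counts.items():
        try:
            total += MONOISOTOPIC_MASS[el] * n
        except KeyError:
            raise FormulaError(f"unsupported element symbol: {el!r}") from None
    return total


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of a neutral mass carrying ``z`` protons (positive mode)."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass in Da of an ion at ``mz`` with charge ``z``."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return mz * z - z * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical == 0:
        raise ValueError("theoretical mass must be nonzero")
    return (observed - theoretical) / theoretical * 1e6


def protonated_ion_mz(ion_formula: MolecularFormula | str) -> float:
    """Theoretical m/z of a singly charged cation given as its ion formula.

    ``ion_formula`` is the composition of the protonated species itself
    (the [M+H]+ convention used when annotating exact masses), so the m/z
    is the atoms' monoisotopic mass minus one electron mass.
    """
    return monoisotopic_mass(ion_formula) - ELECTRON_MASS


def neutral_mass_from_mh(mh_mz: float) -> float:
    """Neutral monoisotopic mass from an observed [M+H]+ m/z."""
    return mh_mz - PROTON_MASS
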