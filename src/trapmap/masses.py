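"""Atomic and residue mass tables and the :class:`MassValue` scalar.

All peptide, glycan and cross-link masses in this package are derived from
elemental compositions and the atomic masses below, never copied from
instrument readings.  Two mass scales are supported and kept strictly
separate: ``monoisotopic`` (lightest-isotope composition, what an ion trap
reports for resolved peaks) and ``average`` (abundance-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

MassScale = Literal["monoisotopic", "average"]

#: Atomic masses, Da.  Monoisotopic values are the principal-isotope masses;
#: average values are standard atomic weights.
ELEMENT_MASSES: dict[str, dict[str, float]] = {
    "monoisotopic": {
        "H": 1.0078250319,
        "C": 12.0,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "S": 31.97207069,
    },
    "average": {
        "H": 1.00794,
        "C": 12.0107,
        "N": 14.0067,
        "O": 15.9994,
        "S": 32.065,
    },
}

#: Elemental composition of each amino-acid *residue* (monomer minus water).
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

CANONICAL_RESIDUES = frozenset(RESIDUE_FORMULAS)


def formula_mass(formula: Mapping[str, int], scale: MassScale = "monoisotopic") -> float:
    """Mass of an elemental composition on the requested scale, Da."""
    table = ELEMENT_MASSES[scale]
    return sum(table[el] * n for el, n in formula.items())


#: Mass of one water molecule, Da.
WATER_MONO = formula_mass({"H": 2, "O": 1})
WATER_AVG = formula_mass({"H": 2, "O": 1}, "average")

#: Proton mass (charge carrier for MH+ and m/z), Da.
PROTON = 1.007276

#: Mass removed per disulfide bond (two hydrogens), Da.
DISULFIDE_DELTA_MONO = formula_mass({"H": 2})

#: C13 - C12 spacing: offset of a mis-picked +1 isotope peak, Da.
ISOTOPE_SPACING = 1.0033548378

#: Carbamidomethyl (+C2H3NO) on Cys from iodoacetamide-type blocking agents.
CARBAMIDOMETHYL_MONO = formula_mass({"C": 2, "H": 3, "N": 1, "O": 1})
CARBAMIDOMETHYL_AVG = formula_mass({"C": 2, "H": 3, "N": 1, "O": 1}, "average")

#: Deamidation / PNGase F Asn->Asp conversion (+O -NH), Da.
DEAMIDATION_MONO = formula_mass({"O": 1}) - formula_mass({"N": 1, "H": 1})
DEAMIDATION_AVG = formula_mass({"O": 1}, "average") - formula_mass({"N": 1, "H": 1}, "average")

#: Oxidation (+O), e.g. on Met.
OXIDATION_MONO = formula_mass({"O": 1})
OXIDATION_AVG = formula_mass({"O": 1}, "average")

_RESIDUE_MASS_CACHE: dict[str, dict[str, float]] = {
    scale: {aa: formula_mass(f, scale) for aa, f in RESIDUE_FORMULAS.items()}
    for scale in ("monoisotopic", "average")
}


@dataclass(frozen=True)
class MassValue:
    """A mass with an explicit scale.

    Arithmetic is only defined between values on the same scale; mixing
    scales raises ``ValueError``, which is the whole point of the type.
    """

    scale: MassScale
    daltons: float

    def __post_init__(self) -> None:
        if self.scale not in ("monoisotopic", "average"):
            raise ValueError(f"unknown mass scale: {self.scale!r}")
        if not (self.daltons >= 0.0):
            raise ValueError(f"mass must be non-negative, got {self.daltons}")

    def _check(self, other: "MassValue") -> None:
        if not isinstance(other, MassValue):
            raise TypeError("can only combine MassValue with MassValue")
        if other.scale != self.scale:
            raise ValueError(f"mass scale mismatch: {self.scale} vs {other.scale}")

    def __add__(self, other: "MassValue") -> "MassValue":
        self._check(other)
        return MassValue(self.scale, self.daltons + other.daltons)

    def __sub__(self, other: "MassValue") -> "MassValue":
        self._check(other)
        return MassValue(self.scale, self.daltons - other.daltons)


def water(scale: MassScale = "monoisotopic") -> MassValue:
    return MassValue(scale, WATER_MONO if scale == "monoisotopic" else WATER_AVG)


def residue_mass(residue: str, scale: MassScale = "monoisotopic") -> MassValue:
    """Residue (monomer-minus-water) mass of one canonical amino acid.

    Raises
    ------
    KeyError
        If ``residue`` is not one of the 20 canonical one-letter codes.
    """
    try:
        m = _RESIDUE_MASS_CACHE[scale][residue]
    except KeyError:
        if scale not in _RESIDUE_MASS_CACHE:
            raise ValueError(f"unknown mass scale: {scale!r}") from None
        raise KeyError(f"unknown residue code: {residue!r}") from None
    return MassValue(scale, m)
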