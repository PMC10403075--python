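"""Residue registry for natural and non-natural amino acids.

The registry covers the 20 proteinogenic residues plus the seven
non-naturals used in hydrocarbon-stapled apolipoprotein mimetics:

* ``R8`` — (R)-alpha-methyl,alpha-octenyl-glycine (long staple arm)
* ``S5`` — (S)-alpha-methyl,alpha-pentenyl-glycine (short arm)
* ``B5`` — bis-pentenyl-glycine (stitch hub, two olefin arms)
* ``S8`` — (S)-alpha-methyl,alpha-octenyl-glycine (long arm)
* ``Nle`` — norleucine, oxidation-resistant Met isostere
* ``Sar`` — sarcosine (N-methyl-glycine)
* ``Aib`` — alpha-aminoisobutyric acid (alpha-methyl-alanine)

Masses are derived from residue elemental formulas (amino acid minus
water).  Hydrophobicities follow the Eisenberg consensus scale; the
olefin-arm residues are assigned the Leu value (aliphatic chains on the
hydrophobic face), Nle likewise, Sar the Gly value and Aib the Ala value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ResidueSpec",
    "REGISTRY",
    "NATURAL_CODES",
    "EISENBERG",
    "formula_mass",
    "WATER",
    "ETHENE",
    "CH2",
    "N_CAP_DELTAS",
    "C_CAP_DELTAS",
    "get_spec",
]

# Monoisotopic / average atomic masses (Da)
_ATOMIC_MONO = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052,
                "O": 15.9949146221, "S": 31.97207069}
_ATOMIC_AVG = {"H": 1.00794, "C": 12.0107, "N": 14.0067,
               "O": 15.9994, "S": 32.065}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str, kind: str = "monoisotopic") -> float:
    """Mass of an elemental formula string such as ``"C6H11NO"``."""
    table = _ATOMIC_MONO if kind == "monoisotopic" else _ATOMIC_AVG
    mass = 0.0
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"bad formula {formula!r}")
        pos = m.end()
        mass += table[m.group(1)] * (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise ValueError(f"bad formula {formula!r}")
    return mass


WATER = {"monoisotopic": formula_mass("H2O"), "average": formula_mass("H2O", "average")}
# ring-closing metathesis releases one ethene per closed staple
ETHENE = {"monoisotopic": formula_mass("C2H4"), "average": formula_mass("C2H4", "average")}
CH2 = {"monoisotopic": formula_mass("CH2"), "average": formula_mass("CH2", "average")}

N_CAP_DELTAS = {
    "free": {"monoisotopic": 0.0, "average": 0.0},
    "acetyl": {"monoisotopic": formula_mass("C2H2O"),
               "average": formula_mass("C2H2O", "average")},
    "octanoyl": {"monoisotopic": formula_mass("C8H14O"),
                 "average": formula_mass("C8H14O", "average")},
}
# amidation swaps the C-terminal OH for NH2
_AMIDE_MONO = (_ATOMIC_MONO["N"] + _ATOMIC_MONO["H"] - _ATOMIC_MONO["O"])
_AMIDE_AVG = (_ATOMIC_AVG["N"] + _ATOMIC_AVG["H"] - _ATOMIC_AVG["O"])
C_CAP_DELTAS = {
    "free_acid": {"monoisotopic": 0.0, "average": 0.0},
    "amide": {"monoisotopic": _AMIDE_MONO, "average": _AMIDE_AVG},
}

# Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


@dataclass(frozen=True)
class ResidueSpec:
    """Registered chemistry of one residue type.

    ``stereo`` is the default stereochemistry of the alpha carbon: ``L``
    for proteinogenic chiral residues, ``achiral`` for Gly, Aib, Sar and
    the alpha,alpha-disubstituted olefin-arm residues (whose R/S arm
    configuration is carried by the code itself, e.g. R8 vs S5).
    """

    code: str
    formula: str
    stereo: str = "L"  # default stereo; 'L', 'D' or 'achiral'
    n_methylated: bool = False
    alpha_disubstituted: bool = False
    olefin_arms: int = 0
    hydrophobicity: float = 0.0

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self.formula, "monoisotopic")

    @property
    def average_mass(self) -> float:
        return formula_mass(self.formula, "average")

    @property
    def chiral(self) -> bool:
        return self.stereo != "achiral"


_NATURAL_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}

NATURAL_CODES = tuple(sorted(_NATURAL_FORMULAS))

REGISTRY: dict[str, ResidueSpec] = {}
for _code, _formula in _NATURAL_FORMULAS.items():
    REGISTRY[_code] = ResidueSpec(
        code=_code,
        formula=_formula,
        stereo="achiral" if _code == "G" else "L",
        hydrophobicity=EISENBERG[_code],
    )

_LEU_H = EISENBERG["L"]
REGISTRY["Nle"] = ResidueSpec("Nle", "C6H11NO", stereo="L", hydrophobicity=_LEU_H)
REGISTRY["Sar"] = ResidueSpec("Sar", "C3H5NO", stereo="achiral", n_methylated=True,
                              hydrophobicity=EISENBERG["G"])
REGISTRY["Aib"] = ResidueSpec("Aib", "C4H7NO", stereo="achiral",
                              alpha_disubstituted=True, hydrophobicity=EISENBERG["A"])
REGISTRY["R8"] = ResidueSpec("R8", "C11H19NO", stereo="achiral",
                             alpha_disubstituted=True, olefin_arms=1, hydrophobicity=_LEU_H)
REGISTRY["S5"] = ResidueSpec("S5", "C8H13NO", stereo="achiral",
                             alpha_disubstituted=True, olefin_arms=1, hydrophobicity=_LEU_H)
REGISTRY["S8"] = ResidueSpec("S8", "C11H19NO", stereo="achiral",
                             alpha_disubstituted=True, olefin_arms=1, hydrophobicity=_LEU_H)
REGISTRY["B5"] = ResidueSpec("B5", "C12H19NO", stereo="achiral",
                             alpha_disubstituted=True, olefin_arms=2, hydrophobicity=_LEU_H)

OLEFIN_CODES = frozenset({"R8", "S5", "S8", "B5"})

_BY_LOWER = {c.lower(): c for c in REGISTRY}


def get_spec(code: str) -> ResidueSpec:
    """Look up a registered residue, case-insensitively."""
    canon = _BY_LOWER.get(code.lower())
    if canon is None:
        raise KeyError(f"unknown residue code {code!r}")
    return REGISTRY[canon]
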