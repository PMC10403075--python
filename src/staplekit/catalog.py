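"""Packaged peptide fixtures for the stapled ApoC2-mimetic design study.

The activation helix of human ApoC2 (mature-chain residues 59-79,
``AMSTYTGIFTDQVLSVLKGEE``) is the scaffold for the stapled mimetics:

* ``P8`` — the unmodified 21-mer ApoC2 59-79 fragment (inactive control).
* ``SP1`` — single long staple (3,10) on the 21-mer, plus the
  proteolysis-protection set: N-acetyl, Met2->Nle, Gly19->Sar,
  D-Glu20/21.
* ``SP2`` — stitched analogue: two contiguous long staples (3,10) and
  (10,17) sharing a bis-pentenyl-glycine hub at position 10.
* ``SP2a`` — SP2 with an octanoyl N-cap and Ala1->Aib.

``D6PV`` is the bi-helical 41-mer predecessor peptide.  Its full sequence
was never published; the packaged fixture is a SYNTHETIC reconstruction
constrained by its described properties: 41 residues; first helix
(positions 1-20) carrying the KEVFEKLRDLY stretch at 4-14 with Glu at
position 8 and the junction Pro at position 20; second helix
(positions 21-41) identical to ApoC2 59-79.  Deleting the 7 N-terminal
residues and the junction Pro yields the 33-mer design scaffold on which
the reported staple placements (3,10), (11,18), (14,18), (15,22) live.
"""

from __future__ import annotations

from .peptide import Peptide, parse_sequence

__all__ = [
    "APOC2_59_79",
    "NATIVE_HELIX1",
    "D6PV_SEQ",
    "SCAFFOLD_33_SEQ",
    "p8",
    "sp1",
    "sp2",
    "sp2a",
    "d6pv",
    "scaffold_33",
    "native_helix1",
    "D6PV_HELIX1_WINDOW",
    "D6PV_HELIX2_WINDOW",
    "KEVFEKLRDLY_SPAN",
]

APOC2_59_79 = "AMSTYTGIFTDQVLSVLKGEE"

#: native ApoC2 39-58, the region the reconstructed D6PV first helix replaces
NATIVE_HELIX1 = "KTYLPAVDEKLRDLYSKSTA"

#: synthetic reconstruction (see module docstring)
D6PV_SEQ = "KTYKEVFEKLRDLYSKSTAP" + APOC2_59_79

#: D6PV minus its 7 N-terminal residues and the junction Pro (Fig-2A scaffold)
SCAFFOLD_33_SEQ = D6PV_SEQ[7:19] + APOC2_59_79

D6PV_HELIX1_WINDOW = (1, 20)
D6PV_HELIX2_WINDOW = (21, 41)

#: 1-based span of the potentially immunogenic stretch within D6PV
KEVFEKLRDLY_SPAN = (4, 14)


def p8() -> Peptide:
    """Native ApoC2 59-79 fragment (no staple, free termini)."""
    return parse_sequence(APOC2_59_79, name="P8")


def sp1() -> Peptide:
    """Single-staple protease-resistant mimetic (21 residues)."""
    return parse_sequence("Ac-A{Nle}{R8}TYTGIF{S5}DQVLSVLK{Sar}ee|3-10", name="SP1")


def sp2() -> Peptide:
    """Stitched (double-staple) mimetic sharing a B5 hub at position 10."""
    return parse_sequence("Ac-A{Nle}{R8}TYTGIF{B5}DQVLSV{S8}K{Sar}ee|3-10|10-17",
                          name="SP2")


def sp2a() -> Peptide:
    """SP2 with octanoyl N-cap and Ala1->Aib."""
    return parse_sequence("Oct-{Aib}{Nle}{R8}TYTGIF{B5}DQVLSV{S8}K{Sar}ee|3-10|10-17",
                          name="SP2a")


def d6pv() -> Peptide:
    """Bi-helical 41-mer predecessor (synthetic sequence reconstruction)."""
    return parse_sequence(D6PV_SEQ, name="D6PV")


def scaffold_33() -> Peptide:
    """33-mer staple-design scaffold derived from D6PV."""
    return parse_sequence(SCAFFOLD_33_SEQ, name="scaffold33")


def native_helix1() -> Peptide:
    """Native ApoC2 39-58, counterpart of the D6PV first helix."""
    return parse_sequence(NATIVE_HELIX1, name="ApoC2_39_58")
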