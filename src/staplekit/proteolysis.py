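"""Rule-based prediction of protease-susceptible bonds and their protection.

The engine is deterministic: an endoprotease rule names the P1 residues it
cleaves after and the structural features that block cleavage at an
otherwise susceptible bond.  Bond ``b`` (1..L-1) joins residues ``b`` (P1)
and ``b+1`` (P1').  Blockers:

* ``proline_at_p1prime`` — Pro at P1' resists most endoproteases
* ``d_residue_at_p1_or_p1prime`` — proteases are stereospecific
* ``n_methyl_at_p1prime`` — N-methylated scissile amide (e.g. sarcosine)
* ``alpha_disubstituted_at_p1prime`` — Aib or an olefin-arm residue at
  P1' sterically blocks the scissile amide
* ``within_staple_span`` — the stapled macrocycle shields the amides it
  spans; by convention bonds with P1 in [i, j-1] for a staple (i, j)

Exopeptidase rules describe terminal vulnerability instead: an
aminopeptidase needs a free, L-configured N-terminus; a carboxypeptidase
needs a free-acid C-terminus without terminal D-residues.

No kinetics are modelled — the output is susceptible-site counts with
protection provenance, mirroring a qualitative full-length-peptide
survival readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .peptide import Peptide

__all__ = [
    "ProteaseRule",
    "Site",
    "DigestResult",
    "trypsin_rule",
    "pepsin_rule",
    "proteinase_k_rule",
    "aminopeptidase_rule",
    "carboxypeptidase_rule",
    "PANEL",
    "get_rule",
    "digest_sites",
    "resistance_report",
]

STANDARD_BLOCKERS = (
    "proline_at_p1prime",
    "d_residue_at_p1_or_p1prime",
    "n_methyl_at_p1prime",
    "alpha_disubstituted_at_p1prime",
    "within_staple_span",
)


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    kind: str                       # 'endo' | 'exo_n' | 'exo_c'
    p1_residues: frozenset[str] = frozenset()
    ph_range: tuple[float, float] = (1.0, 14.0)
    ph_optimum: float = 7.4
    blockers: tuple[str, ...] = STANDARD_BLOCKERS


def trypsin_rule() -> ProteaseRule:
    """Trypsin: cleaves C-terminal to Lys and Arg at near-neutral pH."""
    return ProteaseRule("trypsin", "endo", frozenset({"K", "R"}),
                        ph_range=(6.0, 10.0), ph_optimum=8.2)


def pepsin_rule() -> ProteaseRule:
    """Pepsin: broad-specificity gastric protease, acidic pH optimum.

    P1 set {F, L, W, Y} — the minimal aromatic/aliphatic broad-specificity
    set; inactive outside pH 1-4.
    """
    return ProteaseRule("pepsin", "endo", frozenset({"F", "L", "W", "Y"}),
                        ph_range=(1.0, 4.0), ph_optimum=2.0)


def proteinase_k_rule() -> ProteaseRule:
    """Proteinase K: cleaves after aliphatic and aromatic residues."""
    return ProteaseRule("proteinase_K", "endo",
                        frozenset({"A", "V", "L", "I", "F", "W", "Y"}),
                        ph_range=(4.0, 12.0), ph_optimum=8.0)


def aminopeptidase_rule() -> ProteaseRule:
    return ProteaseRule("aminopeptidase", "exo_n", ph_range=(5.0, 9.0))


def carboxypeptidase_rule() -> ProteaseRule:
    return ProteaseRule("carboxypeptidase", "exo_c", ph_range=(5.0, 9.0))


PANEL = {r().name: r for r in (trypsin_rule, pepsin_rule, proteinase_k_rule,
                               aminopeptidase_rule, carboxypeptidase_rule)}


def get_rule(name: str) -> ProteaseRule:
    try:
        return PANEL[name]()
    except KeyError:
        raise ValueError(f"unknown protease {name!r}") from None


@dataclass(frozen=True)
class Site:
    bond_index: int           # = P1 position, 1..L-1
    p1_code: str
    protected: bool
    protection_reasons: tuple[str, ...]


@dataclass(frozen=True)
class DigestResult:
    peptide: str
    protease: str
    sites: tuple[Site, ...]
    susceptible_count: int
    terminal_open: bool | None = None   # exopeptidase rules only


def _protection_reasons(p: Peptide, bond: int, rule: ProteaseRule) -> tuple[str, ...]:
    p1 = p.residue(bond)
    p1p = p.residue(bond + 1)
    reasons = []
    if "proline_at_p1prime" in rule.blockers and p1p.code == "P":
        reasons.append("proline_at_p1prime")
    if ("d_residue_at_p1_or_p1prime" in rule.blockers
            and ("D" in (p1.stereo, p1p.stereo))):
        reasons.append("d_residue_at_p1_or_p1prime")
    if "n_methyl_at_p1prime" in rule.blockers and p1p.n_methylated:
        reasons.append("n_methyl_at_p1prime")
    if ("alpha_disubstituted_at_p1prime" in rule.blockers
            and p1p.spec.alpha_disubstituted):
        reasons.append("alpha_disubstituted_at_p1prime")
    if "within_staple_span" in rule.blockers:
        if any(s.i <= bond <= s.j - 1 for s in p.staples):
            reasons.append("within_staple_span")
    return tuple(reasons)


def digest_sites(p: Peptide, rule: ProteaseRule, ph: float) -> DigestResult:
    """Predict susceptible bonds (or terminal vulnerability) for one rule."""
    if rule.kind == "exo_n":
        open_ = (p.n_cap == "free" and p.residue(1).stereo != "D")
        return DigestResult(p.name, rule.name, (), int(open_), terminal_open=open_)
    if rule.kind == "exo_c":
        last_two_d = (len(p) >= 2
                      and p.residue(len(p)).stereo == "D"
                      and p.residue(len(p) - 1).stereo == "D")
        open_ = not (p.c_cap == "amide" or last_two_d)
        return DigestResult(p.name, rule.name, (), int(open_), terminal_open=open_)

    active = rule.ph_range[0] <= ph <= rule.ph_range[1]
    sites = []
    if active:
        for bond in range(1, len(p)):
            if p.residue(bond).code not in rule.p1_residues:
                continue
            reasons = _protection_reasons(p, bond, rule)
            sites.append(Site(bond_index=bond, p1_code=p.residue(bond).code,
                              protected=bool(reasons), protection_reasons=reasons))
    susceptible = sum(1 for s in sites if not s.protected)
    return DigestResult(p.name, rule.name, tuple(sites), susceptible)


def resistance_report(p: Peptide, panel: list[ProteaseRule] | None = None,
                      ph: float | None = None) -> dict[str, DigestResult]:
    """Digest a peptide against a protease panel.

    Each rule runs at ``ph`` if given, otherwise at its own pH optimum.
    Returns a mapping protease name -> DigestResult; exopeptidase entries
    report terminal vulnerability.
    """
    if panel is None:
        panel = [make() for make in PANEL.values()]
    if not panel:
        raise ValueError("protease panel is empty")
    return {rule.name: digest_sites(p, rule, rule.ph_optimum if ph is None else ph)
            for rule in panel}
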