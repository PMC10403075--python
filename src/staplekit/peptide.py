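"""Peptide data model, sequence-dialect parsing and modification bookkeeping.

The sequence dialect is a compact one-line encoding of stapled peptides:

* uppercase letter — L-residue, lowercase letter — D-residue
* ``{Token}`` — non-natural residue (``{Nle}``, ``{Sar}``, ``{Aib}``,
  ``{R8}``, ``{S5}``, ``{B5}``, ``{S8}``); lowercase token = D-isomer
  where the residue is chiral; ``{NMeX}`` — N-methylated natural residue X
* optional ``Ac-`` or ``Oct-`` prefix (N-terminal acetyl / octanoyl cap)
* optional ``-NH2`` suffix (C-terminal amide)
* staples appended as ``|i-j`` (1-based arm positions), e.g. ``|3-10``

Example (single-staple mimetic): ``Ac-A{Nle}{R8}TYTGIF{S5}DQVLSVLK{Sar}ee|3-10``
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .residues import OLEFIN_CODES, REGISTRY, get_spec

__all__ = [
    "Residue",
    "Staple",
    "Peptide",
    "parse_sequence",
    "write_sequence",
    "apply_modifications",
    "peptide_mass",
    "read_dialect_file",
    "read_fasta",
    "ParseError",
    "ValidationError",
]


class ParseError(ValueError):
    """Raised when a dialect string cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a structurally invalid peptide is constructed."""


@dataclass(frozen=True)
class Residue:
    """One sequence position: a registered code plus per-position state."""

    code: str
    stereo: str = "L"
    n_methylated: bool = False

    @property
    def spec(self):
        return get_spec(self.code)

    @classmethod
    def of(cls, code: str, stereo: str | None = None,
           n_methylated: bool | None = None) -> "Residue":
        spec = get_spec(code)
        if stereo is None:
            stereo = spec.stereo
        elif spec.stereo == "achiral" and stereo != "achiral":
            raise ValidationError(f"{spec.code} is achiral; cannot assign stereo {stereo!r}")
        return cls(code=spec.code, stereo=stereo,
                   n_methylated=spec.n_methylated if n_methylated is None else n_methylated)


@dataclass(frozen=True)
class Staple:
    """Hydrocarbon staple between arm positions ``i`` and ``j`` (1-based).

    ``span_class`` is ``short`` for i,i+4, ``long`` for i,i+7 and
    ``stitch_segment`` for a segment of a stitched (double) staple that
    shares a bis-olefin (B5) hub residue.  ``closed`` records whether
    ring-closing metathesis was performed (affects the mass by one
    released ethene per closed staple).
    """

    i: int
    j: int
    span_class: str = "long"
    closed: bool = True

    @property
    def offset(self) -> int:
        return self.j - self.i


_SPAN_BY_OFFSET = {4: "short", 7: "long"}


@dataclass(frozen=True)
class Peptide:
    name: str = ""
    residues: tuple[Residue, ...] = ()
    staples: tuple[Staple, ...] = ()
    n_cap: str = "free"       # free | acetyl | octanoyl
    c_cap: str = "free_acid"  # free_acid | amide

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError("peptide must contain at least one residue")
        if self.n_cap not in ("free", "acetyl", "octanoyl"):
            raise ValidationError(f"unknown N-cap {self.n_cap!r}")
        if self.c_cap not in ("free_acid", "amide"):
            raise ValidationError(f"unknown C-cap {self.c_cap!r}")
        arm_use: dict[int, int] = {}
        for s in self.staples:
            for pos in (s.i, s.j):
                if not 1 <= pos <= len(self.residues):
                    raise ValidationError(f"staple arm position {pos} outside sequence")
                code = self.residues[pos - 1].code
                if code not in OLEFIN_CODES:
                    raise ValidationError(
                        f"staple arm at position {pos} requires an olefin residue, found {code}")
                arm_use[pos] = arm_use.get(pos, 0) + 1
            if s.offset not in (4, 7):
                raise ValidationError(f"staple span j-i must be 4 or 7, got {s.offset}")
        for pos, n in arm_use.items():
            max_arms = self.residues[pos - 1].spec.olefin_arms
            if n > max_arms:
                raise ValidationError(
                    f"residue {self.residues[pos - 1].code} at {pos} carries {n} staple arms "
                    f"but supports {max_arms}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, pos: int) -> Residue:
        """1-based positional access."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]

    @property
    def classified_staples(self) -> tuple[Staple, ...]:
        """Staples with span_class resolved, marking stitch segments.

        A staple whose arm lands on a B5 hub shared with another staple is a
        ``stitch_segment``; otherwise the class follows the i,i+4 / i,i+7
        arithmetic.
        """
        hub_count: dict[int, int] = {}
        for s in self.staples:
            for pos in (s.i, s.j):
                hub_count[pos] = hub_count.get(pos, 0) + 1
        out = []
        for s in self.staples:
            shared = any(
                hub_count[pos] > 1 and self.residues[pos - 1].code == "B5"
                for pos in (s.i, s.j))
            cls = "stitch_segment" if shared else _SPAN_BY_OFFSET[s.offset]
            out.append(replace(s, span_class=cls))
        return tuple(out)

    def sequence_str(self) -> str:
        return write_sequence(self)


# ---------------------------------------------------------------------------
# dialect parsing

_PREFIX_RE = re.compile(r"^(Ac|Oct)-")
_STAPLE_RE = re.compile(r"\|(\d+)-(\d+)")


def _parse_token(tok: str) -> Residue:
    if tok.lower().startswith("nme") and len(tok) == 4:
        base = tok[3]
        spec = get_spec(base)
        stereo = "D" if base.islower() and spec.chiral else spec.stereo
        return Residue(code=spec.code, stereo=stereo, n_methylated=True)
    try:
        spec = get_spec(tok)
    except KeyError:
        raise ParseError(f"unknown residue token {tok!r}") from None
    stereo = "D" if tok == tok.lower() and spec.chiral else spec.stereo
    return Residue(code=spec.code, stereo=stereo, n_methylated=spec.n_methylated)


def parse_sequence(text: str, name: str = "") -> Peptide:
    """Parse a sequence-dialect string into a :class:`Peptide`."""
    s = text.strip()
    n_cap = "free"
    m = _PREFIX_RE.match(s)
    if m:
        n_cap = {"Ac": "acetyl", "Oct": "octanoyl"}[m.group(1)]
        s = s[m.end():]

    staples: list[Staple] = []
    body = s
    first_pipe = s.find("|")
    if first_pipe != -1:
        body, tail = s[:first_pipe], s[first_pipe:]
        pos = 0
        for m in _STAPLE_RE.finditer(tail):
            if m.start() != pos:
                raise ParseError(f"malformed staple annotation in {tail!r}")
            pos = m.end()
            staples.append(Staple(i=int(m.group(1)), j=int(m.group(2))))
        if pos != len(tail):
            raise ParseError(f"malformed staple annotation in {tail!r}")

    c_cap = "free_acid"
    if body.endswith("-NH2"):
        c_cap = "amide"
        body = body[:-4]

    residues: list[Residue] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "{":
            end = body.find("}", i)
            if end == -1:
                raise ParseError(f"unterminated token at offset {i} in {text!r}")
            residues.append(_parse_token(body[i + 1:end]))
            i = end + 1
        elif ch.isalpha():
            spec_code = ch.upper()
            if spec_code not in REGISTRY:
                raise ParseError(f"unknown residue token {ch!r}")
            spec = REGISTRY[spec_code]
            stereo = "D" if ch.islower() and spec.chiral else spec.stereo
            residues.append(Residue(code=spec_code, stereo=stereo,
                                    n_methylated=spec.n_methylated))
            i += 1
        else:
            raise ParseError(f"unexpected character {ch!r} at offset {i} in {text!r}")

    offsets = {4: "short", 7: "long"}
    staples = [replace(s, span_class=offsets.get(s.offset, "long")) for s in staples]
    try:
        pep = Peptide(name=name, residues=tuple(residues), staples=tuple(staples),
                      n_cap=n_cap, c_cap=c_cap)
    except ValidationError:
        raise
    return pep


def _write_residue(r: Residue) -> str:
    spec = r.spec
    if r.n_methylated and not spec.n_methylated:
        tok = r.code.lower() if r.stereo == "D" else r.code
        return "{NMe" + tok + "}"
    if len(r.code) == 1:
        return r.code.lower() if r.stereo == "D" else r.code
    tok = r.code.lower() if r.stereo == "D" else r.code
    return "{" + tok + "}"


def write_sequence(p: Peptide) -> str:
    """Serialize a peptide to its dialect string (inverse of parse_sequence)."""
    parts = []
    if p.n_cap == "acetyl":
        parts.append("Ac-")
    elif p.n_cap == "octanoyl":
        parts.append("Oct-")
    parts.extend(_write_residue(r) for r in p.residues)
    if p.c_cap == "amide":
        parts.append("-NH2")
    parts.extend(f"|{s.i}-{s.j}" for s in p.staples)
    return "".join(parts)


# ---------------------------------------------------------------------------
# modification directives

def _substitute(p: Peptide, pos: int, code: str, **kw) -> Peptide:
    res = list(p.residues)
    p.residue(pos)  # bounds check
    res[pos - 1] = Residue.of(code, **kw)
    return replace(p, residues=tuple(res))


def _delete(p: Peptide, pos: int) -> Peptide:
    p.residue(pos)
    for s in p.staples:
        if pos in (s.i, s.j):
            raise ValidationError(f"cannot delete staple arm at position {pos}")
    res = list(p.residues)
    del res[pos - 1]
    staples = tuple(
        replace(s, i=s.i - (s.i > pos), j=s.j - (s.j > pos)) for s in p.staples)
    return replace(p, residues=tuple(res), staples=staples)


def _stereo_flip(p: Peptide, pos: int) -> Peptide:
    r = p.residue(pos)
    if not r.spec.chiral:
        raise ValidationError(f"cannot stereo-flip achiral residue {r.code} at {pos}")
    res = list(p.residues)
    res[pos - 1] = replace(r, stereo="D" if r.stereo == "L" else "L")
    return replace(p, residues=tuple(res))


def _n_methylate(p: Peptide, pos: int) -> Peptide:
    r = p.residue(pos)
    res = list(p.residues)
    # N-methyl-Gly is sarcosine, a registered residue of its own
    if r.code == "G":
        res[pos - 1] = Residue.of("Sar")
    else:
        res[pos - 1] = replace(r, n_methylated=True)
    return replace(p, residues=tuple(res))


def _cap(p: Peptide, terminus: str, value: str) -> Peptide:
    if terminus == "n":
        return replace(p, n_cap=value)
    if terminus == "c":
        return replace(p, c_cap=value)
    raise ValidationError(f"unknown terminus {terminus!r}")


def _add_staple(p: Peptide, i: int, j: int, closed: bool = True) -> Peptide:
    offset = j - i
    if offset not in (4, 7):
        raise ValidationError(f"staple span j-i must be 4 or 7, got {offset}")
    res = list(p.residues)
    for pos, default_arm in ((i, "R8"), (j, "S5")):
        if p.residue(pos).code not in OLEFIN_CODES:
            res[pos - 1] = Residue.of(default_arm)
    staples = p.staples + (Staple(i=i, j=j, span_class=_SPAN_BY_OFFSET[offset],
                                  closed=closed),)
    return replace(p, residues=tuple(res), staples=staples)


_DIRECTIVES = {
    "substitute": _substitute,
    "delete": _delete,
    "stereo_flip": _stereo_flip,
    "n_methylate": _n_methylate,
    "cap": _cap,
    "add_staple": _add_staple,
}


def apply_modifications(p: Peptide, mods: list[tuple]) -> Peptide:
    """Apply edit directives, returning a new peptide (the input is unchanged).

    Each directive is a tuple ``(kind, *args)`` with kind one of
    ``substitute(pos, code)``, ``delete(pos)``, ``stereo_flip(pos)``,
    ``n_methylate(pos)``, ``cap(terminus, value)``,
    ``add_staple(i, j[, closed])``.
    """
    out = p
    for mod in mods:
        kind, *args = mod
        try:
            fn = _DIRECTIVES[kind]
        except KeyError:
            raise ValidationError(f"unknown directive kind {kind!r}") from None
        out = fn(out, *args)
    return out


# ---------------------------------------------------------------------------
# mass bookkeeping

def peptide_mass(p: Peptide, kind: str = "monoisotopic") -> float:
    """Peptide mass in Da.

    Sum of residue masses plus one water, plus terminal-cap deltas, minus
    one ethene per closed staple (the olefin released by ring-closing
    metathesis), plus one CH2 per post-hoc N-methylation of a residue whose
    registered formula is not already N-methylated.
    """
    from .residues import C_CAP_DELTAS, CH2, ETHENE, N_CAP_DELTAS, WATER

    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass kind {kind!r}")
    if len(p.residues) == 0:
        raise ValidationError("cannot compute mass of an empty peptide")
    total = WATER[kind]
    for r in p.residues:
        spec = r.spec
        total += spec.monoisotopic_mass if kind == "monoisotopic" else spec.average_mass
        if r.n_methylated and not spec.n_methylated:
            total += CH2[kind]
    total += N_CAP_DELTAS[p.n_cap][kind]
    total += C_CAP_DELTAS[p.c_cap][kind]
    total -= ETHENE[kind] * sum(1 for s in p.staples if s.closed)
    return total


# ---------------------------------------------------------------------------
# file I/O

def read_dialect_file(path) -> list[Peptide]:
    """Read a sequence-dialect file: one record per line, ``name<TAB>dialect``."""
    peptides = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, seq = line.split("\t", 1)
            else:
                name, seq = f"pep{lineno}", line
            peptides.append(parse_sequence(seq.strip(), name=name.strip()))
    return peptides


def read_fasta(path) -> list[Peptide]:
    """Import plain natural-residue sequences from FASTA."""
    from biotite.sequence.io.fasta import FastaFile

    fasta = FastaFile.read(str(path))
    return [parse_sequence(seq, name=header) for header, seq in fasta.items()]
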