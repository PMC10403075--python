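"""Helical-wheel geometry, hydrophobic moment and staple-site design.

An ideal alpha-helix advances 100 degrees per residue when projected onto
the plane normal to the helix axis, so residue n sits at wheel angle
((n-1) * 100) mod 360.  The hydrophobic moment is the vector sum of the
per-residue hydrophobicities placed at those angles; its direction defines
the hydrophobic face of an amphipathic helix, and staple arms are placed
on that face so the hydrocarbon macrocycle packs against lipid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .peptide import Peptide, ValidationError, apply_modifications

__all__ = [
    "HelixProjection",
    "VariantArray",
    "WHEEL_DEGREES_PER_RESIDUE",
    "wheel_angle",
    "project_wheel",
    "compute_moment",
    "hydrophobic_face",
    "propose_staple",
    "build_variant_array",
    "UndefinedFaceError",
]

WHEEL_DEGREES_PER_RESIDUE = 100.0


class UndefinedFaceError(ValueError):
    """The hydrophobic moment is too small to define a face direction."""


def wheel_angle(pos: int) -> float:
    """Wheel angle in degrees [0, 360) of 1-based residue position ``pos``."""
    return ((pos - 1) * WHEEL_DEGREES_PER_RESIDUE) % 360.0


@dataclass(frozen=True)
class HelixProjection:
    """Helical-wheel projection of a window of a peptide."""

    positions: tuple[int, ...]
    angles: tuple[float, ...]           # degrees, [0, 360)
    hydrophobicities: tuple[float, ...]
    moment_magnitude: float
    moment_angle: float                 # degrees, [0, 360)

    def face_members(self, half_width: float = 90.0,
                     min_moment: float = 1e-6) -> frozenset[int]:
        return hydrophobic_face(self, half_width=half_width, min_moment=min_moment)


def _window_positions(p: Peptide, window: tuple[int, int] | None) -> list[int]:
    if window is None:
        window = (1, len(p))
    a, b = window
    if not (1 <= a <= b <= len(p)):
        raise ValueError(f"window {window} invalid for peptide of length {len(p)}")
    return list(range(a, b + 1))


def compute_moment(p: Peptide, window: tuple[int, int] | None = None) -> tuple[float, float]:
    """Hydrophobic moment (magnitude, angle_deg) over a window.

    The moment is the complex sum ``sum_n h_n * exp(i * theta_n)`` with
    ``theta_n`` the wheel angle; magnitude is in hydrophobicity-scale
    units, angle in wheel-frame degrees.
    """
    positions = _window_positions(p, window)
    vec = complex(0.0, 0.0)
    for n in positions:
        h = p.residue(n).spec.hydrophobicity
        theta = math.radians(wheel_angle(n))
        vec += h * complex(math.cos(theta), math.sin(theta))
    magnitude = abs(vec)
    angle = math.degrees(math.atan2(vec.imag, vec.real)) % 360.0
    return magnitude, angle


def project_wheel(p: Peptide, window: tuple[int, int] | None = None) -> HelixProjection:
    """Project a peptide window onto the 100-degree helical wheel."""
    positions = _window_positions(p, window)
    if not positions:
        raise ValueError("empty window")
    magnitude, angle = compute_moment(p, window)
    return HelixProjection(
        positions=tuple(positions),
        angles=tuple(wheel_angle(n) for n in positions),
        hydrophobicities=tuple(p.residue(n).spec.hydrophobicity for n in positions),
        moment_magnitude=magnitude,
        moment_angle=angle,
    )


def _circ_dist(a: float, b: float) -> float:
    """Minor-arc angular distance between two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def hydrophobic_face(proj: HelixProjection, half_width: float = 90.0,
                     min_moment: float = 1e-6) -> frozenset[int]:
    """Positions whose wheel angle lies within +-half_width of the moment."""
    if proj.moment_magnitude < min_moment:
        raise UndefinedFaceError(
            f"moment magnitude {proj.moment_magnitude:.3g} below {min_moment:.3g}; "
            "face direction undefined")
    return frozenset(
        pos for pos, ang in zip(proj.positions, proj.angles)
        if _circ_dist(ang, proj.moment_angle) <= half_width)


_SPANS = {"short": 4, "long": 7}


def propose_staple(p: Peptide, span: str, window: tuple[int, int] | None = None,
                   half_width: float = 90.0) -> list[tuple[int, int]]:
    """Rank candidate staple arm pairs (i, j) within the hydrophobic face.

    Both arms must lie in the hydrophobic face of the window projection.
    Candidates are ranked by the summed hydrophobicity of the residues the
    arms would displace, least hydrophobic first (displacing polar residues
    costs the design least).  Returns an empty list when no face-compatible
    pair exists.
    """
    try:
        offset = _SPANS[span]
    except KeyError:
        raise ValueError(f"span must be 'short' or 'long', got {span!r}") from None
    positions = _window_positions(p, window)
    if len(positions) < offset + 1:
        raise ValueError(f"window of {len(positions)} residues cannot host an "
                         f"i,i+{offset} staple")
    proj = project_wheel(p, window)
    face = hydrophobic_face(proj, half_width=half_width)
    candidates = []
    for i in positions:
        j = i + offset
        if j > positions[-1]:
            break
        if i in face and j in face:
            cost = (p.residue(i).spec.hydrophobicity +
                    p.residue(j).spec.hydrophobicity)
            candidates.append((cost, i, j))
    candidates.sort()
    return [(i, j) for _, i, j in candidates]


# ---------------------------------------------------------------------------
# variant arrays

@dataclass(frozen=True)
class VariantArray:
    scaffold: Peptide
    variants: tuple[tuple[str, Peptide], ...]
    design: str


def _staple_arm_positions(p: Peptide) -> set[int]:
    arms = set()
    for s in p.staples:
        arms.update((s.i, s.j))
    return arms


def build_variant_array(p: Peptide, design: str,
                        window: tuple[int, int] | None = None) -> VariantArray:
    """Build a designed variant array of a scaffold peptide.

    ``ala_scan`` substitutes each non-Ala position in the window with Ala,
    one variant per position (staple-arm positions are skipped).
    ``quad_AE`` simultaneously replaces the four LPL-activation residues
    Y5, I8, D11, Q12 (window-relative numbering) with Ala.
    ``damaged_helix1`` deletes the Glu at window-relative position 8,
    re-indexing every downstream residue on the wheel.
    """
    positions = _window_positions(p, window)
    start = positions[0]

    if design == "ala_scan":
        arms = _staple_arm_positions(p)
        variants = []
        for n in positions:
            r = p.residue(n)
            if r.code == "A" or n in arms:
                continue
            label = f"{r.code}{n - start + 1}A"
            variants.append((label, apply_modifications(p, [("substitute", n, "A")])))
        return VariantArray(scaffold=p, variants=tuple(variants), design=design)

    if design == "quad_AE":
        targets = {5: "Y", 8: "I", 11: "D", 12: "Q"}
        mods = []
        for rel, expected in targets.items():
            n = start + rel - 1
            if n > positions[-1] or p.residue(n).code != expected:
                raise ValidationError(
                    f"quad_AE requires {expected} at window position {rel}, "
                    f"found {p.residue(n).code if n <= len(p) else 'nothing'}")
            mods.append(("substitute", n, "A"))
        return VariantArray(scaffold=p,
                            variants=(("AE", apply_modifications(p, mods)),),
                            design=design)

    if design == "damaged_helix1":
        n = start + 7  # window-relative position 8
        if n > positions[-1] or p.residue(n).code != "E":
            raise ValidationError(
                f"damaged_helix1 requires E at window position 8, "
                f"found {p.residue(n).code if n <= len(p) else 'nothing'}")
        return VariantArray(scaffold=p,
                            variants=(("dE8", apply_modifications(p, [("delete", n)])),),
                            design=design)

    raise ValueError(f"unknown design {design!r}")


def wheel_table(p: Peptide, window: tuple[int, int] | None = None,
                half_width: float = 90.0):
    """Per-position wheel geometry as a pandas DataFrame (CLI backend)."""
    import pandas as pd

    proj = project_wheel(p, window)
    try:
        face = hydrophobic_face(proj, half_width=half_width)
    except UndefinedFaceError:
        face = frozenset()
    return pd.DataFrame({
        "position": proj.positions,
        "residue": [p.residue(n).code for n in proj.positions],
        "angle_deg": np.round(proj.angles, 6),
        "hydrophobicity": proj.hydrophobicities,
        "in_face": [n in face for n in proj.positions],
    })
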