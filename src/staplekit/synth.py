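"""Synthetic trilayer/trajectory generator with planted ground truth.

Emulates the geometry of a POPC/triolein (PL/TO) trilayer with an
embedded helical peptide so the trajectory statistics are fully testable
without molecular dynamics: every quantity the analysis module measures
(insertion depth, TO contact count, hydrogen-bond fraction) is planted by
construction and recorded in a ground-truth sidecar.

No physical realism is attempted — no energies, no dynamics, no water
unless requested.  Atom placement only guarantees the *geometric*
relations the analysis operators read:

* PL phosphorus atoms jittered about the two leaflet planes at +-plane_z,
* the peptide's C-alpha atoms at the planted depth relative to its
  leaflet plane (the helix z is flattened to the planted depth by
  default so per-residue recovery is exact),
* ``planted_contacts`` TO molecules hung within coordination range of the
  peptide, all remaining TO kept far enough that their whole-peptide
  coordination stays well below the contact threshold,
* with probability ``hbond_fraction`` per frame, one ester oxygen of the
  first contact TO placed in ideal hydrogen-bond geometry (r = 0.29 nm,
  theta = 0) to a peptide amide donor.

All randomness derives from ``seed`` and the frame index, so identical
configs produce byte-identical trajectories.
"""

from __future__ import annotations

import json
import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .peptide import Peptide, parse_sequence
from .trilayer import TrilayerFrame, TrilayerTrajectory, write_trajectory_pdb

__all__ = [
    "GeneratorConfig",
    "ideal_helix_coords",
    "build_frame",
    "generate_frames",
    "generate_trajectory",
]

#: defaults are a quarter of the reference trilayer composition
#: (160 POPC / 128 TO) for fast test-scale trajectories
DEFAULT_N_PL = 40
DEFAULT_N_TO = 32

_DEFAULT_PEPTIDE = "Ac-A{Nle}{R8}TYTGIF{S5}DQVLSVLK{Sar}ee|3-10"


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic trilayer generator (lengths in nm)."""

    n_pl: int = Field(DEFAULT_N_PL, ge=2, description="PL molecules per leaflet")
    n_to: int = Field(DEFAULT_N_TO, ge=0, description="TO molecules in the core")
    box: tuple[float, float, float] = (6.0, 6.0, 14.0)
    plane_z: float = Field(2.0, gt=0, description="leaflet planes at +-plane_z")
    peptide: str = _DEFAULT_PEPTIDE
    planted_depth: float = -0.5     # nm, negative = toward the TO core
    leaflet: str = "upper"          # 'upper' | 'lower'
    planted_contacts: int = Field(2, ge=0)
    hbond_fraction: float = Field(0.105, ge=0.0, le=1.0)
    jitter_sd: float = Field(0.02, ge=0.0, description="P-atom z jitter SD")
    n_frames: int = Field(100, ge=1)
    seed: int = 0
    flatten_depth: bool = True
    include_ions: bool = False

    @model_validator(mode="after")
    def _consistency(self):
        if self.leaflet not in ("upper", "lower"):
            raise ValueError("leaflet must be 'upper' or 'lower'")
        if self.n_to == 0:
            object.__setattr__(self, "hbond_fraction", 0.0)
            object.__setattr__(self, "planted_contacts", 0)
        if self.planted_contacts > self.n_to:
            raise ValueError("planted_contacts cannot exceed n_to")
        if self.hbond_fraction > 0 and self.planted_contacts < 1:
            raise ValueError("hydrogen-bond planting shares a contact TO; "
                             "need planted_contacts >= 1 when hbond_fraction > 0")
        return self

    def parsed_peptide(self) -> Peptide:
        return parse_sequence(self.peptide, name="synthetic")


def ideal_helix_coords(p, rise: float = 0.15, twist_deg: float = 100.0,
                       radius: float = 0.23, kink_residue: int | None = None,
                       kink_angle_deg: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix C-alpha backbone coordinates (nm).

    The helix axis runs along x with 0.15 nm rise and 100 degree twist per
    residue (consecutive C-alpha spacing ~0.38 nm).  ``kink_residue``
    bends the axis by ``kink_angle_deg`` (about y) at that residue,
    modelling the helical break that occurs near a Gly.
    """
    length = len(p) if isinstance(p, Peptide) else int(p)
    if length < 1:
        raise ValueError("helix needs at least one residue")
    n = np.arange(length)
    theta = np.radians(n * twist_deg)
    coords = np.column_stack([n * rise, radius * np.cos(theta),
                              radius * np.sin(theta)])
    if kink_residue is not None and kink_angle_deg != 0.0:
        k = kink_residue - 1
        if not 0 <= k < length:
            raise ValueError(f"kink residue {kink_residue} outside sequence")
        a = math.radians(kink_angle_deg)
        rot = np.array([[math.cos(a), 0, math.sin(a)],
                        [0, 1, 0],
                        [-math.sin(a), 0, math.cos(a)]])
        pivot = coords[k]
        coords[k:] = (coords[k:] - pivot) @ rot.T + pivot
    return coords


# TO reduced-atom template: 3 glycerol carbons, 6 ester oxygens,
# 3 truncated tail carbons (local coordinates, nm)
_TO_NAMES = ["C1", "C2", "C3", "O1", "O2", "O3", "O4", "O5", "O6",
             "C4", "C5", "C6"]
_TO_ELEMENTS = ["C", "C", "C", "O", "O", "O", "O", "O", "O", "C", "C", "C"]
_TO_TEMPLATE = np.array([
    [-0.13, 0.00, 0.00], [0.00, 0.00, 0.00], [0.13, 0.00, 0.00],
    [-0.13, 0.12, 0.05], [-0.13, 0.12, -0.05],
    [0.00, 0.12, 0.05], [0.00, 0.12, -0.05],
    [0.13, 0.12, 0.05], [0.13, 0.12, -0.05],
    [-0.13, -0.15, 0.00], [0.00, -0.15, 0.00], [0.13, -0.15, 0.00],
])

# contact-TO layout relative to the anchor C-alpha, for the *upper*
# leaflet (core below, amide donors above); z is mirrored for the lower
# leaflet.  The near atoms are tail carbons; ester oxygens stay >= 0.55 nm
# below the C-alpha so they cannot hydrogen-bond to the amide donors.
_CONTACT_TEMPLATE = np.array([
    [-0.10, 0.05, -0.50], [0.00, 0.08, -0.55], [0.10, 0.05, -0.50],   # C1-3
    [-0.15, 0.00, -0.62], [-0.08, 0.12, -0.62], [0.00, -0.15, -0.64],  # O1-3
    [0.08, 0.12, -0.62], [0.15, 0.00, -0.62], [0.00, 0.15, -0.66],     # O4-6
    [0.00, 0.00, -0.30], [-0.12, -0.08, -0.42], [0.12, -0.08, -0.42],  # C4-6
])

_N_OFFSET = 0.15   # amide N sits this far from the C-alpha, away from core
_H_OFFSET = 0.10   # amide H beyond the N
_HBOND_R = 0.29    # planted donor-acceptor distance (within the cone)
_TO_EXCLUSION = 1.5  # min distance, background TO atom to peptide atom
_CORE_MARGIN = 0.5   # background TO kept this far inside the planes


class OverfilledBoxError(RuntimeError):
    """Background TO placement failed within the attempt budget."""


def _peptide_atoms(cfg: GeneratorConfig, pep: Peptide, plane: float, sign: float):
    """C-alpha / N / H coordinates and bookkeeping arrays for the peptide."""
    length = len(pep)
    ca = ideal_helix_coords(pep)
    box = np.asarray(cfg.box)
    ca[:, 0] += (box[0] - ca[-1, 0]) / 2.0   # centre the helix in x
    ca[:, 1] += box[1] / 2.0
    if cfg.flatten_depth:
        ca[:, 2] = plane + sign * cfg.planted_depth
    else:
        ca[:, 2] += plane + sign * cfg.planted_depth
    n_at = ca.copy()
    n_at[:, 2] += sign * _N_OFFSET           # away from the core
    h_at = n_at.copy()
    h_at[:, 2] += sign * _H_OFFSET
    coords = np.concatenate([ca, n_at, h_at])
    names = ["CA"] * length + ["N"] * length + ["H"] * length
    elements = ["C"] * length + ["N"] * length + ["H"] * length
    residue = np.tile(np.arange(1, length + 1), 3)
    donor_parent_local = np.full(3 * length, -1, dtype=int)
    donor_parent_local[2 * length:] = np.arange(length, 2 * length)
    return coords, names, elements, residue, donor_parent_local


def build_frame(cfg: GeneratorConfig, frame_index: int) -> TrilayerFrame:
    """Deterministically build one trilayer frame (see module docstring)."""
    rng = np.random.default_rng((cfg.seed, 7919, frame_index))
    # hydrogen-bond coin flip is the first draw so the ground-truth record
    # can replay it without re-simulating the placement stream
    bonded = bool(rng.random() < cfg.hbond_fraction)
    box = np.asarray(cfg.box, dtype=float)
    pep = cfg.parsed_peptide()
    sign = 1.0 if cfg.leaflet == "upper" else -1.0
    plane_pep = sign * cfg.plane_z

    coords_list, name_list, elem_list = [], [], []
    class_list, molid_list, res_list, donor_list = [], [], [], []
    next_mol = 1

    # --- phospholipids: grid per leaflet, jittered phosphorus z
    grid = math.ceil(math.sqrt(cfg.n_pl))
    for leaf_sign in (1.0, -1.0):
        placed = 0
        for gy in range(grid):
            for gx in range(grid):
                if placed >= cfg.n_pl:
                    break
                x = (gx + 0.5) * box[0] / grid + rng.uniform(-0.05, 0.05)
                y = (gy + 0.5) * box[1] / grid + rng.uniform(-0.05, 0.05)
                pz = leaf_sign * cfg.plane_z + rng.normal(0.0, cfg.jitter_sd)
                # P head plus two chain carbons pointing toward the core
                coords_list.extend([[x, y, pz],
                                    [x, y, pz - leaf_sign * 0.25],
                                    [x, y, pz - leaf_sign * 0.50]])
                name_list.extend(["P", "C1", "C2"])
                elem_list.extend(["P", "C", "C"])
                class_list.extend(["PL"] * 3)
                molid_list.extend([next_mol] * 3)
                res_list.extend([0] * 3)
                donor_list.extend([-1] * 3)
                next_mol += 1
                placed += 1

    # --- peptide
    pep_mol = next_mol
    next_mol += 1
    pcoords, pnames, pelems, pres, pdonor = _peptide_atoms(cfg, pep, plane_pep, sign)
    offset = len(coords_list)
    coords_list.extend(pcoords.tolist())
    name_list.extend(pnames)
    elem_list.extend(pelems)
    class_list.extend(["peptide"] * len(pnames))
    molid_list.extend([pep_mol] * len(pnames))
    res_list.extend(pres.tolist())
    donor_list.extend([d + offset if d >= 0 else -1 for d in pdonor])
    length = len(pep)
    ca_coords = pcoords[:length]
    n_coords = pcoords[length:2 * length]

    # --- contact TO molecules hung below anchor residues
    anchors = np.unique(np.linspace(max(1, length // 4),
                                    max(1, (3 * length) // 4),
                                    max(cfg.planted_contacts, 1)).round().astype(int))
    while anchors.size < cfg.planted_contacts:   # tiny peptides: spread fallback
        anchors = np.unique(np.concatenate([anchors, [min(length, anchors[-1] + 1)]]))
    anchors = anchors[:cfg.planted_contacts]
    for c, anchor in enumerate(anchors):
        local = _CONTACT_TEMPLATE.copy()
        local[:, :2] += rng.uniform(-0.03, 0.03, size=2)
        local[:, 2] *= sign
        to_xyz = ca_coords[anchor - 1] + local
        if c == 0 and bonded:
            # first ester oxygen moved into ideal bond geometry with the
            # anchor residue's amide donor (collinear N-H...O, r = 0.29 nm)
            to_xyz[3] = n_coords[anchor - 1] + np.array([0.0, 0.0, sign * _HBOND_R])
        coords_list.extend(to_xyz.tolist())
        name_list.extend(_TO_NAMES)
        elem_list.extend(_TO_ELEMENTS)
        class_list.extend(["TO"] * len(_TO_NAMES))
        molid_list.extend([next_mol] * len(_TO_NAMES))
        res_list.extend([0] * len(_TO_NAMES))
        donor_list.extend([-1] * len(_TO_NAMES))
        next_mol += 1

    # --- background TO in the core slab, kept away from the peptide
    slab = cfg.plane_z - _CORE_MARGIN
    pep_xyz = pcoords
    n_background = cfg.n_to - cfg.planted_contacts
    for _ in range(n_background):
        for attempt in range(2000):
            centre = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                               rng.uniform(-slab, slab)])
            to_xyz = centre + _TO_TEMPLATE
            d = pep_xyz[:, None, :] - to_xyz[None, :, :]
            d -= box * np.round(d / box)
            if np.sqrt((d ** 2).sum(-1)).min() >= _TO_EXCLUSION:
                break
        else:
            raise OverfilledBoxError(
                "could not place a background TO molecule away from the "
                "peptide; box too small for the requested composition")
        coords_list.extend(to_xyz.tolist())
        name_list.extend(_TO_NAMES)
        elem_list.extend(_TO_ELEMENTS)
        class_list.extend(["TO"] * len(_TO_NAMES))
        molid_list.extend([next_mol] * len(_TO_NAMES))
        res_list.extend([0] * len(_TO_NAMES))
        donor_list.extend([-1] * len(_TO_NAMES))
        next_mol += 1

    if cfg.include_ions:
        for elem in ("NA", "CL", "NA", "CL"):
            z = rng.uniform(cfg.plane_z + 0.8, box[2] / 2 - 0.5)
            coords_list.append([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                                z if rng.random() < 0.5 else -z])
            name_list.append(elem)
            elem_list.append(elem.capitalize())
            class_list.append("ion")
            molid_list.append(next_mol)
            res_list.append(0)
            donor_list.append(-1)
            next_mol += 1

    names = np.array(name_list)
    return TrilayerFrame(
        coords=np.array(coords_list),
        box=box,
        mol_class=np.array(class_list),
        mol_id=np.array(molid_list, dtype=int),
        residue_index=np.array(res_list, dtype=int),
        element=np.array(elem_list),
        atom_name=names,
        is_phosphorus=(np.array(class_list) == "PL") & (names == "P"),
        is_calpha=names == "CA",
        is_acceptor=(np.array(class_list) == "TO")
                    & np.char.startswith(names, "O"),
        donor_parent=np.array(donor_list, dtype=int),
    )


def _hbond_outcomes(cfg: GeneratorConfig) -> list[int]:
    """Replay the per-frame Bernoulli draws (first draw of each frame rng)."""
    outcomes = []
    for t in range(cfg.n_frames):
        rng = np.random.default_rng((cfg.seed, 7919, t))
        outcomes.append(int(rng.random() < cfg.hbond_fraction))
    return outcomes


def generate_frames(cfg: GeneratorConfig) -> tuple[TrilayerTrajectory, dict]:
    """Generate the full trajectory in memory plus its ground-truth record."""
    frames = [build_frame(cfg, t) for t in range(cfg.n_frames)]
    outcomes = _hbond_outcomes(cfg)
    truth = {
        "seed": cfg.seed,
        "n_frames": cfg.n_frames,
        "peptide": cfg.peptide,
        "leaflet": cfg.leaflet,
        "plane_z": cfg.plane_z,
        "planted_depth": cfg.planted_depth,
        "planted_contacts": cfg.planted_contacts,
        "hbond_fraction": cfg.hbond_fraction,
        "hbond_outcomes": outcomes,
        "realized_hbond_fraction": (sum(outcomes) / len(outcomes)),
        "jitter_sd": cfg.jitter_sd,
    }
    return TrilayerTrajectory(frames), truth


def generate_trajectory(cfg: GeneratorConfig, out_pdb, truth_json=None
                        ) -> tuple[TrilayerTrajectory, dict]:
    """Generate and write a multi-model PDB plus a ground-truth JSON sidecar."""
    traj, truth = generate_frames(cfg)
    pep = cfg.parsed_peptide()
    codes = {n: r.code for n, r in enumerate(pep.residues, 1)}
    write_trajectory_pdb(traj, out_pdb, peptide_codes=codes)
    if truth_json is not None:
        with open(truth_json, "w") as fh:
            json.dump(truth, fh, indent=1)
    return traj, truth
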