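"""Trilayer trajectory statistics for peptide/lipid systems.

The model system is a phospholipid (PL) / triolein (TO) trilayer emulating
the surface of a triglyceride-rich lipoprotein: two phospholipid
monolayers whose phosphorus atoms define an upper and a lower plane, a TO
core between them, and one or more helical peptides bound at a monolayer.
Analyses operate on frames of typed atoms with periodic boundaries
(orthorhombic box, minimum image in all three axes):

* leaflet assignment by z relative to the phosphorus midplane,
* per-residue C-alpha insertion depth relative to the leaflet's
  phosphorus plane (negative = toward the TO core),
* peptide-TO hydrogen-bond timeseries under the distance/angle cone
  criterion r <= r_max0 - curvature * theta^2,
* residue-wise TO coordination number via the rational switching
  function s = sum (1 - (r/r0)^6) / (1 - (r/r0)^12), reported as the
  maximum over TO molecules,
* mean count of TO molecules in whole-peptide contact.

All coordinates are in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrilayerFrame",
    "TrilayerTrajectory",
    "HBondCriterion",
    "CoordinationParams",
    "LeafletAssignment",
    "DepthProfile",
    "HBondSeries",
    "DegenerateGeometryError",
    "assign_leaflets",
    "insertion_depth",
    "hbond_series",
    "tg_coordination",
    "tg_contact_count",
    "coordination_term",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "DEFAULT_CLASS_MAP",
]


class DegenerateGeometryError(ValueError):
    """Raised when leaflets cannot be separated (e.g. a single plane)."""


@dataclass
class TrilayerFrame:
    """One frame of typed atoms.

    ``mol_class`` entries are in {"PL", "TO", "peptide", "ion", "water"};
    ``mol_id`` groups atoms into molecules; ``residue_index`` is the
    1-based residue for peptide atoms (0 elsewhere).  Roles are boolean
    masks; ``donor_parent[k]`` is the index of the heavy donor atom of
    hydrogen ``k`` (-1 for non-donor-H atoms).
    """

    coords: np.ndarray                  # (n, 3) nm
    box: np.ndarray                     # (3,) nm
    mol_class: np.ndarray               # (n,) str
    mol_id: np.ndarray                  # (n,) int
    residue_index: np.ndarray           # (n,) int
    element: np.ndarray                 # (n,) str
    atom_name: np.ndarray               # (n,) str
    is_phosphorus: np.ndarray           # (n,) bool
    is_calpha: np.ndarray               # (n,) bool
    is_acceptor: np.ndarray             # (n,) bool
    donor_parent: np.ndarray            # (n,) int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.coords)
        for name in ("mol_class", "mol_id", "residue_index", "element",
                     "atom_name", "is_phosphorus", "is_calpha",
                     "is_acceptor", "donor_parent"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def peptide_ids(self) -> np.ndarray:
        return np.unique(self.mol_id[self.mol_class == "peptide"])

    def translated(self, shift) -> "TrilayerFrame":
        """Rigidly translated copy (analysis results must be invariant)."""
        out = TrilayerFrame(self.coords + np.asarray(shift, dtype=float),
                            self.box, self.mol_class, self.mol_id,
                            self.residue_index, self.element, self.atom_name,
                            self.is_phosphorus, self.is_calpha,
                            self.is_acceptor, self.donor_parent)
        return out


class TrilayerTrajectory:
    """Sequence of frames sharing a topology."""

    def __init__(self, frames: list[TrilayerFrame]):
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        self.frames = list(frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, idx):
        return self.frames[idx]


@dataclass(frozen=True)
class HBondCriterion:
    """Distance/angle cone criterion for a hydrogen bond.

    A donor-acceptor pair is bonded iff
    ``r(donor_heavy, acceptor) <= r_max0 - curvature * theta**2`` with
    ``theta`` the deviation (degrees) of the donor-H from the
    donor->acceptor axis.
    """

    r_max0: float = 0.33        # nm
    curvature: float = 0.00044  # nm / deg^2


@dataclass(frozen=True)
class CoordinationParams:
    r0: float = 0.4             # nm switching radius
    exponents: tuple[int, int] = (6, 12)

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


@dataclass(frozen=True)
class LeafletAssignment:
    plane_upper: float
    plane_lower: float
    pl_leaflet: dict            # PL mol_id -> 'upper' | 'lower'
    peptide_leaflet: dict       # peptide mol_id -> 'upper' | 'lower'


@dataclass(frozen=True)
class DepthProfile:
    """Per-(leaflet, residue) mean/SD of signed insertion depth in nm.

    Sign convention: negative = toward the TO core.  ``mean[leaflet]`` and
    ``sd[leaflet]`` are arrays over ``residues[leaflet]``; a leaflet is
    present only if the peptide was assigned to it in at least one frame.
    """

    residues: dict
    mean: dict
    sd: dict
    n_frames: dict


@dataclass(frozen=True)
class HBondSeries:
    counts: dict                # leaflet -> (n_frames,) int array
    percent_bonded: float       # % of frames with >= 1 bond (pooled)
    status: str = "ok"

    @property
    def total_counts(self) -> np.ndarray:
        arrs = list(self.counts.values())
        return np.sum(arrs, axis=0) if arrs else np.zeros(0, dtype=int)


# ---------------------------------------------------------------------------
# geometry helpers

def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) minimum-image distance matrix."""
    d = a[:, None, :] - b[None, :, :]
    d = _min_image(d, box)
    return np.sqrt((d ** 2).sum(axis=-1))


def coordination_term(r, r0: float = 0.4):
    """Switching-function term (1 - (r/r0)^6) / (1 - (r/r0)^12).

    Evaluated in the algebraically equivalent form 1 / (1 + (r/r0)^6),
    which carries the continuity limit 0.5 at r = r0.  The term lies in
    (0, 1] and decreases strictly with r.
    """
    x = np.asarray(r, dtype=float) / r0
    return 1.0 / (1.0 + x ** 6)


# ---------------------------------------------------------------------------
# leaflet assignment

def assign_leaflets(frame: TrilayerFrame) -> LeafletAssignment:
    """Partition PL molecules and peptides into upper/lower leaflets."""
    pz = frame.coords[frame.is_phosphorus, 2]
    if pz.size < 2:
        raise DegenerateGeometryError("need at least 2 phosphorus atoms")
    if np.ptp(pz) == 0:
        raise DegenerateGeometryError("all phosphorus atoms at identical z; "
                                      "single plane cannot be split")
    mid = 0.5 * (pz.max() + pz.min())
    p_idx = np.flatnonzero(frame.is_phosphorus)
    upper_mask = frame.coords[p_idx, 2] >= mid
    if upper_mask.all() or (~upper_mask).all():
        raise DegenerateGeometryError("phosphorus atoms do not split into two leaflets")
    plane_upper = float(frame.coords[p_idx[upper_mask], 2].mean())
    plane_lower = float(frame.coords[p_idx[~upper_mask], 2].mean())

    pl_leaflet = {}
    for idx, up in zip(p_idx, upper_mask):
        pl_leaflet[int(frame.mol_id[idx])] = "upper" if up else "lower"

    peptide_leaflet = {}
    for pid in frame.peptide_ids():
        mask = (frame.mol_id == pid) & frame.is_calpha
        if not mask.any():
            mask = frame.mol_id == pid
        z = frame.coords[mask, 2].mean()
        peptide_leaflet[int(pid)] = ("upper" if abs(z - plane_upper) <= abs(z - plane_lower)
                                     else "lower")
    return LeafletAssignment(plane_upper, plane_lower, pl_leaflet, peptide_leaflet)


def _resolve_peptide(frame: TrilayerFrame, peptide_id):
    ids = frame.peptide_ids()
    if peptide_id is None:
        if len(ids) != 1:
            raise ValueError(f"frame contains {len(ids)} peptides; specify peptide_id")
        return int(ids[0])
    if peptide_id not in ids:
        raise ValueError(f"peptide id {peptide_id} absent from frame")
    return int(peptide_id)


# ---------------------------------------------------------------------------
# insertion depth

def insertion_depth(traj: TrilayerTrajectory, peptide_id=None) -> DepthProfile:
    """Per-residue C-alpha depth relative to the leaflet phosphorus plane.

    For each frame the plane is the mean phosphorus z of the leaflet the
    peptide is assigned to; depth is ``z_CA - plane`` for the upper
    leaflet and ``plane - z_CA`` for the lower, so negative always points
    toward the TO core.
    """
    acc: dict[str, dict[int, list[float]]] = {}
    for frame in traj:
        pid = _resolve_peptide(frame, peptide_id)
        assignment = assign_leaflets(frame)
        leaflet = assignment.peptide_leaflet[pid]
        plane = (assignment.plane_upper if leaflet == "upper"
                 else assignment.plane_lower)
        sign = 1.0 if leaflet == "upper" else -1.0
        mask = (frame.mol_id == pid) & frame.is_calpha
        for ridx, z in zip(frame.residue_index[mask], frame.coords[mask, 2]):
            acc.setdefault(leaflet, {}).setdefault(int(ridx), []).append(
                sign * (float(z) - plane))
    residues, mean, sd, n_frames = {}, {}, {}, {}
    for leaflet, per_res in acc.items():
        rs = sorted(per_res)
        residues[leaflet] = np.array(rs, dtype=int)
        mean[leaflet] = np.array([np.mean(per_res[r]) for r in rs])
        sd[leaflet] = np.array([np.std(per_res[r]) for r in rs])
        n_frames[leaflet] = len(per_res[rs[0]])
    return DepthProfile(residues=residues, mean=mean, sd=sd, n_frames=n_frames)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _frame_hbond_count(frame: TrilayerFrame, crit: HBondCriterion,
                       pid: int) -> int:
    h_idx = np.flatnonzero((frame.donor_parent >= 0) & (frame.mol_id == pid))
    a_idx = np.flatnonzero(frame.is_acceptor & (frame.mol_class == "TO"))
    if h_idx.size == 0 or a_idx.size == 0:
        return 0
    count = 0
    box = frame.box
    for h in h_idx:
        d = frame.donor_parent[h]
        dh = _min_image(frame.coords[h] - frame.coords[d], box)
        da = _min_image(frame.coords[a_idx] - frame.coords[d], box)
        r = np.sqrt((da ** 2).sum(axis=1))
        cos = (da @ dh) / np.maximum(r * np.linalg.norm(dh), 1e-300)
        theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        count += int(np.sum(r <= crit.r_max0 - crit.curvature * theta ** 2))
    return count


def hbond_series(traj: TrilayerTrajectory,
                 crit: HBondCriterion | None = None,
                 peptide_id=None) -> HBondSeries:
    """Peptide-to-TO hydrogen-bond count per (leaflet, frame).

    Donors are the peptide donor hydrogens (with their heavy parents);
    acceptors are the TO ester oxygens.  ``percent_bonded`` is the pooled
    percentage of frames with at least one bond.
    """
    crit = crit or HBondCriterion()
    n = len(traj)
    counts: dict[str, np.ndarray] = {}
    status = "ok"
    for t, frame in enumerate(traj):
        pid = _resolve_peptide(frame, peptide_id)
        has_donors = np.any((frame.donor_parent >= 0) & (frame.mol_id == pid))
        has_acceptors = np.any(frame.is_acceptor & (frame.mol_class == "TO"))
        if not (has_donors and has_acceptors):
            status = "empty"
        assignment = assign_leaflets(frame)
        leaflet = assignment.peptide_leaflet[pid]
        counts.setdefault(leaflet, np.zeros(n, dtype=int))
        counts[leaflet][t] = _frame_hbond_count(frame, crit, pid)
    if status == "empty":
        warnings.warn("no donors or acceptors present in at least one frame; "
                      "hydrogen-bond series is empty there", stacklevel=2)
    total = np.sum(list(counts.values()), axis=0) if counts else np.zeros(n, dtype=int)
    percent = float(100.0 * np.mean(total >= 1))
    return HBondSeries(counts=counts, percent_bonded=percent, status=status)


# ---------------------------------------------------------------------------
# coordination and contacts

def _coordination_matrix(frame: TrilayerFrame, pid: int,
                         params: CoordinationParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(residues, to_ids, S) with S[r, m] = sum of switching terms between
    the atoms of peptide residue r and TO molecule m."""
    pep_mask = frame.mol_id == pid
    to_mask = frame.mol_class == "TO"
    residues = np.unique(frame.residue_index[pep_mask])
    to_ids = np.unique(frame.mol_id[to_mask])
    S = np.zeros((residues.size, to_ids.size))
    if to_ids.size == 0:
        return residues, to_ids, S
    pep_idx = np.flatnonzero(pep_mask)
    to_idx = np.flatnonzero(to_mask)
    r = _pair_distances(frame.coords[pep_idx], frame.coords[to_idx], frame.box)
    terms = coordination_term(r, params.r0)
    res_code = np.searchsorted(residues, frame.residue_index[pep_idx])
    to_code = np.searchsorted(to_ids, frame.mol_id[to_idx])
    np.add.at(S, (res_code[:, None], to_code[None, :]), terms)
    return residues, to_ids, S


def tg_coordination(traj: TrilayerTrajectory, peptide_id=None,
                    params: CoordinationParams | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Residue-wise TO coordination, frame-averaged.

    For each residue the per-frame value is the maximum over TO molecules
    of the switching-function sum over all (residue atom, TO atom) pairs.
    Returns ``(residue_indices, mean_coordination)``; zero when no TO is
    present.
    """
    params = params or CoordinationParams()
    per_frame = []
    residues = None
    for frame in traj:
        pid = _resolve_peptide(frame, peptide_id)
        res, to_ids, S = _coordination_matrix(frame, pid, params)
        residues = res if residues is None else residues
        per_frame.append(S.max(axis=1) if to_ids.size else np.zeros(res.size))
    return residues, np.mean(per_frame, axis=0)


def tg_contact_count(traj: TrilayerTrajectory, peptide_id=None,
                     threshold: float = 0.5,
                     params: CoordinationParams | None = None) -> float:
    """Mean number of TO molecules in whole-peptide contact per frame.

    A TO molecule is in contact when its whole-peptide coordination
    (switching-function sum over all peptide atoms) exceeds ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    params = params or CoordinationParams()
    counts = []
    for frame in traj:
        pid = _resolve_peptide(frame, peptide_id)
        _, to_ids, S = _coordination_matrix(frame, pid, params)
        counts.append(int(np.sum(S.sum(axis=0) > threshold)) if to_ids.size else 0)
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# multi-model PDB I/O (biotite backend)

#: residue-name -> molecule class used when reading PDB trajectories
DEFAULT_CLASS_MAP = {
    "POP": "PL", "POPC": "PL",
    "TRO": "TO", "TRIO": "TO",
    "HOH": "water", "TIP3": "water", "SOL": "water",
    "NA": "ion", "CL": "ion", "SOD": "ion", "CLA": "ion", "K": "ion",
}

_PEPTIDE_RESNAMES = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "NLE": "Nle", "SAR": "Sar", "AIB": "Aib",
    "XR8": "R8", "XS5": "S5", "XB5": "B5", "XS8": "S8",
}
_RESNAME_BY_CODE = {v: k for k, v in _PEPTIDE_RESNAMES.items()}


def write_trajectory_pdb(traj: TrilayerTrajectory, path,
                         peptide_codes: dict | None = None) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates nm -> A).

    ``peptide_codes`` optionally maps residue_index -> residue code for
    proper residue names; unknown residues are written as UNK.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    first = traj[0]
    n = first.n_atoms
    arrays = []
    for frame in traj:
        atoms = struc.AtomArray(n)
        atoms.coord = np.asarray(frame.coords) * 10.0  # nm -> Angstrom
        chain, res_id, res_name = [], [], []
        for k in range(n):
            cls = frame.mol_class[k]
            if cls == "PL":
                chain.append("L")
                res_id.append(int(frame.mol_id[k]))
                res_name.append("POP")
            elif cls == "TO":
                chain.append("T")
                res_id.append(int(frame.mol_id[k]))
                res_name.append("TRO")
            elif cls == "peptide":
                chain.append("A")
                res_id.append(int(frame.residue_index[k]))
                code = (peptide_codes or {}).get(int(frame.residue_index[k]))
                res_name.append(_RESNAME_BY_CODE.get(code, "UNK"))
            elif cls == "water":
                chain.append("W")
                res_id.append(int(frame.mol_id[k]))
                res_name.append("HOH")
            else:
                chain.append("I")
                res_id.append(int(frame.mol_id[k]))
                res_name.append(str(frame.atom_name[k]).upper())
        atoms.chain_id = np.array(chain)
        atoms.res_id = np.array(res_id)
        atoms.res_name = np.array(res_name)
        atoms.atom_name = np.array(frame.atom_name, dtype="U6")
        atoms.element = np.array([e.upper() for e in frame.element], dtype="U2")
        atoms.hetero = np.array([c != "peptide" for c in frame.mol_class])
        atoms.box = np.diag(np.asarray(frame.box) * 10.0)
        arrays.append(atoms)
    stack = struc.stack(arrays)
    stack.box = np.array([np.diag(np.asarray(f.box) * 10.0) for f in traj])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _roles_from_names(mol_class, atom_name, residue_index):
    n = len(mol_class)
    is_p = np.array([c == "PL" and a == "P" for c, a in zip(mol_class, atom_name)])
    is_ca = np.array([c == "peptide" and a == "CA"
                      for c, a in zip(mol_class, atom_name)])
    is_acc = np.array([c == "TO" and a.startswith("O")
                       for c, a in zip(mol_class, atom_name)])
    donor_parent = np.full(n, -1, dtype=int)
    # peptide amide H: parent N of the same residue
    n_of_res = {}
    for k in range(n):
        if mol_class[k] == "peptide" and atom_name[k] == "N":
            n_of_res[int(residue_index[k])] = k
    for k in range(n):
        if mol_class[k] == "peptide" and atom_name[k] in ("H", "HN"):
            parent = n_of_res.get(int(residue_index[k]))
            if parent is not None:
                donor_parent[k] = parent
    return is_p, is_ca, is_acc, donor_parent


def read_trajectory_pdb(path, class_map: dict | None = None) -> TrilayerTrajectory:
    """Read a multi-model PDB trajectory written by :func:`write_trajectory_pdb`.

    Molecule classes are inferred from residue names via ``class_map``
    (default :data:`DEFAULT_CLASS_MAP`; unmapped residue names are treated
    as peptide).  Atom roles come from atom names: PL ``P`` = phosphorus,
    peptide ``CA``/``N``/``H``, TO ``O*`` = acceptors.
    """
    from biotite.structure.io.pdb import PDBFile

    cmap = dict(DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update(class_map)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    boxes = stack.box
    frames = []
    res_name = stack.res_name
    atom_name = stack.atom_name
    chain_id = stack.chain_id
    res_id = stack.res_id
    element = stack.element
    n = stack.array_length()

    mol_class = np.array([cmap.get(rn, "peptide") for rn in res_name])
    # molecule ids: one per residue for non-peptide, one per chain for peptide
    mol_id = np.zeros(n, dtype=int)
    key_to_id: dict = {}
    next_id = 1
    for k in range(n):
        key = (("chain", chain_id[k]) if mol_class[k] == "peptide"
               else (chain_id[k], int(res_id[k])))
        if key not in key_to_id:
            key_to_id[key] = next_id
            next_id += 1
        mol_id[k] = key_to_id[key]
    residue_index = np.where(mol_class == "peptide", res_id, 0).astype(int)
    is_p, is_ca, is_acc, donor_parent = _roles_from_names(mol_class, atom_name,
                                                          residue_index)
    for m in range(stack.stack_depth()):
        box = np.diag(boxes[m]) / 10.0 if boxes is not None else np.full(3, 1e6)
        frames.append(TrilayerFrame(
            coords=stack.coord[m] / 10.0,
            box=box,
            mol_class=mol_class,
            mol_id=mol_id,
            residue_index=residue_index,
            element=element,
            atom_name=atom_name,
            is_phosphorus=is_p,
            is_calpha=is_ca,
            is_acceptor=is_acc,
            donor_parent=donor_parent,
        ))
    return TrilayerTrajectory(frames)
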