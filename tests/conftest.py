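"""Shared fixtures: catalog peptides and randomized small trilayer frames."""

import numpy as np
import pytest

from staplekit import catalog
from staplekit.trilayer import TrilayerFrame


@pytest.fixture
def p8():
    return catalog.p8()


@pytest.fixture
def sp1():
    return catalog.sp1()


@pytest.fixture
def sp2():
    return catalog.sp2()


@pytest.fixture
def sp2a():
    return catalog.sp2a()


@pytest.fixture
def d6pv():
    return catalog.d6pv()


def make_random_frame(rng, n_pl_per_leaflet=4, n_to=3, n_res=4,
                      box=(5.0, 5.0, 10.0)):
    """A structurally valid trilayer frame with fully random coordinates.

    Used to exercise the analysis operators against brute-force oracles on
    arbitrary geometry (not generator output): PL phosphorus atoms split
    around +-1.5 nm, TO molecules of 4 atoms (2 acceptor O), a peptide of
    n_res residues with CA/N/H atoms anywhere in the box.
    """
    box = np.asarray(box, dtype=float)
    coords, names, elems, classes, mids, res, donor = [], [], [], [], [], [], []
    mol = 1
    for sign in (1.0, -1.0):
        for _ in range(n_pl_per_leaflet):
            xy = rng.uniform(0, box[:2])
            z = sign * 1.5 + rng.normal(0, 0.2)
            coords.append([xy[0], xy[1], z])
            names.append("P"); elems.append("P"); classes.append("PL")
            mids.append(mol); res.append(0); donor.append(-1)
            mol += 1
    for _ in range(n_to):
        centre = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                           rng.uniform(-2.0, 2.0)])
        for k in range(4):
            coords.append(centre + rng.normal(0, 0.2, 3))
            names.append(f"O{k+1}" if k < 2 else f"C{k+1}")
            elems.append("O" if k < 2 else "C")
            classes.append("TO"); mids.append(mol); res.append(0); donor.append(-1)
        mol += 1
    pep_mol = mol
    for r in range(1, n_res + 1):
        base = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                         rng.uniform(-2.5, 2.5)])
        ca_i = len(coords)
        coords.append(base)
        names.append("CA"); elems.append("C"); classes.append("peptide")
        mids.append(pep_mol); res.append(r); donor.append(-1)
        n_i = len(coords)
        coords.append(base + rng.normal(0, 0.1, 3))
        names.append("N"); elems.append("N"); classes.append("peptide")
        mids.append(pep_mol); res.append(r); donor.append(-1)
        coords.append(np.asarray(coords[n_i]) + rng.normal(0, 0.08, 3))
        names.append("H"); elems.append("H"); classes.append("peptide")
        mids.append(pep_mol); res.append(r); donor.append(n_i)
    names = np.array(names)
    classes = np.array(classes)
    return TrilayerFrame(
        coords=np.array(coords), box=box,
        mol_class=classes, mol_id=np.array(mids),
        residue_index=np.array(res), element=np.array(elems),
        atom_name=names,
        is_phosphorus=(classes == "PL") & (names == "P"),
        is_calpha=names == "CA",
        is_acceptor=(classes == "TO") & np.char.startswith(names, "O"),
        donor_parent=np.array(donor),
    )
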