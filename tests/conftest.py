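"""Shared fixtures: compound library, toy pockets, synthetic poses."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D

from cypscreen.pose_io import LigandPose
from cypscreen.receptor_prep import build_oxyheme
from cypscreen.synthetic_fixtures import (
    ResiduePlacement,
    ToyPocketConfig,
    builtin_fixture_library,
    generate_toy_pocket,
)


@pytest.fixture(scope="session")
def library():
    return builtin_fixture_library()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {rec.name: rec for rec in library}


def make_pose(coords, elements, name="probe", rank=1, bonds=()):
    """Build a LigandPose directly from coordinates (test helper)."""
    rw = Chem.RWMol()
    for el in elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(elements))
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, Point3D(*xyz))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    return LigandPose(name=name, rank=rank, mol=mol)


@pytest.fixture
def anchored_pocket():
    """Toy pocket with the canonical anchoring residues (ASP301, GLU216, PHE120)."""
    cfg = ToyPocketConfig(
        seed=11,
        residues=(
            ResiduePlacement("ASP", 8.0, (0.8, 0.0, 0.6), res_seq=301),
            ResiduePlacement("GLU", 8.0, (-0.8, 0.0, 0.6), res_seq=216),
            ResiduePlacement("PHE", 7.0, (0.0, 0.8, 0.6), res_seq=120),
        ),
    )
    pocket, scaffold = generate_toy_pocket(cfg)
    return build_oxyheme(pocket), scaffold


@pytest.fixture
def bare_pocket():
    cfg = ToyPocketConfig(seed=5, residues=(), axial_cys=True)
    pocket, scaffold = generate_toy_pocket(cfg)
    return build_oxyheme(pocket), scaffold
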