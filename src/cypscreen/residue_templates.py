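"""Idealized amino-acid side-chain templates as internal coordinates.

Each side-chain atom beyond CB is defined by (name, (ref1, ref2, ref3), bond Å,
angle deg, torsion deg) where the torsion is ref1-ref2-ref3-new and references
are atoms already placed (backbone or earlier side-chain atoms).  Torsions use
an extended-rotamer default.  Bond lengths/angles follow standard engh-huber
style ideal values (rounded); classification cutoffs downstream tolerate
~0.3 Å, so rounded ideals are adequate.
"""

from __future__ import annotations

import numpy as np

from ._geometry import place_atom
from .errors import MutationError

__all__ = [
    "SIDECHAIN_TEMPLATES",
    "RESIDUE_HEAVY_ATOMS",
    "ANCHOR_ATOMS",
    "build_sidechain",
    "build_backbone",
]

# name, (torsion refs a,b,c), bond, angle, torsion  -- new atom bonded to c
SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.41, 110.5, 180.0)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.0, 180.0)],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.5, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
        ("CD1", ("CA", "CB", "CG1"), 1.53, 113.0, 180.0),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.0, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.53, 110.5, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.53, 110.5, 60.0),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.5, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.5, 180.0),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.23, 121.0, 0.0),
        ("ND2", ("CA", "CB", "CG"), 1.32, 117.0, 180.0),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.5, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.5, 180.0),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.23, 121.0, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.32, 117.0, 180.0),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.5, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.5, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, 180.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.51, 113.8, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
}

_BACKBONE = ("N", "CA", "C", "O")

RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    res: _BACKBONE + (("CB",) if res != "GLY" else ()) + tuple(t[0] for t in tmpl)
    for res, tmpl in SIDECHAIN_TEMPLATES.items()
}

# functional anchor group per residue type, used by the toy-pocket generator
ANCHOR_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SER": ("OG",),
    "CYS": ("SG",),
    "GLN": ("OE1", "NE2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}


def build_sidechain(res_name: str, frame: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Place the side-chain atoms beyond CB in the given N/CA/CB frame.

    ``frame`` must hold coordinates for N, CA and (except glycine) CB; placed
    atoms are added to a copy of it and the new-atom subset is returned.
    """
    if res_name not in SIDECHAIN_TEMPLATES:
        raise MutationError(f"no side-chain template for residue {res_name!r}")
    coords = dict(frame)
    placed: dict[str, np.ndarray] = {}
    for name, (a, b, c), bond, angle, torsion in SIDECHAIN_TEMPLATES[res_name]:
        missing = [r for r in (a, b, c) if r not in coords]
        if missing:
            raise MutationError(f"{res_name}: reference atoms {missing} absent")
        pos = place_atom(coords[a], coords[b], coords[c], bond, angle, torsion)
        coords[name] = pos
        placed[name] = pos
    return placed


def build_backbone() -> dict[str, np.ndarray]:
    """An idealized backbone + CB fragment with CA at the origin.

    Orientation is an arbitrary but fixed local frame; callers rigidly
    transform the result into place.
    """
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    ang = np.deg2rad(111.2)
    c = 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, 0.0)
    cb = place_atom(c, n, ca, 1.53, 110.5, -122.0)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}
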