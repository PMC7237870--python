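"""CYP receptor preparation: stripping, oxy-heme construction, point mutations.

The preparation policy mirrors standard docking prep for cytochromes: keep one
protein chain, delete waters and all heteroatoms except the heme, resolve
alternate locations to the highest occupancy, then model the reactive
compound-I state by adding an axial oxygen on the distal side of the porphyrin
plane at a fixed Fe-O distance (default 1.97 Å).  Allelic variants are built
by swapping side chains beyond CB for idealized templates (no force-field
minimization; a steric-clash report is available instead).  Hydrogens are
never added — downstream interaction detection is heavy-atom based.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from ._geometry import fit_plane, rotation_between
from .errors import MutationError, ReceptorError
from .residue_templates import RESIDUE_HEAVY_ATOMS, build_sidechain

__all__ = [
    "Atom",
    "HemeModel",
    "ReceptorModel",
    "MutationSpec",
    "SearchBox",
    "load_receptor",
    "build_oxyheme",
    "apply_point_mutations",
    "compute_search_box",
    "steric_clashes",
    "write_pdb",
    "DEFAULT_FE_O_DISTANCE",
    "FLEXIBLE_RESIDUES",
]

DEFAULT_FE_O_DISTANCE = 1.97
PYRROLE_N_NAMES = ("NA", "NB", "NC", "ND")
AXIAL_O_NAME = "OXY"

# side-chain-flexible residues used when configuring an external docking engine
FLEXIBLE_RESIDUES = (112, 120, 211, 215, 216, 221, 244, 296, 297, 301, 304, 483)

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    element: str
    name: str
    pos: np.ndarray
    res_name: str
    res_seq: int
    chain: str
    het: bool = False

    def copy(self) -> "Atom":
        return Atom(self.element, self.name, self.pos.copy(), self.res_name,
                    self.res_seq, self.chain, self.het)


@dataclass
class HemeModel:
    """Porphyrin plane geometry: Fe, the 4 pyrrole N, macrocycle, axial O."""

    fe_position: np.ndarray
    pyrrole_n: np.ndarray  # (4, 3)
    macrocycle: np.ndarray  # (m, 3)
    plane_normal: np.ndarray
    axial_oxygen: np.ndarray | None = None
    fe_o_distance: float | None = None

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom]) -> "HemeModel":
        by_name = {a.name: a for a in atoms}
        fe = by_name.get("FE")
        if fe is None:
            raise ReceptorError("heme group has no FE atom")
        missing = [n for n in PYRROLE_N_NAMES if n not in by_name]
        if missing:
            raise ReceptorError(f"heme group missing pyrrole nitrogens {missing}")
        pyrrole = np.array([by_name[n].pos for n in PYRROLE_N_NAMES])
        macro = np.array(
            [a.pos for a in atoms if a.name not in PYRROLE_N_NAMES + ("FE", AXIAL_O_NAME)]
        ).reshape(-1, 3)
        _, normal, max_dev = fit_plane(pyrrole)
        if max_dev > 0.5:
            raise ReceptorError(
                f"pyrrole nitrogens deviate {max_dev:.2f} Å from a common plane"
            )
        axial = by_name.get(AXIAL_O_NAME)
        model = cls(
            fe_position=fe.pos.copy(),
            pyrrole_n=pyrrole,
            macrocycle=macro,
            plane_normal=normal,
        )
        if axial is not None:
            model.axial_oxygen = axial.pos.copy()
            model.fe_o_distance = float(np.linalg.norm(axial.pos - fe.pos))
        return model


@dataclass
class ReceptorModel:
    atoms: list[Atom]
    heme: HemeModel | None = None
    provenance: list[str] = field(default_factory=list)

    def copy(self) -> "ReceptorModel":
        return ReceptorModel(
            [a.copy() for a in self.atoms],
            copy.deepcopy(self.heme),
            list(self.provenance),
        )

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms]).reshape(-1, 3)

    def residue_atoms(self, res_seq: int, chain: str | None = None) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.res_seq == res_seq and (chain is None or a.chain == chain)
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ReceptorModel":
        """Rigidly transformed copy (used by invariance checks)."""
        r = self.copy()
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for a in r.atoms:
            a.pos = rot @ a.pos + t
        if r.heme is not None:
            h = r.heme
            h.fe_position = rot @ h.fe_position + t
            h.pyrrole_n = h.pyrrole_n @ rot.T + t
            if h.macrocycle.size:
                h.macrocycle = h.macrocycle @ rot.T + t
            h.plane_normal = rot @ h.plane_normal
            if h.axial_oxygen is not None:
                h.axial_oxygen = rot @ h.axial_oxygen + t
        return r


@dataclass(frozen=True)
class MutationSpec:
    """List of (chain, residue number, wild-type code, mutant code)."""

    mutations: tuple[tuple[str, int, str, str], ...]

    @classmethod
    def parse(cls, items: Iterable[str], chain: str = "A") -> "MutationSpec":
        """Parse strings like 'F120I' (one-letter) using the given chain."""
        one2three = {
            "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
            "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
            "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
            "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
        }
        out = []
        for item in items:
            wt, num, mut = item[0], int(item[1:-1]), item[-1]
            out.append((chain, num, one2three[wt], one2three[mut]))
        return cls(tuple(out))


@dataclass(frozen=True)
class SearchBox:
    center: tuple[float, float, float]
    extents: tuple[float, float, float]

    def __post_init__(self):
        if any(e <= 0 for e in self.extents):
            raise ValueError(f"search box extents must be positive: {self.extents}")

    def contains(self, point) -> bool:
        c, e = np.asarray(self.center), np.asarray(self.extents)
        return bool(np.all(np.abs(np.asarray(point) - c) <= e / 2 + 1e-9))


def _structure_to_atoms(structure: gemmi.Structure, chain_id: str) -> list[Atom]:
    structure.remove_alternative_conformations()
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [ch.name for ch in model]
        raise ReceptorError(f"chain {chain_id!r} not found (have {available})")
    atoms: list[Atom] = []
    for res in chain:
        het = res.het_flag == "H"
        for at in res:
            atoms.append(
                Atom(
                    element=at.element.name.upper(),
                    name=at.name,
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain=chain_id,
                    het=het,
                )
            )
    return atoms


def load_receptor(path, chain: str = "A") -> ReceptorModel:
    """Read a PDB file and return a stripped single-chain receptor.

    Waters and all heteroatoms except HEM are removed; alternate locations are
    resolved to the highest occupancy; the HEM group (if any) becomes a
    :class:`HemeModel` without an axial oxygen.
    """
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    atoms = _structure_to_atoms(structure, chain)
    kept = [a for a in atoms if not (a.het and a.res_name != "HEM") and a.res_name != "HOH"]
    heme_atoms = [a for a in kept if a.res_name == "HEM"]
    heme = None
    if heme_atoms:
        heme = HemeModel.from_atoms(heme_atoms)
    else:
        warnings.warn(f"{path}: no HEM group found; heme absent", stacklevel=2)
    n_dropped = len(atoms) - len(kept)
    model = ReceptorModel(
        atoms=kept,
        heme=heme,
        provenance=[f"source={path.name}", f"chain={chain}", f"stripped_het_atoms={n_dropped}"],
    )
    if not np.isfinite(model.coords()).all():
        raise ReceptorError(f"{path}: non-finite coordinates")
    return model


def build_oxyheme(
    receptor: ReceptorModel, distance: float = DEFAULT_FE_O_DISTANCE
) -> ReceptorModel:
    """Add the compound-I axial oxygen at ``distance`` Å from Fe.

    The oxygen is placed along the porphyrin plane normal through Fe on the
    distal side: opposite the axial cysteine sulfur when one is within 3.5 Å
    of Fe, otherwise on the side with fewer protein atoms within 5 Å.
    Idempotent: if an axial oxygen at this distance already exists the
    receptor is returned unchanged.
    """
    if receptor.heme is None:
        raise ReceptorError("cannot build oxy-heme: receptor has no heme")
    heme = receptor.heme
    if heme.axial_oxygen is not None and heme.fe_o_distance is not None:
        if abs(heme.fe_o_distance - distance) <= 1e-6:
            return receptor
        raise ReceptorError(
            f"axial oxygen already present at {heme.fe_o_distance:.3f} Å"
        )
    r = receptor.copy()
    heme = r.heme
    fe = heme.fe_position
    normal = heme.plane_normal

    sign = None
    sg_atoms = [
        a for a in r.atoms
        if a.res_name == "CYS" and a.name == "SG"
        and np.linalg.norm(a.pos - fe) <= 3.5
    ]
    if sg_atoms:
        sg = min(sg_atoms, key=lambda a: np.linalg.norm(a.pos - fe))
        sign = -1.0 if np.dot(normal, sg.pos - fe) > 0 else 1.0
    else:
        protein = np.array(
            [a.pos for a in r.atoms if a.res_name != "HEM"]
        ).reshape(-1, 3)
        counts = []
        for s in (1.0, -1.0):
            candidate = fe + s * distance * normal
            n_close = (
                int((np.linalg.norm(protein - candidate, axis=1) <= 5.0).sum())
                if protein.size
                else 0
            )
            counts.append(n_close)
        sign = 1.0 if counts[0] <= counts[1] else -1.0

    o_pos = fe + sign * distance * normal
    heme_chain = next(a.chain for a in r.atoms if a.res_name == "HEM")
    heme_seq = next(a.res_seq for a in r.atoms if a.res_name == "HEM")
    r.atoms.append(
        Atom("O", AXIAL_O_NAME, o_pos, "HEM", heme_seq, heme_chain, het=True)
    )
    heme.axial_oxygen = o_pos
    heme.fe_o_distance = float(np.linalg.norm(o_pos - fe))
    r.provenance.append(f"oxyheme_fe_o={distance:.3f}")
    return r


def apply_point_mutations(receptor: ReceptorModel, spec: MutationSpec) -> ReceptorModel:
    """Swap side chains beyond CB for idealized mutant templates.

    Backbone and CB coordinates are untouched; the residue is renamed.  An
    identity mutation leaves the residue bitwise unchanged.  The wild-type
    code in the spec must match the residue found at that position.
    """
    r = receptor.copy()
    for chain, res_seq, wt, mut in spec.mutations:
        res_atoms = [a for a in r.atoms if a.res_seq == res_seq and a.chain == chain]
        if not res_atoms:
            raise MutationError(f"no residue {res_seq} in chain {chain}")
        found = res_atoms[0].res_name
        if found != wt:
            raise MutationError(
                f"wild-type mismatch at {chain}{res_seq}: expected {wt}, found {found}"
            )
        if mut == wt:
            continue
        if mut not in RESIDUE_HEAVY_ATOMS:
            raise MutationError(f"no template for mutant residue {mut}")
        by_name = {a.name: a for a in res_atoms}
        for req in ("N", "CA"):
            if req not in by_name:
                raise MutationError(f"{chain}{res_seq}: backbone atom {req} missing")
        keep_names = _BACKBONE_NAMES | ({"CB"} if mut != "GLY" else set())
        if mut != "GLY" and "CB" not in by_name:
            raise MutationError(f"{chain}{res_seq}: CB required to graft {mut} side chain")
        r.atoms = [
            a
            for a in r.atoms
            if not (a.res_seq == res_seq and a.chain == chain and a.name not in keep_names)
        ]
        frame = {n: by_name[n].pos for n in ("N", "CA", "CB") if n in by_name}
        new_atoms = build_sidechain(mut, frame) if mut not in ("GLY", "ALA") else {}
        insert_at = max(
            i for i, a in enumerate(r.atoms) if a.res_seq == res_seq and a.chain == chain
        ) + 1
        for offset, (name, pos) in enumerate(new_atoms.items()):
            r.atoms.insert(
                insert_at + offset,
                Atom(name[0], name, pos, mut, res_seq, chain, het=False),
            )
        for a in r.atoms:
            if a.res_seq == res_seq and a.chain == chain:
                a.res_name = mut
        r.provenance.append(f"mutation={wt}{res_seq}{mut}")
    return r


def steric_clashes(
    receptor: ReceptorModel, cutoff: float = 2.2
) -> list[tuple[Atom, Atom, float]]:
    """Non-bonded heavy-atom pairs closer than ``cutoff`` Å.

    Pairs within one residue, or between backbone atoms of sequence
    neighbours, are treated as bonded and skipped.  This report replaces
    force-field minimization after template-based mutation.
    """
    clashes = []
    atoms = receptor.atoms
    coords = receptor.coords()
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        a, b = atoms[i], atoms[j]
        if a.res_seq == b.res_seq and a.chain == b.chain:
            continue
        if (
            a.chain == b.chain
            and abs(a.res_seq - b.res_seq) == 1
            and a.name in _BACKBONE_NAMES
            and b.name in _BACKBONE_NAMES
        ):
            continue
        clashes.append((a, b, float(np.linalg.norm(a.pos - b.pos))))
    return clashes


def compute_search_box(reference_ligands: Sequence, buffer: float = 8.0) -> SearchBox:
    """Axis-aligned box around reference ligand atoms, each face pushed out by
    ``buffer`` Å (so each extent grows by 2*buffer)."""
    coords = [
        pose.coords() for pose in reference_ligands if pose.coords().shape[0] > 0
    ]
    if not coords:
        raise ValueError("need at least one reference ligand with atoms")
    allc = np.vstack(coords)
    lo, hi = allc.min(axis=0), allc.max(axis=0)
    center = (lo + hi) / 2
    extents = (hi - lo) + 2.0 * buffer
    return SearchBox(center=tuple(center), extents=tuple(extents))


def write_pdb(receptor: ReceptorModel, path) -> None:
    """Write the receptor as plain ATOM/HETATM records (fixed format, stable)."""
    lines = []
    for i, a in enumerate(receptor.atoms, start=1):
        record = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{i:5d} {name}{'':1s}{a.res_name:<3s} {a.chain:1s}"
            f"{a.res_seq:4d}    {a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
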