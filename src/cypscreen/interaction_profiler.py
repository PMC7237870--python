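"""Typed protein-ligand contacts and heme-proximity labels for docked poses.

All criteria are heavy-atom based (receptor preparation adds no hydrogens):

* hydrogen bond: donor-acceptor distance <= 3.5 Å with an antecedent-angle
  proxy (antecedent-donor-acceptor >= 90°) standing in for the explicit
  D-H...A angle;
* ionic: cation-anion heavy-atom distance <= 4.0 Å, with ligand protonation
  states from a pH-7.4 rule model (aliphatic amines +, carboxylates -);
* pi stacking: aromatic ring-centroid distance <= 5.5 Å, inter-plane angle
  classified parallel (<=30°), t_shaped (60-90°) or oblique;
* hydrophobic: closest apolar C-C pair per ligand-atom/residue pair <= 4.0 Å
  (porphyrin carbons count as apolar receptor carbons);
* heme coordination: ligand N/O/S or methylenedioxy carbon within 4.0 Å of Fe.

A pose is *proximal* when any ligand heavy atom lies strictly below 6 Å from
the heme iron, else *distal*.  Only the 6 Å rule is a modelling commitment of
the triage itself; the remaining cutoffs are standard literature values and
are overridable through :class:`ProfilerParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .errors import CypscreenError
from .pose_io import LigandPose
from .receptor_prep import Atom, HemeModel, ReceptorModel
from ._geometry import fit_plane

__all__ = [
    "ProfilerParams",
    "Contact",
    "InteractionProfile",
    "min_heme_distance",
    "detect_interactions",
    "profile_pose",
    "ligand_atom_types",
    "functional_group_label",
]


@dataclass(frozen=True)
class ProfilerParams:
    proximal_cutoff: float = 6.0
    hbond_da_max: float = 3.5
    ionic_max: float = 4.0
    pistack_centroid_max: float = 5.5
    pistack_parallel_max_deg: float = 30.0
    pistack_tshape_min_deg: float = 60.0
    hydrophobic_cc_max: float = 4.0
    heme_coordination_max: float = 4.0

    def __post_init__(self):
        for name in (
            "proximal_cutoff", "hbond_da_max", "ionic_max", "pistack_centroid_max",
            "hydrophobic_cc_max", "heme_coordination_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.proximal_cutoff <= self.heme_coordination_max:
            raise ValueError("proximal_cutoff must exceed heme_coordination_max")


@dataclass(frozen=True)
class Contact:
    """One typed ligand-receptor contact.

    ``residue`` is "RES seq" (e.g. "ASP 301") or "HEM" for heme contacts.
    For pi stacks ``ligand_atom`` is the first atom of the ligand ring and
    ``annotation`` carries the angle class.
    """

    type: str
    ligand_atom: int
    residue: str
    rec_atom: str
    distance: float
    annotation: str | None = None


@dataclass
class InteractionProfile:
    pose: LigandPose
    contacts: list[Contact]
    min_heme_fe_distance: float
    closest_atom_index: int
    closest_atom_element: str
    closest_atom_label: str
    proximity: str  # "proximal" | "distal"


# ---------------------------------------------------------------- ligand side

_CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1,OX1-]")


@dataclass
class LigandTypes:
    donors: set[int] = field(default_factory=set)
    acceptors: set[int] = field(default_factory=set)
    cations: set[int] = field(default_factory=set)
    anions: set[int] = field(default_factory=set)
    hydrophobic: set[int] = field(default_factory=set)
    coordinating: set[int] = field(default_factory=set)
    rings: list[tuple[int, ...]] = field(default_factory=list)
    antecedent: dict[int, int] = field(default_factory=dict)


def _is_aliphatic_amine(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
        return False
    if atom.GetFormalCharge() < 0:
        return False
    if atom.GetDegree() > 3:
        return False
    for bond in atom.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            return False
        other = bond.GetOtherAtom(atom)
        if other.GetAtomicNum() == 6:
            for b2 in other.GetBonds():
                if (
                    b2.GetBondType() == Chem.BondType.DOUBLE
                    and b2.GetOtherAtom(other).GetAtomicNum() in (7, 8)
                ):
                    return False  # amide/amidine nitrogen
    return True


def ligand_atom_types(mol: Chem.Mol) -> LigandTypes:
    """Donor/acceptor/charge/aromatic/hydrophobic typing under the pH-7.4
    rule model: aliphatic amines protonated, carboxylic acids deprotonated,
    phenols neutral."""
    t = LigandTypes()
    carboxylate_o: set[int] = set()
    for match in mol.GetSubstructMatches(_CARBOXYL):
        carboxylate_o.update(i for i in match[1:])

    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        z = atom.GetAtomicNum()
        if z == 6:
            if all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors()):
                t.hydrophobic.add(idx)
            n_oxy = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() == 8)
            if n_oxy >= 2 and not atom.GetIsAromatic():
                t.coordinating.add(idx)  # methylenedioxy-type carbon
            continue
        if z not in (7, 8, 16):
            continue
        t.coordinating.add(idx)
        if z == 16:
            continue
        heavy_neighbors = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if heavy_neighbors:
            t.antecedent[idx] = min(n.GetIdx() for n in heavy_neighbors)

        if idx in carboxylate_o:
            t.anions.add(idx)
            t.acceptors.add(idx)
            continue
        amine = _is_aliphatic_amine(atom)
        if amine:
            t.cations.add(idx)
            t.donors.add(idx)
            continue
        if atom.GetTotalNumHs() >= 1:
            t.donors.add(idx)
        # acceptor: N/O lone-pair bearer (exclude amide N, pyrrole-type n)
        if z == 7:
            if atom.GetIsAromatic() and atom.GetTotalNumHs() >= 1:
                continue
            if atom.GetIsAromatic() and atom.GetDegree() == 3:
                continue
            is_amide = any(
                n.GetAtomicNum() == 6
                and any(
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(n).GetAtomicNum() == 8
                    for b in n.GetBonds()
                )
                for n in atom.GetNeighbors()
            )
            if is_amide:
                continue
        t.acceptors.add(idx)

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            t.rings.append(tuple(ring))
    return t


_FG_VOCAB = (
    "hydroxyl", "carbonyl", "ether/methylenedioxy", "aromatic carbon",
    "aliphatic carbon", "amine", "other",
)


def functional_group_label(mol: Chem.Mol, idx: int) -> str:
    """Coarse functional-group label of one ligand atom, from a fixed vocabulary."""
    atom = mol.GetAtomWithIdx(idx)
    z = atom.GetAtomicNum()
    if z == 7:
        return "amine"
    if z == 8:
        if atom.GetTotalNumHs() >= 1 or atom.GetFormalCharge() < 0:
            return "hydroxyl"
        if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
            return "carbonyl"
        if sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1) >= 2:
            return "ether/methylenedioxy"
        return "other"
    if z == 6:
        return "aromatic carbon" if atom.GetIsAromatic() else "aliphatic carbon"
    return "other"


# -------------------------------------------------------------- receptor side

_SC_DONORS = {
    ("SER", "OG"): "CB", ("THR", "OG1"): "CB", ("TYR", "OH"): "CZ",
    ("TRP", "NE1"): "CD1", ("HIS", "ND1"): "CG", ("HIS", "NE2"): "CD2",
    ("LYS", "NZ"): "CE", ("ARG", "NE"): "CD", ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ", ("ASN", "ND2"): "CG", ("GLN", "NE2"): "CD",
}
_SC_ACCEPTORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "OD1"),
    ("GLN", "OE1"), ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
    ("GLU", "OE2"), ("HIS", "ND1"), ("HIS", "NE2"),
}
_CATIONS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_ANIONS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_AROMATIC_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}
_HYDROPHOBIC_C = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"},
    "PRO": {"CB", "CG", "CD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "THR": {"CG2"},
    "CYS": {"CB"},
}


def _res_id(atom: Atom) -> str:
    return f"{atom.res_name} {atom.res_seq}"


def _receptor_typed_atoms(receptor: ReceptorModel):
    donors, acceptors, cations, anions, hydrophobic = [], [], [], [], []
    by_residue: dict[tuple[str, int, str], dict[str, Atom]] = {}
    for a in receptor.atoms:
        by_residue.setdefault((a.chain, a.res_seq, a.res_name), {})[a.name] = a
    for (chain, seq, res_name), atoms in by_residue.items():
        for name, a in atoms.items():
            key = (res_name, name)
            if name == "N" and res_name not in ("PRO", "HEM"):
                ante = atoms.get("CA")
                donors.append((a, ante))
            if key in _SC_DONORS:
                donors.append((a, atoms.get(_SC_DONORS[key])))
            if name == "O" and res_name != "HEM":
                acceptors.append(a)
            if key in _SC_ACCEPTORS:
                acceptors.append(a)
            if key in _CATIONS:
                cations.append(a)
            if key in _ANIONS:
                anions.append(a)
            if name in _HYDROPHOBIC_C.get(res_name, ()):
                hydrophobic.append(a)
            if res_name == "HEM" and a.element == "C":
                hydrophobic.append(a)
    rings = []
    for (chain, seq, res_name), atoms in by_residue.items():
        for ring_names in _AROMATIC_RINGS.get(res_name, ()):
            ring_atoms = [atoms[n] for n in ring_names if n in atoms]
            if len(ring_atoms) >= 5:
                rings.append((res_name, seq, ring_atoms))
    return donors, acceptors, cations, anions, hydrophobic, rings


# ------------------------------------------------------------------ operations

def min_heme_distance(pose: LigandPose, heme: HemeModel) -> tuple[float, int]:
    """Minimum ligand-heavy-atom to Fe distance; ties broken by lowest index."""
    if heme is None:
        raise CypscreenError("receptor has no heme")
    heavy = pose.heavy_indices()
    if not heavy:
        raise CypscreenError("pose has no heavy atoms")
    coords = pose.coords()[heavy]
    d = np.linalg.norm(coords - heme.fe_position, axis=1)
    best = int(np.argmin(d))  # argmin returns the first (lowest-index) minimum
    return float(d[best]), heavy[best]


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid, normal, _ = fit_plane(coords)
    return centroid, normal


def detect_interactions(
    pose: LigandPose,
    receptor: ReceptorModel,
    params: ProfilerParams = ProfilerParams(),
) -> list[Contact]:
    """All typed contacts between one pose and the prepared receptor.

    Contacts are deduplicated: at most one per atom pair (or ring pair /
    atom-residue pair) per interaction type.
    """
    mol = pose.mol
    lt = ligand_atom_types(mol)
    lig_coords = pose.coords()
    donors, acceptors, cations, anions, hydrophobic, rings = _receptor_typed_atoms(receptor)
    contacts: dict[tuple, Contact] = {}

    def _add(key, contact):
        if key not in contacts or contact.distance < contacts[key].distance:
            contacts[key] = contact

    def _angle_ok(ante_pos, donor_pos, acc_pos) -> bool:
        v1 = ante_pos - donor_pos
        v2 = acc_pos - donor_pos
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < 1e-9:
            return False
        cosang = float(np.dot(v1, v2) / denom)
        return cosang <= 1e-9  # angle >= 90 degrees

    # hydrogen bonds: ligand donor -> receptor acceptor
    for li in sorted(lt.donors):
        for ra in acceptors:
            d = float(np.linalg.norm(lig_coords[li] - ra.pos))
            if d > params.hbond_da_max:
                continue
            ante = lt.antecedent.get(li)
            if ante is not None and not _angle_ok(lig_coords[ante], lig_coords[li], ra.pos):
                continue
            _add(("hbond", li, _res_id(ra), ra.name),
                 Contact("hbond", li, _res_id(ra), ra.name, d))
    # hydrogen bonds: receptor donor -> ligand acceptor
    for rd, ante_atom in donors:
        for li in sorted(lt.acceptors):
            d = float(np.linalg.norm(lig_coords[li] - rd.pos))
            if d > params.hbond_da_max:
                continue
            if ante_atom is not None and not _angle_ok(ante_atom.pos, rd.pos, lig_coords[li]):
                continue
            _add(("hbond", li, _res_id(rd), rd.name),
                 Contact("hbond", li, _res_id(rd), rd.name, d))

    # ionic
    for li, pool in ((lt.cations, anions), (lt.anions, cations)):
        for lidx in sorted(li):
            for ra in pool:
                d = float(np.linalg.norm(lig_coords[lidx] - ra.pos))
                if d <= params.ionic_max:
                    _add(("ionic", lidx, _res_id(ra), ra.name),
                         Contact("ionic", lidx, _res_id(ra), ra.name, d))

    # pi stacking
    for ring in lt.rings:
        lc, ln = _ring_geometry(lig_coords[list(ring)])
        for res_name, seq, ring_atoms in rings:
            rc, rn = _ring_geometry(np.array([a.pos for a in ring_atoms]))
            d = float(np.linalg.norm(lc - rc))
            if d > params.pistack_centroid_max:
                continue
            cosang = abs(float(np.dot(ln, rn)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= params.pistack_parallel_max_deg:
                klass = "parallel"
            elif angle >= params.pistack_tshape_min_deg:
                klass = "t_shaped"
            else:
                klass = "oblique"
            _add(("pi_stack", ring, f"{res_name} {seq}"),
                 Contact("pi_stack", ring[0], f"{res_name} {seq}", "ring", d, klass))

    # hydrophobic: closest apolar C-C per ligand-atom/residue pair
    if hydrophobic and lt.hydrophobic:
        rec_pos = np.array([a.pos for a in hydrophobic])
        lig_idx = sorted(lt.hydrophobic)
        dmat = cdist(lig_coords[lig_idx], rec_pos)
        residues = [_res_id(a) for a in hydrophobic]
        for row, li in enumerate(lig_idx):
            per_res: dict[str, tuple[float, Atom]] = {}
            for col, ra in enumerate(hydrophobic):
                d = float(dmat[row, col])
                rid = residues[col]
                if d <= params.hydrophobic_cc_max and (
                    rid not in per_res or d < per_res[rid][0]
                ):
                    per_res[rid] = (d, ra)
            for rid, (d, ra) in per_res.items():
                _add(("hydrophobic", li, rid),
                     Contact("hydrophobic", li, rid, ra.name, d))

    # heme coordination
    if receptor.heme is not None:
        fe = receptor.heme.fe_position
        for li in sorted(lt.coordinating):
            d = float(np.linalg.norm(lig_coords[li] - fe))
            if d <= params.heme_coordination_max:
                _add(("heme_coordination", li),
                     Contact("heme_coordination", li, "HEM", "FE", d))

    return sorted(
        contacts.values(), key=lambda c: (c.type, c.ligand_atom, c.residue, c.rec_atom)
    )


def profile_pose(
    pose: LigandPose,
    receptor: ReceptorModel,
    params: ProfilerParams = ProfilerParams(),
) -> InteractionProfile:
    """Full per-pose profile: contacts + heme proximity + closest-atom label."""
    if receptor.heme is None:
        raise CypscreenError("cannot profile pose: receptor has no heme")
    dist, closest = min_heme_distance(pose, receptor.heme)
    return InteractionProfile(
        pose=pose,
        contacts=detect_interactions(pose, receptor, params),
        min_heme_fe_distance=dist,
        closest_atom_index=closest,
        closest_atom_element=pose.mol.GetAtomWithIdx(closest).GetSymbol(),
        closest_atom_label=functional_group_label(pose.mol, closest),
        proximity="proximal" if dist < params.proximal_cutoff else "distal",
    )
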