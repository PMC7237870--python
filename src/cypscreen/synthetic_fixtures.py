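"""Synthetic toy pockets and probe poses with constructed ground truth.

The generator builds a minimal CYP-like active site: a planar porphyrin ring
(Fe + 4 pyrrole N + macrocycle carbons), an axial cysteine thiolate below the
plane, and idealized anchoring residues (Asp/Glu/Phe/Ser/Gln analogues)
placed at configurable distances and directions from the iron.  Probe
molecules are then positioned at controlled distances with known interaction
labels, so the profiler and classifier can be validated end-to-end without
downloading any real structure.

Ground-truth labels are derived from the placement parameters and plain
distance arithmetic on the constructed geometry — never from the profiler.
Placements that cannot guarantee their label with a safety margin (e.g. a
probe straddling the 6 Å proximal boundary) raise :class:`PlacementError`.

The module also ships the 19-compound natural-antidepressant fixture library
with the published descriptor values and inhibition-evidence marks as
annotations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._geometry import fit_plane, perpendicular, rotation_between, unit
from .compound_library import CompoundRecord, DescriptorSet
from .errors import PlacementError
from .interaction_profiler import functional_group_label
from .inhibition_classifier import NONMETABOLIZED_LABELS
from .pose_io import LigandPose, pose_from_mol
from .receptor_prep import Atom, HemeModel, ReceptorModel, write_pdb
from .residue_templates import ANCHOR_ATOMS, RESIDUE_HEAVY_ATOMS, build_backbone, build_sidechain

__all__ = [
    "ResiduePlacement",
    "ToyPocketConfig",
    "ProbePlacement",
    "GroundTruthEntry",
    "TruthCase",
    "generate_toy_pocket",
    "generate_probe_pose",
    "standard_truth_cases",
    "builtin_fixture_library",
    "published_descriptor_rows",
    "write_pocket_pdb",
]

write_pocket_pdb = write_pdb

_CHAIN = "A"
_MIN_SEPARATION = 2.0


@dataclass(frozen=True)
class ResiduePlacement:
    """One anchoring residue: type, anchor-group distance from Fe, direction."""

    res_name: str
    distance: float
    direction: tuple[float, float, float]
    res_seq: int | None = None


@dataclass(frozen=True)
class ToyPocketConfig:
    seed: int = 0
    fe_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    porphyrin_radius: float = 2.05
    residues: tuple[ResiduePlacement, ...] = ()
    decoy_atoms: int = 0
    axial_cys: bool = True

    def __post_init__(self):
        for rp in self.residues:
            if rp.distance <= self.porphyrin_radius:
                raise ValueError(
                    f"residue {rp.res_name} at {rp.distance} Å is inside the porphyrin"
                )


def _porphyrin_atoms(fe: np.ndarray, radius: float) -> list[Atom]:
    atoms = [Atom("FE", "FE", fe.copy(), "HEM", 501, _CHAIN, het=True)]
    n_names = ("NA", "NB", "NC", "ND")
    for name, ang in zip(n_names, (0.0, 90.0, 180.0, 270.0)):
        th = np.deg2rad(ang)
        pos = fe + radius * np.array([np.cos(th), np.sin(th), 0.0])
        atoms.append(Atom("N", name, pos, "HEM", 501, _CHAIN, het=True))
    idx = 1
    for base in (0.0, 90.0, 180.0, 270.0):  # alpha carbons flanking each N
        for delta in (-25.0, 25.0):
            th = np.deg2rad(base + delta)
            pos = fe + 1.25 * radius * np.array([np.cos(th), np.sin(th), 0.0])
            atoms.append(Atom("C", f"C{idx}", pos, "HEM", 501, _CHAIN, het=True))
            idx += 1
    for ang in (45.0, 135.0, 225.0, 315.0):  # meso carbons
        th = np.deg2rad(ang)
        pos = fe + 1.7 * radius * np.array([np.cos(th), np.sin(th), 0.0])
        atoms.append(Atom("C", f"C{idx}", pos, "HEM", 501, _CHAIN, het=True))
        idx += 1
    return atoms


def _anchor_centroid(coords: dict[str, np.ndarray], res_name: str) -> np.ndarray:
    names = ANCHOR_ATOMS[res_name]
    return np.mean([coords[n] for n in names], axis=0)


def _place_residue(
    res_name: str, anchor_target: np.ndarray, outward: np.ndarray,
    res_seq: int,
) -> list[Atom]:
    """Build an idealized residue whose anchor-group centroid sits at
    ``anchor_target`` with the backbone on the outward side."""
    if res_name not in ANCHOR_ATOMS:
        raise PlacementError(f"no anchor definition for residue {res_name!r}")
    coords = build_backbone()
    coords.update(build_sidechain(res_name, coords))
    anchor_local = _anchor_centroid(coords, res_name)
    v = anchor_local - coords["CA"]
    rot = rotation_between(v, -unit(outward))
    atoms = []
    for name in RESIDUE_HEAVY_ATOMS[res_name]:
        world = rot @ (coords[name] - anchor_local) + anchor_target
        atoms.append(Atom(name[0], name, world, res_name, res_seq, _CHAIN))
    return atoms


def generate_toy_pocket(cfg: ToyPocketConfig) -> tuple[ReceptorModel, dict]:
    """Deterministic toy pocket; same config (incl. seed) -> identical pocket.

    Returns the receptor model and a ground-truth scaffold describing the
    placed geometry (Fe, plane normal, per-residue anchor positions).
    """
    fe = np.asarray(cfg.fe_position, dtype=float)
    atoms = _porphyrin_atoms(fe, cfg.porphyrin_radius)
    scaffold: dict = {
        "fe": fe.copy(),
        "normal": np.array([0.0, 0.0, 1.0]),
        "residues": {},
    }

    next_seq = 100
    if cfg.axial_cys:
        sg_target = fe + np.array([0.0, 0.0, -2.3])
        atoms.extend(_place_residue("CYS", sg_target, np.array([0.0, 0.0, -1.0]), 95))
        scaffold["residues"][95] = {"res_name": "CYS", "anchor": sg_target}

    for rp in cfg.residues:
        seq = rp.res_seq if rp.res_seq is not None else next_seq
        next_seq = max(next_seq, seq) + 1
        direction = unit(np.asarray(rp.direction, dtype=float))
        anchor_target = fe + rp.distance * direction
        res_atoms = _place_residue(rp.res_name, anchor_target, direction, seq)
        atoms.extend(res_atoms)
        entry = {"res_name": rp.res_name, "anchor": anchor_target,
                 "direction": direction, "distance": rp.distance}
        if rp.res_name == "PHE":
            ring = np.array([a.pos for a in res_atoms if a.name in ANCHOR_ATOMS["PHE"]])
            centroid, normal, _ = fit_plane(ring)
            entry["ring_centroid"] = centroid
            entry["ring_normal"] = normal
        scaffold["residues"][seq] = entry

    rng = np.random.default_rng(cfg.seed)
    placed = 0
    tries = 0
    while placed < cfg.decoy_atoms:
        tries += 1
        if tries > 200 * max(cfg.decoy_atoms, 1):
            raise PlacementError("could not place decoy atoms without overlaps")
        v = rng.normal(size=3)
        pos = fe + rng.uniform(16.0, 22.0) * unit(v)
        if min(np.linalg.norm(pos - a.pos) for a in atoms) < 4.0:
            continue
        atoms.append(Atom("C", "C", pos, "DEC", 900 + placed, _CHAIN, het=True))
        placed += 1

    # inter-residue overlap check
    keys = [(a.res_seq, a.chain) for a in atoms]
    coords = np.array([a.pos for a in atoms])
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if keys[i] == keys[j]:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < _MIN_SEPARATION:
                raise PlacementError(
                    f"overlapping placement: {atoms[i].res_name}{atoms[i].res_seq}/"
                    f"{atoms[i].name} vs {atoms[j].res_name}{atoms[j].res_seq}/"
                    f"{atoms[j].name}"
                )

    heme = HemeModel.from_atoms([a for a in atoms if a.res_name == "HEM"])
    model = ReceptorModel(
        atoms=atoms, heme=heme,
        provenance=[f"toy_pocket_seed={cfg.seed}"],
    )
    return model, scaffold


# ------------------------------------------------------------------- probes

@dataclass(frozen=True)
class ProbePlacement:
    """Where to put a probe molecule.

    mode "fe_axial": anchor atom at ``distance`` from Fe along the distal
    plane normal; "residue_anchor": anchor atom at ``distance`` laterally off
    the residue's anchor group; "ring_stack": probe aromatic-ring centroid at
    ``distance`` along the residue ring normal, planes parallel; "absolute":
    anchor atom at Fe + distance * direction.
    """

    smiles: str
    mode: str
    distance: float
    anchor_atom: int = 0
    residue_seq: int | None = None
    direction: tuple[float, float, float] | None = None
    seed: int = 0


@dataclass(frozen=True)
class GroundTruthEntry:
    proximity: str
    contact_types: frozenset[str]
    call: str
    anchor_label: str | None = None


@dataclass(frozen=True)
class TruthCase:
    kind: str
    pocket: ReceptorModel
    scaffold: dict
    pose: LigandPose
    truth: GroundTruthEntry


def _embed(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise PlacementError(f"unparsable probe SMILES {smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise PlacementError(f"probe {smiles!r} could not be embedded in 3D")
    return Chem.RemoveHs(molh)


def _coords(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])


def _set_coords(mol: Chem.Mol, coords: np.ndarray) -> None:
    from rdkit.Geometry import Point3D

    conf = mol.GetConformer()
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*xyz))


def _rigid_place(
    mol: Chem.Mol, anchor: int, target: np.ndarray, away: np.ndarray
) -> None:
    coords = _coords(mol)
    coords = coords - coords[anchor]
    others = [i for i in range(len(coords)) if i != anchor]
    if others:
        centroid = coords[others].mean(axis=0)
        if np.linalg.norm(centroid) > 1e-6:
            rot = rotation_between(centroid, away)
            coords = coords @ rot.T
    _set_coords(mol, coords + target)


def _receptor_clearance(
    lig_coords: np.ndarray, receptor: ReceptorModel, exclude_seqs: set[int]
) -> float:
    rec = np.array(
        [a.pos for a in receptor.atoms
         if a.res_name != "HEM" and a.res_seq not in exclude_seqs]
    ).reshape(-1, 3)
    if rec.size == 0:
        return np.inf
    from scipy.spatial.distance import cdist

    return float(cdist(lig_coords, rec).min())


_PROXIMITY_MARGIN = 0.25


def _proximity_of(dmin: float, occlusion_max: float = 12.0) -> str:
    if abs(dmin - 6.0) < _PROXIMITY_MARGIN or abs(dmin - occlusion_max) < _PROXIMITY_MARGIN:
        raise PlacementError(
            f"min heme distance {dmin:.2f} Å too close to a classification boundary"
        )
    return "proximal" if dmin < 6.0 else "distal"


def generate_probe_pose(
    pocket: ReceptorModel,
    placement: ProbePlacement,
    scaffold: dict | None = None,
    anchors: frozenset[tuple[str, int]] | None = None,
) -> tuple[LigandPose, GroundTruthEntry]:
    """Place a probe with a guaranteed ground-truth label.

    ``anchors`` names the (residue, number) pairs the classifier treats as
    anchoring; by default every placed ASP/GLU counts.  Raises
    :class:`PlacementError` when the requested placement cannot guarantee its
    labels with a safety margin.
    """
    if pocket.heme is None:
        raise PlacementError("toy pocket has no heme")
    fe = pocket.heme.fe_position
    normal = pocket.heme.plane_normal
    if np.dot(normal, np.array([0.0, 0.0, 1.0])) < 0:
        normal = -normal
    mol = _embed(placement.smiles, placement.seed)
    anchor = placement.anchor_atom
    if anchor >= mol.GetNumAtoms():
        raise PlacementError(f"anchor atom {anchor} out of range")

    scaffold = scaffold or {"residues": {}}
    res_meta = scaffold.get("residues", {})
    if anchors is None:
        anchors = frozenset(
            (meta["res_name"], seq)
            for seq, meta in res_meta.items()
            if meta["res_name"] in ("ASP", "GLU")
        )

    expected_types: set[str] = set()
    exclude: set[int] = set()
    clearance_needed = 4.5

    if placement.mode == "fe_axial":
        target = fe + placement.distance * normal
        _rigid_place(mol, anchor, target, normal)
        z = mol.GetAtomWithIdx(anchor).GetAtomicNum()
        if z in (7, 8, 16) and placement.distance <= 4.0 - _PROXIMITY_MARGIN:
            expected_types.add("heme_coordination")
        elif placement.distance <= 4.0 + _PROXIMITY_MARGIN:
            raise PlacementError("anchor distance too close to the coordination cutoff")
    elif placement.mode == "residue_anchor":
        if placement.residue_seq not in res_meta:
            raise PlacementError(f"no placed residue {placement.residue_seq}")
        meta = res_meta[placement.residue_seq]
        if meta["res_name"] not in ("ASP", "GLU"):
            raise PlacementError("residue_anchor placement expects an ASP/GLU target")
        exclude = {placement.residue_seq}
        carboxylate = np.array(
            [a.pos for a in pocket.residue_atoms(placement.residue_seq)
             if a.name in ANCHOR_ATOMS[meta["res_name"]]]
        )
        direction = meta["direction"]
        placed = False
        for theta in range(0, 360, 20):  # deterministic search for a clean slot
            axis = unit(direction)
            p0 = perpendicular(axis)
            th = np.deg2rad(theta)
            p1 = unit(np.cross(axis, p0))
            perp = np.cos(th) * p0 + np.sin(th) * p1
            target = meta["anchor"] + placement.distance * perp
            _rigid_place(mol, anchor, target, perp)
            lig = _coords(mol)
            d_ox = np.linalg.norm(carboxylate - lig[anchor], axis=1).min()
            others = np.delete(lig, anchor, axis=0)
            res_pos = np.array([a.pos for a in pocket.residue_atoms(placement.residue_seq)])
            from scipy.spatial.distance import cdist

            if (
                2.4 <= d_ox <= 3.4
                and (others.size == 0 or cdist(others, res_pos).min() > 4.2)
            ):
                placed = True
                break
        if not placed:
            raise PlacementError("no clean lateral slot around the anchoring residue")
        expected_types.update({"ionic", "hbond"})
    elif placement.mode == "ring_stack":
        meta = res_meta.get(placement.residue_seq)
        if meta is None or "ring_centroid" not in meta:
            raise PlacementError("ring_stack placement needs a placed PHE residue")
        exclude = {placement.residue_seq}
        ring_idx = next(
            (list(r) for r in mol.GetRingInfo().AtomRings()
             if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)),
            None,
        )
        if ring_idx is None:
            raise PlacementError("ring_stack probe has no aromatic ring")
        rn = meta["ring_normal"]
        side = 1.0 if np.dot(rn, meta["ring_centroid"] - fe) >= 0 else -1.0
        rn = side * rn
        coords = _coords(mol)
        lc, ln, _ = fit_plane(coords[ring_idx])
        rot = rotation_between(ln, rn)
        coords = (coords - lc) @ rot.T + meta["ring_centroid"] + placement.distance * rn
        _set_coords(mol, coords)
        expected_types.update({"pi_stack", "hydrophobic"})
    elif placement.mode == "absolute":
        if placement.direction is None:
            raise PlacementError("absolute placement needs a direction")
        direction = unit(np.asarray(placement.direction, dtype=float))
        target = fe + placement.distance * direction
        _rigid_place(mol, anchor, target, direction)
    else:
        raise PlacementError(f"unknown placement mode {placement.mode!r}")

    lig = _coords(mol)
    heavy = [i for i in range(mol.GetNumAtoms())
             if mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
    dmin = float(np.linalg.norm(lig[heavy] - fe, axis=1).min())
    proximity = _proximity_of(dmin)

    clearance = _receptor_clearance(lig, pocket, exclude)
    if placement.mode in ("fe_axial", "absolute") and clearance < clearance_needed:
        raise PlacementError(
            f"probe too close ({clearance:.2f} Å) to pocket residues for a clean label"
        )

    label = functional_group_label(mol, anchor)
    if proximity == "proximal":
        inhibitory = "heme_coordination" in expected_types or label in NONMETABOLIZED_LABELS
        call = "proximal_inhibitory" if inhibitory else "none"
    else:
        anchored = placement.mode == "residue_anchor" and (
            (res_meta[placement.residue_seq]["res_name"], placement.residue_seq) in anchors
        )
        call = "distal_inhibitory" if (dmin <= 12.0 - _PROXIMITY_MARGIN and anchored) else "none"

    truth = GroundTruthEntry(
        proximity=proximity,
        contact_types=frozenset(expected_types),
        call=call,
        anchor_label=label,
    )
    pose = pose_from_mol(mol, name=placement.smiles, rank=1)
    return pose, truth


# ---------------------------------------------------------- standard cases

_CASE_KINDS = (
    "proximal_coordinating",
    "proximal_alcohol",
    "distal_anchored",
    "none_far",
    "none_mid",
)


def standard_truth_cases(n_cases: int = 50, seed: int = 0) -> list[TruthCase]:
    """Seeded (pocket, pose, ground-truth) triples cycling through proximal
    coordination, distal anchored and non-binding scenarios."""
    rng = np.random.default_rng(seed)
    cases: list[TruthCase] = []
    attempts = 0
    while len(cases) < n_cases:
        attempts += 1
        if attempts > 20 * n_cases:
            raise PlacementError("could not generate the requested truth cases")
        kind = _CASE_KINDS[len(cases) % len(_CASE_KINDS)]
        case_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(case_seed)
        az = crng.uniform(0, 2 * np.pi)
        zc = crng.uniform(0.25, 0.6)
        lat = np.sqrt(1 - zc**2)
        direction = (lat * np.cos(az), lat * np.sin(az), zc)
        res_name = "ASP" if crng.random() < 0.5 else "GLU"
        res_seq = 301 if res_name == "ASP" else 216  # canonical anchor numbering
        res_dist = float(crng.uniform(6.5, 8.5))
        cfg = ToyPocketConfig(
            seed=case_seed,
            residues=(ResiduePlacement(res_name, res_dist, direction, res_seq=res_seq),),
        )
        try:
            pocket, scaffold = generate_toy_pocket(cfg)
            if kind == "proximal_coordinating":
                placement = ProbePlacement(
                    "CN", mode="fe_axial", anchor_atom=1,
                    distance=float(crng.uniform(2.8, 3.7)), seed=case_seed,
                )
            elif kind == "proximal_alcohol":
                placement = ProbePlacement(
                    "CO", mode="fe_axial", anchor_atom=1,
                    distance=float(crng.uniform(2.8, 3.7)), seed=case_seed,
                )
            elif kind == "distal_anchored":
                placement = ProbePlacement(
                    "CN", mode="residue_anchor", anchor_atom=1, residue_seq=res_seq,
                    distance=float(crng.uniform(2.9, 3.2)), seed=case_seed,
                )
            elif kind == "none_far":
                away_az = az + np.pi  # opposite the placed residue
                away = (lat * np.cos(away_az), lat * np.sin(away_az), zc)
                placement = ProbePlacement(
                    "CC", mode="absolute", direction=away,
                    distance=float(crng.uniform(16.0, 24.0)), seed=case_seed,
                )
            else:  # none_mid: inside the occlusion window, below the plane
                tilt = crng.uniform(np.deg2rad(35), np.deg2rad(55))
                below = (np.sin(tilt) * np.cos(az + np.pi),
                         np.sin(tilt) * np.sin(az + np.pi), -np.cos(tilt))
                placement = ProbePlacement(
                    "CC", mode="absolute", direction=below,
                    distance=float(crng.uniform(9.0, 11.0)), seed=case_seed,
                )
            pose, truth = generate_probe_pose(pocket, placement, scaffold)
        except PlacementError:
            continue
        cases.append(TruthCase(kind, pocket, scaffold, pose, truth))
    return cases


# --------------------------------------------------------- fixture library

_PAPER_COLS = ("mw", "hbd", "hba", "logp", "logs", "psa", "rotb")


def builtin_fixture_library() -> list[CompoundRecord]:
    """The 19-compound natural-antidepressant fixture library.

    Annotations carry the published descriptor values (``mw_published`` etc.) and
    the literature CYP2D6 inhibition-evidence mark (``cyp2d6_evidence``:
    inhibition / no_inhibition / unknown).
    """
    with resources.as_file(
        resources.files("cypscreen").joinpath("data/compounds_19.tsv")
    ) as path:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    records = []
    for row in rows:
        annotations = {f"{c}_published": float(row[f"{c}_published"]) for c in _PAPER_COLS}
        annotations["cyp2d6_evidence"] = row["cyp2d6_evidence"]
        records.append(
            CompoundRecord.from_smiles(row["name"], row["smiles"], annotations)
        )
    return records


def published_descriptor_rows(
    records: Iterable[CompoundRecord] | None = None,
) -> list[tuple[str, DescriptorSet]]:
    """The published descriptor rows, verbatim, as DescriptorSet inputs."""
    records = list(records) if records is not None else builtin_fixture_library()
    out = []
    for rec in records:
        a = rec.annotations
        out.append(
            (
                rec.name,
                DescriptorSet(
                    mw=a["mw_published"], hbd=int(a["hbd_published"]), hba=int(a["hba_published"]),
                    logp=a["logp_published"], logs=a["logs_published"], psa=a["psa_published"],
                    rotb=int(a["rotb_published"]),
                ),
            )
        )
    return out
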