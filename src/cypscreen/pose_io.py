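"""Reading and writing ranked docked poses (SDF V2000 and PDBQT).

Poses are ranked in file order (rank 1 = first record / first MODEL), the
convention of every docking engine's output.  Only the first ``max_poses``
(default 10) are retained; extra records are dropped with a warning.  Scores
are picked up from the SDF tags ``minimizedAffinity``/``score`` or from
``REMARK VINA RESULT`` lines in PDBQT.  PDBQT carries no bonds, so bonds are
perceived from interatomic distances (sum of covalent radii + 0.45 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .errors import PoseFormatError

__all__ = ["LigandPose", "read_poses", "write_poses_sdf", "pose_from_mol"]

DEFAULT_MAX_POSES = 10

_SCORE_TAGS = ("minimizedAffinity", "score")

# single-bond covalent radii (Å) for bond perception
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SI": 1.11,
}

# AutoDock atom types -> elements
_AUTODOCK_TYPES = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "S": "S", "SA": "S", "H": "H", "HD": "H", "HS": "H", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "P": "P", "FE": "Fe", "ZN": "Zn",
    "MG": "Mg", "MN": "Mn", "CA": "Ca",
}


@dataclass
class LigandPose:
    """One docked pose: compound name, 1-based rank, optional engine score,
    and an RDKit molecule carrying a single 3D conformer (heavy atoms)."""

    name: str
    rank: int
    mol: Chem.Mol
    score: float | None = None

    def coords(self) -> np.ndarray:
        conf = self.mol.GetConformer()
        return np.array(
            [list(conf.GetAtomPosition(i)) for i in range(self.mol.GetNumAtoms())]
        ).reshape(-1, 3)

    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    def heavy_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for i in range(mol.GetNumAtoms()):
            p = rot @ np.array(list(conf.GetAtomPosition(i))) + t
            conf.SetAtomPosition(i, Point3D(*p))
        return LigandPose(self.name, self.rank, mol, self.score)


def pose_from_mol(
    mol: Chem.Mol, name: str, rank: int = 1, score: float | None = None
) -> LigandPose:
    if mol.GetNumConformers() == 0:
        raise PoseFormatError(f"{name}: molecule has no conformer")
    heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    if heavy < 1:
        raise PoseFormatError(f"{name}: pose has no heavy atoms")
    return LigandPose(name=name, rank=rank, mol=mol, score=score)


def _score_from_props(mol: Chem.Mol) -> float | None:
    for tag in _SCORE_TAGS:
        if mol.HasProp(tag):
            try:
                return float(mol.GetProp(tag))
            except ValueError:
                return None
    return None


def _read_sdf(path: Path, name: str | None, max_poses: int) -> list[LigandPose]:
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise PoseFormatError(f"{path}: {exc}") from exc
    poses: list[LigandPose] = []
    n_records = 0
    for idx, mol in enumerate(supplier):
        n_records += 1
        if mol is None:
            raise PoseFormatError(f"{path}: record {idx + 1} failed to parse")
        if len(poses) >= max_poses:
            continue
        pose_name = name or (mol.GetProp("_Name") if mol.GetProp("_Name") else path.stem)
        poses.append(
            pose_from_mol(mol, pose_name, rank=len(poses) + 1, score=_score_from_props(mol))
        )
    if n_records == 0:
        raise PoseFormatError(f"{path}: no records")
    if n_records > max_poses:
        warnings.warn(
            f"{path}: kept top {max_poses} of {n_records} poses", stacklevel=2
        )
    return poses


def _element_from_pdbqt_line(line: str) -> str:
    adtype = line[77:79].strip().upper() if len(line) > 77 else ""
    if adtype in _AUTODOCK_TYPES:
        return _AUTODOCK_TYPES[adtype]
    name = line[12:16].strip()
    guess = "".join(c for c in name if c.isalpha())[:2].upper()
    if guess in _AUTODOCK_TYPES:
        return _AUTODOCK_TYPES[guess]
    return guess[:1].capitalize() or "C"


def perceive_bonds(mol: Chem.RWMol, tolerance: float = 0.45) -> None:
    """Add single bonds between atoms closer than the covalent-radius sum
    plus ``tolerance`` (heavy atoms only)."""
    conf = mol.GetConformer()
    n = mol.GetNumAtoms()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
    for i in range(n):
        ri = _COVALENT_RADII.get(mol.GetAtomWithIdx(i).GetSymbol().upper(), 0.77)
        if mol.GetAtomWithIdx(i).GetAtomicNum() == 1:
            continue
        for j in range(i + 1, n):
            if mol.GetAtomWithIdx(j).GetAtomicNum() == 1:
                continue
            rj = _COVALENT_RADII.get(mol.GetAtomWithIdx(j).GetSymbol().upper(), 0.77)
            if np.linalg.norm(coords[i] - coords[j]) <= ri + rj + tolerance:
                mol.AddBond(i, j, Chem.BondType.SINGLE)


def _read_pdbqt(path: Path, name: str | None, max_poses: int) -> list[LigandPose]:
    text = path.read_text(encoding="utf-8")
    blocks: list[list[str]] = []
    current: list[str] | None = None
    has_models = "MODEL" in text
    if not has_models:
        current = []
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None:
            current.append(line)
    if not has_models and current:
        blocks.append(current)
    if not blocks:
        raise PoseFormatError(f"{path}: no MODEL blocks or atom records")

    poses: list[LigandPose] = []
    for model_idx, block in enumerate(blocks, start=1):
        if len(poses) >= max_poses:
            break
        score = None
        rw = Chem.RWMol()
        positions: list[tuple[float, float, float]] = []
        for line in block:
            if line.startswith("REMARK VINA RESULT"):
                try:
                    score = float(line.split(":", 1)[1].split()[0])
                except (IndexError, ValueError):
                    score = None
            elif line.startswith(("ATOM", "HETATM")):
                try:
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError as exc:
                    raise PoseFormatError(
                        f"{path}: bad coordinates in model {model_idx}: {exc}"
                    ) from exc
                element = _element_from_pdbqt_line(line)
                atom = Chem.Atom(element)
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
                positions.append(xyz)
        if rw.GetNumAtoms() == 0:
            raise PoseFormatError(f"{path}: model {model_idx} has no atoms")
        conf = Chem.Conformer(rw.GetNumAtoms())
        for i, xyz in enumerate(positions):
            conf.SetAtomPosition(i, Point3D(*xyz))
        rw.AddConformer(conf, assignId=True)
        perceive_bonds(rw)
        mol = rw.GetMol()
        mol.UpdatePropertyCache(strict=False)
        poses.append(
            pose_from_mol(mol, name or path.stem, rank=len(poses) + 1, score=score)
        )
    if len(blocks) > max_poses:
        warnings.warn(
            f"{path}: kept top {max_poses} of {len(blocks)} poses", stacklevel=2
        )
    return poses


def read_poses(
    path, name: str | None = None, max_poses: int = DEFAULT_MAX_POSES
) -> list[LigandPose]:
    """Read ranked poses from an SDF or PDBQT file.

    Records are ranked 1..n in file order; at most ``max_poses`` are kept.
    """
    path = Path(path)
    if not path.exists():
        raise PoseFormatError(f"no such file: {path}")
    if path.suffix.lower() == ".pdbqt":
        return _read_pdbqt(path, name, max_poses)
    return _read_sdf(path, name, max_poses)


def write_poses_sdf(poses, path) -> None:
    """Write poses to a V2000 SDF, one record per pose in rank order."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in sorted(poses, key=lambda p: p.rank):
            mol = Chem.Mol(pose.mol)
            mol.SetProp("_Name", pose.name)
            if pose.score is not None:
                mol.SetProp("minimizedAffinity", repr(pose.score))
            writer.write(mol)
    finally:
        writer.close()
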