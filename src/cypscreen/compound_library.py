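"""Compound tables and the seven physicochemical descriptors used for CNS triage.

A compound library is a list of :class:`CompoundRecord` (name + SMILES + parsed
molecule + free-form annotations).  For every record seven descriptors are
computed: molecular weight (g/mol), hydrogen-bond donor and acceptor counts,
an atom-contribution octanol/water logP (Crippen), an ESOL-style aqueous
solubility estimate (logS), topological polar surface area (Å²), and the
rotatable-bond count (non-ring single bonds between non-terminal heavy atoms,
amide C-N excluded).

Donor/acceptor conventions
--------------------------
hbd counts O-H plus N-H hydrogens on the neutral input form.  hba counts N and
O atoms excluding amide nitrogens, pyrrole-type aromatic nitrogens (ring N
donating its lone pair to the aromatic system), and nitro-group oxygens.
These are common 2D conventions; proprietary 3D models will disagree on
individual compounds, which is expected and documented in the methods note.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .errors import DescriptorError, LibraryError

__all__ = [
    "CompoundRecord",
    "DescriptorSet",
    "load_library",
    "compute_descriptors",
    "write_descriptor_table",
]

DESCRIPTOR_ORDER = ("mw", "hbd", "hba", "logp", "logs", "psa", "rotb")


@dataclass
class CompoundRecord:
    """A named small molecule plus optional annotations."""

    name: str
    smiles: str
    mol: Chem.Mol
    annotations: dict = field(default_factory=dict)

    @classmethod
    def from_smiles(cls, name: str, smiles: str, annotations: dict | None = None):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise LibraryError(f"unparsable SMILES for {name!r}: {smiles!r}")
        if mol.GetNumHeavyAtoms() < 1:
            raise LibraryError(f"{name!r} has no heavy atoms")
        return cls(name=name, smiles=smiles, mol=mol, annotations=dict(annotations or {}))


@dataclass(frozen=True)
class DescriptorSet:
    """The seven physicochemical descriptors of one compound.

    mw g/mol; hbd/hba counts; logp and logs unitless; psa Å²; rotb count.
    """

    mw: float
    hbd: int
    hba: int
    logp: float
    logs: float
    psa: float
    rotb: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in DESCRIPTOR_ORDER}


def _read_delimited(path: Path) -> list[tuple[str, str]]:
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not {"name", "smiles"} <= set(reader.fieldnames):
            raise LibraryError(f"{path}: header must contain 'name' and 'smiles' columns")
        return [(row["name"] or "", row["smiles"] or "") for row in reader]


def _read_smi(path: Path) -> list[tuple[str, str]]:
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else ""
        rows.append((name, smiles))
    return rows


def load_library(path) -> list[CompoundRecord]:
    """Load a compound table (CSV/TSV with name,smiles columns, or .smi file).

    Returns one record per parsable row, in input order.  Rows whose SMILES do
    not parse are reported (with their 1-based row number) as warnings; the
    whole run aborts only when every row fails.  Duplicate names abort.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"no such file: {path}")
    rows = _read_smi(path) if path.suffix.lower() == ".smi" else _read_delimited(path)
    if not rows:
        raise LibraryError(f"{path}: empty compound table")

    records: list[CompoundRecord] = []
    failures: list[str] = []
    for i, (name, smiles) in enumerate(rows, start=1):
        if not name or not smiles:
            failures.append(f"row {i}: missing name or smiles")
            continue
        try:
            records.append(CompoundRecord.from_smiles(name, smiles))
        except LibraryError as exc:
            failures.append(f"row {i}: {exc}")
    if failures and not records:
        raise LibraryError(f"{path}: all rows failed: " + "; ".join(failures))
    for msg in failures:
        warnings.warn(f"{path}: {msg}", stacklevel=2)

    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise LibraryError(f"{path}: duplicate compound names: {sorted(dupes)}")
    return records


_AMIDE_N = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")
_PYRROLE_N = Chem.MolFromSmarts("[n;X3;+0]")
_NITRO_O = Chem.MolFromSmarts("[OX1]~[NX3](~[OX1])~*")


def _hba_count(mol: Chem.Mol) -> int:
    """N and O atoms minus amide N, pyrrole-type aromatic N and nitro O."""
    excluded: set[int] = set()
    for match in mol.GetSubstructMatches(_AMIDE_N):
        excluded.add(match[0])
    for match in mol.GetSubstructMatches(_PYRROLE_N):
        excluded.add(match[0])
    for match in mol.GetSubstructMatches(_NITRO_O):
        excluded.add(match[0])
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetAtomicNum() in (7, 8) and a.GetIdx() not in excluded
    )


def _esol_logs(mol: Chem.Mol, logp: float, mw: float, rotb: int) -> float:
    # Delaney's ESOL regression on 2D descriptors; AP = aromatic heavy-atom fraction.
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotb - 0.74 * ap


def compute_descriptors(record: CompoundRecord) -> DescriptorSet:
    """Compute the seven-descriptor set for one compound.

    Deterministic: identical records give identical values.
    """
    mol = record.mol
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise DescriptorError(
                f"{record.name}: no atomic mass for element {atom.GetSymbol()!r}"
            )
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rotb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    return DescriptorSet(
        mw=mw,
        hbd=Lipinski.NHOHCount(mol),
        hba=_hba_count(mol),
        logp=logp,
        logs=_esol_logs(mol, logp, mw, rotb),
        psa=rdMolDescriptors.CalcTPSA(mol),
        rotb=rotb,
    )


def write_descriptor_table(records: Iterable[CompoundRecord], path) -> None:
    """Write a TSV with the seven descriptor columns (mw rounded for display)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tmw\thbd\thba\tlogp\tlogs\tpsa\trotb\n")
        for rec in records:
            d = compute_descriptors(rec)
            fh.write(
                f"{rec.name}\t{round(d.mw)}\t{d.hbd}\t{d.hba}"
                f"\t{d.logp:.1f}\t{d.logs:.1f}\t{d.psa:.0f}\t{d.rotb}\n"
            )
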