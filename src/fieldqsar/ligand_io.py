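"""Aligned-ligand input and activity handling.

Ligand structures arrive pre-aligned in one shared coordinate frame
(typically exported from a docking run) as SDF V2000 or MOL2.  Partial
charges are taken from the file when present (the ``PARTIAL_CHARGES``
SD field or Tripos charges); otherwise Gasteiger charges are assigned
as a deterministic fallback.  Activities are joined from a CSV table on
the nanomolar IC50 or pIC50 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .params import vdw_params

CHARGE_PROP = "PARTIAL_CHARGES"
SCORE_PROP = "DOCKING_SCORE"


@dataclass
class Atom:
    """A parameterized atom in the shared alignment frame."""

    element: str
    position: np.ndarray  # (3,) Å
    partial_charge: float  # e
    vdw_radius: float  # Å
    vdw_epsilon: float  # kcal/mol

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom coordinates must be finite")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if self.vdw_epsilon < 0:
            raise ValueError("vdw_epsilon must be non-negative")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Molecule:
    """A rigid ligand pose: atoms in the shared frame plus bookkeeping."""

    ligand_id: str
    atoms: list[Atom]
    docking_score: float | None = None
    pose_index: int | None = None

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise ValueError("ligand_id must be non-empty")
        if len(self.atoms) == 0:
            raise ValueError("molecule must contain at least one atom")
        if not math.isfinite(self.net_charge):
            raise ValueError("net charge must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class ActivityRecord:
    """Measured potency for one ligand: IC50 in nM and/or pIC50 (molar log)."""

    ligand_id: str
    pic50: float
    ic50_nM: float | None = None
    set_label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.ic50_nM is not None:
            if self.ic50_nM <= 0:
                raise ValueError("ic50_nM must be positive")
            expected = pic50_from_ic50(self.ic50_nM)
            if abs(expected - self.pic50) > 5e-4:
                raise ValueError(
                    f"{self.ligand_id}: pic50 {self.pic50} inconsistent with "
                    f"ic50_nM {self.ic50_nM} (expected {expected:.4f})"
                )


@dataclass
class LigandSet:
    """Aligned molecules joined to their activities (ids unique, resolved)."""

    molecules: list[Molecule]
    activities: list[ActivityRecord] = field(default_factory=list)
    frame_tag: str = "shared"

    def __post_init__(self) -> None:
        ids = [m.ligand_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("ligand ids must be unique")
        known = set(ids)
        for rec in self.activities:
            if rec.ligand_id not in known:
                raise ValueError(f"activity for unknown ligand {rec.ligand_id!r}")

    def __len__(self) -> int:
        return len(self.molecules)

    def molecule(self, ligand_id: str) -> Molecule:
        for m in self.molecules:
            if m.ligand_id == ligand_id:
                return m
        raise KeyError(ligand_id)

    def activity(self, ligand_id: str) -> ActivityRecord:
        for rec in self.activities:
            if rec.ligand_id == ligand_id:
                return rec
        raise KeyError(ligand_id)

    @property
    def pic50(self) -> np.ndarray:
        """pIC50 vector in molecule order (requires complete activities)."""
        by_id = {r.ligand_id: r.pic50 for r in self.activities}
        return np.array([by_id[m.ligand_id] for m in self.molecules])


def pic50_from_ic50(ic50_nM: float) -> float:
    """Convert an IC50 in nmol/dm³ to pIC50 = −log10 of the molar value."""
    if ic50_nM <= 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50_nM * 1e-9)


def _mol_from_rdkit(rdmol: Chem.Mol, index: int, fallback_charges: bool) -> Molecule:
    if rdmol.GetNumConformers() == 0:
        raise ValueError(f"record {index}: no 3D coordinates")
    conf = rdmol.GetConformer()
    n = rdmol.GetNumAtoms()

    charges: list[float] | None = None
    if rdmol.HasProp(CHARGE_PROP):
        charges = [float(v) for v in rdmol.GetProp(CHARGE_PROP).split()]
        if len(charges) != n:
            raise ValueError(f"record {index}: {CHARGE_PROP} length mismatch")
    elif all(a.HasProp("_TriposPartialCharge") for a in rdmol.GetAtoms()):
        charges = [a.GetDoubleProp("_TriposPartialCharge") for a in rdmol.GetAtoms()]
    elif fallback_charges:
        try:
            m = Chem.Mol(rdmol)
            Chem.SanitizeMol(m)
            AllChem.ComputeGasteigerCharges(m)
            charges = [a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()]
        except Exception as exc:  # pragma: no cover - rdkit edge cases
            raise ValueError(f"record {index}: Gasteiger fallback failed: {exc}")
        warnings.warn(
            f"record {index}: no charges in file, assigned Gasteiger charges",
            stacklevel=3,
        )
    if charges is None or not all(math.isfinite(c) for c in charges):
        raise ValueError(f"record {index}: unusable partial charges")

    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        symbol = a.GetSymbol()
        radius, eps = vdw_params(symbol)  # raises on unknown element
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(symbol, np.array([pos.x, pos.y, pos.z]), charges[i], radius, eps))

    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    score = float(rdmol.GetProp(SCORE_PROP)) if rdmol.HasProp(SCORE_PROP) else None
    return Molecule(ligand_id=name or f"mol{index}", atoms=atoms, docking_score=score)


def read_ligand_set(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read aligned ligand structures from an SDF (V2000) or MOL2 file.

    One :class:`Molecule` per record.  Charges come from the file when
    present; otherwise Gasteiger charges are assigned with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mol2" if path.suffix.lower() == ".mol2" else "sdf")

    if path.stat().st_size == 0:
        raise ValueError(f"no records in {path}")

    mols: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ValueError(f"unparseable SDF record at index {i}")
            mols.append(_mol_from_rdkit(rdmol, i, fallback_charges=True))
    elif fmt == "mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
        for i, block in enumerate(blocks):
            rdmol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
            if rdmol is None:
                raise ValueError(f"unparseable MOL2 record at index {i}")
            mols.append(_mol_from_rdkit(rdmol, i, fallback_charges=True))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if not mols:
        raise ValueError(f"no records in {path}")
    return mols


def write_ligand_set(mols: Sequence[Molecule], path: str | Path) -> None:
    """Write molecules as SDF V2000 with charges in the PARTIAL_CHARGES field.

    Bonds are not reconstructed — downstream field computation is
    bond-agnostic — so records carry atoms, coordinates and charges only.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in mols:
        rw = Chem.RWMol()
        conf = Chem.Conformer(len(mol.atoms))
        for i, atom in enumerate(mol.atoms):
            a = Chem.Atom(atom.element)
            a.SetNoImplicit(True)
            rw.AddAtom(a)
            conf.SetAtomPosition(i, atom.position.tolist())
        rw.AddConformer(conf)
        out = rw.GetMol()
        out.SetProp("_Name", mol.ligand_id)
        out.SetProp(CHARGE_PROP, " ".join(f"{a.partial_charge:.6f}" for a in mol.atoms))
        if mol.docking_score is not None:
            out.SetProp(SCORE_PROP, f"{mol.docking_score:.6f}")
        writer.write(out)
    writer.close()


def read_activity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "ligand_id" not in df.columns:
        raise ValueError("activity table needs a ligand_id column")
    if "ic50_nM" not in df.columns and "pic50" not in df.columns:
        raise ValueError("activity table needs ic50_nM or pic50")
    df["ligand_id"] = df["ligand_id"].astype(str)
    return df


def attach_activities(
    mols: Sequence[Molecule],
    table: pd.DataFrame | str | Path,
    frame_tag: str = "shared",
) -> LigandSet:
    """Join an activity table onto structures, computing pIC50 if absent."""
    if not isinstance(table, pd.DataFrame):
        table = read_activity_table(table)
    if table["ligand_id"].duplicated().any():
        dups = table.loc[table["ligand_id"].duplicated(), "ligand_id"].tolist()
        raise ValueError(f"duplicate ligand id(s) in activity table: {dups}")
    by_id = {m.ligand_id: m for m in mols}
    records = []
    for row in table.itertuples(index=False):
        lid = str(row.ligand_id)
        if lid not in by_id:
            raise ValueError(f"activity row {lid!r} has no matching structure")
        ic50 = getattr(row, "ic50_nM", None)
        ic50 = None if ic50 is None or pd.isna(ic50) else float(ic50)
        pic50 = getattr(row, "pic50", None)
        if pic50 is None or pd.isna(pic50):
            if ic50 is None:
                raise ValueError(f"{lid}: neither ic50_nM nor pic50 given")
            pic50 = pic50_from_ic50(ic50)
        label = getattr(row, "set_label", "unassigned")
        if label is None or pd.isna(label):
            label = "unassigned"
        records.append(ActivityRecord(lid, float(pic50), ic50, str(label)))
    return LigandSet(molecules=list(mols), activities=records, frame_tag=frame_tag)


def select_top_pose(
    poses: Sequence[Molecule], scores: Sequence[float] | None = None
) -> Molecule:
    """Return the highest-scoring pose; ties break to the lowest pose_index."""
    if len(poses) == 0:
        raise ValueError("empty pose sequence")
    if scores is None:
        scores = [p.docking_score for p in poses]
        if any(s is None for s in scores):
            raise ValueError("poses lack docking scores")
    if len(scores) != len(poses):
        raise ValueError("scores not aligned with poses")

    def sort_key(item: tuple[int, Molecule, float]):
        i, pose, score = item
        idx = pose.pose_index if pose.pose_index is not None else i
        return (-score, idx)

    return min(
        ((i, p, float(s)) for i, (p, s) in enumerate(zip(poses, scores))), key=sort_key
    )[1]


def rmsd_in_frame(a: Molecule, b: Molecule, heavy_only: bool = True) -> float:
    """In-frame RMSD (Å) between two index-matched poses; no superposition."""
    atoms_a = a.heavy_atoms() if heavy_only else a.atoms
    atoms_b = b.heavy_atoms() if heavy_only else b.atoms
    if len(atoms_a) != len(atoms_b):
        raise ValueError(
            f"atom count mismatch: {len(atoms_a)} vs {len(atoms_b)}"
        )
    pa = np.array([x.position for x in atoms_a])
    pb = np.array([x.position for x in atoms_b])
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
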