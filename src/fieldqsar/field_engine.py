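"""Probe interaction-energy grids over an aligned ligand ensemble.

At every node of a rectilinear grid enclosing the aligned ligands, two
probe energies are evaluated: a Coulomb electrostatic energy for a unit
positive test charge and a Lennard-Jones 12-6 steric energy for a
carbon-like probe atom (1.73 Å radius).  The per-ligand energies form
the descriptor matrix regressed against activity.

Conventions
-----------
* Coulomb constant K = 332.0636 kcal·Å/(mol·e²), constant dielectric 1.
* Energies are truncated: electrostatic to ±elec_cap, steric above at
  steric_cap (classic molecular-field truncation; defaults ±30 / +30
  kcal/mol).
* Grid point linear order is z-fastest (matches OpenDX export);
  descriptor columns are point-major with the electrostatic column
  before the steric column at each point.
* No distance cutoff on the atom sums: ligand-sized systems keep the
  O(atoms × points) cost trivial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ligand_io import LigandSet, Molecule

COULOMB_K = 332.0636  # kcal·Å/(mol·e²)
MIN_DISTANCE = 1e-6  # Å; grid point "coincident with an atom" below this

FieldKind = Literal["electrostatic", "steric"]
FIELD_KINDS: tuple[FieldKind, FieldKind] = ("electrostatic", "steric")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectilinear grid: origin, uniform spacing, node counts."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(c < 2 for c in self.counts):
            raise ValueError("each axis needs at least 2 grid points")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid nodes, shape (n_points, 3), z-fastest order."""
        nx, ny, nz = self.counts
        ax = [np.asarray(self.origin)[i] + self.spacing * np.arange(n) for i, n in enumerate((nx, ny, nz))]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def to_dict(self) -> dict:
        return {"origin": list(self.origin), "spacing": self.spacing, "counts": list(self.counts)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["origin"]), float(d["spacing"]), tuple(d["counts"]))


@dataclass(frozen=True)
class ProbeSpec:
    """Probe parameters: +1 test charge, carbon-like 1.73 Å LJ sphere."""

    charge: float = 1.0
    radius: float = 1.73
    epsilon: float = 0.0903

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.epsilon < 0:
            raise ValueError("probe epsilon must be non-negative")


def build_grid(
    mols: Sequence[Molecule], spacing: float = 1.5, margin: float = 4.0
) -> GridSpec:
    """Grid covering the union bounding box of all atoms plus a margin.

    Node counts per axis are ``floor(extent / spacing) + 1`` with a
    minimum of 2 so that degenerate (planar or linear) ensembles still
    produce a volumetric grid.
    """
    if len(mols) == 0:
        raise ValueError("empty molecule list")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    counts = tuple(max(2, int(np.floor(e / spacing)) + 1) for e in hi - lo)
    return GridSpec(origin=tuple(lo.tolist()), spacing=spacing, counts=counts)


def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    return np.maximum(d, MIN_DISTANCE)


def electrostatic_field(
    mol: Molecule, grid: GridSpec, probe: ProbeSpec = ProbeSpec(), elec_cap: float = 30.0
) -> np.ndarray:
    """Coulomb probe energies (kcal/mol) at each grid node, clipped to ±cap."""
    r = _distances(grid.points(), mol.coords)
    energy = COULOMB_K * probe.charge * (mol.charges[None, :] / r).sum(axis=1)
    return np.clip(energy, -elec_cap, elec_cap)


def steric_field(
    mol: Molecule, grid: GridSpec, probe: ProbeSpec = ProbeSpec(), steric_cap: float = 30.0
) -> np.ndarray:
    """LJ 12-6 probe energies (kcal/mol) at each node, truncated above at cap.

    Per atom: ε_c[(r_m/r)¹² − 2(r_m/r)⁶] with r_m = probe radius + atom
    radius and ε_c the geometric mean of the well depths.
    """
    r = _distances(grid.points(), mol.coords)
    r_m = probe.radius + np.array([a.vdw_radius for a in mol.atoms])
    eps = np.sqrt(probe.epsilon * np.array([a.vdw_epsilon for a in mol.atoms]))
    ratio6 = (r_m[None, :] / r) ** 6
    energy = (eps[None, :] * (ratio6**2 - 2.0 * ratio6)).sum(axis=1)
    return np.minimum(energy, steric_cap)


@dataclass
class DescriptorMatrix:
    """Ligands × grid-field energy matrix with column provenance.

    ``values`` holds the retained columns only; ``retained_mask`` maps
    them back to the full point-major column layout (2 × n_points wide,
    electrostatic before steric at each point).
    """

    values: np.ndarray  # (n_ligands, n_retained)
    ligand_ids: list[str]
    grid: GridSpec
    point_index: np.ndarray  # (n_retained,) grid point per column
    field_kind: np.ndarray  # (n_retained,) "electrostatic" | "steric"
    retained_mask: np.ndarray  # (2 * n_points,) bool
    elec_cap: float = 30.0
    steric_cap: float = 30.0

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.ligand_ids):
            raise ValueError("row count must equal ligand count")
        if self.values.shape[1] != len(self.point_index) or self.values.shape[1] != len(self.field_kind):
            raise ValueError("column metadata length mismatch")

    @property
    def n_ligands(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def column_sds(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=0)

    def rows_for(self, ligand_ids: Sequence[str]) -> np.ndarray:
        index = {lid: i for i, lid in enumerate(self.ligand_ids)}
        return self.values[[index[l] for l in ligand_ids]]

    # --- persistence ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV plus a JSON sidecar with grid/column metadata."""
        path = Path(path)
        cols = [f"{k[0]}{p}" for p, k in zip(self.point_index, self.field_kind)]
        pd.DataFrame(self.values, index=self.ligand_ids, columns=cols).to_csv(
            path, sep="\t", index_label="ligand_id", float_format="%.10g"
        )
        meta = {
            "grid": self.grid.to_dict(),
            "point_index": self.point_index.tolist(),
            "field_kind": self.field_kind.tolist(),
            "retained_mask": self.retained_mask.astype(int).tolist(),
            "elec_cap": self.elec_cap,
            "steric_cap": self.steric_cap,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="ligand_id")
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(
            values=df.to_numpy(dtype=float),
            ligand_ids=[str(i) for i in df.index],
            grid=GridSpec.from_dict(meta["grid"]),
            point_index=np.asarray(meta["point_index"], dtype=int),
            field_kind=np.asarray(meta["field_kind"], dtype=object),
            retained_mask=np.asarray(meta["retained_mask"], dtype=bool),
            elec_cap=float(meta["elec_cap"]),
            steric_cap=float(meta["steric_cap"]),
        )


def build_descriptor_matrix(
    ligs: LigandSet | Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    elec_cap: float = 30.0,
    steric_cap: float = 30.0,
) -> DescriptorMatrix:
    """One row per ligand, columns = grid points × {electrostatic, steric}."""
    mols = ligs.molecules if isinstance(ligs, LigandSet) else list(ligs)
    if len(mols) == 0:
        raise ValueError("no ligands")

    lo = np.asarray(grid.origin)
    hi = lo + grid.spacing * (np.asarray(grid.counts) - 1)
    all_coords = np.vstack([m.coords for m in mols])
    if np.any(all_coords < lo) or np.any(all_coords > hi):
        warnings.warn("grid does not cover all atoms", stacklevel=2)

    n_points = grid.n_points
    values = np.empty((len(mols), 2 * n_points))
    for i, mol in enumerate(mols):
        elec = electrostatic_field(mol, grid, probe, elec_cap)
        steric = steric_field(mol, grid, probe, steric_cap)
        # interleave: column 2p = electrostatic at point p, 2p+1 = steric
        values[i, 0::2] = elec
        values[i, 1::2] = steric

    point_index = np.repeat(np.arange(n_points), 2)
    field_kind = np.array(FIELD_KINDS * n_points, dtype=object)
    return DescriptorMatrix(
        values=values,
        ligand_ids=[m.ligand_id for m in mols],
        grid=grid,
        point_index=point_index,
        field_kind=field_kind,
        retained_mask=np.ones(2 * n_points, dtype=bool),
        elec_cap=elec_cap,
        steric_cap=steric_cap,
    )


def filter_columns(dm: DescriptorMatrix, min_sd: float = 0.05) -> DescriptorMatrix:
    """Drop columns whose standard deviation across ligands is below min_sd."""
    keep = dm.column_sds >= min_sd
    if not keep.any():
        raise ValueError("no informative columns left after filtering")
    full_mask = dm.retained_mask.copy()
    full_mask[np.flatnonzero(dm.retained_mask)] = keep
    return DescriptorMatrix(
        values=dm.values[:, keep],
        ligand_ids=list(dm.ligand_ids),
        grid=dm.grid,
        point_index=dm.point_index[keep],
        field_kind=dm.field_kind[keep],
        retained_mask=full_mask,
        elec_cap=dm.elec_cap,
        steric_cap=dm.steric_cap,
    )
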