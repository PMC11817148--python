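"""Synthetic aligned ligand sets with a planted field–activity relation.

The generator emulates the statistical structure the analysis assumes:
a rigid common scaffold (two ring-like atom clusters joined by a
linker, echoing a trans-stilbene) shared by every ligand in one
coordinate frame, with per-ligand variation confined to pseudo-atom
substituents at fixed sites — present or absent, with random partial
charge and vdW radius.  Activities are then planted as a sparse linear
function of the grid field descriptors plus Gaussian noise, so the
downstream PLS model has a known ground truth (coefficient signs,
noiseless recovery) to be tested against.

Also packaged here: the 41-compound printed activity table (fixture)
with experimental/predicted pIC50, residuals and the 8-compound test
split used for the external-validation battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .field_engine import (
    DescriptorMatrix,
    GridSpec,
    ProbeSpec,
    build_descriptor_matrix,
)
from .ligand_io import ActivityRecord, Atom, LigandSet, Molecule

TEST_COMPOUNDS = (11, 12, 13, 23, 25, 28, 33, 37)


def _hexagon(center: np.ndarray, radius: float = 1.4) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)]) * radius
    return ring + center


def default_scaffold() -> np.ndarray:
    """Two hexagonal rings bridged by a two-atom linker, in the xy plane."""
    left = _hexagon(np.array([-3.5, 0.0, 0.0]))
    right = _hexagon(np.array([3.5, 0.0, 0.0]))
    linker = np.array([[-0.7, 0.25, 0.0], [0.7, -0.25, 0.0]])
    return np.vstack([left, linker, right])


def default_substituent_sites() -> np.ndarray:
    """Eight attachment positions fanned around the two rings."""
    scaffold = default_scaffold()
    ring_atoms = scaffold[[0, 2, 4, 5, 8, 10, 12, 13]]
    centers = np.array([[-3.5, 0, 0]] * 4 + [[3.5, 0, 0]] * 4)
    out = ring_atoms - centers
    norm = np.linalg.norm(out[:, :2], axis=1, keepdims=True)
    out = out / np.where(norm > 0, norm, 1.0)
    sites = ring_atoms + 1.4 * out
    sites[:, 2] += np.tile([0.5, -0.5], 4)  # push sites off-plane
    return sites


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic aligned-ligand data set."""

    n_ligands: int = 40
    scaffold: np.ndarray = field(default_factory=default_scaffold)
    substituent_sites: np.ndarray = field(default_factory=default_substituent_sites)
    substituent_prob: float = 0.5
    charge_range: tuple[float, float] = (-0.4, 0.4)
    radius_range: tuple[float, float] = (1.2, 1.9)
    planted_coefficients: dict[int, float] = field(default_factory=dict)
    intercept: float = 6.5  # pIC50 scale midpoint of the printed activity range
    noise_sd: float = 0.0  # pIC50 units (absolute), or relative if flagged
    noise_relative: bool = False  # noise_sd interpreted as fraction of signal sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 4:
            raise ValueError("need at least 4 ligands")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        sites = np.asarray(self.substituent_sites)
        if len(sites) > 1:
            d = np.linalg.norm(sites[:, None] - sites[None, :], axis=2)
            if np.any(d[np.triu_indices(len(sites), k=1)] < 1e-6):
                raise ValueError("overlapping substituent sites")


SCAFFOLD_CHARGE = -0.05
SCAFFOLD_EPSILON = 0.0903
SUBSTITUENT_EPSILON = 0.10


def generate_ligand_set(spec: SyntheticSpec) -> LigandSet:
    """Generate rigid aligned molecules (structures only) from the spec.

    Deterministic for a fixed seed: every random draw flows from one
    ``numpy`` generator seeded once.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = np.asarray(spec.scaffold, dtype=float)
    sites = np.asarray(spec.substituent_sites, dtype=float)
    mols = []
    for i in range(spec.n_ligands):
        atoms = [
            Atom("C", pos.copy(), SCAFFOLD_CHARGE, 1.70, SCAFFOLD_EPSILON)
            for pos in scaffold
        ]
        present = rng.random(len(sites)) < spec.substituent_prob
        charges = rng.uniform(*spec.charge_range, size=len(sites))
        radii = rng.uniform(*spec.radius_range, size=len(sites))
        for s in range(len(sites)):
            if present[s]:
                atoms.append(
                    Atom("C", sites[s].copy(), float(charges[s]),
                         float(radii[s]), SUBSTITUENT_EPSILON)
                )
        mols.append(Molecule(ligand_id=f"syn{i + 1:03d}", atoms=atoms))
    return LigandSet(molecules=mols, activities=[], frame_tag="synthetic")


PLANT_OFFSET = 2.5  # Å off the substituent sites, where fields vary smoothly


def default_planted_coefficients(
    grid: GridSpec, sites: np.ndarray | None = None
) -> dict[int, float]:
    """Sparse planted weights near (not at) four substituent sites.

    Alternating-sign weights on electrostatic and steric columns of grid
    points 2.5 Å off-plane from the sites: close enough that substituent
    presence/charge/size drives the column, far enough that the probe
    energies are smooth rather than pinned at the truncation caps (a
    capped column is near-constant and would be pruned by the variance
    filter).  Gives the planted model both field kinds and both signs.
    """
    if sites is None:
        sites = default_substituent_sites()
    pts = grid.points()
    weights: dict[int, float] = {}
    chosen = [0, 2, 4, 6]
    signs = [1.0, -1.0, 1.0, -1.0]
    for rank, (s, sign) in enumerate(zip(chosen, signs)):
        away = 1.0 if sites[s][2] > 0 else -1.0
        target = sites[s] + np.array([0.0, 0.0, PLANT_OFFSET * away])
        p = int(np.argmin(np.linalg.norm(pts - target, axis=1)))
        kind_offset = rank % 2  # alternate electrostatic / steric columns
        weights[2 * p + kind_offset] = sign * (0.08 if kind_offset == 0 else 0.3)
    return weights


def plant_activities(
    ligs: LigandSet,
    grid: GridSpec,
    probe: ProbeSpec,
    spec: SyntheticSpec,
) -> tuple[LigandSet, DescriptorMatrix]:
    """Attach activities y = intercept + Σ w_c·D[:,c] + ε to the ligand set.

    The descriptor matrix used for planting (unfiltered, full column
    layout) is returned alongside so tests can verify recovery against
    the exact planted columns.
    """
    if not spec.planted_coefficients:
        raise ValueError("spec.planted_coefficients is empty")
    dm = build_descriptor_matrix(ligs, grid, probe)
    n_cols = dm.n_columns
    for c in spec.planted_coefficients:
        if not 0 <= c < n_cols:
            raise ValueError(f"planted column {c} outside grid layout (0..{n_cols - 1})")

    signal = np.full(dm.n_ligands, float(spec.intercept))
    for c, w in spec.planted_coefficients.items():
        signal += w * dm.values[:, c]

    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from structures
    sd = spec.noise_sd * float(np.std(signal)) if spec.noise_relative else spec.noise_sd
    y = signal + rng.normal(0.0, sd, size=len(signal)) if sd > 0 else signal

    activities = [
        ActivityRecord(ligand_id=m.ligand_id, pic50=float(y[i]))
        for i, m in enumerate(ligs.molecules)
    ]
    out = LigandSet(molecules=ligs.molecules, activities=activities,
                    frame_tag=ligs.frame_tag)
    return out, dm


def table1_fixture() -> pd.DataFrame:
    """The packaged 41-compound printed activity table.

    Columns: compound, ic50_nM, pic50_exp, pic50_pred, residual,
    set_label ('test' for the 8 externally validated compounds).
    """
    with resources.files("fieldqsar.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def table1_activity_table() -> pd.DataFrame:
    """Fixture reshaped to the standard activity-table schema."""
    df = table1_fixture()
    return pd.DataFrame({
        "ligand_id": df["compound"].astype(str),
        "ic50_nM": df["ic50_nM"],
        "pic50": df["pic50_exp"],
        "set_label": df["set_label"],
    })
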