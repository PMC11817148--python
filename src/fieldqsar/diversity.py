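"""Diversity-driven train/test partition over whole-molecule descriptors.

Five simple descriptors are computed per ligand — molecular weight,
heavy-atom count, net charge, radius of gyration, and an approximate
solvent-accessible surface area (Shrake–Rupley with a deterministic
golden-spiral point set) — standardized, and a maximin selection picks
the training subset: start from the medoid, then repeatedly add the
compound farthest (in minimum Euclidean distance) from the current
selection.  The procedure is fully deterministic, so repeated runs give
identical partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .ligand_io import Molecule

WATER_PROBE_RADIUS = 1.4  # Å
SASA_POINTS_PER_ATOM = 960


@dataclass
class FeatureVector:
    """Whole-molecule descriptors used for the diversity split."""

    ligand_id: str
    molecular_weight: float  # Da
    heavy_atom_count: int
    net_charge: float  # e
    radius_of_gyration: float  # Å
    sasa: float  # Å²

    def as_array(self) -> np.ndarray:
        return np.array([
            self.molecular_weight,
            self.heavy_atom_count,
            self.net_charge,
            self.radius_of_gyration,
            self.sasa,
        ])


def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points via the golden-angle spiral."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    mol: Molecule,
    probe_radius: float = WATER_PROBE_RADIUS,
    n_points: int = SASA_POINTS_PER_ATOM,
) -> float:
    """Approximate SASA (Å²) by golden-spiral surface-point counting.

    A surface point of atom i is buried if it lies within the expanded
    sphere of another atom j; boundary ties (relevant only for exactly
    coincident atoms) are kept by the lower-index atom so duplicated
    atoms do not double-count surface.
    """
    coords = mol.coords
    radii = np.array([a.vdw_radius for a in mol.atoms]) + probe_radius
    sphere = golden_spiral_points(n_points)
    total = 0.0
    tol = 1e-9
    for i in range(len(mol.atoms)):
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(mol.atoms)):
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            buried = d < radii[j] - tol
            if j < i:  # boundary tie-break: earlier atom keeps the point
                buried |= np.abs(d - radii[j]) <= tol
            accessible &= ~buried
        total += 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def feature_vector(mol: Molecule) -> FeatureVector:
    """Compute the descriptor vector for one ligand."""
    pt = Chem.GetPeriodicTable()
    mw = float(sum(pt.GetAtomicWeight(a.element) for a in mol.atoms))
    coords = mol.coords
    centroid = coords.mean(axis=0)
    rog = float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))
    return FeatureVector(
        ligand_id=mol.ligand_id,
        molecular_weight=mw,
        heavy_atom_count=len(mol.heavy_atoms()),
        net_charge=mol.net_charge,
        radius_of_gyration=rog,
        sasa=shrake_rupley_sasa(mol),
    )


def maximin_split(
    features: list[FeatureVector] | pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Deterministic maximin train/test partition.

    Features are standardized to zero mean / unit sd; the training set
    (round(train_fraction·n) compounds) is seeded Kennard–Stone style
    with the most distant pair of compounds, then greedily adds the
    compound with the greatest minimum distance to the selected set,
    ties broken by ligand_id order.  ``seed`` is accepted for interface
    uniformity but unused — the algorithm is deterministic.
    """
    del seed
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if isinstance(features, pd.DataFrame):
        ids = [str(i) for i in features["ligand_id"]]
        X = features.drop(columns=["ligand_id"]).to_numpy(dtype=float)
    else:
        ids = [f.ligand_id for f in features]
        X = np.array([f.as_array() for f in features])
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    if len(set(ids)) != n:
        raise ValueError("ligand ids must be unique")

    order = np.argsort(np.array(ids, dtype=object))  # tie-break order
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        warnings.warn("all features identical; falling back to id-ordered split",
                      stacklevel=2)
        train = [ids[i] for i in order[:n_train]]
        test = [ids[i] for i in order[n_train:]]
        return train, test
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    dist = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
    if n_train == 1:
        # degenerate: single training compound = medoid
        totals = dist.sum(axis=1)
        start = min(range(n), key=lambda i: (totals[i], ids[i]))
        selected = [start]
    else:
        # Kennard-Stone seed: the most distant pair, ties by ligand_id
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        d_max = max(dist[p] for p in pairs)
        i0, j0 = min(
            (p for p in pairs if dist[p] == d_max),
            key=lambda p: (ids[p[0]], ids[p[1]]),
        )
        selected = [i0, j0]
    remaining = set(range(n)) - set(selected)
    while len(selected) < n_train:
        min_d = dist[:, selected].min(axis=1)
        best = min(remaining, key=lambda i: (-min_d[i], ids[i]))
        selected.append(best)
        remaining.remove(best)
    train_ids = sorted((ids[i] for i in selected), key=lambda s: ids.index(s))
    test_ids = [ids[i] for i in sorted(remaining)]
    return train_ids, test_ids


def split_table(train_ids: list[str], test_ids: list[str]) -> pd.DataFrame:
    """CSV-ready `ligand_id,set_label` table for a partition."""
    return pd.DataFrame({
        "ligand_id": list(train_ids) + list(test_ids),
        "set_label": ["train"] * len(train_ids) + ["test"] * len(test_ids),
    })
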