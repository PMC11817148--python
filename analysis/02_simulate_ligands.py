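#!/usr/bin/env python
"""Generate the synthetic aligned-ligand study set.

Forty rigid ligands on a shared two-ring scaffold, varying only in
substituent presence/charge/size, with activity planted as a sparse
linear function of the grid field descriptors plus Gaussian noise at 5%
of the signal sd.  The set is written through the standard SDF/CSV
entry points so later stages exercise the same I/O as real data.

Writes: results/synthetic/ligands.sdf, results/synthetic/activities.csv
"""

from pathlib import Path

import pandas as pd

from fieldqsar.field_engine import ProbeSpec, build_grid
from fieldqsar.ligand_io import write_ligand_set
from fieldqsar.synthetic import (
    SyntheticSpec,
    default_planted_coefficients,
    generate_ligand_set,
    plant_activities,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(n_ligands=40, noise_sd=0.05, noise_relative=True,
                         seed=SEED)
    ligs = generate_ligand_set(spec)
    grid = build_grid(ligs.molecules, spacing=1.5, margin=4.0)
    spec.planted_coefficients = default_planted_coefficients(grid)
    ligs, _ = plant_activities(ligs, grid, ProbeSpec(), spec)

    write_ligand_set(ligs.molecules, OUT / "ligands.sdf")
    acts = pd.DataFrame({
        "ligand_id": [m.ligand_id for m in ligs.molecules],
        "pic50": [r.pic50 for r in ligs.activities],
    })
    acts.to_csv(OUT / "activities.csv", index=False)

    y = ligs.pic50
    print(f"Wrote {len(ligs)} aligned ligands (seed {SEED}) to {OUT}")
    print(f"Planted activity range: {y.min():.2f}..{y.max():.2f} pIC50, "
          f"sd {y.std():.2f}; planted columns: "
          f"{sorted(spec.planted_coefficients)}")


if __name__ == "__main__":
    main()
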