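# fieldqsar

Molecular field analysis (CoMFA-style) 3D-QSAR for aligned ligand sets:
probe interaction-energy grids as descriptors, NIPALS partial least
squares with cross-validated component selection, the full
Golbraikh–Tropsha external-validation battery, a leverage-based
applicability domain (Williams plot), and contour-region extraction for
interpreting where charge or steric bulk drives predicted potency.

The package was built around a study of 41 trans-stilbene derivatives
inhibiting cytochrome P450 1B1 (CYP1B1), a target of interest because
it activates procarcinogens and inactivates several chemotherapeutics
in tumor tissue. Given docking-aligned 3D conformers and IC50 data, the
pipeline reproduces that style of analysis end to end; the published
41-compound activity table ships as a packaged fixture, and a synthetic
aligned-ligand generator provides ground-truth data for testing every
stage without any external download.

## The model

For ligands aligned in a common frame, a rectilinear grid (default
spacing 1.5 Å, 4 Å margin) is laid over the ensemble. At every node
two probe energies are evaluated per ligand:

* electrostatic: `E_q(g) = Σ_i 332.0636 · q_probe · q_i / r_gi` (kcal/mol,
  unit positive test charge, dielectric 1, truncated to ±30 kcal/mol);
* steric: `E_s(g) = Σ_i ε_ci [(r_m/r_gi)¹² − 2(r_m/r_gi)⁶]` with
  `r_m = R_probe + R_i` (carbon-like probe, R = 1.73 Å), truncated above
  at +30 kcal/mol.

Rows (ligands) × columns (grid point × field kind) form the descriptor
matrix **X**; near-constant columns (sd < 0.05 kcal/mol) are dropped.
Activity `y = pIC50 = −log10(IC50 [mol/dm³])` is regressed on **X** by
NIPALS PLS with mean-centering only. The component count A maximizes
the 5-fold cross-validated `Q² = 1 − PRESS/SS_tot`. External validity
uses the standard battery: `r²`, through-origin `r0², k0` (observed on
predicted) and `r0′², k0′` (reversed axes), `rm² = r²(1 − √(r²−r0²))`,
with thresholds Q² > 0.5, r² > 0.6, slope and closeness conditions.
The applicability domain is delimited by leverage `h = 1/n + t(TᵀT)⁻¹tᵀ`
in latent-score space against `h* = 3p′/n` and by ±3 standardized
residuals. Fitted coefficients map back onto the grid as sd-weighted
values whose extreme percentiles mark the favorable/unfavorable
steric ("green"/"yellow") and electrostatic ("blue"/"red") regions.

## Worked example

The analysis is organized as numbered drivers over the library:

```sh
python analysis/01_table1_battery.py    # published-table validation
python analysis/02_simulate_ligands.py  # synthetic aligned ligand set
python analysis/03_fit_and_validate.py  # fields -> PLS -> validation -> AD
python analysis/04_contour_maps.py      # contour region summary
```

`01` runs the external battery on the 8 test-set (experimental,
predicted) pIC50 pairs of the packaged 41-compound table and prints

```
Q2(cv)          0.554
r2              0.808
r0^2            0.801
r0'^2           0.795
(r2-r0^2)/r2    0.009
(r2-r0'^2)/r2   0.016
|r0^2-r0'^2|    0.006
k0              0.993
k0'             1.004
rm^2            0.739
rm'^2           0.716
overall         PASS
```

i.e. the model behind the table is externally predictive: r² > 0.6, the
through-origin fits track the correlation (ratios ≪ 0.1), slopes are
within 0.85–1.15, and both rm² metrics clear 0.5. It also reports the
largest residual (compound 12, +0.623 pIC50) and the warning leverage
`h* = 3·3/33 = 0.273` for the 33-compound training set of the
3-component model.

`02`–`04` generate 40 synthetic aligned ligands whose activity is a
planted linear function of four field columns plus 5% noise, then run
the full pipeline on them. A typical run selects 2 components with
Q² = 0.885 and a training r² = 0.945; the run directory contains the
model JSON, the descriptor TSV, residual/AD tables and OpenDX contour
maps. The printed note about the failed external battery on this
synthetic set is itself instructive: the maximin split concentrates the
activity extremes in the training set (activity sd 1.43 train vs 0.18
test), so correlation metrics on the homogeneous test remainder are
underpowered — a caveat worth knowing when applying diversity splits to
narrow-range data.

A `fieldqsar` command-line interface exposes each stage
(`fields`, `fit`, `validate`, `ad`, `contour`, `split`, `simulate`,
`run`) for use on real aligned SDF/MOL2 + CSV inputs.

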