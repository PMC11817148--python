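# Methods

## Field descriptors

Ligands must arrive rigid and pre-aligned in one shared coordinate
frame (the intended source is a docking run; the package deliberately
contains no docking, minimization, or conformer generation). The grid
is the union bounding box of all atoms expanded by a margin (default
4 Å) on every face, with nodes every `spacing` Å (default 1.5 Å) and
`floor(extent/spacing) + 1` nodes per axis, minimum 2 so planar
ensembles still yield a volume. Grid nodes are ordered z-fastest, and
descriptor columns are point-major with the electrostatic column before
the steric column at each point — fixed so that matrices, serialized
models, and OpenDX exports all agree on the layout.

Electrostatics use Coulomb's law with K = 332.0636 kcal·Å/(mol·e²) and
a constant dielectric of 1 for a +1 e probe. The source protocol names
the probe but not its dielectric model; a unit constant dielectric is
the simplest defensible convention and is exposed in the configuration.
Sterics use a 12-6 Lennard-Jones probe of radius 1.73 Å and well depth
0.0903 kcal/mol (a generic sp³ carbon; only the radius is
protocol-fixed), with Lorentz–Berthelot-style combination: arithmetic
radii, geometric well depths. Energies are truncated — electrostatic to
±30 kcal/mol, steric above +30 kcal/mol — the classic molecular-field
treatment of grid points inside atoms; a node within 10⁻⁶ Å of an atom
is clamped to the cap rather than diverging. No distance cutoff is
applied to the atom sums: the cost is O(atoms × points) and negligible
at ligand scale. Columns with standard deviation below 0.05 kcal/mol
across the ligand set carry no usable signal (most are flat background
or saturated caps) and are removed before regression.

Per-atom vdW parameters come from a packaged element table (H, C, N, O,
S, P, halogens); unknown elements raise rather than defaulting
silently. Partial charges are read from the input file
(`PARTIAL_CHARGES` SD field or Tripos charges); when a file carries
none, Gasteiger charges are assigned with a warning — a deterministic,
widely reproduced scheme chosen because the original force-field
charge assignment is bound to a proprietary toolchain.

## PLS regression and component selection

The regression is NIPALS PLS for a single response, fitted on
mean-centered X and y with no per-column scaling: all field columns
share kcal/mol units, and autoscaling would inflate near-noise columns.
Optional per-field block scaling (each field kind divided by its pooled
sd) is available behind a flag for data where one field dominates.
Convergence tolerance is 1e−10 on the weight vector with a 500
iteration cap (for a single y the inner loop converges in one pass);
requesting more components than the rank of X raises once the deflated
covariance vanishes. Coefficients are folded back to the original
column space, so prediction is a plain affine map and serialized models
(JSON) reload exactly.

Q² is computed by k-fold cross-validation (default 5 folds): fold
membership by a seeded uniform shuffle into near-equal parts, PRESS
pooled over folds, and SS_tot taken about the full-training-set mean.
The component count scans A = 1..max_A (default min(10, n−2)), keeping
the highest Q² with ties to the smaller model; the full candidate trace
is stored on the model. The default CV seed is 20250124; fold
construction is not specified by the source protocol, so the seed is
part of the reported configuration rather than a hidden state.

## External validation

The battery follows the standard external-validation conventions:
squared Pearson r² between observed and predicted; through-origin
regression of observed on predicted giving k0 = Σ(y·ŷ)/Σ(ŷ²) and
r0² = 1 − SSE₀/SST; the reversed-axes pair (k0′, r0′²); closeness
ratios (r²−r0²)/r²; and rm² = r²(1 − √max(0, r²−r0²)). The axis
convention is pinned by arithmetic against the published table: the
"corresponding" plot regresses observed on predicted (k0 = 0.993 from
the printed pairs), the "reversed" plot the transpose (≈1.004). The
r²−r0² difference is clamped at zero before the square root — negative
values can arise only from rounding noise. Thresholds: Q² > 0.5,
r² > 0.6, either closeness ratio < 0.1, either slope in [0.85, 1.15],
|r0²−r0′²| < 0.3, both rm² > 0.5. A missing Q² marks that check
not-applicable instead of failing the battery.

Published values recomputed from the 3-decimal printed pairs agree at
3 decimals for r², r0², r0′², k0 and the ratios; rm², rm′² and
r0²−r0′² land within 0.003/0.002 of the printed values, consistent with
the published battery having been computed from unrounded predictions.
Tests assert at exactly those tolerances.

## Applicability domain

Leverage is computed in the model's latent-score space with an
intercept column: h = 1/n + t(T_trainᵀT_train)⁻¹tᵀ. This is the
standard choice for PLS models — the raw descriptor space has thousands
of collinear columns and no invertible covariance — and yields the
trace identity Σh = A + 1 over training rows, which the tests assert.
The warning leverage is h* = 3p′/n with p′ = the number of latent
variables: with the published 33-compound training set and 3 components
this reproduces the printed 0.273 (the alternative "variables + 1"
reading would contradict the 3-component model). p′ is exposed as a
parameter. Standardized residuals divide by the training estimate
s = √(SSE/(n−A−1)) for training and test compounds alike; flags are
h > h* (structural) and |σ| > 3 (response).

## Contour maps

Each retained column belongs to one grid point and field kind; its
sd-weighted coefficient (coefficient × column sd, pIC50 per sd of field
energy) is mapped back to its point, filtered columns contributing 0.
The sd-weighting makes contour levels scale-free, so the default
levels — the 90th/10th percentiles of the nonzero values — need no
energy units. Points strictly above/below the levels are labeled
favorable_high/favorable_low; with constant nonzero values both levels
coincide and everything stays neutral; filtered (zero) points are
always neutral. Sign semantics follow the probes: positive
electrostatic values mark regions where positive potential raises
predicted activity (the "blue" regions of the usual rendering, "red"
for negative), positive steric values the bulk-favored "green"
("yellow" for negative). Export is an OpenDX scalar grid (z-fastest
order, round-trip tested to 1e−6) plus a CSV of labeled points — data
sufficient to redraw the isosurfaces, with no 3D rendering in scope.

## Diversity split

Whole-molecule descriptors: molecular weight, heavy-atom count, net
charge, radius of gyration, and approximate SASA by Shrake–Rupley
counting over a deterministic golden-spiral point set (960 points per
atom, 1.4 Å water probe). Boundary ties in the occlusion test —
relevant only for exactly coincident atoms — are kept by the
lower-index atom, so duplicated atoms do not double-count surface.
Features are standardized and the training subset (round(fraction·n),
default 80%) selected by maximin: seeded Kennard–Stone style with the
most distant pair, then greedily adding the compound with the greatest
minimum distance to the selection, ties broken by ligand id. The
farthest-pair seed (rather than a medoid start) makes the two-compound
selection coincide with the brute-force maximin pair, which is the
defining property of the design. The original study's "Diverse
Molecules" algorithm is proprietary; its actual 33/8 partition ships
with the packaged activity table and should be used for reproduction
runs, the algorithm being intended for new data sets.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes: a rigid shared scaffold (two hexagonal rings plus a two-atom
linker, echoing a trans-stilbene) with eight substituent sites where
pseudo-atoms appear with probability 0.5, uniform charge in
(−0.4, 0.4) e and radius in (1.2, 1.9) Å. Activities are planted as
y = intercept + Σ w_c·X_c + ε on four descriptor columns (both field
kinds, both signs) at grid points 2.5 Å off-plane from four sites —
columns at the sites themselves sit inside atoms whenever the
substituent is present, are pinned at the truncation caps, and are
pruned by the variance filter, which would make the planted signal
unrecoverable by construction. Noise is Gaussian, either absolute in
pIC50 units or relative to the planted signal sd; the study condition
used throughout the tests is 40 ligands at 5% relative noise. All
randomness flows from a single integer seed through one named
generator.

What the generator does not emulate: real chemistry (no bonds, no
conformers — the pipeline is chemistry-agnostic downstream of
atoms + charges + radii), structured noise, activity cliffs, or the
decorrelation of activity from whole-molecule size found in real
series. The last point matters for interpretation: because planted
activity tracks substituent load, a maximin-diverse training selection
concentrates the activity range in training and leaves a
narrow-range test set on which correlation-based external metrics are
underpowered (driver 03 reports this). Passing tests therefore
demonstrate correctness of the machinery, not external predictivity on
any particular real data set.

## Problem sizes and numerical choices

Test and driver runs use 14–40 ligands on grids of roughly 800 points
(≈1600 raw columns, ≈1000 after filtering), where a full pipeline run
takes a few seconds. Exact training-fit recovery of noiseless planted
signals requires NIPALS depth near the matrix rank, so that check runs
at n = 20 with A = 18; the permutation-null and noise-monotonicity
simulations use 100 shuffles and 10 replicates per noise level
respectively. Degenerate inputs are rejected loudly rather than
patched: zero-variance y, empty ligand lists, all-filtered descriptor
matrices, singular score covariances and mismatched column counts all
raise with named causes.

## Known limitations

* The published Q² = 0.554 and per-compound predictions depend on the
  proprietary docking poses and the commercial field implementation and
  cannot be reproduced desk-side; the package anchors itself instead on
  the printed activity table (exactly reproduced) and on property-based
  ground truth from the synthetic generator.
* Only electrostatic and steric probe fields are implemented — no
  hydrophobic, H-bond or indicator fields.
* MOL2 reading relies on RDKit's Tripos parser; exotic atom types may
  need pre-conversion.
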