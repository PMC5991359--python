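# Methods

This note documents the models, algorithms, parameters and design choices
behind `mc3ssm`, and what its synthetic validation does and does not
demonstrate.

## Problem and model

The package builds statistical shape models (point distribution models) of
the distal epiphysis of the equine third metacarpal bone (MC3), combining
three-dimensional geometry with subchondral bone mineral density (BMD)
mapped from calibrated CT. A training population of corresponded surface
meshes — every specimen expressed on the same fixed template topology, node
`j` meaning the same anatomical location everywhere — is stacked into a
matrix and decomposed by PCA: any specimen is approximated as

    x  =  x̄  +  Σᵢ ωᵢ φᵢ

with mean `x̄`, orthonormal components `φᵢ` and per-mode scores `ωᵢ`
(expressed in standard-deviation units throughout the API, so ±2 SD spans
roughly 95% of the population along a mode). Three flavors are supported:
shape-only (N×3n coordinates, covariance PCA), density-only (N×n), and the
combined N×4n model interleaving (x, y, z, I) per node, standardized
per variable before the SVD (correlation PCA) because coordinates (mm) and
density (g/cm³) carry different units. The number of retained modes is the
smallest count reaching the cumulative variance target (default 80%).

Mode signs are arbitrary in PCA; components are oriented so that the shape
loading has a positive inner product with the mean shape's outward radial
directions (ties: first nonzero entry positive), making directional
statements like "larger bones are denser" reproducible.

## Synthetic study population

No CT archive ships with the package; a fully analytic generator stands in
for the training set so every stage can be validated against known ground
truth. Its defaults are the study conditions used by the tests and the
acceptance script:

* 40 specimens; CT voxels 0.3 × 0.3 mm in plane, 0.6 mm slices; a
  hydroxyapatite phantom of 800 mg/cm³ (phantom HU 1600, water 0); the
  mesh cut 45 mm proximal to the most distal point.
* Base surface: superelliptical cross-sections (half-axes 26 × 20 mm,
  exponent 2.5) lofted over an elliptically rounded distal cap
  (12 mm axial extent), with medial/lateral condylar bulges (5.0 / 3.5 mm),
  parasagittal grooves (1.5 mm) and a central sagittal ridge
  (2.0 mm high, dimensionless width 0.26 in cos-azimuth). Features are
  dorsally biased (+35%) and the distal centerline shifts 4 mm dorsally —
  real MC3 epiphyses are not mirror symmetric, and without these
  asymmetries rigid initialization could settle in a flipped frame.
* Three generative latent modes at variance fractions 0.50 / 0.30 / 0.15:
  overall size (isotropic about the centroid, ~4%/SD before
  normalization), dorsal sagittal-ridge prominence, and lateral/medial
  condyle asymmetry; each couples a displacement field with a BMD loading
  (size ↔ +BMD, ridge ↔ +local BMD, asymmetry ↔ −dorsal condylar BMD).
  The displacement fields are Gram–Schmidt orthogonalized and rescaled so
  the fractions are exact by construction; scores are standard normal.
* Noise: 0.05 mm iid node jitter, 0.1 mm point-cloud jitter (sub-voxel
  segmentation error), 0.02 g/cm³ density jitter, 5 HU scanner noise.
  Poses: rotations ±30°, translations ±20 mm.
* Point clouds are Poisson-sampled area-uniformly at 1 point/mm²
  (≈ 8000 points) and evaluated on the exact parametric surface.

Voxelization assigns piecewise-constant HU per region (no beam hardening
or partial-volume modeling beyond the grid itself). Bone interior HU is
the surface density transported inward along interpolated nodal normals
(a stack of offset shells to 6 mm; deeper voxels take the closest-surface
value), inverted through the phantom calibration — by construction, 5 mm
subchondral ray averages recover the generator's node densities. This
transport is only single-valued where the density field varies on scales
broader than the local curvature radius; the generator therefore uses
wider spatial windows for density loadings than for shape bumps, and the
ridge is kept broad enough that inward rays stay inside bone. The bone is
also filled 3.5 mm past the proximal cut plane (the physical specimen is
transected further up), so boundary-ring rays do not sample air.

## Template and fitting

The template is a fixed quad-patch layout instantiated once on the
synthetic base surface: 36 bicubic Lagrange patches (4×4 nodes each,
C⁰ across shared edges; whether the original-style meshes enforced C¹ is
unknown, C⁰ proved sufficient), 337 nodes — a 2×2 "squircle" cap closes
the distal end without degenerate edges (the pole is a regular valence-4
node) and an 8×4 shell covers the epiphysis/metaphysis up to the cutoff
ring. Anatomical landmarks (medial/lateral edges, condylar and groove
stations, ridge crest, metaphysis ring) and the condylar region subsets
are frozen node/patch index lists in the template manifest; the palmar and
dorsal BMD regions are deliberate approximations.

Fitting a segmented cloud:

1. **Pre-alignment** — area-weighted centroid/principal-axes/scale
   initialization (best of the four proper axis-sign choices, scored by
   mean nearest-sample distance), polished by 12 similarity-ICP and 8
   affine-ICP iterations on ~800 area-weighted surface samples. The
   affine phase exists because the host lattice spans affine maps but
   closest-point iteration recovers them only at a crawl.
2. **Host-mesh fit** — the template is embedded in a 4×4×4 tricubic
   Bernstein free-form-deformation lattice over its bounding box
   (+5% + 2 mm margin); ICP rounds alternate point-to-surface
   correspondence with a linear solve for the 64 control points,
   penalizing lattice second differences (weight 1e-5 — weaker than an
   initial guess of 1e-2/1e-4 because the coarse 0.5 mm threshold must be
   met on every specimen within the iteration budget; 40 iterations,
   stop at <1e-4 mm improvement). Non-convergence is reported via the
   `converged` flag, never an exception.
3. **Fine fit** — per-node linear solves with a Sobolev-type penalty
   (patch second parametric derivatives of the displacement from the
   initial nodes, weight 1e-3, plus a 1e-3 L2 anchor so an infinite
   smoothing weight reproduces the initial fit); the best-RMS iterate is
   kept, so the fine fit never worsens its initialization.

Point-to-surface projection seeds Newton iterations from a KD-tree over a
17×17-per-patch sample grid with 4 candidate patches per query; full
Newton (with curvature terms) is used because distant queries mislead
Gauss–Newton. Exact ties break toward the lowest patch id. RMS is always
cloud-point-to-surface (the direction is a convention choice; the
alternative node-to-cloud direction is not used).

## Correspondence

Per-specimen fits share topology but nodes can slide tangentially —
point-to-surface RMS cannot see sliding. Two stages address this:

1. The classic fit–train–refit loop: generalized Procrustes alignment
   (rigid only — size must stay in the model, since the leading mode is
   overall size), shape PCA, projection of each fit onto the components
   covering 98% variance (regularizing the parameterization), release to
   an unconstrained fine fit; repeated until the population mean RMS is
   below 0.3 mm and no longer improves (≤10 rounds; refits that would
   worsen a specimen's RMS by more than 1e-3 mm are rejected).
2. A normal-projection reparameterization polish (12 rounds; the first
   half "deflated", see below): the template plus the current model's
   normal-projected mode fields is registered to each fitted surface by a
   linearized similarity+modes solve (an active-shape-model fit: the
   modes absorb the non-rigid variation, so the similarity pose is not
   biased by it), then every node is re-placed where the ray from the
   similarity-posed, isotropically scaled template node, cast along the
   template normal, pierces the fitted surface. Rays that miss (open
   boundary) fall back to closest-point projection. This fixes the
   correspondence *convention*: inter-specimen variation becomes
   similarity pose plus normal offsets from the template.

Deflation: mode fields learned from sliding-contaminated fits carry
"ghost" components along the similarity group's normal-action fields
(the apparent normal displacement a small rotation or scaling produces),
which lets the registration trade pose against modes. Warm-up rounds
remove that span from the mode fields to break the feedback; later rounds
use the full fields.

**Known limitation.** With oracle (true generator) mode fields the
reparameterization recovers the generator's correspondence to ~0.17 mm
mean (99% of node/specimen distances < 0.6 mm). With modes learned from
the data, a score-correlated contamination feedback survives the
bootstrap: the pipeline converges to ~0.39 mm mean node-to-ground-truth
distance at the default study scale — well under the 0.6 mm (2 in-plane
voxels) criterion on the mean, with the residual concentrated on the
featureless distal cap where tangential position is weakly observable
(per-node mean distances exceed 0.6 mm for ~7% of nodes, all cap
interior). Statistics built on the model (variance fractions, LOO
curves) are unaffected, because the contamination is self-consistent
across the population.

## Density mapping

At each node the unit inward normal (from the parametric patches, with
consistent outward winding fixed in the template) is followed 5 mm into
the bone — the depth at which subchondral plate porosity increases in
mature racehorses — in 0.25 mm steps (≲ the in-plane voxel), both
endpoints included with uniform weights; the volume is sampled
trilinearly and the mean HU is converted by the phantom calibration

    ρ_HA  = (CT_bone − CT_H2O) / (CT_HA − CT_H2O) · ρ_phantom
    ρ_app = ρ_HA / 0.626          E = 2017.3 · ρ_app^2.46  [MPa]

The 0.626 divisor is treated as a unitless constant. Negative ρ_HA
(sub-water HU) is propagated but flagged and excluded from regional means
and the power law. Rays leaving the volume flag their node. Units are
g/cm³ internally; phantom config is mg/cm³, converted on load. The
combined model's intensity channel is apparent BMD by default (`modulus`
via config), matching how results are usually reported.

## Morphometry

All measurements are topology-driven: widths are distances between named
landmark node pairs, the metaphysis circumference is a closed polyline,
areas are 4×4 Gauss–Legendre quadrature over named patch subsets, and
regional BMD averages node densities over named subsets (flagged nodes
excluded). "Total area" is the whole meshed surface up to the cutoff
ring. Mode effects reconstruct a single component at ±2 SD and report
percent changes with the mean-shape value as the denominator.

## Validation scale and runtime choices

The default test/acceptance problem sizes are the packaged study
conditions: 40 specimens for fitting/correspondence/training, n = 200
(five seeds) for generative-mode recovery, N = 20 for leave-one-out
sanity, one noiseless specimen for the voxel round trip. These sizes keep
a full run in the tens of minutes on one CPU while leaving the
statistical checks meaningful; the generator itself scales to larger
populations unchanged.

What passing these checks shows: the pipeline's numerics (projection,
fitting, PCA, calibration) are correct against independent oracles, and
the method recovers *known* latent structure under CT-like noise. What it
does not show: behavior on real segmentations (outliers, missing data,
cartilage, beam hardening), anatomically exact MC3 geometry, or clinical
interpretability of the modes.

## Numerical details and edge cases

* Degenerate inputs: N = 2 trains a one-mode model; constant variables in
  the correlation PCA get unit scale and contribute nothing; identical
  populations give zero LOO error at every k.
* Rigid-motion equivariance of fitting holds to ~1e-3 mm RMS (ICP
  correspondences switch discretely under round-off, so exact
  equivariance is not attainable); the variance spectrum of a trained
  model is invariant to common rigid motion to 1e-9 and to density unit
  rescaling (combined flavor) to 1e-12.
* Determinism: every random draw flows from explicit seeds
  (`numpy.random.default_rng`); pipeline stages are pure functions of
  (config, seed) and re-runs are byte-identical.
* The correspondence loop records per-round RMS; the mean is
  non-increasing over the refit rounds by construction (worsening refits
  are rejected) and the final reparameterization stage stays within the
  0.3 mm target.
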