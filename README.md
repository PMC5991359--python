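# mc3ssm

Statistical shape and subchondral bone-mineral-density (BMD) modeling of
the **equine distal third metacarpal bone (MC3)** — the most common site
of catastrophic fracture in Thoroughbred racehorses. The package builds
point distribution models that describe how three-dimensional epiphyseal
geometry and phantom-calibrated subchondral density co-vary across a
population of CT-scanned bones.

It is aimed at musculoskeletal/biomechanics researchers who want a fully
tested, reproducible reference implementation of the classic
template-fitting SSM workflow, with a synthetic CT generator standing in
for real scan archives so that every stage can be validated against known
ground truth.

## The model

A training set of N corresponded surface meshes (n nodes on a shared
bicubic-Lagrange quad-patch template) is stacked into a matrix and
decomposed by SVD after centering. Any bone is approximated as

```
x = x̄ + Σᵢ ωᵢ φᵢ
```

with mean shape `x̄`, principal components `φᵢ` and scores `ωᵢ` in
standard-deviation units. Shape-only (N×3n, covariance PCA), density-only
(N×n) and combined (N×4n per-node `(x, y, z, I)`, correlation PCA for the
mixed units) flavors are provided; retained components cover a cumulative
variance target (default 80%).

The full workflow:

1. **synthetic data** — analytic MC3-like surfaces with three latent modes
   (size, sagittal-ridge prominence, condylar asymmetry) coupled to BMD
   loadings; Poisson-sampled point clouds; voxelized Hounsfield-unit
   volumes with a hydroxyapatite calibration phantom;
2. **mesh fitting** — host-mesh (free-form-deformation lattice)
   registration of the template to each cloud (< 0.5 mm RMS), then
   per-node fine fitting with Sobolev smoothing;
3. **correspondence** — generalized Procrustes alignment plus the
   iterated fit–train–refit loop with a shape-model constraint
   (population mean RMS < 0.3 mm), finished by a normal-projection
   reparameterization that removes tangential node sliding;
4. **density mapping** — 5 mm inward-normal sampling of the CT volume at
   each node; `ρ_HA = (CT_bone − CT_H2O)/(CT_HA − CT_H2O)·ρ_phantom`;
   `ρ_app = ρ_HA/0.626`; `E = 2017.3·ρ_app^2.46` MPa;
5. **statistics** — PCA training, reconstruction/projection,
   leave-one-out error curves, per-component morphometry (±2 SD widths,
   areas, regional BMD).

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import numpy as np
from mc3ssm import (SyntheticSpec, sample_population, export_point_cloud,
                    host_mesh_fit, fine_fit, correspondence_loop,
                    stack_shape, train)

spec = SyntheticSpec(n_specimens=10, seed=7)
base, modes, pop = sample_population(spec, return_base=True)
rng = np.random.default_rng(11)
clouds = [export_point_cloud(base, p, spec.cloud_density,
                             spec.point_noise_sd, rng) for p in pop]

fits = [fine_fit(host_mesh_fit(base, c), c) for c in clouds]
result = correspondence_loop(base, clouds, fits)
model = train(result.aligned.shape_matrix(), "shape")

print(f"mean surface RMS : {result.mean_rms:.3f} mm")
print("variance fractions:", np.round(model.variance_fractions[:4], 3))
```

Output (exact numbers depend on the seeds):

```
mean surface RMS : 0.101 mm
variance fractions: [0.526 0.269 0.195 0.004]
```

The mean cloud-to-surface RMS of 0.101 mm is comfortably below the 0.3 mm
correspondence target (about 0.1 mm of it is the synthetic segmentation
jitter), and the first three recovered components carry essentially all
of the population variance, matching the three latent modes the generator
planted (0.50/0.30/0.15 for this 10-bone sample, up to sampling noise).

The same workflow is scriptable from the shell:

```
mc3ssm run-all --stage-dir run1 --seed 7
```

which writes per-stage artifacts (clouds, fits, aligned set, per-node
density CSVs, model archives, variance table, LOO curve, morphometry
report) plus JSON manifests into `run1/`.

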