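"""Point-distribution models of shape and bone mineral density.

A training set of N corresponded meshes (n nodes each) is stacked into a
matrix and decomposed by SVD after centering:

* ``shape``    -- N x 3n matrix of node coordinates, covariance PCA;
* ``density``  -- N x n matrix of node densities, covariance PCA;
* ``combined`` -- N x 4n matrix interleaving (x, y, z, I) per node, where I
  is the density (or modulus) channel; correlation-based PCA (each variable
  divided by its population standard deviation) because the channels carry
  mixed units.

Any specimen is approximated as the mean plus a weighted sum of the
retained principal components; weights are expressed in standard-deviation
units, so reconstructing at +-2 SD of a single mode spans roughly 95% of
the population along that mode.  The number of retained modes is the
smallest count whose cumulative explained variance reaches the variance
target (default 80%).

Model quality is assessed by leave-one-out reconstruction error
(:func:`loo_analysis`): geometric RMS in mm and density RMS in g/cm^3 as a
function of the number of components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SSMModel",
    "LooCurve",
    "train",
    "reconstruct",
    "project",
    "loo_analysis",
    "stack_shape",
    "stack_density",
    "stack_combined",
    "split_combined",
    "save_model",
    "load_model",
    "variance_table",
]

FLAVORS = ("shape", "density", "combined")


def stack_shape(coords: np.ndarray) -> np.ndarray:
    """(N, n, 3) node coordinates -> (N, 3n) with per-node x,y,z interleave."""
    coords = np.asarray(coords, float)
    return coords.reshape(coords.shape[0], -1)


def stack_density(densities: np.ndarray) -> np.ndarray:
    return np.asarray(densities, float).reshape(len(densities), -1)


def stack_combined(coords: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """(N, n, 3) + (N, n) -> (N, 4n) with fixed per-node (x, y, z, I) order."""
    coords = np.asarray(coords, float)
    intensity = np.asarray(intensity, float)
    N, n, _ = coords.shape
    out = np.empty((N, 4 * n))
    out.reshape(N, n, 4)[:, :, :3] = coords
    out.reshape(N, n, 4)[:, :, 3] = intensity
    return out


def split_combined(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`stack_combined` for a single 4n vector."""
    v = np.asarray(vec, float).reshape(-1, 4)
    return v[:, :3].copy(), v[:, 3].copy()


@dataclass
class SSMModel:
    """A trained point-distribution model.

    ``components`` rows are orthonormal in the standardized space;
    ``scales`` are the per-variable standardization divisors (all ones for
    covariance PCA); ``mode_sd[i]`` is the standard deviation of the
    training scores along mode i (singular value / sqrt(N - 1)).
    """

    flavor: str
    mean_vector: np.ndarray
    components: np.ndarray          # (n_modes, n_vars), orthonormal rows
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    scales: np.ndarray
    n_retained: int
    n_training: int
    variance_target: float

    @property
    def mode_sd(self) -> np.ndarray:
        return self.singular_values / np.sqrt(self.n_training - 1)

    @property
    def n_variables(self) -> int:
        return self.mean_vector.size

    @property
    def n_modes(self) -> int:
        return len(self.components)


def _shape_block_indices(flavor: str, n_vars: int) -> np.ndarray:
    if flavor == "shape":
        return np.arange(n_vars)
    if flavor == "combined":
        return np.delete(np.arange(n_vars), np.arange(3, n_vars, 4))
    return np.arange(0)


def _fix_signs(components: np.ndarray, mean_vector: np.ndarray, flavor: str) -> np.ndarray:
    """Deterministic mode-sign convention.

    PCA component signs are arbitrary, but directional statements (e.g.
    "larger bones have higher density") need a reproducible orientation.
    Each component is flipped, if necessary, so that its shape loading has
    positive inner product with the per-node outward radial directions of
    the mean shape (for the density flavor: positive loading sum); exact
    ties fall back to a positive first nonzero entry.
    """
    comp = components.copy()
    n_vars = mean_vector.size
    if flavor in ("shape", "combined"):
        idx = _shape_block_indices(flavor, n_vars)
        mean_nodes = mean_vector[idx].reshape(-1, 3)
        radial = mean_nodes - mean_nodes.mean(axis=0)
        nrm = np.linalg.norm(radial, axis=1, keepdims=True)
        nrm[nrm < 1e-12] = 1.0
        radial = (radial / nrm).ravel()
        keys = comp[:, idx] @ radial
    else:
        keys = comp.sum(axis=1)
    for i, key in enumerate(keys):
        if abs(key) > 1e-12:
            if key < 0:
                comp[i] = -comp[i]
        else:
            nz = np.nonzero(np.abs(comp[i]) > 1e-12)[0]
            if len(nz) and comp[i, nz[0]] < 0:
                comp[i] = -comp[i]
    return comp


def train(
    training_matrix: np.ndarray,
    flavor: str = "shape",
    variance_target: float = 0.80,
    standardize: str | None = None,
) -> SSMModel:
    """Fit a point-distribution model to stacked training vectors.

    Parameters
    ----------
    training_matrix : (N, n_vars)
        One specimen per row (see the ``stack_*`` helpers).
    flavor : 'shape' | 'density' | 'combined'
        Combined flavor standardizes each variable by its standard
        deviation before the SVD (correlation PCA, mixed units); the other
        flavors use covariance PCA.
    variance_target : float
        Retain the smallest number of modes reaching this cumulative
        explained-variance fraction.
    standardize : None | 'per-variable' | 'per-block'
        Override the combined flavor's standardization granularity.
        'per-block' uses one scale for the coordinate block and one for the
        intensity block (root-mean variance over the block's variables).
    """
    X = np.asarray(training_matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training matrix must have at least two specimen rows")
    if flavor not in FLAVORS:
        raise ValueError(f"flavor must be one of {FLAVORS}")
    bad = np.argwhere(~np.isfinite(X))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-finite value in training matrix at specimen {i}, variable {j}"
            + (f" (node {j // 4}, channel {j % 4})" if flavor == "combined" else
               f" (node {j // 3})" if flavor == "shape" else f" (node {j})")
        )

    N, n_vars = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    if flavor == "combined":
        mode = standardize or "per-variable"
        if mode == "per-variable":
            scales = X.std(axis=0, ddof=1)
        elif mode == "per-block":
            scales = np.empty(n_vars)
            coord_idx = _shape_block_indices("combined", n_vars)
            int_idx = np.arange(3, n_vars, 4)
            scales[coord_idx] = np.sqrt(np.mean(X[:, coord_idx].var(axis=0, ddof=1)))
            scales[int_idx] = np.sqrt(np.mean(X[:, int_idx].var(axis=0, ddof=1)))
        else:
            raise ValueError("standardize must be 'per-variable' or 'per-block'")
        # zero-variance variables carry no information; give them unit scale
        scales = np.where(scales < 1e-12, 1.0, scales)
        Xc = Xc / scales
    else:
        scales = np.ones(n_vars)

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    nz = s > max(1e-12, s[0] * 1e-10) if len(s) else s > 0
    s, Vt = s[nz], Vt[nz]
    var = s**2
    fractions = var / var.sum()
    comp = _fix_signs(Vt, mean, flavor)
    n_retained = int(np.searchsorted(np.cumsum(fractions), variance_target - 1e-12) + 1)
    n_retained = min(n_retained, len(s))
    return SSMModel(flavor, mean, comp, s, fractions, scales, n_retained, N,
                    variance_target)


def reconstruct(model: SSMModel, weights) -> np.ndarray:
    """Mean + weighted principal components; weights in SD units.

    ``weights[i]`` multiplies mode i scaled by its training-score standard
    deviation, so ``reconstruct(model, [2])`` is the "+2 SD" instance of
    mode 1.
    """
    w = np.atleast_1d(np.asarray(weights, float))
    if len(w) > model.n_retained:
        raise ValueError(
            f"{len(w)} weights but only {model.n_retained} retained modes")
    x = model.mean_vector.copy()
    if len(w):
        x = x + ((w * model.mode_sd[: len(w)]) @ model.components[: len(w)]) * model.scales
    return x


def project(model: SSMModel, vector: np.ndarray, k: int | None = None):
    """Least-squares mode weights (SD units) of a specimen vector.

    Returns
    -------
    weights : (k,) array
    residual : float
        Norm of the out-of-subspace remainder in the standardized space.
    """
    v = np.asarray(vector, float)
    if v.shape != model.mean_vector.shape:
        raise ValueError("vector length does not match the model")
    k = model.n_retained if k is None else int(k)
    k = min(k, model.n_modes)
    z = (v - model.mean_vector) / model.scales
    raw = model.components[:k] @ z
    sd = model.mode_sd[:k]
    sd = np.where(sd < 1e-15, 1.0, sd)
    residual = float(np.linalg.norm(z - raw @ model.components[:k]))
    return raw / sd, residual


@dataclass
class LooCurve:
    """Mean leave-one-out reconstruction error vs number of components.

    Index k of each array is the error using k components (k = 0 is the
    mean-only reconstruction).  Geometry in mm, density in g/cm^3
    (unstandardized); density entries are nan for the shape flavor.
    """

    geometric_rms: np.ndarray
    density_rms: np.ndarray
    per_specimen_geometric: np.ndarray = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.geometric_rms) - 1


def _geom_density_rms(err: np.ndarray, flavor: str) -> tuple[float, float]:
    if flavor == "shape":
        per_node = err.reshape(-1, 3)
        return float(np.sqrt(np.mean(np.sum(per_node**2, axis=1)))), np.nan
    if flavor == "density":
        return np.nan, float(np.sqrt(np.mean(err**2)))
    per_node = err.reshape(-1, 4)
    g = float(np.sqrt(np.mean(np.sum(per_node[:, :3] ** 2, axis=1))))
    d = float(np.sqrt(np.mean(per_node[:, 3] ** 2)))
    return g, d


def loo_analysis(
    training_matrix: np.ndarray,
    flavor: str = "shape",
    max_components: int | None = None,
    variance_target: float = 0.80,
) -> LooCurve:
    """Leave-one-out reconstruction error of the model family.

    For every left-out specimen a model is trained on the remaining N-1
    rows and the held-out row is projected onto its leading k components,
    for k = 0..max_components; the curves are means over specimens.
    Geometric RMS is the RMS over nodes of the node position error (mm);
    density RMS is over node density errors in original units.
    """
    X = np.asarray(training_matrix, float)
    N = X.shape[0]
    if N < 3:
        raise ValueError("leave-one-out needs at least three specimens")
    kmax = N - 2 if max_components is None else int(max_components)
    if kmax > N - 2:
        import warnings

        warnings.warn(
            f"max_components={kmax} exceeds the N-2 modes available; truncating",
            stacklevel=2,
        )
        kmax = N - 2
    geom = np.zeros((N, kmax + 1))
    dens = np.zeros((N, kmax + 1))
    for i in range(N):
        rest = np.delete(X, i, axis=0)
        model = train(rest, flavor, variance_target=1.0)
        z = (X[i] - model.mean_vector) / model.scales
        raw = model.components @ z  # coefficients for all modes
        for k in range(kmax + 1):
            approx = model.mean_vector + (raw[:k] @ model.components[:k]) * model.scales
            geom[i, k], dens[i, k] = _geom_density_rms(X[i] - approx, flavor)
    return LooCurve(geom.mean(axis=0), dens.mean(axis=0), geom)


# ---------------------------------------------------------------------------
# Persistence and reporting
# ---------------------------------------------------------------------------


def save_model(model: SSMModel, path) -> None:
    """JSON metadata + npz arrays, version-stamped."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        mean_vector=model.mean_vector,
        components=model.components,
        singular_values=model.singular_values,
        variance_fractions=model.variance_fractions,
        scales=model.scales,
    )
    meta = {
        "format": "mc3ssm-model",
        "version": 1,
        "flavor": model.flavor,
        "n_retained": model.n_retained,
        "n_training": model.n_training,
        "variance_target": model.variance_target,
        "variance_fractions": model.variance_fractions.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> SSMModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.load(path.with_suffix(".npz"))
    return SSMModel(
        meta["flavor"], arr["mean_vector"], arr["components"],
        arr["singular_values"], arr["variance_fractions"], arr["scales"],
        meta["n_retained"], meta["n_training"], meta["variance_target"],
    )


def variance_table(models: dict[str, SSMModel]):
    """Tidy per-component absolute and cumulative explained variance."""
    import pandas as pd

    rows = []
    for name, m in models.items():
        cum = np.cumsum(m.variance_fractions)
        for i, (f, c) in enumerate(zip(m.variance_fractions, cum), start=1):
            rows.append({"model": name, "component": i,
                         "variance_fraction": f, "cumulative": c,
                         "retained": i <= m.n_retained})
    return pd.DataFrame(rows)
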