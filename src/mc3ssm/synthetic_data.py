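"""Synthetic populations of distal-MC3-like specimens with known latent structure.

Real training data for this kind of model is a set of CT scans of equine
third metacarpal (MC3) bones.  This module emulates such a training set with
a fully analytic stand-in so that every downstream stage (surface fitting,
correspondence, density calibration, PCA) can be tested against ground truth:

* an analytic base surface -- superelliptical cross-sections lofted over a
  rounded distal cap, with two condylar bulges, flanking parasagittal
  grooves and a raised central sagittal ridge;
* a small set of generative latent modes (overall size, ridge prominence,
  medial/lateral condyle asymmetry), each coupling a per-node displacement
  field with a per-node bone-mineral-density loading;
* Poisson-sampled surface point clouds with isotropic segmentation jitter;
* voxelized CT volumes in Hounsfield units containing a hydroxyapatite
  calibration phantom cylinder and a water background.

Axes: +x medial, +y dorsal, +z proximal; the most distal point of the base
shape sits at the origin and the mesh is cut at ``proximal_cutoff`` mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh_core import PatchMesh, build_template_topology
from .density_mapping import ImageVolume

__all__ = [
    "BaseShapeParams",
    "GenerativeMode",
    "GroundTruthSpecimen",
    "SyntheticSpec",
    "cross_section_radius",
    "make_base_shape",
    "default_modes",
    "sample_population",
    "export_point_cloud",
    "voxelize",
    "write_point_cloud_ply",
    "write_point_cloud_csv",
    "save_ground_truth",
    "load_ground_truth",
]

# dimensionless feature placements on the cross-section (x_hat = cos(azimuth))
_CONDYLE_POS = 0.55
_CONDYLE_WIDTH = 0.25
_GROOVE_POS = 0.28
_GROOVE_WIDTH = 0.12
_RIDGE_WIDTH = 0.26


@dataclass
class BaseShapeParams:
    """Dimensions (mm) of the analytic base surface.

    ``condyle_radius_*`` are the extra cross-section radii of the condylar
    bulges; ``groove_depth`` the parasagittal groove depression;
    ``ridge_height`` the sagittal ridge elevation.  ``epiphysis_length``
    controls the rounded distal cap; features fade proximally over
    1.5 x ``epiphysis_length``.
    """

    shaft_radius: float = 20.0
    condyle_radius_medial: float = 5.0
    condyle_radius_lateral: float = 3.5
    groove_depth: float = 1.5
    ridge_height: float = 2.0
    epiphysis_length: float = 12.0
    proximal_cutoff: float = 45.0
    ml_aspect: float = 1.3
    superellipse_power: float = 2.5
    # dorso-palmar asymmetries; real condyles and ridge are not mirror
    # symmetric, and without them rigid initialization could settle in a
    # flipped frame that fits the surface but scrambles correspondence
    dorsal_palmar_bias: float = 0.35   # dimensionless bump weighting (+y side)
    dorsal_shift: float = 4.0          # mm, distal cross-section centerline shift

    def validate(self) -> None:
        for name in ("shaft_radius", "condyle_radius_medial", "condyle_radius_lateral",
                     "epiphysis_length", "proximal_cutoff", "ml_aspect",
                     "superellipse_power"):
            if getattr(self, name) <= 0:
                raise ValueError(f"base shape parameter {name} must be positive")
        if self.groove_depth < 0 or self.ridge_height < 0:
            raise ValueError("groove_depth and ridge_height must be non-negative")
        if not -1.0 < self.dorsal_palmar_bias < 1.0:
            raise ValueError("dorsal_palmar_bias must lie in (-1, 1)")


def cross_section_radius(theta, z, params: BaseShapeParams):
    """Analytic polar radius of the generating cross-section at height ``z``.

    Superellipse (half-axes ml_aspect*shaft_radius medio-laterally and
    shaft_radius dorso-palmarly) plus condyle/groove/ridge bumps that fade
    proximally as a Gaussian in z.
    """
    theta = np.asarray(theta, float)
    z = np.asarray(z, float)
    A = params.ml_aspect * params.shaft_radius
    B = params.shaft_radius
    m = params.superellipse_power
    ct, st = np.cos(theta), np.sin(theta)
    r_se = (np.abs(ct / A) ** m + np.abs(st / B) ** m) ** (-1.0 / m)
    xh, yh = ct, st
    bump = (
        params.condyle_radius_medial * np.exp(-(((xh - _CONDYLE_POS) / _CONDYLE_WIDTH) ** 2))
        + params.condyle_radius_lateral * np.exp(-(((xh + _CONDYLE_POS) / _CONDYLE_WIDTH) ** 2))
        - params.groove_depth * (
            np.exp(-(((xh - _GROOVE_POS) / _GROOVE_WIDTH) ** 2))
            + np.exp(-(((xh + _GROOVE_POS) / _GROOVE_WIDTH) ** 2))
        )
        + params.ridge_height * np.exp(-((xh / _RIDGE_WIDTH) ** 2)) * yh * yh
    )
    bump = bump * (1.0 + params.dorsal_palmar_bias * yh)
    z_decay = 1.5 * params.epiphysis_length
    return r_se + bump * np.exp(-((z / z_decay) ** 2))


def make_base_shape(params: BaseShapeParams | None = None) -> PatchMesh:
    """Instantiate the template topology on the analytic base surface.

    The surface is closed over the distal cap (an elliptic profile of axial
    extent ``epiphysis_length``) and open at the proximal cutoff ring.  With
    equal condylar radii the shape is bilaterally symmetric.  Deterministic.
    """
    params = params or BaseShapeParams()
    params.validate()
    n_nodes, patches, st, landmarks, regions = build_template_topology()
    z_e, L = params.epiphysis_length, params.proximal_cutoff
    if L <= z_e:
        raise ValueError("proximal_cutoff must exceed epiphysis_length")

    z = np.empty(n_nodes)
    w = np.empty(n_nodes)
    cap = st.kind == 0
    psi = np.where(cap, np.nan_to_num(st.cap_rho), 1.0) * (np.pi / 2.0)
    z[cap] = z_e * (1.0 - np.cos(psi[cap]))
    w[cap] = np.sin(psi[cap])
    side = ~cap | (st.ring == 0)
    z[st.ring >= 0] = z_e + (L - z_e) * st.ring[st.ring >= 0] / 12.0
    w[st.ring >= 0] = 1.0
    # ring 0 coincides with the cap boundary (psi = pi/2): z = z_e, w = 1
    R = cross_section_radius(st.theta, z, params)
    # distal cross-section centers shift dorsally (same shift for a whole
    # ring, so landmark widths keep their closed cross-section form)
    y_shift = params.dorsal_shift * (1.0 - z / L) ** 2
    nodes = np.stack(
        [R * w * np.cos(st.theta), R * w * np.sin(st.theta) + y_shift, z], axis=1
    )

    mesh = PatchMesh(nodes, patches, landmarks, regions, st, proximal_cutoff=L)
    return mesh


# ---------------------------------------------------------------------------
# Generative modes
# ---------------------------------------------------------------------------


@dataclass
class GenerativeMode:
    """One latent mode: per-node displacement (mm) and density loading
    (g/cm^3), both per unit standard-normal score."""

    variance_fraction: float
    shape_displacement: np.ndarray  # (n_nodes, 3)
    density_loading: np.ndarray     # (n_nodes,)

    def validate(self, n_nodes: int) -> None:
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ValueError("variance_fraction must lie in (0, 1]")
        if self.shape_displacement.shape != (n_nodes, 3):
            raise ValueError("shape_displacement must have one 3-vector per node")
        if self.density_loading.shape != (n_nodes,):
            raise ValueError("density_loading must have one entry per node")


def default_modes(
    base: PatchMesh,
    params: BaseShapeParams | None = None,
    variance_fractions: tuple[float, ...] = (0.50, 0.30, 0.15),
) -> list[GenerativeMode]:
    """The packaged three latent modes, scaled to exact variance fractions.

    1. overall size (isotropic scaling about the centroid), positively
       coupled to subchondral density -- larger bones are denser;
    2. sagittal-ridge prominence at the dorsal epiphysis/metaphysis
       junction, positively coupled to local density;
    3. lateral-vs-medial condyle asymmetry, negatively coupled to dorsal
       condylar density.

    Raw fields are rescaled so that, with standard-normal scores, mode k
    contributes exactly ``variance_fractions[k]`` of the total generative
    coordinate variance.
    """
    params = params or BaseShapeParams()
    z_e = params.epiphysis_length
    z_decay = 1.5 * z_e
    nodes = base.nodes
    st = base.stations
    normals = base.node_normals()
    xh = np.cos(st.theta)
    yh = np.sin(st.theta)
    pole = (st.kind == 0) & (np.nan_to_num(st.cap_rho) == 0.0)
    xh[pole] = 0.0
    yh[pole] = 0.0
    z = nodes[:, 2]

    centroid = nodes.mean(axis=0)
    d1 = 0.04 * (nodes - centroid)
    l1 = 0.05 * np.exp(-((z / z_decay) ** 2))

    w2 = (
        np.exp(-((xh / 0.35) ** 2))
        * np.exp(-(((z - 1.2 * z_e) / (0.8 * z_e)) ** 2))
        * 0.5 * (1.0 + np.tanh(yh / 0.3))
    )
    d2 = 1.5 * w2[:, None] * normals
    # density loadings use broader spatial windows than the shape bumps:
    # subchondral BMD varies on coarser scales than surface relief, and the
    # volumetric density extension is only single-valued along normals when
    # the field is smoother than the local curvature radius
    w2d = (
        np.exp(-((xh / 0.55) ** 2))
        * np.exp(-(((z - 1.2 * z_e) / (1.4 * z_e)) ** 2))
        * 0.5 * (1.0 + np.tanh(yh / 0.5))
    )
    l2 = 0.04 * w2d

    w3 = (
        np.exp(-(((xh + _CONDYLE_POS) / 0.3) ** 2))
        - np.exp(-(((xh - _CONDYLE_POS) / 0.3) ** 2))
    ) * np.exp(-((z / z_decay) ** 2))
    d3 = 1.0 * w3[:, None] * normals
    w3d = (
        np.exp(-(((xh - _CONDYLE_POS) / 0.5) ** 2))
        + np.exp(-(((xh + _CONDYLE_POS) / 0.5) ** 2))
    ) * 0.5 * (1.0 + np.tanh(yh / 0.5)) * np.exp(-((z / (1.5 * z_decay)) ** 2))
    l3 = -0.03 * w3d

    raw = [(d1, l1), (d2, l2), (d3, l3)]
    fr = np.asarray(variance_fractions, float)
    if len(raw) != len(fr):
        raise ValueError("expected exactly three variance fractions")
    # orthogonalize the displacement fields (Gram-Schmidt): with independent
    # standard-normal scores the per-mode variance fractions are then exact,
    # not blurred by field overlap (the ridge and asymmetry fields both have
    # a radial component the size mode would otherwise share)
    flats = [d.ravel().copy() for d, _ in raw]
    for i in range(1, len(flats)):
        for j in range(i):
            flats[i] -= (flats[i] @ flats[j]) / (flats[j] @ flats[j]) * flats[j]
    raw = [(flats[i].reshape(-1, 3), raw[i][1]) for i in range(len(raw))]
    norms2 = np.array([np.sum(d * d) for d, _ in raw])
    total = norms2.sum()
    modes = []
    for (d, l), f, n2 in zip(raw, fr, norms2):
        gamma = np.sqrt(f * total / n2)
        modes.append(GenerativeMode(float(f), d * gamma, l * gamma))
    for mo in modes:
        mo.validate(base.n_nodes)
    return modes


# ---------------------------------------------------------------------------
# Population spec and sampling
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Generative recipe for one synthetic training population.

    Defaults reproduce the study conditions this package is designed around:
    40 specimens, CT voxels of 0.3 x 0.3 mm in plane and 0.6 mm slices, a
    hydroxyapatite phantom of 800 mg/cm^3, and a mesh cut 45 mm proximal to
    the most distal point.
    """

    n_specimens: int = 40
    base_shape_params: BaseShapeParams = field(default_factory=BaseShapeParams)
    variance_fractions: tuple[float, ...] = (0.50, 0.30, 0.15)
    modes: list[GenerativeMode] | None = None
    point_noise_sd: float = 0.1        # mm, cloud segmentation jitter
    node_noise_sd: float = 0.05        # mm, iid per-node residual variation
    density_base: float = 0.7          # g/cm^3 HA-equivalent
    density_noise_sd: float = 0.02     # g/cm^3
    cloud_density: float = 1.0         # points per mm^2
    voxel_spacing: tuple[float, float, float] = (0.3, 0.3, 0.6)
    phantom_density: float = 800.0     # mg/cm^3 HA
    phantom_hu: float = 1600.0         # HU of the phantom insert
    water_hu: float = 0.0              # HU of water background
    hu_noise_sd: float = 5.0           # HU, additive Gaussian; 0 disables
    pose_rotation_deg: float = 30.0    # rigid pose: rotation range +-
    pose_translation_mm: float = 20.0  # rigid pose: translation range +-
    seed: int = 42

    def validate(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be at least 2")
        self.base_shape_params.validate()
        if sum(self.variance_fractions) > 1.0 + 1e-12:
            raise ValueError("variance fractions must sum to at most 1")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing components must be positive")
        if self.phantom_density <= 0:
            raise ValueError("phantom_density must be positive")
        for name in ("point_noise_sd", "node_noise_sd", "density_noise_sd",
                     "hu_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("modes")
        d["variance_fractions"] = list(self.variance_fractions)
        d["voxel_spacing"] = list(self.voxel_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "base_shape_params" in d and isinstance(d["base_shape_params"], dict):
            d["base_shape_params"] = BaseShapeParams(**d["base_shape_params"])
        if "variance_fractions" in d:
            d["variance_fractions"] = tuple(d["variance_fractions"])
        if "voxel_spacing" in d:
            d["voxel_spacing"] = tuple(d["voxel_spacing"])
        return cls(**d)


@dataclass
class GroundTruthSpecimen:
    """One generated specimen: posed node coordinates on the template
    topology, per-node density, latent scores and the applied rigid pose."""

    node_coords: np.ndarray    # (n, 3), pose applied
    node_density: np.ndarray   # (n,), g/cm^3, clamped >= 0
    mode_scores: np.ndarray    # (k,)
    rotation: np.ndarray       # (3, 3)
    translation: np.ndarray    # (3,)

    @property
    def local_coords(self) -> np.ndarray:
        """Node coordinates in the unposed (generator) frame."""
        return (self.node_coords - self.translation) @ self.rotation


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(-max_deg, max_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def sample_population(
    spec: SyntheticSpec, return_base: bool = False
) -> list[GroundTruthSpecimen] | tuple[PatchMesh, list[GenerativeMode], list[GroundTruthSpecimen]]:
    """Draw a population of ground-truth specimens from the generative model.

    Specimen i has node coordinates ``base + sum_k w_ik * D_k + noise`` with
    standard-normal scores ``w`` and mode fields ``D_k`` pre-scaled to the
    spec's variance fractions, densities analogously, and a random rigid pose
    applied.  Fully reproducible for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = make_base_shape(spec.base_shape_params)
    modes = spec.modes
    if modes is None:
        modes = default_modes(base, spec.base_shape_params, spec.variance_fractions)
    for m in modes:
        m.validate(base.n_nodes)

    n = spec.n_specimens
    k = len(modes)
    scores = rng.standard_normal((n, k))
    out = []
    for i in range(n):
        coords = base.nodes.copy()
        dens = np.full(base.n_nodes, spec.density_base)
        for j, m in enumerate(modes):
            coords = coords + scores[i, j] * m.shape_displacement
            dens = dens + scores[i, j] * m.density_loading
        if spec.node_noise_sd > 0:
            coords = coords + rng.normal(0, spec.node_noise_sd, coords.shape)
        if spec.density_noise_sd > 0:
            dens = dens + rng.normal(0, spec.density_noise_sd, dens.shape)
        dens = np.clip(dens, 0.0, None)
        R = _random_rotation(rng, spec.pose_rotation_deg)
        t = rng.uniform(-spec.pose_translation_mm, spec.pose_translation_mm, 3)
        out.append(GroundTruthSpecimen(coords @ R.T + t, dens, scores[i].copy(), R, t))
    if return_base:
        return base, modes, out
    return out


def specimen_mesh(base: PatchMesh, specimen: GroundTruthSpecimen) -> PatchMesh:
    """Posed ground-truth surface of one specimen (template topology)."""
    return base.with_nodes(specimen.node_coords, node_density=specimen.node_density)


# ---------------------------------------------------------------------------
# Point-cloud export
# ---------------------------------------------------------------------------


def export_point_cloud(
    base: PatchMesh,
    specimen: GroundTruthSpecimen,
    density: float = 1.0,
    point_noise_sd: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Poisson-sample the specimen surface at ``density`` points/mm^2.

    Points are drawn area-uniformly from a dense triangulation of the posed
    surface, then jittered with iid isotropic Gaussian noise of standard
    deviation ``point_noise_sd`` (mm).  No correspondence information leaks:
    the output is an unordered (m, 3) array.
    """
    if density <= 0:
        raise ValueError("point density must be positive")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mesh = specimen_mesh(base, specimen)
    # area-weighted triangle selection, but points are evaluated on the
    # exact parametric surface (no chord error): map the barycentric draw
    # back to (u, v) within the triangle's patch
    m = 10
    verts, faces, fpid = mesh.triangulate(m=m)
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total = areas.sum()
    count = rng.poisson(density * total)
    choice = rng.choice(len(faces), size=count, p=areas / total)
    g = np.linspace(0.0, 1.0, m + 1)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
    local_faces = faces[choice] % ((m + 1) ** 2)
    tri_uv = uv[local_faces]  # (count, 3, 2)
    r1 = np.sqrt(rng.uniform(size=count))[:, None]
    r2 = rng.uniform(size=count)[:, None]
    bary_uv = ((1 - r1) * tri_uv[:, 0] + r1 * (1 - r2) * tri_uv[:, 1]
               + r1 * r2 * tri_uv[:, 2])
    pts = mesh.evaluate_many(fpid[choice], bary_uv[:, 0], bary_uv[:, 1])
    if point_noise_sd > 0:
        pts = pts + rng.normal(0, point_noise_sd, pts.shape)
    return pts


def write_point_cloud_ply(points: np.ndarray, path) -> None:
    """Binary little-endian PLY."""
    import trimesh

    trimesh.PointCloud(np.asarray(points, float)).export(str(path))


def write_point_cloud_csv(points: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(points, float), delimiter=",",
               header="x,y,z", comments="")


def read_point_cloud(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",", skiprows=1)
    import trimesh

    obj = trimesh.load(str(path))
    return np.asarray(obj.vertices, float)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def voxelize(
    base: PatchMesh,
    specimen: GroundTruthSpecimen,
    spec: SyntheticSpec,
    fov: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ImageVolume:
    """Rasterize one specimen into a CT-like Hounsfield-unit volume.

    The bone interior carries the HU that the phantom calibration maps back
    to the surface density field (each interior voxel takes the density of
    its closest surface point); a uniform phantom cylinder at ``phantom_hu``
    and a water background at ``water_hu`` are included, so downstream
    calibration and subchondral sampling can recover the generator densities.

    HU assignment is piecewise-constant per region; optional additive
    Gaussian HU noise emulates scanner noise.
    """
    from scipy.spatial import cKDTree

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mesh = specimen_mesh(base, specimen)
    spacing = np.asarray(spec.voxel_spacing, float)

    blo = mesh.nodes.min(axis=0)
    bhi = mesh.nodes.max(axis=0)
    phantom_radius = 6.0
    phantom_cx = bhi[0] + 6.0 + phantom_radius
    margin = 4.0
    lo_req = blo - margin
    hi_req = np.array([phantom_cx + phantom_radius + margin, bhi[1] + margin, bhi[2] + margin])
    if fov is not None:
        lo, hi = np.asarray(fov[0], float), np.asarray(fov[1], float)
        if np.any(lo > blo - spacing) or np.any(hi < bhi + spacing):
            raise ValueError("specimen extends outside the requested field of view")
    else:
        lo, hi = lo_req, hi_req
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    data = np.full(shape, spec.water_hu, dtype=np.float32)

    # dense surface samples with interpolated density; normals interpolate
    # the *nodal* normal field so the volumetric density transport follows
    # the same directions the subchondral sampler will later walk
    pts, pids, us, vs = mesh.dense_samples(15)
    node_nrm = mesh.node_normals()
    nrm = np.stack(
        [mesh.interpolate_node_field(node_nrm[:, c], pids, us, vs) for c in range(3)],
        axis=1,
    )
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    ok = ln[:, 0] > 1e-6
    pts, nrm = pts[ok], nrm[ok] / ln[ok]
    sdens = mesh.interpolate_node_field(specimen.node_density, pids, us, vs)[ok]
    tree = cKDTree(pts)

    # candidate voxels: bone bounding box plus a rind for the proximal
    # extension below
    ilo = np.maximum(np.floor((blo - 3.9 - lo) / spacing).astype(int), 0)
    ihi = np.minimum(np.ceil((bhi + 3.9 - lo) / spacing).astype(int), shape - 1)
    axes = [lo[d] + spacing[d] * np.arange(ilo[d], ihi[d] + 1) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    nc = [len(a) for a in axes]

    # banded inside/outside classification: exact nearest-surface queries
    # are only needed near the boundary.  A coarse signed-distance grid
    # (1-Lipschitz up to curvature) classifies everything further than the
    # band half-width from the surface.
    step = 3
    sub = [np.unique(np.r_[np.arange(0, n, step), n - 1]) for n in nc]
    Xc, Yc, Zc = np.meshgrid(axes[0][sub[0]], axes[1][sub[1]], axes[2][sub[2]],
                             indexing="ij")
    coarse = np.stack([Xc.ravel(), Yc.ravel(), Zc.ravel()], axis=1)
    _, cn = tree.query(coarse)
    csigned = np.sum((coarse - pts[cn]) * nrm[cn], axis=1).reshape(Xc.shape)
    from scipy import ndimage

    # fractional coarse-grid indices of every fine voxel (linear interp)
    frac = [np.interp(np.arange(n), s, np.arange(len(s))) for n, s in zip(nc, sub)]
    FI = np.meshgrid(*frac, indexing="ij")
    approx = ndimage.map_coordinates(
        csigned, [f.ravel() for f in FI], order=1, mode="nearest")
    band = np.abs(approx) < 5.0
    signed = approx.copy()
    _, nearest_b = tree.query(centers[band])
    signed[band] = np.sum((centers[band] - pts[nearest_b]) * nrm[nearest_b], axis=1)

    delta = 0.75 * spacing.max()
    z_local = ((centers - specimen.translation) @ specimen.rotation)[:, 2]
    # the physical bone continues proximal to the mesh cutoff (the specimen
    # is transected further up); extend the shaft fill past the cut plane so
    # subchondral rays at the boundary ring stay inside bone
    inside = (signed < delta) & (z_local <= mesh.proximal_cutoff + 3.5)

    # density is transported into the bone along inward normals (a stack of
    # offset shells), so that averaging along an inward normal recovers the
    # surface field even under narrow features like the sagittal ridge.
    # The nearest-shell-point lookup is done with a voxelized Euclidean
    # distance transform (sub-voxel precision is unnecessary for a smooth
    # density field).
    depths = np.arange(0.0, 6.1, 0.75)
    shell_pts = (pts[None, :, :] - depths[:, None, None] * nrm[None, :, :]).reshape(-1, 3)
    shell_dens = np.tile(sdens, len(depths))
    from scipy import ndimage as _ndi

    dens_grid = np.zeros(nc, np.float32)
    mark = np.zeros(nc, bool)
    sij = np.round((shell_pts - np.array([a[0] for a in axes])) / spacing).astype(int)
    ok_s = np.all((sij >= 0) & (sij < np.array(nc)), axis=1)
    sij = sij[ok_s]
    dens_grid[sij[:, 0], sij[:, 1], sij[:, 2]] = shell_dens[ok_s]
    mark[sij[:, 0], sij[:, 1], sij[:, 2]] = True
    idx = _ndi.distance_transform_edt(~mark, sampling=spacing,
                                      return_distances=False, return_indices=True)
    transported = dens_grid[idx[0], idx[1], idx[2]].ravel()

    calib_slope = (spec.phantom_hu - spec.water_hu) / (spec.phantom_density / 1000.0)
    hu = np.empty(len(centers))
    hu[inside] = spec.water_hu + transported[inside] * calib_slope
    block = data[ilo[0]:ihi[0] + 1, ilo[1]:ihi[1] + 1, ilo[2]:ihi[2] + 1]
    flat = block.ravel()
    flat[inside] = hu[inside]
    data[ilo[0]:ihi[0] + 1, ilo[1]:ihi[1] + 1, ilo[2]:ihi[2] + 1] = flat.reshape(block.shape)

    # phantom cylinder, axis along the slice (z) direction
    cy = 0.5 * (blo[1] + bhi[1])
    z0, z1 = lo[2] + 0.2 * (hi[2] - lo[2]), lo[2] + 0.8 * (hi[2] - lo[2])
    xs = lo[0] + spacing[0] * np.arange(shape[0])
    ys = lo[1] + spacing[1] * np.arange(shape[1])
    zs = lo[2] + spacing[2] * np.arange(shape[2])
    in_disc = ((xs[:, None] - phantom_cx) ** 2 + (ys[None, :] - cy) ** 2
               <= phantom_radius**2)
    in_z = (zs >= z0) & (zs <= z1)
    phantom_mask3 = in_disc[:, :, None] & in_z[None, None, :]
    data[phantom_mask3] = spec.phantom_hu

    if spec.hu_noise_sd > 0:
        data += rng.normal(0, spec.hu_noise_sd, data.shape).astype(np.float32)

    phantom_region = {
        "kind": "cylinder",
        "center_xy": [float(phantom_cx), float(cy)],
        "radius": phantom_radius * 0.8,   # erode to stay clear of edge voxels
        "z_range": [float(z0 + 2.0), float(z1 - 2.0)],
    }
    water_region = {
        "kind": "box",
        "lo": [float(lo[0]), float(lo[1]), float(lo[2])],
        "hi": [float(lo[0] + 3.0), float(lo[1] + 3.0), float(lo[2] + 3.0)],
    }
    return ImageVolume(data, spacing, lo.copy(), phantom_region, water_region)


# ---------------------------------------------------------------------------
# Ground-truth sidecars (testing only; the pipeline proper never reads them)
# ---------------------------------------------------------------------------


def save_ground_truth(specimen: GroundTruthSpecimen, path) -> None:
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        node_coords=specimen.node_coords,
        node_density=specimen.node_density,
        mode_scores=specimen.mode_scores,
        rotation=specimen.rotation,
        translation=specimen.translation,
    )
    path.with_suffix(".json").write_text(json.dumps(
        {"format": "mc3ssm-ground-truth", "version": 1,
         "n_nodes": int(len(specimen.node_coords)),
         "n_modes": int(len(specimen.mode_scores))}, indent=1))


def load_ground_truth(path) -> GroundTruthSpecimen:
    arr = np.load(Path(path).with_suffix(".npz"))
    return GroundTruthSpecimen(
        arr["node_coords"], arr["node_density"], arr["mode_scores"],
        arr["rotation"], arr["translation"],
    )
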