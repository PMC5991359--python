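"""Phantom-calibrated mapping from CT Hounsfield units to bone density.

A hydroxyapatite (HA) phantom of known mineral density scanned alongside the
bone gives a linear HU -> HA-equivalent-density calibration

    rho_HA = (CT_bone - CT_H2O) / (CT_HA - CT_H2O) * rho_phantom

which is invariant to any affine recalibration of the scanner HU scale.
Apparent density and elastic modulus follow the empiric trabecular-bone
power law

    rho_app = rho_HA / 0.626        [g/cm^3]
    E       = 2017.3 * rho_app^2.46 [MPa]

Subchondral bone is sampled per mesh node along the inward surface normal to
a depth of 5 mm (the approximate depth at which subchondral plate porosity
increases in mature racehorses), averaging trilinearly interpolated HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "CalibrationParams",
    "NodeDensityField",
    "estimate_calibration",
    "sample_subchondral",
    "hu_to_rho_ha",
    "rho_ha_to_modulus",
    "build_density_field",
    "export_density_ply",
    "region_mask",
]

APP_OVER_HA = 0.626          # rho_app = rho_HA / 0.626
MODULUS_COEF = 2017.3        # MPa
MODULUS_EXP = 2.46
DEFAULT_DEPTH_MM = 5.0
DEFAULT_STEP_MM = 0.25


@dataclass
class ImageVolume:
    """A calibrated voxel grid in Hounsfield units.

    ``data[i, j, k]`` sits at world position ``origin + (i, j, k) * spacing``
    (mm).  ``phantom_region`` / ``water_region`` are serializable region
    descriptors (see :func:`region_mask`).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    phantom_region: dict | None = None
    water_region: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float32)
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) / self.spacing

    def sample(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear HU at world points; second return flags out-of-bounds."""
        idx = self.world_to_index(points)
        shape = np.array(self.data.shape)
        in_bounds = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        vals = ndimage.map_coordinates(self.data, idx.T, order=1, mode="nearest")
        return vals, in_bounds

    # -- I/O ---------------------------------------------------------------
    def save_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.data, affine)
        desc = json.dumps({"phantom": self.phantom_region, "water": self.water_region})
        img.header["descrip"] = desc[:79].encode()
        nib.save(img, str(path))
        Path(str(path) + ".regions.json").write_text(desc)

    @classmethod
    def load_nifti(cls, path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        regions = {"phantom": None, "water": None}
        sidecar = Path(str(path) + ".regions.json")
        if sidecar.exists():
            regions = json.loads(sidecar.read_text())
        return cls(np.asarray(img.dataobj, np.float32), np.diag(aff[:3, :3]).copy(),
                   aff[:3, 3].copy(), regions.get("phantom"), regions.get("water"))

    def save_raw(self, path) -> None:
        """Flat raw + JSON header fallback (no NIfTI reader required)."""
        path = Path(path)
        self.data.astype("<f4").tofile(path.with_suffix(".raw"))
        hdr = {
            "shape": list(self.data.shape), "dtype": "<f4",
            "spacing": self.spacing.tolist(), "origin": self.origin.tolist(),
            "phantom_region": self.phantom_region, "water_region": self.water_region,
        }
        path.with_suffix(".json").write_text(json.dumps(hdr, indent=1))

    @classmethod
    def load_raw(cls, path) -> "ImageVolume":
        path = Path(path)
        hdr = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path.with_suffix(".raw"), dtype=hdr["dtype"]).reshape(hdr["shape"])
        return cls(data, hdr["spacing"], hdr["origin"],
                   hdr.get("phantom_region"), hdr.get("water_region"))


def region_mask(volume: ImageVolume, region: dict | np.ndarray) -> np.ndarray:
    """Boolean voxel mask for a region descriptor (or pass a mask through)."""
    if isinstance(region, np.ndarray):
        return region.astype(bool)
    shape = volume.data.shape
    xs = volume.origin[0] + volume.spacing[0] * np.arange(shape[0])
    ys = volume.origin[1] + volume.spacing[1] * np.arange(shape[1])
    zs = volume.origin[2] + volume.spacing[2] * np.arange(shape[2])
    if region["kind"] == "cylinder":
        cx, cy = region["center_xy"]
        disc = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= region["radius"] ** 2
        inz = (zs >= region["z_range"][0]) & (zs <= region["z_range"][1])
        return disc[:, :, None] & inz[None, None, :]
    if region["kind"] == "box":
        lo, hi = np.asarray(region["lo"]), np.asarray(region["hi"])
        return ((xs[:, None, None] >= lo[0]) & (xs[:, None, None] <= hi[0])
                & (ys[None, :, None] >= lo[1]) & (ys[None, :, None] <= hi[1])
                & (zs[None, None, :] >= lo[2]) & (zs[None, None, :] <= hi[2]))
    raise ValueError(f"unknown region kind {region.get('kind')!r}")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationParams:
    """HU landmarks of the scan: phantom mean, water mean, phantom density."""

    ct_ha: float                 # HU of the HA phantom
    ct_h2o: float                # HU of water
    rho_phantom: float = 800.0   # mg/cm^3 HA

    def __post_init__(self):
        if self.rho_phantom <= 0:
            raise ValueError("rho_phantom must be positive")
        if np.isclose(self.ct_ha, self.ct_h2o):
            raise ValueError("degenerate calibration: ct_ha equals ct_h2o")


def estimate_calibration(
    volume: ImageVolume,
    phantom_region: dict | np.ndarray | None = None,
    water_region: dict | np.ndarray | None = None,
    rho_phantom: float = 800.0,
) -> CalibrationParams:
    """Mean HU over the phantom and water regions of a volume."""
    phantom_region = phantom_region if phantom_region is not None else volume.phantom_region
    water_region = water_region if water_region is not None else volume.water_region
    if phantom_region is None or water_region is None:
        raise ValueError("phantom and water regions are required")
    pm = region_mask(volume, phantom_region)
    wm = region_mask(volume, water_region)
    if not pm.any() or not wm.any():
        raise ValueError("empty calibration region")
    return CalibrationParams(float(volume.data[pm].mean()),
                             float(volume.data[wm].mean()), rho_phantom)


def hu_to_rho_ha(mean_hu, calib: CalibrationParams):
    """Linear HU -> HA-equivalent density map, in g/cm^3.

    Values below water come out negative and are deliberately preserved;
    clamping is deferred to reporting.
    """
    frac = (np.asarray(mean_hu, float) - calib.ct_h2o) / (calib.ct_ha - calib.ct_h2o)
    return frac * calib.rho_phantom / 1000.0


def rho_ha_to_modulus(rho_ha):
    """(rho_app [g/cm^3], E [MPa]) from HA-equivalent density.

    Raises on negative input: the caller decides whether to clamp or exclude
    sub-water samples first.
    """
    rho_ha = np.asarray(rho_ha, float)
    if np.any(rho_ha < 0):
        raise ValueError("rho_ha must be non-negative; clamp or exclude first")
    rho_app = rho_ha / APP_OVER_HA
    return rho_app, MODULUS_COEF * rho_app**MODULUS_EXP


# ---------------------------------------------------------------------------
# Subchondral sampling
# ---------------------------------------------------------------------------


def sample_subchondral(
    mesh,
    volume: ImageVolume,
    depth: float = DEFAULT_DEPTH_MM,
    step: float = DEFAULT_STEP_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean HU along the inward surface normal at every mesh node.

    The node's unit inward normal (from the parametric patches) is followed
    from the surface to ``depth`` mm in uniform ``step`` increments, both
    endpoints included with equal weight; the volume is sampled trilinearly.

    Returns
    -------
    mean_hu : (n,) array; nan where the ray left the volume
    ok : (n,) bool, False for flagged (excluded) nodes
    """
    if depth <= 0 or step <= 0:
        raise ValueError("depth and step must be positive")
    inward = -mesh.node_normals()
    n_steps = int(round(depth / step))
    ds = np.linspace(0.0, depth, n_steps + 1)
    pts = mesh.nodes[:, None, :] + ds[None, :, None] * inward[:, None, :]
    flat = pts.reshape(-1, 3)
    vals, in_bounds = volume.sample(flat)
    vals = vals.reshape(len(mesh.nodes), -1)
    ok = in_bounds.reshape(len(mesh.nodes), -1).all(axis=1)
    mean_hu = np.where(ok, vals.mean(axis=1), np.nan)
    return mean_hu, ok


@dataclass
class NodeDensityField:
    """Per-node density/modulus field mapped from a CT volume."""

    mean_hu: np.ndarray
    rho_ha: np.ndarray       # g/cm^3
    rho_app: np.ndarray      # g/cm^3
    modulus: np.ndarray      # MPa
    sample_depth: float      # mm
    ok: np.ndarray           # False = ray left volume or rho_HA < 0

    def to_csv(self, mesh, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "node_id": np.arange(len(self.mean_hu)),
            "x": mesh.nodes[:, 0], "y": mesh.nodes[:, 1], "z": mesh.nodes[:, 2],
            "mean_hu": self.mean_hu, "rho_ha": self.rho_ha,
            "rho_app": self.rho_app, "modulus": self.modulus,
            "ok": self.ok.astype(int),
        })
        df.to_csv(path, index=False)


def export_density_ply(mesh, field: "NodeDensityField", path, m: int = 8) -> None:
    """ASCII PLY of the triangulated surface with a per-vertex density
    property (for visualization)."""
    verts, faces, pids = mesh.triangulate(m)
    # interpolate node density at the triangulation vertices
    g = np.linspace(0.0, 1.0, m + 1)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    us = np.tile(uu.ravel(), mesh.n_patches)
    vs = np.tile(vv.ravel(), mesh.n_patches)
    vp = np.repeat(np.arange(mesh.n_patches), (m + 1) ** 2)
    dens = mesh.interpolate_node_field(field.rho_app, vp, us, vs)
    lines = ["ply", "format ascii 1.0", f"element vertex {len(verts)}",
             "property float x", "property float y", "property float z",
             "property float density", f"element face {len(faces)}",
             "property list uchar int vertex_indices", "end_header"]
    lines += [f"{x:.5f} {y:.5f} {z:.5f} {d:.5f}"
              for (x, y, z), d in zip(verts, dens)]
    lines += ["3 " + " ".join(map(str, f)) for f in faces]
    Path(path).write_text("\n".join(lines) + "\n")


def build_density_field(
    mesh,
    volume: ImageVolume,
    calib: CalibrationParams,
    depth: float = DEFAULT_DEPTH_MM,
    step: float = DEFAULT_STEP_MM,
) -> NodeDensityField:
    """Sample, calibrate and convert to modulus in one pass.

    Negative rho_HA values (air/fat near the surface) are propagated in
    ``rho_ha`` but flagged and clamped to zero for the modulus power law.
    """
    mean_hu, ok = sample_subchondral(mesh, volume, depth, step)
    rho_ha = hu_to_rho_ha(np.nan_to_num(mean_hu), calib)
    ok = ok & (rho_ha >= 0)
    rho_app, modulus = rho_ha_to_modulus(np.clip(rho_ha, 0.0, None))
    return NodeDensityField(mean_hu, rho_ha, rho_app, modulus, depth, ok)
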