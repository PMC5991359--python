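"""Landmark-based measurements and regional density summaries.

Because every fitted mesh shares the template topology, anatomical
landmarks identified once on the template transfer automatically to every
specimen and model reconstruction.  Measurements are therefore purely
topology-driven and deterministic: widths are distances between named
landmark node pairs, the metaphysis circumference is the closed polyline
length of a named node ring, areas are Gauss-quadrature sums over named
patch subsets, and regional bone-mineral-density values are means of node
densities over named node subsets (nodes flagged invalid by the density
mapping are excluded).

``mode_effect`` reconstructs a statistical-model mode at +/- a given number
of standard deviations (2 SD spans roughly 95% of the population) and
reports the signed percent change of every metric, using the mean-shape
value as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .mesh_core import PatchMesh
from . import statistical_model as sm

__all__ = ["MorphometryResult", "ModeEffect", "measure", "mode_effect", "results_to_frame"]


@dataclass
class MorphometryResult:
    """Scalar geometry and density metrics of one mesh (mm, mm^2, g/cm^3)."""

    medio_lateral_width: float
    lateral_condylar_width: float
    medial_condylar_width: float
    sagittal_ridge_width: float
    metaphysis_circumference: float
    total_area: float
    lateral_condylar_area: float
    medial_condylar_area: float
    palmar_condylar_bmd: float = np.nan
    dorsal_condylar_bmd: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _landmark(mesh: PatchMesh, name: str) -> int:
    try:
        return mesh.landmarks[name]
    except KeyError:
        raise KeyError(f"mesh is missing required landmark {name!r}") from None


def measure(mesh: PatchMesh, density: np.ndarray | None = None) -> MorphometryResult:
    """Compute all metrics on a fitted mesh (or model reconstruction).

    ``density`` overrides ``mesh.node_density``; the two BMD fields are nan
    when no density is available.  All geometric quantities are invariant
    to rigid motion of the mesh.
    """
    regions = mesh.regions
    widths = {}
    for metric, (a, b) in regions["width_pairs"].items():
        pa = mesh.nodes[_landmark(mesh, a)]
        pb = mesh.nodes[_landmark(mesh, b)]
        widths[metric] = float(np.linalg.norm(pa - pb))

    ring = mesh.nodes[np.asarray(regions["metaphysis_ring"], int)]
    circumference = float(
        np.sum(np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1))
    )

    areas = mesh.patch_areas()
    med_patches = np.asarray(regions["medial_condyle_patches"], int)
    lat_patches = np.asarray(regions["lateral_condyle_patches"], int)

    dens = density if density is not None else mesh.node_density
    palmar = dorsal = np.nan
    if dens is not None:
        dens = np.asarray(dens, float)
        ok = mesh.node_flags if mesh.node_flags is not None else np.ones(len(dens), bool)
        ok = ok & np.isfinite(dens)

        def regional(ids):
            ids = np.asarray(ids, int)
            ids = ids[ok[ids]]
            return float(dens[ids].mean()) if len(ids) else np.nan

        palmar = regional(regions["palmar_condyle_nodes"])
        dorsal = regional(regions["dorsal_condyle_nodes"])

    return MorphometryResult(
        medio_lateral_width=widths["medio_lateral_width"],
        lateral_condylar_width=widths["lateral_condylar_width"],
        medial_condylar_width=widths["medial_condylar_width"],
        sagittal_ridge_width=widths["sagittal_ridge_width"],
        metaphysis_circumference=circumference,
        total_area=float(areas.sum()),
        lateral_condylar_area=float(areas[lat_patches].sum()),
        medial_condylar_area=float(areas[med_patches].sum()),
        palmar_condylar_bmd=palmar,
        dorsal_condylar_bmd=dorsal,
    )


@dataclass
class ModeEffect:
    """Morphometry at -/+ ``sd_range`` SD of one mode, with percent changes.

    ``percent_change[metric]`` is ``100 * (value(+sd) - value(-sd)) /
    value(mean)`` -- the mean-shape value is the denominator throughout, so
    half-range changes compose additively.
    """

    mode_index: int
    sd_range: float
    minus: MorphometryResult
    mean: MorphometryResult
    plus: MorphometryResult
    percent_change: dict
    lateral_medial_area_ratio_minus: float
    lateral_medial_area_ratio_plus: float


def _vector_to_mesh(model: sm.SSMModel, vec: np.ndarray, template: PatchMesh) -> tuple[PatchMesh, np.ndarray | None]:
    if model.flavor == "combined":
        coords, dens = sm.split_combined(vec)
        return template.with_nodes(coords, node_density=dens, node_flags=np.ones(len(dens), bool)), dens
    if model.flavor == "shape":
        return template.with_nodes(vec.reshape(-1, 3)), None
    raise ValueError("mode_effect needs a shape or combined model")


def mode_effect(
    model: sm.SSMModel,
    mode_index: int,
    template: PatchMesh,
    sd_range: float = 2.0,
) -> ModeEffect:
    """Morphometric footprint of a single principal component.

    ``mode_index`` is 1-based.  The mode is reconstructed in isolation at
    -sd_range and +sd_range (all other weights zero) and measured; percent
    changes are relative to the mean shape.
    """
    if not 1 <= mode_index <= model.n_retained:
        raise ValueError(
            f"mode_index {mode_index} outside the {model.n_retained} retained modes")
    w = np.zeros(mode_index)
    results = {}
    for label, amp in (("minus", -sd_range), ("mean", 0.0), ("plus", +sd_range)):
        w[-1] = amp
        mesh, dens = _vector_to_mesh(model, sm.reconstruct(model, w), template)
        results[label] = measure(mesh, dens)
    pct = {}
    for name, mean_val in results["mean"].as_dict().items():
        lo = getattr(results["minus"], name)
        hi = getattr(results["plus"], name)
        pct[name] = 100.0 * (hi - lo) / mean_val if mean_val not in (0.0,) and np.isfinite(mean_val) else np.nan
    return ModeEffect(
        mode_index, sd_range, results["minus"], results["mean"], results["plus"], pct,
        results["minus"].lateral_condylar_area / results["minus"].medial_condylar_area,
        results["plus"].lateral_condylar_area / results["plus"].medial_condylar_area,
    )


def results_to_frame(results: dict[str, MorphometryResult]):
    """Dict of labelled results -> tidy DataFrame (one row per label)."""
    import pandas as pd

    return pd.DataFrame(
        [{"label": k, **v.as_dict()} for k, v in results.items()]
    ).set_index("label")
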