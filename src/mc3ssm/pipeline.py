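"""End-to-end workflow orchestration with config, manifests and provenance.

Stages (each reads the previous stage's artifacts from the stage directory
and writes its own, plus a JSON manifest with the config hash and seed):

    generate  -> synthetic point clouds + ground-truth sidecars
    fit       -> per-specimen host-mesh + fine fits
    correspond-> group correspondence (aligned training set)
    densify   -> CT volumes regenerated per specimen, phantom calibration,
                 subchondral sampling, HU -> density -> modulus per node
    train     -> shape / density / combined PCA models + variance table
    loo       -> leave-one-out error curves
    morpho    -> per-specimen morphometry + mode-effect report

Stage outputs are pure functions of (config, seed): re-running a stage with
the same inputs reproduces identical numeric outputs.  Ground-truth
sidecars are written for validation only; the analysis stages never read
them (the densify stage hands them to the voxelizer, which plays the role
of the CT scanner).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .synthetic_data import (SyntheticSpec, sample_population, export_point_cloud,
                             voxelize, save_ground_truth, load_ground_truth,
                             write_point_cloud_ply, read_point_cloud, specimen_mesh)
from .mesh_core import host_mesh_fit, fine_fit, FitResult, save_mesh
from .correspondence import correspondence_loop, save_aligned_set, load_aligned_set
from .density_mapping import estimate_calibration, build_density_field
from . import statistical_model as sm
from . import morphometry as mm

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

STAGES = ("generate", "fit", "correspond", "densify", "train", "loo", "morpho")


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializes losslessly to JSON (TOML read
    is also supported)."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    coarse_threshold: float = 0.5       # mm, host-mesh stage bound
    rms_target: float = 0.3             # mm, correspondence loop target
    max_rounds: int = 10
    reparam_rounds: int = 12
    host_regularization: float = 1e-5
    smoothing_weight: float = 1e-3
    sample_depth: float = 5.0           # mm, subchondral ray depth
    sample_step: float = 0.25           # mm
    variance_target: float = 0.80
    density_channel: str = "bmd"        # 'bmd' (apparent density) or 'modulus'
    loo_max_components: int = 15
    seed: int = 42

    def __post_init__(self):
        for name in ("coarse_threshold", "rms_target", "sample_depth",
                     "sample_step", "variance_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.density_channel not in ("bmd", "modulus"):
            raise ValueError("density_channel must be 'bmd' or 'modulus'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticSpec.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            return cls.from_dict(tomllib.loads(text))
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def with_seed(self, seed: int | None) -> "PipelineConfig":
        if seed is None:
            return self
        new = PipelineConfig.from_dict(self.to_dict())
        new.seed = int(seed)
        new.synthetic.seed = int(seed)
        return new


def _manifest(cfg: PipelineConfig, stage: str, extra: dict) -> dict:
    return {"stage": stage, "config_hash": cfg.hash(), "seed": cfg.seed,
            "version": __version__, **extra}


def _write_manifest(path: Path, m: dict) -> None:
    path.write_text(json.dumps(m, indent=1, sort_keys=True))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}: run the '{producer}' stage first")
    return path


def _cloud_rng(cfg: PipelineConfig, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + i]))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_generate(cfg: PipelineConfig, d: Path) -> dict:
    base, modes, pop = sample_population(cfg.synthetic, return_base=True)
    save_mesh(base, d / "template")
    counts = []
    for i, spec in enumerate(pop):
        cloud = export_point_cloud(base, spec, cfg.synthetic.cloud_density,
                                   cfg.synthetic.point_noise_sd, _cloud_rng(cfg, i))
        write_point_cloud_ply(cloud, d / f"cloud_{i:03d}.ply")
        save_ground_truth(spec, d / f"ground_truth_{i:03d}")
        counts.append(len(cloud))
    return {"n_specimens": len(pop), "cloud_sizes": counts}


def _load_template(d: Path):
    from .mesh_core import load_mesh
    from .mesh_core import build_template_topology
    mesh = load_mesh(_require(d / "template.npz", "generate").with_suffix(""))
    # stations are pure topology; re-derive them (not serialized)
    _, _, stations, _, _ = build_template_topology()
    mesh.stations = stations
    return mesh


def _stage_fit(cfg: PipelineConfig, d: Path) -> dict:
    template = _load_template(d)
    n = cfg.synthetic.n_specimens
    host_rms, fine_rms = [], []
    nodes = []
    for i in range(n):
        cloud = read_point_cloud(_require(d / f"cloud_{i:03d}.ply", "generate"))
        coarse = host_mesh_fit(template, cloud,
                               regularization_weight=cfg.host_regularization)
        fit = fine_fit(coarse, cloud, smoothing_weight=cfg.smoothing_weight)
        host_rms.append(coarse.rms)
        fine_rms.append(fit.rms)
        nodes.append(fit.fitted_nodes)
    np.savez_compressed(d / "fits.npz", nodes=np.array(nodes),
                        host_rms=np.array(host_rms), fine_rms=np.array(fine_rms))
    return {"host_rms": host_rms, "fine_rms": fine_rms,
            "coarse_threshold": cfg.coarse_threshold,
            "coarse_ok": bool(max(host_rms) < cfg.coarse_threshold)}


def _stage_correspond(cfg: PipelineConfig, d: Path) -> dict:
    template = _load_template(d)
    arr = np.load(_require(d / "fits.npz", "fit"))
    n = len(arr["nodes"])
    clouds = [read_point_cloud(d / f"cloud_{i:03d}.ply") for i in range(n)]
    fits = [FitResult(arr["nodes"][i], float(arr["fine_rms"][i]), 0, True,
                      template.with_nodes(arr["nodes"][i])) for i in range(n)]
    res = correspondence_loop(
        template, clouds, fits, rms_target=cfg.rms_target,
        max_rounds=cfg.max_rounds, smoothing_weight=cfg.smoothing_weight,
        reparam_rounds=cfg.reparam_rounds,
    )
    save_aligned_set(res.aligned, d / "aligned")
    np.savez_compressed(d / "corresponded_fits.npz",
                        nodes=np.array([f.fitted_nodes for f in res.fits]),
                        rms=np.array([f.rms for f in res.fits]),
                        rms_history=res.rms_history)
    return {"mean_rms": res.mean_rms, "converged": bool(res.converged),
            "rounds": len(res.rms_history) - 1,
            "rms_history_mean": res.rms_history.mean(axis=1).tolist()}


def _stage_densify(cfg: PipelineConfig, d: Path) -> dict:
    template = _load_template(d)
    arr = np.load(_require(d / "corresponded_fits.npz", "correspond"))
    n = len(arr["nodes"])
    base, _, _ = sample_population(cfg.synthetic, return_base=True)
    all_rho = []
    flagged = []
    calibs = []
    for i in range(n):
        gt = load_ground_truth(d / f"ground_truth_{i:03d}")
        vol = voxelize(base, gt, cfg.synthetic,
                       rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 2000 + i])))
        calib = estimate_calibration(vol, rho_phantom=cfg.synthetic.phantom_density)
        mesh = template.with_nodes(arr["nodes"][i])
        fieldres = build_density_field(mesh, vol, calib,
                                       depth=cfg.sample_depth, step=cfg.sample_step)
        mesh.node_density = fieldres.rho_app
        fieldres.to_csv(mesh, d / f"density_{i:03d}.csv")
        channel = fieldres.rho_app if cfg.density_channel == "bmd" else fieldres.modulus
        all_rho.append(channel)
        flagged.append(~fieldres.ok)
        calibs.append((calib.ct_ha, calib.ct_h2o))
    np.savez_compressed(d / "density.npz", channel=np.array(all_rho),
                        flagged=np.array(flagged))
    return {"density_channel": cfg.density_channel,
            "mean_density": float(np.mean(all_rho)),
            "flagged_nodes": int(np.sum(flagged)),
            "calibrations": calibs}


def _stage_train(cfg: PipelineConfig, d: Path) -> dict:
    aligned = load_aligned_set(_require(d / "aligned.npz", "correspond").with_suffix(""))
    dens = np.load(_require(d / "density.npz", "densify"))["channel"]
    models = {
        "shape": sm.train(sm.stack_shape(aligned.coords), "shape",
                          variance_target=cfg.variance_target),
        "density": sm.train(sm.stack_density(dens), "density",
                            variance_target=cfg.variance_target),
        "combined": sm.train(sm.stack_combined(aligned.coords, dens), "combined",
                             variance_target=cfg.variance_target),
    }
    for name, model in models.items():
        sm.save_model(model, d / f"model_{name}")
    table = sm.variance_table(models)
    table.to_csv(d / "variance_table.csv", index=False)
    return {name: {"n_retained": m.n_retained,
                   "variance_fractions": m.variance_fractions[:10].tolist()}
            for name, m in models.items()}


def _stage_loo(cfg: PipelineConfig, d: Path) -> dict:
    import pandas as pd

    aligned = load_aligned_set(_require(d / "aligned.npz", "correspond").with_suffix(""))
    dens = np.load(_require(d / "density.npz", "densify"))["channel"]
    X = sm.stack_combined(aligned.coords, dens)
    kmax = min(cfg.loo_max_components, len(X) - 2)
    if len(X) < 3 or kmax < 1:
        (d / "loo_curve.csv").write_text("components,geometric_rms_mm,density_rms\n")
        return {"skipped": "leave-one-out needs at least three specimens"}
    curve = sm.loo_analysis(X, "combined", max_components=kmax)
    df = pd.DataFrame({"components": np.arange(kmax + 1),
                       "geometric_rms_mm": curve.geometric_rms,
                       "density_rms": curve.density_rms})
    df.to_csv(d / "loo_curve.csv", index=False)
    return {"geometric_rms": curve.geometric_rms.tolist(),
            "density_rms": curve.density_rms.tolist()}


def _stage_morpho(cfg: PipelineConfig, d: Path) -> dict:
    template = _load_template(d)
    arr = np.load(_require(d / "corresponded_fits.npz", "correspond"))
    dens = np.load(_require(d / "density.npz", "densify"))["channel"]
    model = sm.load_model(_require(d / "model_combined.npz", "train").with_suffix(""))
    results = {}
    for i in range(len(arr["nodes"])):
        mesh = template.with_nodes(arr["nodes"][i], node_density=dens[i])
        results[f"specimen_{i:03d}"] = mm.measure(mesh)
    mm.results_to_frame(results).to_csv(d / "morphometry.csv")
    report = {}
    for k in range(1, min(3, model.n_retained) + 1):
        eff = mm.mode_effect(model, k, template)
        report[f"component_{k}"] = {
            "percent_change": {m: (None if not np.isfinite(v) else round(v, 3))
                               for m, v in eff.percent_change.items()},
            "lateral_medial_area_ratio": [eff.lateral_medial_area_ratio_minus,
                                          eff.lateral_medial_area_ratio_plus],
        }
    (d / "mode_effects.json").write_text(json.dumps(report, indent=1))
    return {"n_specimens": len(results), "components_reported": len(report)}


_IMPLS = {
    "generate": _stage_generate,
    "fit": _stage_fit,
    "correspond": _stage_correspond,
    "densify": _stage_densify,
    "train": _stage_train,
    "loo": _stage_loo,
    "morpho": _stage_morpho,
}


def run_stage(stage: str, config: PipelineConfig, stage_dir) -> dict:
    """Execute one stage; returns (and writes) its manifest."""
    if stage not in _IMPLS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    d = Path(stage_dir)
    d.mkdir(parents=True, exist_ok=True)
    extra = _IMPLS[stage](config, d)
    manifest = _manifest(config, stage, extra)
    _write_manifest(d / f"manifest_{stage}.json", manifest)
    return manifest


def run_all(config: PipelineConfig, stage_dir) -> dict:
    """Run every stage in order; returns the combined manifest."""
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, config, stage_dir)
    return out
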