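"""Population-wide point-to-point correspondence.

Each specimen cloud is first fitted individually (host-mesh then fine fit,
:mod:`mc3ssm.mesh_core`), which yields meshes of identical topology but
imperfect node correspondence (nodes may slide tangentially).  This module

1. rigidly co-aligns the fitted meshes by generalized Procrustes analysis
   (no scaling -- size must remain in the statistical model), and
2. iterates the classic fit--train--refit loop: train a shape PCA on the
   aligned meshes, regularize every fit by projecting it onto the leading
   components (98% variance by default), release it to an unconstrained
   fine fit against its cloud, and repeat until the population mean RMS
   drops below the target (default 0.3 mm) and stops improving.

The PCA projection propagates a consistent node parameterization across the
population; the release step preserves per-specimen accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh_core import PatchMesh, FitResult, fine_fit, host_mesh_fit
from . import statistical_model as sm

__all__ = [
    "AlignedTrainingSet",
    "CorrespondenceResult",
    "kabsch",
    "rigid_align",
    "correspondence_loop",
    "save_aligned_set",
    "load_aligned_set",
]


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping source onto target.

    SVD-based orthogonal Procrustes restricted to proper rotations
    (det R = +1); no scaling.
    """
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    return R, t


@dataclass
class AlignedTrainingSet:
    """Rigidly co-aligned corresponded meshes plus the applied transforms.

    ``coords[i] = raw_coords[i] @ rotations[i].T + translations[i]``.
    """

    coords: np.ndarray                    # (N, n, 3)
    rotations: np.ndarray                 # (N, 3, 3)
    translations: np.ndarray              # (N, 3)
    reference_id: int = 0
    densities: np.ndarray | None = None   # (N, n), optional
    rms_history: np.ndarray | None = None

    @property
    def n_specimens(self) -> int:
        return len(self.coords)

    @property
    def mean_coords(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def shape_matrix(self) -> np.ndarray:
        return sm.stack_shape(self.coords)

    def to_cloud_frame(self, i: int, aligned_nodes: np.ndarray) -> np.ndarray:
        """Map node coordinates from the common frame back to specimen i's frame."""
        return (aligned_nodes - self.translations[i]) @ self.rotations[i]


def _coords_of(meshes) -> np.ndarray:
    if isinstance(meshes, np.ndarray):
        return np.asarray(meshes, float)
    first = meshes[0]
    coords = []
    for m in meshes:
        if isinstance(m, PatchMesh):
            if m.patches.shape != first.patches.shape or not np.array_equal(
                m.patches, first.patches
            ):
                raise ValueError("meshes must share an identical patch topology")
            coords.append(m.nodes)
        elif isinstance(m, FitResult):
            coords.append(m.fitted_nodes)
        else:
            coords.append(np.asarray(m, float))
    coords = np.asarray(coords, float)
    if coords.ndim != 3 or coords.shape[1:] != coords[0].shape:
        raise ValueError("specimens must share node count")
    return coords


def rigid_align(meshes, tol: float = 1e-6, max_iters: int = 100) -> AlignedTrainingSet:
    """Generalized Procrustes alignment (rotation + translation only).

    Every specimen is aligned to the evolving mean by orthogonal Procrustes,
    the mean is recomputed, and the process repeats until the mean moves by
    less than ``tol`` mm (RMS).  The first specimen anchors the initial
    frame.  Scaling is deliberately excluded so that overall size stays in
    the statistical model.
    """
    coords = _coords_of(meshes)
    N = len(coords)
    if N < 2:
        raise ValueError("need at least two meshes to align")
    R = np.tile(np.eye(3), (N, 1, 1))
    t = np.zeros((N, 3))
    aligned = coords.copy()
    mean = aligned[0].copy()
    for _ in range(max_iters):
        for i in range(N):
            Ri, ti = kabsch(coords[i], mean)
            R[i], t[i] = Ri, ti
            aligned[i] = coords[i] @ Ri.T + ti
        new_mean = aligned.mean(axis=0)
        move = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if move < tol:
            break
    return AlignedTrainingSet(aligned, R, t, reference_id=0)


def _footpoint_normals(surf: PatchMesh, pids, us, vs) -> np.ndarray:
    Su = surf.evaluate_many(pids, us, vs, du=1)
    Sv = surf.evaluate_many(pids, us, vs, dv=1)
    n = np.cross(Su, Sv)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _similarity_kabsch(source: np.ndarray, target: np.ndarray):
    """(s, R, t) of the least-squares similarity mapping source onto target."""
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    s = np.sum(S * np.array([1.0, 1.0, d])) / np.sum((source - cs) ** 2)
    t = ct - s * R @ cs
    return s, R, t


def _asm_register(
    surf: PatchMesh,
    base_nodes: np.ndarray,
    mode_fields: np.ndarray,
    init: tuple[float, np.ndarray, np.ndarray] | None = None,
    iters: int = 15,
    max_weight: float = 4.0,
):
    """Register a deformable reference (base + mode fields) onto a surface.

    Active-shape-model style fit: alternately project the posed reference
    nodes onto the surface and solve a point-to-plane linearized least
    squares for a similarity update (rotation about the reference centroid,
    translation, scale) together with mode-weight updates.  The mode fields
    carry the population's non-rigid variation, so the similarity estimate
    is not biased by it.

    Returns (scale, R, t, weights) with the reference posed as
    ``scale * (base + w . fields) @ R.T + t``.
    """
    k = len(mode_fields)
    if init is None:
        sc, R, tau = 1.0, np.eye(3), np.zeros(3)
    else:
        sc, R, tau = init
        R = R.copy()
        tau = np.asarray(tau, float).copy()
    w = np.zeros(k)
    n_pts = len(base_nodes)
    for _ in range(iters):
        B = base_nodes + (np.tensordot(w, mode_fields, axes=1) if k else 0.0)
        X = sc * (B @ R.T) + tau
        pids, us, vs, _, F = surf.project_points(X, k=4, iters=6)
        N = _footpoint_normals(surf, pids, us, vs)
        xbar = X.mean(axis=0)
        Xc = X - xbar
        cols = [np.cross(np.broadcast_to(e, (n_pts, 3)), Xc) for e in np.eye(3)]
        cols = [np.einsum("nj,nj->n", N, c) for c in cols]
        cols += [N @ e for e in np.eye(3)]
        cols.append(np.einsum("nj,nj->n", N, Xc))  # scale column
        if k:
            phiR = sc * np.einsum("knj,ij->kni", mode_fields, R)
            cols += [np.einsum("nj,nj->n", N, phiR[kk]) for kk in range(k)]
        A = np.stack(cols, axis=1)
        b = np.einsum("nj,nj->n", N, F - X)
        H = A.T @ A
        ridge = 1e-4 * np.trace(H) / H.shape[0]
        delta = np.linalg.solve(H + ridge * np.eye(H.shape[0]), A.T @ b)
        th = delta[:3]
        ang = np.linalg.norm(th)
        if ang > 1e-12:
            K = np.array([[0, -th[2], th[1]], [th[2], 0, -th[0]], [-th[1], th[0], 0]])
            dR = (np.eye(3) + np.sin(ang) / ang * K
                  + (1 - np.cos(ang)) / ang**2 * (K @ K))
        else:
            dR = np.eye(3)
        ds = 1.0 + delta[6]
        # update acts about xbar: x -> xbar + ds*dR(x - xbar) + dtau
        R = dR @ R
        sc = sc * ds
        tau = ds * (dR @ tau) + (xbar - ds * (dR @ xbar)) + delta[3:6]
        if k:
            # scores live on a standard-normal scale; clamping guards the
            # linearized solve against ill-conditioned noise modes
            w = np.clip(w + delta[7:], -max_weight, max_weight)
    return sc, R, tau, w


def reparameterize_fits(
    template: PatchMesh,
    fits: list[FitResult],
    clouds: list[np.ndarray] | None = None,
    n_modes: int = 8,
    smoothing_weight: float = 1e-3,
    deflate_similarity: bool = False,
) -> list[FitResult]:
    """Re-anchor every fit's node parameterization by normal projection.

    Surface fitting pins the mesh to each specimen's surface but leaves the
    node parameterization free to slide tangentially (a rotation-like
    sliding is invisible to point-to-surface distance).  This step fixes the
    correspondence *convention*:

    1. a shape PCA of the current fits supplies normal-displacement mode
       fields (tangential components are discarded -- they are exactly the
       sliding being removed);
    2. for each specimen, the template plus those modes is registered onto
       the fitted surface (:func:`_asm_register`), which recovers the
       specimen's similarity pose without the non-rigid variation biasing
       it;
    3. node j is re-placed where the ray from node j of the similarity-posed,
       isotropically scaled template, cast along the template normal,
       pierces the fitted surface.  Rays that miss (open proximal boundary)
       fall back to closest-point projection.

    Inter-specimen variation is thereby expressed as similarity pose plus
    displacements along template normals -- the standard normal-offset
    parameterization of shape-model training sets.  When ``clouds`` is
    given, each reparameterized mesh is re-tightened by a fine fit.

    ``deflate_similarity`` additionally removes from the mode fields their
    component along the similarity group's normal-action fields (the
    apparent normal displacement a small rotation or scaling produces).
    Modes learned from sliding-contaminated fits carry exactly such ghost
    components, which would otherwise let the registration trade pose
    against modes; deflated warm-up rounds break that feedback, after
    which undeflated rounds refine with the full mode fields.
    """
    aligned = rigid_align([f.fitted_nodes for f in fits])
    model = sm.train(aligned.shape_matrix(), "shape", variance_target=0.98)
    k = int(min(n_modes, model.n_retained))
    # drop near-noise modes: they destabilize the registration
    strong = model.mode_sd[:k] > 0.05 * model.mode_sd[0]
    k = int(np.sum(strong))
    # rotate mode fields from the aligned frame into the template frame
    R_f, _ = kabsch(aligned.mean_coords, template.nodes)
    phi = (model.components[:k] * model.mode_sd[:k, None]).reshape(k, -1, 3)
    phi = phi @ R_f.T
    tn = template.node_normals()
    phi = tn[None] * np.einsum("knj,nj->kn", phi, tn)[..., None]
    if deflate_similarity and k:
        tc0 = template.nodes.mean(axis=0)
        acts = [np.cross(e, template.nodes - tc0) for e in np.eye(3)]
        acts.append(template.nodes - tc0)
        actn = np.array([tn * np.einsum("nj,nj->n", a, tn)[:, None] for a in acts])
        Qs, _ = np.linalg.qr(actn.reshape(4, -1).T)
        flat = phi.reshape(k, -1)
        phi = (flat - (flat @ Qs) @ Qs.T).reshape(k, -1, 3)

    tc = template.nodes.mean(axis=0)
    r_t = np.sqrt(np.mean(np.sum((template.nodes - tc) ** 2, axis=1)))
    out = []
    for i, fit in enumerate(fits):
        surf = fit.mesh if fit.mesh is not None else template.with_nodes(fit.fitted_nodes)
        init = _similarity_kabsch(template.nodes, fit.fitted_nodes)
        sc, R, tau, w = _asm_register(surf, template.nodes, phi, init=init)
        recon = template.nodes + np.tensordot(w, phi, axes=1)
        s_i = np.sqrt(np.mean(np.sum((recon - recon.mean(0)) ** 2, axis=1))) / r_t
        ref = sc * ((tc + s_i * (template.nodes - tc)) @ R.T) + tau
        dirs = tn @ R.T
        pts, tt, ok = surf.intersect_rays(ref, dirs)
        ok = ok & (np.abs(tt) < 6.0)
        if not ok.all():
            _, _, _, _, foot = surf.project_points(ref[~ok])
            pts[~ok] = foot
        mesh = template.with_nodes(pts)
        if clouds is not None:
            refit = fine_fit(mesh, clouds[i], smoothing_weight=smoothing_weight)
            out.append(refit)
        else:
            out.append(FitResult(pts, fit.rms, fit.iterations, fit.converged, mesh))
    return out


@dataclass
class CorrespondenceResult:
    """Final aligned set, per-specimen fits (in cloud frames) and RMS history."""

    aligned: AlignedTrainingSet
    fits: list[FitResult] = field(repr=False)
    rms_history: np.ndarray  # (rounds, N), round 0 = initial fits
    converged: bool

    @property
    def mean_rms(self) -> float:
        return float(self.rms_history[-1].mean())


def correspondence_loop(
    template: PatchMesh,
    clouds: list[np.ndarray],
    initial_fits: list[FitResult] | None = None,
    rms_target: float = 0.3,
    max_rounds: int = 10,
    variance_capture: float = 0.98,
    improvement_tol: float = 1e-3,
    smoothing_weight: float = 1e-3,
    reparam_rounds: int = 12,
) -> CorrespondenceResult:
    """Iterated fit--train--refit correspondence over a population of clouds.

    Parameters
    ----------
    template : the packaged template mesh (topology + landmarks)
    clouds : list of (m_i, 3) segmented point clouds
    initial_fits : per-cloud fits from mesh_core; computed (host + fine)
        when omitted
    rms_target : population mean cloud-to-surface RMS (mm) at which the
        loop stops
    variance_capture : variance fraction of the shape PCA used as the
        model constraint during refitting

    A refit is accepted only if it does not worsen that specimen's RMS by
    more than ``improvement_tol`` mm, so the population mean RMS is
    non-increasing up to that slack.  After the RMS-driven rounds,
    ``reparam_rounds`` passes of :func:`reparameterize_fits` re-anchor the
    node parameterization (normal projection from the similarity-posed
    template), which removes tangential sliding that point-to-surface RMS
    cannot see.
    """
    if initial_fits is None:
        initial_fits = []
        for cloud in clouds:
            coarse = host_mesh_fit(template, cloud)
            initial_fits.append(fine_fit(coarse, cloud, smoothing_weight=smoothing_weight))
    fits = list(initial_fits)
    history = [np.array([f.rms for f in fits])]
    converged = False
    for _ in range(max_rounds):
        aligned = rigid_align([f.fitted_nodes for f in fits])
        model = sm.train(aligned.shape_matrix(), "shape", variance_target=variance_capture)
        new_fits = []
        for i, cloud in enumerate(clouds):
            vec = aligned.coords[i].ravel()
            w, _ = sm.project(model, vec)
            recon = sm.reconstruct(model, w).reshape(-1, 3)
            init_nodes = aligned.to_cloud_frame(i, recon)
            init = FitResult(init_nodes, np.inf, 0, False, template.with_nodes(init_nodes))
            refit = fine_fit(init, cloud, smoothing_weight=smoothing_weight)
            if refit.rms <= fits[i].rms + improvement_tol:
                new_fits.append(refit)
            else:
                new_fits.append(fits[i])
        fits = new_fits
        history.append(np.array([f.rms for f in fits]))
        mean_rms = history[-1].mean()
        if mean_rms < rms_target or history[-2].mean() - mean_rms < improvement_tol:
            converged = mean_rms < rms_target
            break
    if reparam_rounds:
        polished = list(fits)
        for r in range(reparam_rounds):
            polished = reparameterize_fits(
                template, polished, clouds=None,
                deflate_similarity=(r < reparam_rounds // 2),
            )
        refitted = [
            fine_fit(f.mesh, cloud, smoothing_weight=smoothing_weight)
            for f, cloud in zip(polished, clouds)
        ]
        fits = refitted
        history.append(np.array([f.rms for f in fits]))
    converged = converged or history[-1].mean() < rms_target
    aligned = rigid_align([f.fitted_nodes for f in fits])
    aligned.rms_history = np.array(history)
    return CorrespondenceResult(aligned, fits, np.array(history), converged)


def save_aligned_set(aset: AlignedTrainingSet, path) -> None:
    """One archive: N x 3n coordinate matrix, transforms, RMS history."""
    arrays = {
        "coords": aset.coords,
        "rotations": aset.rotations,
        "translations": aset.translations,
        "reference_id": np.array(aset.reference_id),
    }
    if aset.densities is not None:
        arrays["densities"] = aset.densities
    if aset.rms_history is not None:
        arrays["rms_history"] = aset.rms_history
    np.savez_compressed(Path(path).with_suffix(".npz"), **arrays)


def load_aligned_set(path) -> AlignedTrainingSet:
    arr = np.load(Path(path).with_suffix(".npz"))
    return AlignedTrainingSet(
        arr["coords"], arr["rotations"], arr["translations"],
        int(arr["reference_id"]),
        arr["densities"] if "densities" in arr else None,
        arr["rms_history"] if "rms_history" in arr else None,
    )
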