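"""Piecewise-parametric quadrilateral surface meshes and point-cloud fitting.

The template surface is a fixed-topology network of bicubic Lagrange patches
(4x4 control nodes each, nodes shared across patch edges, C0 continuous).
Fitting a segmented bone point cloud proceeds in two stages:

1. :func:`host_mesh_fit` -- coarse registration.  The template is embedded in
   a tricubic Bernstein free-form-deformation lattice and the lattice control
   points are optimized (iterative-closest-point style Gauss--Newton) to
   minimize mean squared cloud-point-to-surface distance plus a lattice
   smoothness penalty.
2. :func:`fine_fit` -- per-node refinement with a Sobolev-type penalty on the
   second parametric derivatives of the displacement field.

Root-mean-square (RMS) error is always the RMS of cloud-point-to-surface
distances, in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "PatchMesh",
    "TemplateMesh",
    "FitResult",
    "build_template_topology",
    "prealign",
    "host_mesh_fit",
    "fine_fit",
    "lagrange_basis",
    "save_mesh",
    "load_mesh",
]

# ---------------------------------------------------------------------------
# Cubic Lagrange basis on [0, 1] with nodes at 0, 1/3, 2/3, 1.
# ---------------------------------------------------------------------------

_STATIONS = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
# L_i(u) = sum_k _COEF[i, k] u^k  with  L_i(station_j) = delta_ij
_COEF = np.linalg.inv(np.vander(_STATIONS, 4, increasing=True)).T


def lagrange_basis(u: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Cubic Lagrange shape functions (or their derivatives) at ``u``.

    Parameters
    ----------
    u : array, shape (m,)
    deriv : 0, 1 or 2

    Returns
    -------
    array, shape (m, 4)
    """
    u = np.asarray(u, dtype=float)
    P = np.empty(u.shape + (4,))
    if deriv == 0:
        P[..., 0] = 1.0
        P[..., 1] = u
        P[..., 2] = u * u
        P[..., 3] = P[..., 2] * u
    elif deriv == 1:
        P[..., 0] = 0.0
        P[..., 1] = 1.0
        P[..., 2] = 2.0 * u
        P[..., 3] = 3.0 * u * u
    elif deriv == 2:
        P[..., 0] = 0.0
        P[..., 1] = 0.0
        P[..., 2] = 2.0
        P[..., 3] = 6.0 * u
    else:  # pragma: no cover
        raise ValueError("deriv must be 0, 1 or 2")
    return P @ _COEF.T


def _gauss01(n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


# ---------------------------------------------------------------------------
# Template topology
# ---------------------------------------------------------------------------

N_AZ = 24          # node stations around the shaft (8 patches x 3)
N_RINGS = 13       # axial node rings, ring 0 = cap boundary
CAP_N = 7          # cap node grid is CAP_N x CAP_N


def _cap_id(ia: int, ib: int) -> int:
    return ia * CAP_N + ib


def _boundary_station(j: int) -> tuple[int, int]:
    """Cap-grid indices of azimuthal station ``j`` on the cap boundary ring."""
    j = j % N_AZ
    if j <= 3:
        return 6, 3 + j
    if j <= 9:
        return 6 - (j - 3), 6
    if j <= 15:
        return 0, 6 - (j - 9)
    if j <= 21:
        return j - 15, 0
    return 6, j - 21


@dataclass
class NodeStations:
    """Per-node parametric bookkeeping used by the synthetic-shape generator."""

    kind: np.ndarray      # 0 = cap, 1 = side
    theta: np.ndarray     # azimuth (rad); pole gets 0
    cap_rho: np.ndarray   # square radius max(|a|,|b|) on the cap, nan for side
    ring: np.ndarray      # axial ring index, -1 for cap interior
    a: np.ndarray
    b: np.ndarray


def build_template_topology() -> tuple[int, np.ndarray, NodeStations, dict, dict]:
    """Build the fixed quad-patch layout of the distal-MC3 template.

    The surface is an open-topped "spherical cube": a 2x2 block of patches
    caps the distal end (no degenerate edges; the pole is a regular valence-4
    node) and an 8 x 4 cylinder of patches forms the epiphysis/metaphysis
    shell up to the proximal cutoff ring.

    Returns
    -------
    n_nodes, patches (P, 4, 4) int node-id grids, stations, landmarks, regions
    """
    n_cap = CAP_N * CAP_N
    n_nodes = n_cap + (N_RINGS - 1) * N_AZ

    def side_id(r: int, j: int) -> int:
        j = j % N_AZ
        if r == 0:
            ia, ib = _boundary_station(j)
            return _cap_id(ia, ib)
        return n_cap + (r - 1) * N_AZ + j

    kind = np.zeros(n_nodes, dtype=int)
    theta = np.zeros(n_nodes)
    cap_rho = np.full(n_nodes, np.nan)
    ring = np.full(n_nodes, -1, dtype=int)
    aa = np.full(n_nodes, np.nan)
    bb = np.full(n_nodes, np.nan)

    def squircle(a: float, b: float) -> tuple[float, float]:
        # smooth square -> disc map; the square boundary lands exactly on
        # the unit circle, so the cap meets the shell without a crease
        return a * np.sqrt(1.0 - 0.5 * b * b), b * np.sqrt(1.0 - 0.5 * a * a)

    for ia in range(CAP_N):
        for ib in range(CAP_N):
            i = _cap_id(ia, ib)
            a = -1.0 + ia / 3.0
            b = -1.0 + ib / 3.0
            u, v = squircle(a, b)
            kind[i] = 0
            aa[i], bb[i] = a, b
            cap_rho[i] = np.hypot(u, v)
            theta[i] = np.arctan2(v, u) if (a, b) != (0.0, 0.0) else 0.0
    for r in range(1, N_RINGS):
        for j in range(N_AZ):
            i = side_id(r, j)
            ja, jb = _boundary_station(j)
            u, v = squircle(-1.0 + ja / 3.0, -1.0 + jb / 3.0)
            kind[i] = 1
            ring[i] = r
            theta[i] = np.arctan2(v, u)
    # boundary ring nodes double as ring 0
    for j in range(N_AZ):
        ring[side_id(0, j)] = 0

    patches = []
    # cap: 2x2, oriented (u along b, v along a) so normals point outward (-z).
    for ca in range(2):
        for cb in range(2):
            grid = np.empty((4, 4), dtype=int)
            for i in range(4):
                for jj in range(4):
                    grid[i, jj] = _cap_id(3 * ca + jj, 3 * cb + i)
            patches.append(grid)
    # side: 8 around x 4 axial, (u along azimuth CCW, v proximal) -> outward.
    for p in range(4):
        for q in range(8):
            grid = np.empty((4, 4), dtype=int)
            for i in range(4):
                for jj in range(4):
                    grid[i, jj] = side_id(3 * p + jj, 3 * q + i)
            patches.append(grid)
    patches = np.array(patches)

    cap_patch_ids = list(range(4))
    stations = NodeStations(kind, theta, cap_rho, ring, aa, bb)

    landmarks = {
        "medial_edge": side_id(0, 0),
        "lateral_edge": side_id(0, 12),
        "medial_condyle_dorsal": side_id(0, 2),
        "medial_groove_dorsal": side_id(0, 5),
        "lateral_groove_dorsal": side_id(0, 7),
        "lateral_condyle_dorsal": side_id(0, 10),
        "sagittal_ridge_crest": side_id(0, 6),
        "distal_pole": _cap_id(3, 3),
    }

    def cap_nodes(pred) -> list[int]:
        out = []
        for ia in range(CAP_N):
            for ib in range(CAP_N):
                a = -1.0 + ia / 3.0
                b = -1.0 + ib / 3.0
                if pred(a, b):
                    out.append(_cap_id(ia, ib))
        return out

    regions = {
        "metaphysis_ring": [side_id(N_RINGS - 1, j) for j in range(N_AZ)],
        "width_pairs": {
            "medio_lateral_width": ("medial_edge", "lateral_edge"),
            "medial_condylar_width": ("medial_condyle_dorsal", "medial_groove_dorsal"),
            "lateral_condylar_width": ("lateral_condyle_dorsal", "lateral_groove_dorsal"),
            "sagittal_ridge_width": ("medial_groove_dorsal", "lateral_groove_dorsal"),
        },
        # medial condyle sits at +x (a > 0), lateral at -x
        "medial_condyle_patches": [p for p in cap_patch_ids if p < 2],
        "lateral_condyle_patches": [p for p in cap_patch_ids if p >= 2],
        "palmar_condyle_nodes": cap_nodes(lambda a, b: abs(a) >= 1 / 3 - 1e-9 and b <= -1 / 3 + 1e-9),
        "dorsal_condyle_nodes": cap_nodes(lambda a, b: abs(a) >= 1 / 3 - 1e-9 and b >= 1 / 3 - 1e-9),
    }
    # patch 0: ca=0 -> a in [-1,0] -> lateral; ca=1 -> medial
    regions["medial_condyle_patches"] = [2, 3]
    regions["lateral_condyle_patches"] = [0, 1]
    return n_nodes, patches, stations, landmarks, regions


# ---------------------------------------------------------------------------
# PatchMesh
# ---------------------------------------------------------------------------


class PatchMesh:
    """A bicubic-Lagrange quad-patch surface with named landmarks.

    Instances are treated as immutable once constructed (fits build new
    instances via :meth:`with_nodes`), which makes it safe to cache dense
    surface samples and KD-trees.
    """

    def __init__(
        self,
        nodes: np.ndarray,
        patches: np.ndarray,
        landmarks: dict | None = None,
        regions: dict | None = None,
        stations: NodeStations | None = None,
        proximal_cutoff: float | None = None,
        node_density: np.ndarray | None = None,
        node_flags: np.ndarray | None = None,
    ):
        self.nodes = np.asarray(nodes, dtype=float)
        self.patches = np.asarray(patches, dtype=int)
        self.landmarks = landmarks or {}
        self.regions = regions or {}
        self.stations = stations
        self.proximal_cutoff = proximal_cutoff
        self.node_density = None if node_density is None else np.asarray(node_density, float)
        self.node_flags = None if node_flags is None else np.asarray(node_flags, bool)
        self._dense_cache: dict[int, tuple] = {}
        self._tree_cache: dict[int, cKDTree] = {}

    # -- basic properties ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def with_nodes(self, nodes: np.ndarray, node_density=None, node_flags=None) -> "PatchMesh":
        """New mesh sharing this topology with replaced node coordinates."""
        return PatchMesh(
            nodes,
            self.patches,
            self.landmarks,
            self.regions,
            self.stations,
            self.proximal_cutoff,
            node_density if node_density is not None else self.node_density,
            node_flags if node_flags is not None else self.node_flags,
        )

    # -- evaluation ---------------------------------------------------------
    def _check_patch(self, patch_id: int) -> None:
        if not (0 <= patch_id < self.n_patches):
            raise IndexError(f"invalid patch id {patch_id}")

    def evaluate(self, patch_id: int, u, v, du: int = 0, dv: int = 0) -> np.ndarray:
        """Evaluate a patch (or a parametric derivative) at (u, v) in [0,1]^2."""
        self._check_patch(patch_id)
        scalar = np.ndim(u) == 0 and np.ndim(v) == 0
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        Bu = lagrange_basis(u, du)
        Bv = lagrange_basis(v, dv)
        P = self.nodes[self.patches[patch_id]]  # (4,4,3)
        out = np.einsum("mi,mj,ijc->mc", Bu, Bv, P)
        return out[0] if scalar else out

    def evaluate_many(self, patch_ids, us, vs, du: int = 0, dv: int = 0) -> np.ndarray:
        """Vectorized evaluation at per-point (patch, u, v) triples."""
        patch_ids = np.asarray(patch_ids, int)
        us = np.asarray(us, float)
        vs = np.asarray(vs, float)
        out = np.empty((len(us), 3))
        Bu = lagrange_basis(us, du)
        Bv = lagrange_basis(vs, dv)
        for p in np.unique(patch_ids):
            m = patch_ids == p
            P = self.nodes[self.patches[p]]
            out[m] = np.einsum("mi,mj,ijc->mc", Bu[m], Bv[m], P)
        return out

    def basis_rows(self, patch_ids, us, vs) -> sparse.csr_matrix:
        """Sparse (n_points x n_nodes) interpolation matrix at (patch,u,v)."""
        patch_ids = np.asarray(patch_ids, int)
        Bu = lagrange_basis(np.asarray(us, float))
        Bv = lagrange_basis(np.asarray(vs, float))
        w = np.einsum("mi,mj->mij", Bu, Bv).reshape(len(patch_ids), 16)
        cols = self.patches[patch_ids].reshape(len(patch_ids), 16)
        rows = np.repeat(np.arange(len(patch_ids)), 16)
        return sparse.csr_matrix(
            (w.ravel(), (rows, cols.ravel())), shape=(len(patch_ids), self.n_nodes)
        )

    def interpolate_node_field(self, values: np.ndarray, patch_ids, us, vs) -> np.ndarray:
        """Interpolate a per-node scalar field at surface parameter points."""
        patch_ids = np.asarray(patch_ids, int)
        Bu = lagrange_basis(np.asarray(us, float))
        Bv = lagrange_basis(np.asarray(vs, float))
        vals = np.asarray(values, float)
        out = np.empty(len(patch_ids))
        for p in np.unique(patch_ids):
            m = patch_ids == p
            V = vals[self.patches[p]]
            out[m] = np.einsum("mi,mj,ij->m", Bu[m], Bv[m], V)
        return out

    # -- dense sampling & projection ---------------------------------------
    def dense_samples(self, m: int = 9):
        """(points, patch_ids, us, vs) on an m x m grid per patch (cached)."""
        if m in self._dense_cache:
            return self._dense_cache[m]
        g = np.linspace(0.0, 1.0, m)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        us = np.tile(uu.ravel(), self.n_patches)
        vs = np.tile(vv.ravel(), self.n_patches)
        pids = np.repeat(np.arange(self.n_patches), m * m)
        pts = self.evaluate_many(pids, us, vs)
        self._dense_cache[m] = (pts, pids, us, vs)
        return self._dense_cache[m]

    def _tree(self, m: int = 9) -> cKDTree:
        if m not in self._tree_cache:
            self._tree_cache[m] = cKDTree(self.dense_samples(m)[0])
        return self._tree_cache[m]

    def project_points(self, queries: np.ndarray, k: int = 4, iters: int = 8, m: int = 17):
        """Closest surface points for many queries.

        Candidate (patch, u, v) seeds come from a KD-tree over a dense sample
        grid; each candidate is refined by a clamped Gauss--Newton iteration.

        Returns
        -------
        patch_ids, us, vs, distances, footpoints
        """
        queries = np.atleast_2d(np.asarray(queries, float))
        nq = len(queries)
        pts, pids, us0, vs0 = self.dense_samples(m)
        _, idx = self._tree(m).query(queries, k=k)
        idx = np.atleast_2d(idx)

        # candidate list: (query_index, patch, u0, v0); dedupe per query+patch
        qi = np.repeat(np.arange(nq), idx.shape[1])
        ci = idx.ravel()
        cp = pids[ci]
        order = np.lexsort((cp, qi))
        qi, ci, cp = qi[order], ci[order], cp[order]
        keep = np.ones(len(qi), bool)
        keep[1:] = (qi[1:] != qi[:-1]) | (cp[1:] != cp[:-1])
        qi, ci, cp = qi[keep], ci[keep], cp[keep]

        P16 = self.nodes[self.patches[cp]].reshape(-1, 16, 3)  # per-candidate
        Q = queries[qi]
        u = us0[ci].copy()
        v = vs0[ci].copy()

        def ev(u, v, du=0, dv=0):
            Bu = lagrange_basis(u, du)
            Bv = lagrange_basis(v, dv)
            W = (Bu[:, :, None] * Bv[:, None, :]).reshape(-1, 1, 16)
            return (W @ P16)[:, 0, :]

        S = ev(u, v)
        d2 = np.sum((S - Q) ** 2, axis=1)
        bu, bv, bd2 = u.copy(), v.copy(), d2.copy()
        for _ in range(iters):
            Su = ev(u, v, 1, 0)
            Sv = ev(u, v, 0, 1)
            r = S - Q
            g1 = np.sum(r * Su, axis=1)
            g2 = np.sum(r * Sv, axis=1)
            # full Newton (curvature terms matter for distant queries),
            # damped toward Gauss-Newton where indefinite
            h11 = np.sum(Su * Su, axis=1) + np.sum(r * ev(u, v, 2, 0), axis=1)
            h12 = np.sum(Su * Sv, axis=1) + np.sum(r * ev(u, v, 1, 1), axis=1)
            h22 = np.sum(Sv * Sv, axis=1) + np.sum(r * ev(u, v, 0, 2), axis=1)
            gn11 = np.sum(Su * Su, axis=1) + 1e-12
            gn22 = np.sum(Sv * Sv, axis=1) + 1e-12
            bad = (h11 <= 0) | (h22 <= 0) | (h11 * h22 - h12 * h12 <= 0)
            h11 = np.where(bad, gn11, h11)
            h22 = np.where(bad, gn22, h22)
            h12 = np.where(bad, np.sum(Su * Sv, axis=1), h12)
            det = h11 * h22 - h12 * h12
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            u = np.clip(u - (h22 * g1 - h12 * g2) / det, 0.0, 1.0)
            v = np.clip(v - (-h12 * g1 + h11 * g2) / det, 0.0, 1.0)
            S = ev(u, v)
            d2 = np.sum((S - Q) ** 2, axis=1)
            better = d2 < bd2
            bu[better], bv[better], bd2[better] = u[better], v[better], d2[better]
            u, v = bu.copy(), bv.copy()
        foot = ev(bu, bv)

        # per-query argmin over candidates; exact ties -> lowest patch id
        sel = np.lexsort((cp, bd2, qi))
        first = np.ones(len(sel), bool)
        qs = qi[sel]
        first[1:] = qs[1:] != qs[:-1]
        win = sel[first]
        out_pid = np.empty(nq, int)
        out_u = np.empty(nq)
        out_v = np.empty(nq)
        out_d2 = np.empty(nq)
        out_f = np.empty((nq, 3))
        out_pid[qi[win]] = cp[win]
        out_u[qi[win]] = bu[win]
        out_v[qi[win]] = bv[win]
        out_d2[qi[win]] = bd2[win]
        out_f[qi[win]] = foot[win]
        return out_pid, out_u, out_v, np.sqrt(out_d2), out_f

    def intersect_rays(self, origins: np.ndarray, directions: np.ndarray,
                       iters: int = 10):
        """Nearby ray--surface intersections, one per ray.

        Solves S(u, v) = origin + t * direction by Newton iteration in
        (u, v, t), seeded from the closest surface point to each origin, so
        the intersection nearest the origin is found (not the far side of a
        closed surface).  Returns (points, t, ok); ``ok`` is False where the
        residual exceeds 1e-6 mm (e.g. rays that leave the open boundary).
        """
        origins = np.atleast_2d(np.asarray(origins, float))
        directions = np.asarray(directions, float)
        directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
        pids, u, v, _, foot = self.project_points(origins)
        t = np.sum((foot - origins) * directions, axis=1)
        P = self.nodes[self.patches[pids]]

        def ev(u, v, du=0, dv=0):
            return np.einsum(
                "mi,mj,mijc->mc", lagrange_basis(u, du), lagrange_basis(v, dv), P
            )

        for _ in range(iters):
            S = ev(u, v)
            F = S - origins - t[:, None] * directions
            J = np.stack([ev(u, v, 1, 0), ev(u, v, 0, 1), -directions], axis=2)
            try:
                step = np.linalg.solve(J, -F[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate ray
                step = np.linalg.lstsq(J.reshape(-1, 3, 3).astype(float),
                                       -F[:, :, None], rcond=None)[0][:, :, 0]
            u = np.clip(u + step[:, 0], 0.0, 1.0)
            v = np.clip(v + step[:, 1], 0.0, 1.0)
            t = t + step[:, 2]
        S = ev(u, v)
        resid = np.linalg.norm(S - origins - t[:, None] * directions, axis=1)
        bad = resid > 1e-6
        if np.any(bad):
            # intersection may sit in a neighboring patch: re-seed failed rays
            # from the dense sample nearest to the ray line
            pts, spids, sus, svs = self.dense_samples(9)
            for i in np.nonzero(bad)[0]:
                rel = pts - origins[i]
                tt = rel @ directions[i]
                perp = np.linalg.norm(rel - tt[:, None] * directions[i], axis=1)
                perp[np.abs(tt) > 10.0] = np.inf  # stay near the origin
                j = int(np.argmin(perp))
                ui, vi, ti = sus[j], svs[j], tt[j]
                Pi = self.nodes[self.patches[spids[j]]]
                for _ in range(iters):
                    Bu0, Bv0 = lagrange_basis([ui]), lagrange_basis([vi])
                    Si = np.einsum("mi,mj,ijc->mc", Bu0, Bv0, Pi)[0]
                    Fi = Si - origins[i] - ti * directions[i]
                    Ji = np.stack([
                        np.einsum("mi,mj,ijc->mc", lagrange_basis([ui], 1), Bv0, Pi)[0],
                        np.einsum("mi,mj,ijc->mc", Bu0, lagrange_basis([vi], 1), Pi)[0],
                        -directions[i],
                    ], axis=1)
                    try:
                        st = np.linalg.solve(Ji, -Fi)
                    except np.linalg.LinAlgError:  # pragma: no cover
                        break
                    ui = float(np.clip(ui + st[0], 0.0, 1.0))
                    vi = float(np.clip(vi + st[1], 0.0, 1.0))
                    ti += st[2]
                Bu0, Bv0 = lagrange_basis([ui]), lagrange_basis([vi])
                Si = np.einsum("mi,mj,ijc->mc", Bu0, Bv0, Pi)[0]
                ri = np.linalg.norm(Si - origins[i] - ti * directions[i])
                if ri < resid[i]:
                    S[i], t[i], resid[i] = Si, ti, ri
        return S, t, resid < 1e-6

    def closest_point(self, query: np.ndarray):
        """(patch_id, u, v, distance) of the closest surface point to ``query``.

        Exact ties between patches are broken toward the lowest patch id.
        """
        p, u, v, d, _ = self.project_points(np.asarray(query, float)[None, :], k=8, iters=12)
        return int(p[0]), float(u[0]), float(v[0]), float(d[0])

    def rms_to_cloud(self, cloud: np.ndarray) -> float:
        """RMS of cloud-point-to-surface distances (mm)."""
        _, _, _, d, _ = self.project_points(cloud)
        return float(np.sqrt(np.mean(d * d)))

    # -- differential quantities -------------------------------------------
    def patch_areas(self, gauss_n: int = 4) -> np.ndarray:
        """Per-patch surface area via tensor Gauss--Legendre quadrature."""
        x, w = _gauss01(gauss_n)
        uu, vv = np.meshgrid(x, x, indexing="ij")
        ww = np.outer(w, w).ravel()
        areas = np.empty(self.n_patches)
        for p in range(self.n_patches):
            P = self.nodes[self.patches[p]]
            Bu = lagrange_basis(uu.ravel())
            Bv = lagrange_basis(vv.ravel())
            dBu = lagrange_basis(uu.ravel(), 1)
            dBv = lagrange_basis(vv.ravel(), 1)
            Su = np.einsum("mi,mj,ijc->mc", dBu, Bv, P)
            Sv = np.einsum("mi,mj,ijc->mc", Bu, dBv, P)
            areas[p] = np.sum(ww * np.linalg.norm(np.cross(Su, Sv), axis=1))
        return areas

    def node_normals(self) -> np.ndarray:
        """Outward unit normals at nodes, averaged over adjacent patches."""
        acc = np.zeros((self.n_nodes, 3))
        st = _STATIONS
        for p in range(self.n_patches):
            P = self.nodes[self.patches[p]]
            for i in range(4):
                for j in range(4):
                    Su = np.einsum(
                        "i,j,ijc->c", lagrange_basis(st[i : i + 1], 1)[0],
                        lagrange_basis(st[j : j + 1])[0], P,
                    )
                    Sv = np.einsum(
                        "i,j,ijc->c", lagrange_basis(st[i : i + 1])[0],
                        lagrange_basis(st[j : j + 1], 1)[0], P,
                    )
                    n = np.cross(Su, Sv)
                    nn = np.linalg.norm(n)
                    if nn > 1e-12:
                        acc[self.patches[p][i, j]] += n / nn
        norms = np.linalg.norm(acc, axis=1, keepdims=True)
        norms[norms < 1e-12] = 1.0
        return acc / norms

    # -- export -------------------------------------------------------------
    def triangulate(self, m: int = 8):
        """Dense triangulation (vertices, faces, patch_ids-per-face) for export."""
        verts = []
        faces = []
        fpid = []
        off = 0
        g = np.linspace(0, 1, m + 1)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        for p in range(self.n_patches):
            pts = self.evaluate_many(
                np.full((m + 1) ** 2, p), uu.ravel(), vv.ravel()
            )
            verts.append(pts)
            for i in range(m):
                for j in range(m):
                    a = off + i * (m + 1) + j
                    b = a + (m + 1)
                    faces.append([a, b, a + 1])
                    faces.append([a + 1, b, b + 1])
                    fpid.extend([p, p])
            off += (m + 1) ** 2
        return np.vstack(verts), np.array(faces), np.array(fpid)

    def to_trimesh(self, m: int = 8):
        import trimesh

        v, f, _ = self.triangulate(m)
        return trimesh.Trimesh(vertices=v, faces=f, process=False)

    def export_ply(self, path, m: int = 8) -> None:
        self.to_trimesh(m).export(str(path))

    def export_vtk(self, path) -> None:
        """Legacy-ASCII VTK with the raw quad-patch control net as quads."""
        lines = ["# vtk DataFile Version 3.0", "mc3ssm patch mesh", "ASCII",
                 "DATASET POLYDATA", f"POINTS {self.n_nodes} float"]
        for x, y, z in self.nodes:
            lines.append(f"{x:.6f} {y:.6f} {z:.6f}")
        quads = []
        for grid in self.patches:
            for i in range(3):
                for j in range(3):
                    quads.append([grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1]])
        lines.append(f"POLYGONS {len(quads)} {5 * len(quads)}")
        for q in quads:
            lines.append("4 " + " ".join(str(i) for i in q))
        if self.node_density is not None:
            lines += [f"POINT_DATA {self.n_nodes}", "SCALARS density float 1",
                      "LOOKUP_TABLE default"]
            lines += [f"{v:.6f}" for v in self.node_density]
        Path(path).write_text("\n".join(lines) + "\n")


TemplateMesh = PatchMesh  # the template is a PatchMesh with landmarks/regions set


def save_mesh(mesh: PatchMesh, path) -> None:
    """Native archive (JSON metadata + npz arrays) preserving patch structure."""
    path = Path(path)
    arrays = {"nodes": mesh.nodes, "patches": mesh.patches}
    if mesh.node_density is not None:
        arrays["node_density"] = mesh.node_density
    if mesh.node_flags is not None:
        arrays["node_flags"] = mesh.node_flags
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "format": "mc3ssm-mesh",
        "version": 1,
        "landmarks": mesh.landmarks,
        "proximal_cutoff": mesh.proximal_cutoff,
        "regions": {
            k: (v if not isinstance(v, dict) else v)
            for k, v in mesh.regions.items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_mesh(path) -> PatchMesh:
    path = Path(path)
    arr = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    regions = meta.get("regions", {})
    if "width_pairs" in regions:
        regions["width_pairs"] = {k: tuple(v) for k, v in regions["width_pairs"].items()}
    return PatchMesh(
        arr["nodes"], arr["patches"],
        landmarks=meta.get("landmarks"),
        regions=regions,
        proximal_cutoff=meta.get("proximal_cutoff"),
        node_density=arr["node_density"] if "node_density" in arr else None,
        node_flags=arr["node_flags"] if "node_flags" in arr else None,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a surface fit: node coordinates, RMS (mm), iteration count."""

    fitted_nodes: np.ndarray
    rms: float
    iterations: int
    converged: bool
    mesh: PatchMesh = field(repr=False, default=None)


def _principal_axes(x: np.ndarray, weights: np.ndarray | None = None):
    """(centroid, axes, rms radius); weighted when ``weights`` given."""
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu = w @ x
    c = x - mu
    cov = (c * w[:, None]).T @ c
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    axes = vecs[:, order]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    rms = np.sqrt(np.sum(w * np.sum(c * c, axis=1)))
    return mu, axes, rms


def _area_samples(mesh: "PatchMesh", m: int = 8):
    """Triangle centroids and areas of a dense triangulation (area weights)."""
    v, f, _ = mesh.triangulate(m)
    tri = v[f]
    centroids = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return centroids, areas


def prealign(template: PatchMesh, cloud: np.ndarray) -> np.ndarray:
    """Rigid + isotropic-scale initialization of the template onto a cloud.

    Centroid translation, principal-axes rotation (best of the four proper
    sign combinations, scored by mean cloud-to-sample distance) and RMS-radius
    scale matching.  The template's centroid/axes/radius are computed
    area-weighted over its surface so they are commensurate with an
    area-uniform segmented cloud.
    """
    cloud = np.asarray(cloud, float)
    tn = template.nodes
    samples, areas = _area_samples(template)
    ct, Vt, rt = _principal_axes(samples, areas)
    cc, Vc, rc = _principal_axes(cloud)
    s = rc / rt
    sub = cloud[:: max(1, len(cloud) // 400)]
    best_score, best = np.inf, None
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = (Vc * np.array(signs)) @ Vt.T
        moved = (samples - ct) @ (s * R).T + cc
        d, _ = cKDTree(moved).query(sub)
        score = float(np.mean(d))
        if score < best_score:
            best_score = score
            best = (s * R, cc - (s * R) @ ct)
    M, t = best

    # similarity-ICP polish: moment axes leave a few degrees of rotation
    # error that the deformable stages recover only very slowly
    sub_s = samples[:: max(1, len(samples) // 800)]
    w_s = areas[:: max(1, len(samples) // 800)]
    tree = cKDTree(cloud)
    for _ in range(12):
        moved = sub_s @ M.T + t
        _, idx = tree.query(moved)
        target = cloud[idx]
        mu_a = np.average(moved, axis=0, weights=w_s)
        mu_b = np.average(target, axis=0, weights=w_s)
        H = ((moved - mu_a) * w_s[:, None]).T @ (target - mu_b)
        U, S, Vt2 = np.linalg.svd(H)
        dsgn = np.sign(np.linalg.det(Vt2.T @ U.T))
        dR = Vt2.T @ np.diag([1.0, 1.0, dsgn]) @ U.T
        var = np.sum(w_s * np.sum((moved - mu_a) ** 2, axis=1))
        ds = np.sum(S * np.array([1.0, 1.0, dsgn])) / var
        dt = mu_b - ds * dR @ mu_a
        M = ds * dR @ M
        t = ds * dR @ t + dt
    # affine-ICP phase: the host lattice spans affine maps, but closest-point
    # correspondence recovers them only at a crawl; estimate them directly
    for _ in range(8):
        moved = sub_s @ M.T + t
        _, idx = tree.query(moved)
        X = np.concatenate([sub_s, np.ones((len(sub_s), 1))], axis=1)
        Xw = X * w_s[:, None]
        beta = np.linalg.solve(Xw.T @ X, Xw.T @ cloud[idx])
        M = beta[:3].T
        t = beta[3]
    return tn @ M.T + t


def _bernstein3(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)[:, None]
    c = np.array([1.0, 3.0, 3.0, 1.0])
    i = np.arange(4)
    return c * t**i * (1 - t) ** (3 - i)


def _lattice_embedding(nodes: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """(n_nodes x 64) tricubic Bernstein basis of nodes in lattice [lo, hi]."""
    t = (nodes - lo) / (hi - lo)
    bx, by, bz = _bernstein3(t[:, 0]), _bernstein3(t[:, 1]), _bernstein3(t[:, 2])
    return np.einsum("ni,nj,nk->nijk", bx, by, bz).reshape(len(nodes), 64)


def _lattice_controls(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    g = [np.linspace(lo[d], hi[d], 4) for d in range(3)]
    X, Y, Z = np.meshgrid(*g, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)  # (64, 3)


def _lattice_regularizer() -> np.ndarray:
    """Second-difference rows over the 4x4x4 lattice (per axis, per line)."""
    rows = []
    idx = np.arange(64).reshape(4, 4, 4)
    for axis in range(3):
        moved = np.moveaxis(idx, axis, 0)
        for i in range(1, 3):
            for j in range(4):
                for k in range(4):
                    r = np.zeros(64)
                    r[moved[i - 1, j, k]] = 1.0
                    r[moved[i, j, k]] = -2.0
                    r[moved[i + 1, j, k]] = 1.0
                    rows.append(r)
    return np.array(rows)


def host_mesh_fit(
    template: PatchMesh,
    cloud: np.ndarray,
    lattice_shape: tuple[int, int, int] = (4, 4, 4),
    regularization_weight: float = 1e-5,
    max_iters: int = 40,
    tol: float = 1e-4,
    do_prealign: bool = True,
) -> FitResult:
    """Coarse host-mesh (free-form deformation) registration to a point cloud.

    The template is embedded in a tricubic Bernstein lattice spanning its
    bounding box; ICP-style rounds alternate point-to-surface correspondence
    with a linear least-squares solve for the 64 lattice control points,
    penalizing lattice second differences (weight ``regularization_weight``).
    """
    cloud = np.asarray(cloud, float)
    if cloud.ndim != 2 or len(cloud) == 0:
        raise ValueError("cloud must be a non-empty (n, 3) array")
    if tuple(lattice_shape) != (4, 4, 4):
        raise NotImplementedError("only a 4x4x4 tricubic lattice is supported")

    nodes0 = prealign(template, cloud) if do_prealign else template.nodes.copy()
    span = nodes0.max(axis=0) - nodes0.min(axis=0)
    lo = nodes0.min(axis=0) - 0.05 * span - 2.0
    hi = nodes0.max(axis=0) + 0.05 * span + 2.0
    Blat = _lattice_embedding(nodes0, lo, hi)
    C0 = _lattice_controls(lo, hi)
    # identity check: Bernstein lattice reproduces the embedded nodes
    # (linear precision); deviation is pure floating-point noise.
    R = _lattice_regularizer()
    RtR = R.T @ R / len(R)

    mesh = template.with_nodes(nodes0)
    D = np.zeros((64, 3))
    best_rms, best_nodes, it = np.inf, nodes0, 0
    converged = False
    prev = np.inf
    for it in range(1, max_iters + 1):
        pids, us, vs, dists, _ = mesh.project_points(cloud, k=4, iters=6)
        rms = float(np.sqrt(np.mean(dists**2)))
        if rms < best_rms:
            best_rms, best_nodes = rms, mesh.nodes
        if prev - rms < tol:
            converged = True
            break
        prev = rms
        A = mesh.basis_rows(pids, us, vs)  # careful: rows act on *current* nodes
        G = A @ Blat  # (n_pts, 64); current nodes = Blat @ (C0 + D)
        n = len(cloud)
        H = G.T @ G / n + regularization_weight * RtR + 1e-9 * np.eye(64)
        rhs = G.T @ (cloud - G @ C0) / n
        D = np.linalg.solve(H, rhs)
        mesh = template.with_nodes(Blat @ (C0 + D))
    final = template.with_nodes(best_nodes)
    return FitResult(best_nodes, best_rms, it, converged, final)


def _second_derivative_operator(mesh: PatchMesh, gauss_n: int = 3) -> sparse.csr_matrix:
    """Sobolev penalty rows: patch second parametric derivatives at Gauss points."""
    x, w = _gauss01(gauss_n)
    uu, vv = np.meshgrid(x, x, indexing="ij")
    ww = np.sqrt(np.outer(w, w).ravel())
    blocks = []
    for p in range(mesh.n_patches):
        cols = mesh.patches[p].reshape(16)
        for du, dv, scale in ((2, 0, 1.0), (0, 2, 1.0), (1, 1, np.sqrt(2.0))):
            Bu = lagrange_basis(uu.ravel(), du)
            Bv = lagrange_basis(vv.ravel(), dv)
            Wm = scale * ww[:, None] * np.einsum("mi,mj->mij", Bu, Bv).reshape(-1, 16)
            r = np.repeat(np.arange(len(Wm)), 16)
            c = np.tile(cols, len(Wm))
            blocks.append(sparse.csr_matrix((Wm.ravel(), (r, c)),
                                            shape=(len(Wm), mesh.n_nodes)))
    return sparse.vstack(blocks).tocsr()


def fine_fit(
    initial: FitResult | PatchMesh,
    cloud: np.ndarray,
    smoothing_weight: float = 1e-3,
    max_iters: int = 30,
    tol: float = 1e-4,
    anchor_weight: float = 1e-3,
) -> FitResult:
    """Per-node surface refinement against a point cloud.

    Minimizes mean squared point-to-surface distance plus
    ``smoothing_weight`` times a Sobolev-type penalty on the second parametric
    derivatives of the displacement from the initial nodes (plus a small
    ``anchor_weight`` L2 pull toward the initial nodes, so that an infinite
    smoothing weight reproduces the initial fit).  The reported RMS never
    exceeds the initial RMS (best iterate is kept).
    """
    cloud = np.asarray(cloud, float)
    if isinstance(initial, FitResult):
        mesh0 = initial.mesh if initial.mesh is not None else None
        nodes0 = initial.fitted_nodes
    else:
        mesh0 = initial
        nodes0 = initial.nodes
    if mesh0 is None:
        raise ValueError("initial FitResult must carry its mesh")
    template = mesh0
    mesh = template.with_nodes(nodes0)

    S2 = _second_derivative_operator(template)
    S2tS2 = (S2.T @ S2).toarray() / S2.shape[0]
    n_nodes = template.n_nodes
    P_smooth = S2tS2 + anchor_weight * np.eye(n_nodes)

    best_rms, best_nodes, it = np.inf, nodes0, 0
    converged = False
    prev = np.inf
    for it in range(1, max_iters + 1):
        pids, us, vs, dists, _ = mesh.project_points(cloud, k=4, iters=6)
        rms = float(np.sqrt(np.mean(dists**2)))
        if rms < best_rms:
            best_rms, best_nodes = rms, mesh.nodes
        if prev - rms < tol:
            converged = True
            break
        prev = rms
        A = mesh.basis_rows(pids, us, vs)
        n = len(cloud)
        AtA = (A.T @ A).toarray() / n
        H = AtA + smoothing_weight * P_smooth
        rhs = (A.T @ cloud) / n + smoothing_weight * (P_smooth @ nodes0)
        new_nodes = np.linalg.solve(H, rhs)
        mesh = template.with_nodes(new_nodes)
    final = template.with_nodes(best_nodes)
    return FitResult(best_nodes, best_rms, it, converged, final)
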