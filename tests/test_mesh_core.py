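"""Patch-surface evaluation, projection and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mc3ssm import mesh_core as mc
from mc3ssm import synthetic_data as sd


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(0.0, 1.0))
def test_lagrange_basis_partition_of_unity_and_interpolation(u):
    B = mc.lagrange_basis(np.array([u]))
    assert np.isclose(B.sum(), 1.0, atol=1e-12)
    # interpolation property at the four stations
    S = mc.lagrange_basis(np.array([0.0, 1 / 3, 2 / 3, 1.0]))
    assert np.allclose(S, np.eye(4), atol=1e-12)


class TestEvaluate:
    def test_corner_returns_corner_node(self, base_mesh):
        for pid in (0, 10, 35):
            grid = base_mesh.patches[pid]
            assert np.allclose(base_mesh.evaluate(pid, 0.0, 0.0),
                               base_mesh.nodes[grid[0, 0]], atol=1e-12)
            assert np.allclose(base_mesh.evaluate(pid, 1.0, 1.0),
                               base_mesh.nodes[grid[3, 3]], atol=1e-12)

    def test_planar_patch_linear_precision(self):
        # nodes on the plane z = 2x + 3y + 1 -> every evaluated point on it
        g = np.linspace(0, 1, 4)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        nodes = np.stack([uu.ravel(), vv.ravel(),
                          2 * uu.ravel() + 3 * vv.ravel() + 1], axis=1)
        mesh = mc.PatchMesh(nodes, np.arange(16).reshape(1, 4, 4))
        pts = mesh.evaluate(0, np.linspace(0, 1, 7), np.linspace(0.1, 0.9, 7))
        assert np.allclose(pts[:, 2], 2 * pts[:, 0] + 3 * pts[:, 1] + 1, atol=1e-10)

    def test_midpoint_matches_direct_basis_product_oracle(self, base_mesh):
        # independent oracle: explicit Lagrange polynomial product sum
        def L(i, u):
            xs = [0, 1 / 3, 2 / 3, 1]
            out = 1.0
            for j, xj in enumerate(xs):
                if j != i:
                    out *= (u - xj) / (xs[i] - xj)
            return out

        pid = 7
        P = base_mesh.nodes[base_mesh.patches[pid]]
        expected = sum(L(i, 0.5) * L(j, 0.5) * P[i, j]
                       for i in range(4) for j in range(4))
        assert np.allclose(base_mesh.evaluate(pid, 0.5, 0.5), expected, atol=1e-12)

    def test_invalid_patch_id_raises(self, base_mesh):
        with pytest.raises(IndexError):
            base_mesh.evaluate(999, 0.5, 0.5)

    def test_c0_across_shared_edges(self, base_mesh):
        # adjacent side patches share their u-boundary curve
        t = np.linspace(0, 1, 9)
        a = base_mesh.evaluate(4, np.ones_like(t), t)   # cap->side orientation differs
        # check two side patches known to be azimuthal neighbours (patch 4+q,4+q+1)
        p1, p2 = 4, 5
        e1 = base_mesh.evaluate(p1, np.ones_like(t), t)
        e2 = base_mesh.evaluate(p2, np.zeros_like(t), t)
        assert np.allclose(e1, e2, atol=1e-12)


class TestClosestPoint:
    def test_on_surface_distance_zero(self, base_mesh):
        q = base_mesh.evaluate(9, 0.37, 0.61)
        _, _, _, d = base_mesh.closest_point(q)
        assert d < 1e-6

    def test_offset_along_flat_patch_normal(self):
        g = np.linspace(0, 10, 4)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        nodes = np.stack([uu.ravel(), vv.ravel(), np.zeros(16)], axis=1)
        mesh = mc.PatchMesh(nodes, np.arange(16).reshape(1, 4, 4))
        _, _, _, d = mesh.closest_point(np.array([5.0, 5.0, 2.5]))
        assert np.isclose(d, 2.5, atol=1e-9)

    def test_agrees_with_dense_grid_oracle(self, base_mesh):
        rng = np.random.default_rng(3)
        queries = rng.uniform([-35, -30, -5], [35, 35, 50], size=(12, 3))
        g = np.linspace(0, 1, 220)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        grids = [
            base_mesh.evaluate_many(np.full(uu.size, p), uu.ravel(), vv.ravel())
            for p in range(base_mesh.n_patches)
        ]
        for q in queries:
            _, _, _, d = base_mesh.closest_point(q)
            brute = min(np.min(np.linalg.norm(gp - q, axis=1)) for gp in grids)
            # the dense grid itself discretizes at ~0.1 mm -> compare loosely
            # downward, tightly upward
            assert d <= brute + 1e-9
            assert brute - d < 1e-3


class TestIntersectRays:
    def test_ray_along_normal_hits_surface_point(self, base_mesh):
        pid, u, v = 20, 0.4, 0.6
        target = base_mesh.evaluate(pid, u, v)
        Su = base_mesh.evaluate(pid, u, v, du=1)
        Sv = base_mesh.evaluate(pid, u, v, dv=1)
        n = np.cross(Su, Sv)
        n /= np.linalg.norm(n)
        origin = target + 1.5 * n
        pts, t, ok = base_mesh.intersect_rays(origin[None, :], -n[None, :])
        assert ok[0]
        assert np.linalg.norm(pts[0] - target) < 1e-6
        assert np.isclose(t[0], 1.5, atol=1e-6)


class TestHostMeshFit:
    def test_self_cloud_identity(self, base_mesh):
        rng = np.random.default_rng(0)
        pids = rng.integers(0, base_mesh.n_patches, 1500)
        us, vs = rng.uniform(0, 1, (2, 1500))
        cloud = base_mesh.evaluate_many(pids, us, vs)
        fit = mc.host_mesh_fit(base_mesh, cloud, do_prealign=False)
        assert fit.rms < 1e-3

    def test_affine_cloud_within_lattice_span(self, base_mesh):
        # an affine map lies exactly in the tricubic lattice's span: the fit
        # recovers it to well below the deformation magnitude (~0.3 mm here)
        rng = np.random.default_rng(1)
        pids = rng.integers(0, base_mesh.n_patches, 3000)
        us, vs = rng.uniform(0, 1, (2, 3000))
        pts = base_mesh.evaluate_many(pids, us, vs)
        A = np.eye(3) + 0.005 * rng.standard_normal((3, 3))
        cloud = pts @ A.T
        fit = mc.host_mesh_fit(base_mesh, cloud, do_prealign=False,
                               max_iters=60, tol=1e-7)
        assert fit.rms < 1e-2

    def test_empty_cloud_raises(self, base_mesh):
        with pytest.raises(ValueError):
            mc.host_mesh_fit(base_mesh, np.empty((0, 3)))


class TestFineFit:
    def test_fixed_point_on_perfect_fit(self, base_mesh):
        rng = np.random.default_rng(2)
        pids = rng.integers(0, base_mesh.n_patches, 2000)
        us, vs = rng.uniform(0, 1, (2, 2000))
        cloud = base_mesh.evaluate_many(pids, us, vs)
        fit = mc.fine_fit(base_mesh, cloud)
        assert fit.rms < 1e-3
        assert np.abs(fit.fitted_nodes - base_mesh.nodes).max() < 0.05

    def test_infinite_smoothing_returns_initial(self, base_mesh, small_population):
        _, base, _, pop, clouds = small_population
        init = base.with_nodes(mc.prealign(base, clouds[0]))
        fit = mc.fine_fit(init, clouds[0], smoothing_weight=1e9, max_iters=5)
        assert np.abs(fit.fitted_nodes - init.nodes).max() < 1e-3

    def test_never_increases_rms(self, base_mesh, small_population):
        _, base, _, pop, clouds = small_population
        coarse = mc.host_mesh_fit(base, clouds[0])
        refined = mc.fine_fit(coarse, clouds[0])
        assert refined.rms <= coarse.rms + 1e-12


def test_rigid_motion_equivariance(small_population):
    """Fitting a rigidly moved cloud gives the same RMS."""
    _, base, _, pop, clouds = small_population
    cloud = clouds[0]
    rng = np.random.default_rng(9)
    axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
    ang = 0.4
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
    moved = cloud @ R.T + np.array([8.0, -5.0, 3.0])
    f1 = mc.fine_fit(mc.host_mesh_fit(base, cloud), cloud)
    f2 = mc.fine_fit(mc.host_mesh_fit(base, moved), moved)
    # ICP correspondences switch discretely under coordinate round-off, so
    # equivariance holds to sub-micrometre RMS, not machine precision
    assert abs(f1.rms - f2.rms) < 1e-3


def test_mesh_archive_round_trip(base_mesh, tmp_path):
    mc.save_mesh(base_mesh, tmp_path / "m")
    loaded = mc.load_mesh(tmp_path / "m")
    assert np.array_equal(loaded.nodes, base_mesh.nodes)
    assert np.array_equal(loaded.patches, base_mesh.patches)
    assert loaded.landmarks == base_mesh.landmarks
    assert loaded.proximal_cutoff == base_mesh.proximal_cutoff


def test_exports_are_readable(base_mesh, tmp_path):
    base_mesh.export_ply(tmp_path / "m.ply")
    base_mesh.export_vtk(tmp_path / "m.vtk")
    import trimesh

    tm = trimesh.load(str(tmp_path / "m.ply"))
    assert len(tm.vertices) > 0
    text = (tmp_path / "m.vtk").read_text()
    assert text.startswith("# vtk DataFile")
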