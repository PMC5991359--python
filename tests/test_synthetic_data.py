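"""Synthetic-population generator: geometry, latent modes, exports, volumes."""

import math

import numpy as np
import pytest

from mc3ssm import synthetic_data as sd
from mc3ssm import morphometry as mm
from mc3ssm import density_mapping as dm


def _sym_params(**kw):
    return sd.BaseShapeParams(condyle_radius_medial=4.0, condyle_radius_lateral=4.0,
                              dorsal_palmar_bias=0.0, **kw)


class TestBaseShape:
    def test_bilateral_symmetry_with_equal_condyles(self):
        res = mm.measure(sd.make_base_shape(_sym_params()))
        assert np.isclose(res.medial_condylar_width, res.lateral_condylar_width,
                          rtol=1e-10)
        assert np.isclose(res.medial_condylar_area, res.lateral_condylar_area,
                          rtol=1e-10)

    def test_scale_equivariance(self):
        p1 = sd.BaseShapeParams()
        scaled = {f: getattr(p1, f) * 2 for f in (
            "shaft_radius", "condyle_radius_medial", "condyle_radius_lateral",
            "groove_depth", "ridge_height", "epiphysis_length",
            "proximal_cutoff", "dorsal_shift")}
        p2 = sd.BaseShapeParams(**scaled)
        r1 = mm.measure(sd.make_base_shape(p1))
        r2 = mm.measure(sd.make_base_shape(p2))
        for name in ("medio_lateral_width", "lateral_condylar_width",
                     "medial_condylar_width", "sagittal_ridge_width",
                     "metaphysis_circumference"):
            assert np.isclose(getattr(r2, name), 2 * getattr(r1, name), rtol=1e-9)
        assert np.isclose(r2.total_area, 4 * r1.total_area, rtol=1e-6)

    def test_medio_lateral_width_matches_cross_section_oracle(self):
        """Closed-form oracle: the landmark nodes sit at theta = 0 and pi on
        the ring at z = epiphysis_length, so the width is the sum of the two
        analytic cross-section radii there (computed here from scratch)."""
        p = sd.BaseShapeParams()
        mesh = sd.make_base_shape(p)

        def radius(theta):
            A, B = p.ml_aspect * p.shaft_radius, p.shaft_radius
            m = p.superellipse_power
            xh, yh = math.cos(theta), math.sin(theta)
            r_se = (abs(xh / A) ** m + abs(yh / B) ** m) ** (-1 / m)
            bump = (p.condyle_radius_medial * math.exp(-(((xh - 0.55) / 0.25) ** 2))
                    + p.condyle_radius_lateral * math.exp(-(((xh + 0.55) / 0.25) ** 2))
                    - p.groove_depth * (math.exp(-(((xh - 0.28) / 0.12) ** 2))
                                        + math.exp(-(((xh + 0.28) / 0.12) ** 2)))
                    + p.ridge_height * math.exp(-((xh / 0.26) ** 2)) * yh * yh)
            bump *= 1.0 + p.dorsal_palmar_bias * yh
            z = p.epiphysis_length
            return r_se + bump * math.exp(-((z / (1.5 * p.epiphysis_length)) ** 2))

        expected = radius(0.0) + radius(math.pi)
        got = np.linalg.norm(mesh.nodes[mesh.landmarks["medial_edge"]]
                             - mesh.nodes[mesh.landmarks["lateral_edge"]])
        assert np.isclose(got, expected, atol=1e-9)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            sd.make_base_shape(sd.BaseShapeParams(shaft_radius=-1.0))


class TestSamplePopulation:
    def test_determinism(self):
        spec = sd.SyntheticSpec(n_specimens=4, seed=123)
        a = sd.sample_population(spec)
        b = sd.sample_population(spec)
        for x, y in zip(a, b):
            assert np.array_equal(x.node_coords, y.node_coords)
            assert np.array_equal(x.node_density, y.node_density)

    def test_no_modes_no_noise_gives_base_up_to_pose(self):
        spec = sd.SyntheticSpec(n_specimens=3, modes=[], node_noise_sd=0.0,
                                density_noise_sd=0.0)
        base, _, pop = sd.sample_population(spec, return_base=True)
        for p in pop:
            assert np.allclose(p.local_coords, base.nodes, atol=1e-9)

    def test_fewer_than_two_specimens_rejected(self):
        with pytest.raises(ValueError):
            sd.sample_population(sd.SyntheticSpec(n_specimens=1))

    def test_variance_fractions_partition_total_variance(self):
        """With zero noise the per-mode share of total coordinate variance
        matches the spec'd fractions (Monte-Carlo, n = 300)."""
        spec = sd.SyntheticSpec(n_specimens=300, node_noise_sd=0.0,
                                density_noise_sd=0.0, pose_rotation_deg=0.0,
                                pose_translation_mm=0.0, seed=31)
        base, modes, pop = sd.sample_population(spec, return_base=True)
        disp = np.array([(p.node_coords - base.nodes).ravel() for p in pop])
        total = np.sum(disp * disp) / len(pop)
        for mode, f in zip(modes, (0.50, 0.30, 0.15)):
            field = mode.shape_displacement.ravel()
            scores = disp @ field / (field @ field)
            contrib = np.var(scores) * (field @ field) / total
            assert abs(contrib - f / 0.95) < 0.05

    def test_densities_clamped_nonnegative(self):
        spec = sd.SyntheticSpec(n_specimens=6, density_base=0.01, seed=2)
        for p in sd.sample_population(spec):
            assert (p.node_density >= 0).all()


class TestPointClouds:
    def test_noiseless_points_lie_on_surface(self, small_population):
        _, base, _, pop, _ = small_population
        pts = sd.export_point_cloud(base, pop[0], density=0.3,
                                    point_noise_sd=0.0, rng=5)
        mesh = sd.specimen_mesh(base, pop[0])
        _, _, _, d, _ = mesh.project_points(pts[:400])
        assert np.max(d) < 0.03  # dense-triangulation chord tolerance

    def test_rms_distance_matches_jitter_sd(self, small_population):
        _, base, _, pop, _ = small_population
        sigma = 0.25
        pts = sd.export_point_cloud(base, pop[0], density=0.5,
                                    point_noise_sd=sigma, rng=6)
        mesh = sd.specimen_mesh(base, pop[0])
        _, _, _, d, _ = mesh.project_points(pts)
        # distance to surface ~ |normal component| of isotropic jitter
        assert np.mean(d) < sigma  # mean of half-normal < sigma
        assert abs(np.sqrt(np.mean(d**2)) - sigma) < 0.2 * sigma

    def test_density_doubles_point_count(self, small_population):
        _, base, _, pop, _ = small_population
        n1 = len(sd.export_point_cloud(base, pop[0], 0.4, 0.1, rng=7))
        n2 = len(sd.export_point_cloud(base, pop[0], 0.8, 0.1, rng=7))
        assert abs(n2 - 2 * n1) < 0.1 * 2 * n1

    def test_ply_csv_round_trip(self, small_population, tmp_path):
        _, base, _, pop, _ = small_population
        pts = sd.export_point_cloud(base, pop[0], 0.2, 0.1, rng=8)
        sd.write_point_cloud_ply(pts, tmp_path / "c.ply")
        sd.write_point_cloud_csv(pts, tmp_path / "c.csv")
        assert np.allclose(sd.read_point_cloud(tmp_path / "c.ply"), pts, atol=1e-5)
        assert np.allclose(sd.read_point_cloud(tmp_path / "c.csv"), pts, atol=1e-5)


class TestVoxelize:
    @pytest.fixture(scope="class")
    def noiseless(self):
        spec = sd.SyntheticSpec(n_specimens=2, hu_noise_sd=0.0,
                                density_noise_sd=0.0, node_noise_sd=0.0,
                                point_noise_sd=0.0)
        base, modes, pop = sd.sample_population(spec, return_base=True)
        vol = sd.voxelize(base, pop[0], spec)
        return spec, base, pop, vol

    def test_phantom_and_background_values(self, noiseless):
        spec, base, pop, vol = noiseless
        pm = dm.region_mask(vol, vol.phantom_region)
        wm = dm.region_mask(vol, vol.water_region)
        assert np.all(vol.data[pm] == spec.phantom_hu)
        assert np.all(vol.data[wm] == spec.water_hu)

    def test_uniform_density_recovered_everywhere(self, noiseless):
        spec, base, pop, _ = noiseless
        p = pop[1]
        p.node_density[:] = 0.65
        vol = sd.voxelize(base, p, spec)
        f = dm.build_density_field(sd.specimen_mesh(base, p), vol,
                                   dm.estimate_calibration(vol))
        assert np.abs(f.rho_ha[f.ok] - 0.65).max() < 0.05 * 0.65

    def test_too_small_fov_rejected(self, noiseless):
        spec, base, pop, _ = noiseless
        with pytest.raises(ValueError):
            sd.voxelize(base, pop[0], spec,
                        fov=(np.array([0.0, 0, 0]), np.array([10.0, 10, 10])))

    def test_nifti_and_raw_round_trip(self, noiseless, tmp_path):
        _, _, _, vol = noiseless
        sub = dm.ImageVolume(vol.data[:20, :20, :10], vol.spacing, vol.origin,
                             vol.phantom_region, vol.water_region)
        sub.save_nifti(tmp_path / "v.nii.gz")
        back = dm.ImageVolume.load_nifti(tmp_path / "v.nii.gz")
        assert np.allclose(back.data, sub.data)
        assert np.allclose(back.spacing, sub.spacing)
        sub.save_raw(tmp_path / "v")
        raw = dm.ImageVolume.load_raw(tmp_path / "v")
        assert np.allclose(raw.data, sub.data)


def test_ground_truth_sidecar_round_trip(small_population, tmp_path):
    _, _, _, pop, _ = small_population
    sd.save_ground_truth(pop[0], tmp_path / "gt")
    back = sd.load_ground_truth(tmp_path / "gt")
    assert np.array_equal(back.node_coords, pop[0].node_coords)
    assert np.array_equal(back.mode_scores, pop[0].mode_scores)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        sd.SyntheticSpec(variance_fractions=(0.6, 0.5)).validate()
    with pytest.raises(ValueError):
        sd.SyntheticSpec(voxel_spacing=(0.3, -0.3, 0.6)).validate()
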