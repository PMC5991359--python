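"""Shape / density / combined point-distribution models."""

import numpy as np
import pytest

from mc3ssm import statistical_model as sm
from mc3ssm import synthetic_data as sd


@pytest.fixture(scope="module")
def random_model():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 30))
    return X, sm.train(X, "shape", variance_target=1.0)


class TestTrain:
    def test_two_specimens_give_one_mode(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 12))
        model = sm.train(X, "shape")
        assert model.n_modes == 1
        assert np.isclose(model.variance_fractions[0], 1.0)

    def test_variance_fractions_match_eigendecomposition_oracle(self, random_model):
        X, model = random_model
        cov = np.cov(X, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1][: model.n_modes]
        assert np.allclose(model.variance_fractions,
                           evals / evals.sum(), atol=1e-8)

    def test_components_orthonormal(self, random_model):
        _, model = random_model
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(model.n_modes), atol=1e-8)

    def test_fractions_sum_to_one_nonincreasing(self, random_model):
        _, model = random_model
        assert np.isclose(model.variance_fractions.sum(), 1.0, atol=1e-9)
        assert np.all(np.diff(model.variance_fractions) <= 1e-12)

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError):
            sm.train(np.zeros((1, 6)))

    def test_nan_error_names_location(self):
        X = np.zeros((3, 12))
        X[2, 7] = np.nan
        with pytest.raises(ValueError, match="specimen 2"):
            sm.train(X, "combined")

    def test_generative_mode_recovery(self):
        """n = 200 direct generator output: fractions and subspace."""
        spec = sd.SyntheticSpec(n_specimens=200, pose_rotation_deg=0.0,
                                pose_translation_mm=0.0, seed=5)
        base, modes, pop = sd.sample_population(spec, return_base=True)
        X = sm.stack_shape(np.array([p.node_coords for p in pop]))
        model = sm.train(X, "shape")
        assert np.abs(model.variance_fractions[:3]
                      - np.array([0.50, 0.30, 0.15])).max() < 0.05
        D = np.array([m.shape_displacement.ravel() for m in modes])
        Qd, _ = np.linalg.qr(D.T)
        Qc, _ = np.linalg.qr(model.components[:3].T)
        angle = np.degrees(np.arccos(np.clip(
            np.linalg.svd(Qd.T @ Qc, compute_uv=False).min(), 0, 1)))
        assert angle < 10.0


class TestReconstructProject:
    def test_zero_weights_give_mean(self, random_model):
        _, model = random_model
        assert np.allclose(sm.reconstruct(model, []), model.mean_vector)

    def test_full_rank_round_trip(self, random_model):
        X, model = random_model
        w, resid = sm.project(model, X[3], k=model.n_modes)
        assert resid < 1e-8
        back = model.mean_vector + ((w * model.mode_sd[: len(w)])
                                    @ model.components[: len(w)]) * model.scales
        assert np.allclose(back, X[3], atol=1e-8)

    def test_projecting_mean_gives_zero(self, random_model):
        _, model = random_model
        w, _ = sm.project(model, model.mean_vector)
        assert np.allclose(w, 0.0, atol=1e-10)

    def test_single_mode_weight_recovered(self, random_model):
        _, model = random_model
        vec = sm.reconstruct(model, [0.0, 1.5])
        w, _ = sm.project(model, vec, k=4)
        assert np.isclose(w[1], 1.5, atol=1e-8)
        assert np.allclose(np.delete(w, 1), 0.0, atol=1e-8)

    def test_residual_matches_lstsq_oracle(self, random_model):
        X, model = random_model
        rng = np.random.default_rng(8)
        v = rng.normal(size=X.shape[1])
        k = 4
        w, resid = sm.project(model, v, k=k)
        A = model.components[:k].T
        z = (v - model.mean_vector) / model.scales
        coef, res, *_ = np.linalg.lstsq(A, z, rcond=None)
        assert np.isclose(resid**2, res[0] if len(res) else
                          np.sum((z - A @ coef) ** 2), atol=1e-8)

    def test_excess_weights_rejected(self, random_model):
        _, model = random_model
        with pytest.raises(ValueError):
            sm.reconstruct(model, np.ones(model.n_retained + 1))


class TestCombinedFlavor:
    def test_density_unit_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(12, 20, 3))
        dens = 0.7 + 0.1 * rng.normal(size=(12, 20))
        m1 = sm.train(sm.stack_combined(coords, dens), "combined")
        m2 = sm.train(sm.stack_combined(coords, dens * 1000.0), "combined")
        assert np.abs(m1.variance_fractions - m2.variance_fractions).max() < 1e-9

    def test_zero_variance_variable_harmless(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(8, 5, 3))
        dens = np.full((8, 5), 0.7)  # constant density channel
        model = sm.train(sm.stack_combined(coords, dens), "combined")
        assert np.isfinite(model.components).all()

    def test_per_block_standardization_option(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(8, 5, 3))
        dens = 0.7 + 0.1 * rng.normal(size=(8, 5))
        model = sm.train(sm.stack_combined(coords, dens), "combined",
                         standardize="per-block")
        scales = model.scales.reshape(-1, 4)
        assert np.allclose(scales[:, :3], scales[0, 0])
        assert np.allclose(scales[:, 3], scales[0, 3])

    def test_split_inverts_stack(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(1, 6, 3))
        dens = rng.normal(size=(1, 6))
        c, d = sm.split_combined(sm.stack_combined(coords, dens)[0])
        assert np.array_equal(c, coords[0])
        assert np.array_equal(d, dens[0])


class TestSignConvention:
    def test_shape_components_point_outward(self):
        spec = sd.SyntheticSpec(n_specimens=60, pose_rotation_deg=0.0,
                                pose_translation_mm=0.0, seed=3)
        base, modes, pop = sd.sample_population(spec, return_base=True)
        model = sm.train(sm.stack_shape(np.array([p.node_coords for p in pop])),
                         "shape")
        mean_nodes = model.mean_vector.reshape(-1, 3)
        radial = mean_nodes - mean_nodes.mean(axis=0)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        for comp in model.components[:3]:
            assert comp.reshape(-1, 3).ravel() @ radial.ravel() >= 0


class TestSpectrumInvariances:
    def test_rigid_motion_of_aligned_frame(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(15, 30, 3)) + np.array([5.0, 0, 0])
        m1 = sm.train(sm.stack_shape(coords), "shape")
        axis = np.array([1.0, 2.0, -1.0]); axis /= np.linalg.norm(axis)
        a = 0.7
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K
        moved = coords @ R.T + np.array([3.0, -9.0, 1.0])
        m2 = sm.train(sm.stack_shape(moved), "shape")
        assert np.abs(m1.variance_fractions - m2.variance_fractions).max() < 1e-9


class TestLoo:
    def test_identical_population_zero_error(self):
        X = np.tile(np.arange(12.0), (5, 1)).reshape(5, 4, 3)
        curve = sm.loo_analysis(sm.stack_shape(X), "shape", max_components=2)
        assert np.allclose(curve.geometric_rms, 0.0, atol=1e-9)

    def test_curves_nonincreasing_with_slack(self):
        spec = sd.SyntheticSpec(n_specimens=14, pose_rotation_deg=0.0,
                                pose_translation_mm=0.0, seed=17)
        base, _, pop = sd.sample_population(spec, return_base=True)
        X = sm.stack_combined(np.array([p.node_coords for p in pop]),
                              np.array([p.node_density for p in pop]))
        curve = sm.loo_analysis(X, "combined", max_components=8)
        g = curve.geometric_rms
        d = curve.density_rms
        assert np.all(g[1:] <= g[:-1] * 1.05)
        assert np.all(d[1:] <= d[:-1] * 1.05)

    def test_truncation_warns(self):
        X = np.random.default_rng(1).normal(size=(5, 9))
        with pytest.warns(UserWarning):
            sm.loo_analysis(X, "shape", max_components=10)

    def test_too_few_specimens_rejected(self):
        with pytest.raises(ValueError):
            sm.loo_analysis(np.zeros((2, 6)), "shape")


def test_model_archive_round_trip(random_model, tmp_path):
    _, model = random_model
    sm.save_model(model, tmp_path / "m")
    back = sm.load_model(tmp_path / "m")
    assert back.flavor == model.flavor
    assert back.n_retained == model.n_retained
    assert np.allclose(back.components, model.components)
    assert np.allclose(back.mean_vector, model.mean_vector)


def test_variance_table_structure(random_model):
    _, model = random_model
    df = sm.variance_table({"shape": model})
    assert set(df.columns) == {"model", "component", "variance_fraction",
                               "cumulative", "retained"}
    assert np.isclose(df["variance_fraction"].sum(), 1.0)
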