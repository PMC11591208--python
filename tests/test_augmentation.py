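import warnings

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from orthotrack.augmentation import (
    ControlPointSet,
    RegistrationConfig,
    TPSConfig,
    bending_energy,
    build_augmented_dataset,
    combine_interphase_dvfs,
    hybrid_dvf,
    register_phases,
    sample_control_points,
    tps_fit,
    tps_to_dvf,
    warp,
)
from orthotrack.core import DVF3D, Grid3D, Mask3D, Volume3D


@pytest.fixture(scope="module")
def landmark_set():
    rng = np.random.default_rng(1)
    p = rng.uniform(-30, 30, (25, 3))
    q = p + rng.uniform(-10, 10, (25, 3))
    return ControlPointSet(p, q)


def constant_dvf(grid, vec):
    v = np.zeros(grid.shape + (3,), np.float32)
    v[:] = vec
    return DVF3D(grid, v)


class TestTPS:
    def test_zero_data_gives_zero_field(self, landmark_set):
        cps = ControlPointSet(landmark_set.sources, landmark_set.sources)
        model = tps_fit(cps, 0.0)
        grid = Grid3D.centered((6, 6, 6), (10, 10, 10))
        assert np.abs(tps_to_dvf(model, grid).vectors).max() < 1e-9

    def test_interpolation_exact_at_lambda_zero(self, landmark_set):
        model = tps_fit(landmark_set, 0.0)
        residual = model.evaluate(landmark_set.sources) - landmark_set.displacements
        assert np.abs(residual).max() < 1e-6

    def test_side_conditions_on_kernel_weights(self, landmark_set):
        model = tps_fit(landmark_set, 0.0)
        assert np.abs(model.kernel_weights.sum(axis=0)).max() < 1e-8
        moments = landmark_set.sources.T @ model.kernel_weights
        assert np.abs(moments).max() < 1e-6

    def test_pure_translation_absorbed_by_affine_term(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(-20, 20, (12, 3))
        t = np.array([3.0, -2.0, 5.0])
        model = tps_fit(ControlPointSet(p, p + t), 0.0)
        assert np.abs(model.kernel_weights).max() < 1e-9
        grid = Grid3D.centered((5, 5, 5), (8, 8, 8))
        field = tps_to_dvf(model, grid).vectors
        np.testing.assert_allclose(field, np.broadcast_to(t, field.shape), atol=1e-5)

    def test_field_linear_in_displacements(self, landmark_set):
        doubled = ControlPointSet(
            landmark_set.sources,
            landmark_set.sources + 2 * landmark_set.displacements,
        )
        pts = np.random.default_rng(3).uniform(-25, 25, (40, 3))
        single = tps_fit(landmark_set, 0.0).evaluate(pts)
        double = tps_fit(doubled, 0.0).evaluate(pts)
        np.testing.assert_allclose(double, 2 * single, atol=1e-8)

    def test_matches_scipy_smoothing_spline(self, landmark_set):
        """Independent oracle: scipy's linear RBF with degree-1 polynomial."""
        pts = np.random.default_rng(4).uniform(-25, 25, (50, 3))
        for lam in (0.0, 1.0, 25.0):
            ours = tps_fit(landmark_set, lam).evaluate(pts)
            ref = RBFInterpolator(
                landmark_set.sources,
                landmark_set.displacements,
                kernel="linear",
                degree=1,
                smoothing=lam,
            )(pts)
            np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_residual_monotone_and_energy_antitone_in_lambda(self, landmark_set):
        grid = Grid3D.centered((12, 12, 12), (5, 5, 5))
        lams = [0.0, 0.5, 2.0, 10.0, 50.0]
        residuals, energies = [], []
        for lam in lams:
            model = tps_fit(landmark_set, lam)
            r = np.linalg.norm(
                model.evaluate(landmark_set.sources) - landmark_set.displacements
            )
            residuals.append(r)
            energies.append(bending_energy(tps_to_dvf(model, grid)))
        assert all(a <= b + 1e-9 for a, b in zip(residuals, residuals[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_duplicate_points_raise(self):
        p = np.zeros((5, 3))
        with pytest.raises(np.linalg.LinAlgError):
            tps_fit(ControlPointSet(p, p + 1.0), 0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ControlPointSet(np.zeros((3, 3)), np.zeros((3, 3)))


class TestBendingEnergy:
    def test_constant_field_has_no_curvature(self):
        grid = Grid3D((6, 6, 6))
        assert bending_energy(constant_dvf(grid, (3, -1, 2))) == 0.0

    def test_affine_field_in_null_space(self):
        grid = Grid3D((7, 7, 7), (1.5, 1.0, 2.0))
        world = grid.world_grid()
        A = np.array([[1.0, 2, 0], [0, 1, 3], [2, 0, 1]])
        vec = (world @ A + np.array([1.0, 2, 3])).astype(np.float32)
        assert bending_energy(DVF3D(grid, vec)) < 1e-8

    def test_quadratic_field_matches_discrete_oracle(self):
        # phi_x = x^2 has second derivative 2 -> squared 4, summed over the
        # interior and scaled by voxel volume.
        grid = Grid3D((9, 9, 9))
        world = grid.world_grid()
        vec = np.zeros(grid.shape + (3,), np.float32)
        vec[..., 0] = world[..., 0] ** 2
        expected = 4.0 * 7**3  # interior voxels x voxel volume 1
        assert abs(bending_energy(DVF3D(grid, vec)) - expected) / expected < 0.01

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            bending_energy(DVF3D.zeros(Grid3D((2, 5, 5))))


class TestFieldMixing:
    grid = Grid3D.centered((4, 4, 4))

    def test_alpha_endpoint_limit(self):
        phi_i = constant_dvf(self.grid, (2, 0, 0))
        phi_j = constant_dvf(self.grid, (0, 0, 4))
        out = combine_interphase_dvfs(phi_i, phi_j, 1 - 1e-12)
        np.testing.assert_allclose(out.vectors, phi_i.vectors, atol=1e-9)

    def test_mixing_identical_fields_is_identity(self):
        phi = constant_dvf(self.grid, (1, 2, 3))
        out = combine_interphase_dvfs(phi, phi, 0.37)
        np.testing.assert_allclose(out.vectors, phi.vectors, atol=1e-6)

    def test_convex_combination_arithmetic(self):
        out = combine_interphase_dvfs(
            constant_dvf(self.grid, (2, 0, 0)), constant_dvf(self.grid, (0, 0, 4)), 0.5
        )
        np.testing.assert_allclose(out.vectors[0, 0, 0], (1, 0, 2))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_alpha_outside_open_interval_rejected(self, alpha):
        phi = constant_dvf(self.grid, (1, 0, 0))
        with pytest.raises(ValueError):
            combine_interphase_dvfs(phi, phi, alpha)

    def test_hybrid_weighted_sum(self):
        out = hybrid_dvf(
            constant_dvf(self.grid, (2, 0, 0)),
            constant_dvf(self.grid, (0, 2, 0)),
            0.5,
            0.5,
        )
        np.testing.assert_allclose(out.vectors[1, 1, 1], (1, 1, 0))
        zero = hybrid_dvf(
            constant_dvf(self.grid, (2, 0, 0)),
            constant_dvf(self.grid, (0, 2, 0)),
            0.0,
            0.0,
        )
        assert np.abs(zero.vectors).max() == 0.0

    def test_exact_linearity_of_mixing(self, rng):
        v1 = DVF3D(self.grid, rng.normal(size=self.grid.shape + (3,)).astype(np.float32))
        v2 = DVF3D(self.grid, rng.normal(size=self.grid.shape + (3,)).astype(np.float32))
        a, b = 0.3, 1.7
        mixed = hybrid_dvf(v1, v2, a, b)
        expected = a * v1.vectors + b * v2.vectors
        np.testing.assert_allclose(mixed.vectors, expected, atol=1e-6)

    def test_grid_mismatch_rejected(self):
        other = Grid3D.centered((5, 5, 5))
        with pytest.raises(ValueError):
            hybrid_dvf(
                constant_dvf(self.grid, (1, 0, 0)), constant_dvf(other, (1, 0, 0)), 1, 1
            )


class TestControlPointSampling:
    def test_counts_and_displacement_bounds(self):
        grid = Grid3D.centered((20, 20, 20), (2, 2, 2))
        cfg = TPSConfig(seed=5)
        cps = sample_control_points(grid, cfg)
        assert 20 <= len(cps) <= 60
        mags = np.linalg.norm(cps.displacements, axis=1)
        assert mags.max() <= 30.0 + 1e-9

    def test_zero_displacement_degenerate_range(self):
        grid = Grid3D.centered((10, 10, 10))
        cps = sample_control_points(grid, TPSConfig(max_displacement=0.0, seed=1))
        np.testing.assert_allclose(cps.targets, cps.sources)

    def test_deterministic_given_seed(self):
        grid = Grid3D.centered((10, 10, 10))
        a = sample_control_points(grid, TPSConfig(seed=9))
        b = sample_control_points(grid, TPSConfig(seed=9))
        np.testing.assert_array_equal(a.sources, b.sources)
        np.testing.assert_array_equal(a.targets, b.targets)

    def test_mask_region_constrains_sources(self):
        grid = Grid3D.centered((16, 16, 16))
        vals = np.zeros(grid.shape, np.uint8)
        vals[4:8, 4:8, 4:8] = 1
        region = Mask3D(grid, vals)
        cps = sample_control_points(region, TPSConfig(seed=2))
        lo = grid.origin[0] + 4 - 0.5
        hi = grid.origin[0] + 7 + 0.5
        assert cps.sources.min() >= lo - 1e-9
        assert cps.sources.max() <= hi + 1e-9

    def test_empty_region_rejected(self):
        grid = Grid3D((6, 6, 6))
        with pytest.raises(ValueError):
            sample_control_points(Mask3D(grid, np.zeros(grid.shape, np.uint8)), TPSConfig())


class TestWarp:
    def test_zero_field_is_identity(self, random_volume):
        out = warp(random_volume, DVF3D.zeros(random_volume.grid))
        np.testing.assert_allclose(out.values, random_volume.values, atol=1e-6)

    def test_one_voxel_shift(self):
        grid = Grid3D((8, 8, 8), (2.0, 1.0, 1.0))
        vals = np.random.default_rng(0).random(grid.shape).astype(np.float32)
        v = Volume3D(grid, vals)
        shifted = warp(v, constant_dvf(grid, (2.0, 0, 0)))  # +1 voxel along x
        np.testing.assert_allclose(shifted.values[:-1], vals[1:], atol=1e-5)

    def test_warped_mask_stays_binary(self):
        grid = Grid3D.centered((10, 10, 10))
        vals = np.zeros(grid.shape, np.uint8)
        vals[3:7, 3:7, 3:7] = 1
        out = warp(Mask3D(grid, vals), constant_dvf(grid, (0.4, -1.3, 0.7)))
        assert isinstance(out, Mask3D)
        assert set(np.unique(out.values)) <= {0, 1}

    def test_grid_mismatch_rejected(self, random_volume):
        with pytest.raises(ValueError):
            warp(random_volume, DVF3D.zeros(Grid3D((3, 3, 3))))


class TestRegistration:
    def test_self_registration_is_near_zero(self, tiny_phantom):
        dvf = register_phases(tiny_phantom.phases[0], tiny_phantom.phases[0])
        assert np.linalg.norm(dvf.vectors, axis=-1).mean() < 0.1

    def test_recovers_phase_displacement_within_1mm(self, tiny_phantom):
        k = 5
        dvf = register_phases(tiny_phantom.phases[0], tiny_phantom.phases[k])
        tumor = tiny_phantom.masks[k].values > 0
        mean_dvf = dvf.vectors[tumor].mean(axis=0)
        expected = -(
            tiny_phantom.gt_centroids[k].as_array()
            - tiny_phantom.gt_centroids[0].as_array()
        )
        assert np.linalg.norm(mean_dvf - expected) <= 1.0

    def test_registration_reduces_mean_squared_difference(self, tiny_phantom):
        k = 5
        moving, fixed = tiny_phantom.phases[0], tiny_phantom.phases[k]
        dvf = register_phases(moving, fixed)
        pre = float(np.mean((moving.values - fixed.values) ** 2))
        post = float(np.mean((warp(moving, dvf).values - fixed.values) ** 2))
        assert post < pre

    def test_grid_mismatch_rejected(self, tiny_phantom):
        other = Volume3D(Grid3D((8, 8, 8)), np.zeros((8, 8, 8), np.float32))
        with pytest.raises(ValueError):
            register_phases(tiny_phantom.phases[0], other)

    def test_bspline_engine_same_contract(self, micro_phantom):
        cfg = RegistrationConfig(
            engine="bspline", levels=2, iterations=(4, 2), bspline_iterations=4
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dvf = register_phases(micro_phantom.phases[0], micro_phantom.phases[2], cfg)
        assert dvf.grid == micro_phantom.config.grid
        assert np.all(np.isfinite(dvf.vectors))

    def test_invalid_engine_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(engine="elastix")


@pytest.fixture(scope="module")
def small_batch(tiny_phantom):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fields = [
            register_phases(tiny_phantom.phases[0], tiny_phantom.phases[k])
            for k in (1, 4, 7)
        ]
        return build_augmented_dataset(
            tiny_phantom,
            6,
            TPSConfig.tiny(),
            seed=23,
            interphase_fields=fields,
        ), fields


class TestBuildDataset:
    def test_sample_count(self, small_batch):
        samples, _ = small_batch
        assert len(samples) == 6

    def test_centroid_is_mask_center_of_mass(self, small_batch, tiny_phantom):
        samples, _ = small_batch
        iso = tiny_phantom.config.grid.isocenter
        for s in samples:
            com = s.sseg.center_of_mass() - iso
            assert np.abs(com - s.gt_centroid.as_array()).max() < 1e-6

    def test_provenance_deterministic(self, small_batch, tiny_phantom):
        samples, fields = small_batch
        again = build_augmented_dataset(
            tiny_phantom, 6, TPSConfig.tiny(), seed=23, interphase_fields=fields
        )
        assert [s.provenance for s in samples] == [s.provenance for s in again]
        np.testing.assert_array_equal(samples[0].sct.values, again[0].sct.values)

    def test_weights_within_open_unit_interval(self, small_batch):
        samples, _ = small_batch
        for s in samples:
            for key in ("alpha", "w1", "w2"):
                assert 0.0 < s.provenance[key] < 1.0
            assert s.provenance["i"] != s.provenance["j"]

    def test_invalid_sample_count_rejected(self, tiny_phantom):
        with pytest.raises(ValueError):
            build_augmented_dataset(tiny_phantom, 0, TPSConfig())
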