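import numpy as np
import pytest

from orthotrack.core import Grid3D, TumorState
from orthotrack.drr import Mask2D, ProjectionGeometry, project_tumor_mask
from orthotrack.phantom import rasterize_tumor
from orthotrack.regression3d import (
    CentroidRegressor,
    RegModelConfig,
    RegTrainConfig,
    build_reg_model,
    predict_position,
    reg_loss,
    train_regression,
    triangulate_centroid,
)


class TestRegLoss:
    def test_perfect_prediction_zero(self):
        states = [TumorState(1, 2, 3), TumorState(-1, 0, 4)]
        assert reg_loss(states, states) == 0.0

    def test_unit_offset_gives_three(self):
        assert reg_loss([TumorState(1, 1, 1)], [TumorState(0, 0, 0)]) == pytest.approx(3.0)

    def test_two_sample_mean(self):
        pred = [TumorState(3, 0, 0), TumorState(0, 0, 0)]
        true = [TumorState(0, 0, 0), TumorState(0, 0, 0)]
        assert reg_loss(pred, true) == pytest.approx(4.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reg_loss([], [])

    def test_nonnegative_and_zero_iff_equal(self, rng):
        a = [TumorState(*rng.normal(size=3)) for _ in range(5)]
        b = [TumorState(*rng.normal(size=3)) for _ in range(5)]
        assert reg_loss(a, b) > 0.0
        assert reg_loss(a, a) == 0.0


class TestModel:
    def test_output_three_finite_numbers(self):
        model = build_reg_model(RegModelConfig.tiny(input_size=32))
        x = np.random.default_rng(0).random((2, 2, 32, 32)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (2, 3)
        assert np.all(np.isfinite(y))

    def test_seeded_builds_identical(self):
        a = build_reg_model(RegModelConfig.tiny(seed=4))
        b = build_reg_model(RegModelConfig.tiny(seed=4))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_full_preset_three_node_head(self):
        model = build_reg_model(RegModelConfig.full())
        assert model.fc.weight.data.shape[1] == 3
        model.set_training(False)
        y = model.forward(np.zeros((1, 2, 224, 224), np.float32))
        assert y.shape == (1, 3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RegModelConfig(preset="huge")
        with pytest.raises(ValueError):
            RegModelConfig(head="attention")


@pytest.fixture(scope="module")
def geom():
    return ProjectionGeometry.tiny()


@pytest.fixture(scope="module")
def sphere_mask_samples(geom):
    """(mask pair, centroid) samples from spheres at random positions."""
    grid = Grid3D.centered((64, 64, 64))
    rng = np.random.default_rng(11)
    samples = []
    for _ in range(40):
        c = rng.uniform(-10, 10, 3)
        m3 = rasterize_tumor(c, (7, 7, 7), grid)
        pair = tuple(
            project_tumor_mask(m3, geom, a) for a in geom.gantry_angles_deg
        )
        samples.append((pair, TumorState.from_array(c)))
    return samples


class TestTriangulation:
    def test_twenty_seeded_spheres_within_half_mm(self, geom):
        grid = Grid3D.centered((64, 64, 64))
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = rng.uniform(-12, 12, 3)
            m3 = rasterize_tumor(c, (6, 6, 6), grid)
            pair = tuple(project_tumor_mask(m3, geom, a) for a in geom.gantry_angles_deg)
            rec = triangulate_centroid(pair, geom).as_array()
            assert np.linalg.norm(rec - c) <= 0.5

    def test_sphere_at_isocenter(self, geom):
        grid = Grid3D.centered((64, 64, 64))
        m3 = rasterize_tumor((0, 0, 0), (8, 8, 8), grid)
        pair = tuple(project_tumor_mask(m3, geom, a) for a in geom.gantry_angles_deg)
        assert np.linalg.norm(triangulate_centroid(pair, geom).as_array()) <= 0.5

    def test_pure_si_offset(self, geom):
        grid = Grid3D.centered((64, 64, 64))
        m3 = rasterize_tumor((0, 0, 10), (6, 6, 6), grid)
        pair = tuple(project_tumor_mask(m3, geom, a) for a in geom.gantry_angles_deg)
        state = triangulate_centroid(pair, geom)
        assert abs(state.z_si - 10.0) <= 0.5

    def test_in_plane_offset(self, geom):
        grid = Grid3D.centered((64, 64, 64))
        m3 = rasterize_tumor((5, -3, 0), (6, 6, 6), grid)
        pair = tuple(project_tumor_mask(m3, geom, a) for a in geom.gantry_angles_deg)
        state = triangulate_centroid(pair, geom)
        assert abs(state.x_lr - 5.0) <= 0.5
        assert abs(state.y_ap + 3.0) <= 0.5

    def test_empty_mask_rejected(self, geom):
        empty = Mask2D(np.zeros(geom.detector_shape, np.uint8), geom, 45.0)
        with pytest.raises(ValueError):
            triangulate_centroid((empty, empty), geom)

    def test_non_orthogonal_angles_rejected(self, geom):
        m = np.zeros(geom.detector_shape, np.uint8)
        m[60:70, 60:70] = 1
        with pytest.raises(ValueError):
            triangulate_centroid(
                (Mask2D(m, geom, 45.0), Mask2D(m, geom, 100.0)), geom
            )


class TestTraining:
    def test_validation_loss_decreases(self, sphere_mask_samples):
        tr, va = sphere_mask_samples[:32], sphere_mask_samples[32:]
        cfg = RegTrainConfig(learning_rate=0.01, epochs=10, batch_size=8, seed=0)
        _, hist = train_regression(tr, cfg, RegModelConfig.tiny(), va)
        assert hist["val_loss"][-1] < hist["val_loss"][0]

    def test_recovers_sphere_positions(self, sphere_mask_samples, geom):
        # 32 training spheres are few; translation augmentation supplies the
        # positional coverage a larger study would have
        tr, te = sphere_mask_samples[:32], sphere_mask_samples[32:]
        cfg = RegTrainConfig(
            learning_rate=0.01, epochs=60, batch_size=8, seed=0, shift_augment_px=4
        )
        model, _ = train_regression(tr, cfg, RegModelConfig.tiny(), te)
        errs = [
            np.linalg.norm(predict_position(model, pair).as_array() - t.as_array())
            for pair, t in te
        ]
        assert np.sqrt(np.mean(np.square(errs))) <= 1.0

    def test_view_order_matters(self, sphere_mask_samples):
        pair, _ = sphere_mask_samples[0]
        cfg = RegTrainConfig(epochs=1, batch_size=8, seed=0)
        model, _ = train_regression(sphere_mask_samples[:8], cfg, RegModelConfig.tiny())
        fwd = predict_position(model, pair).as_array()
        swapped = predict_position(model, (pair[1], pair[0])).as_array()
        assert not np.allclose(fwd, swapped)

    def test_empty_mask_prediction_flagged(self, sphere_mask_samples, geom):
        cfg = RegTrainConfig(epochs=1, batch_size=8, seed=0)
        model, _ = train_regression(sphere_mask_samples[:8], cfg, RegModelConfig.tiny())
        empty = Mask2D(np.zeros(geom.detector_shape, np.uint8), geom, 45.0)
        state, meta = predict_position(model, (empty, empty), return_meta=True)
        assert np.all(np.isfinite(state.as_array()))
        assert meta["low_confidence"]

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            train_regression([], RegTrainConfig(epochs=1))


class TestEstimator:
    def test_params_round_trip(self):
        reg = CentroidRegressor(epochs=7, seed=1)
        assert CentroidRegressor(**reg.get_params()).get_params() == reg.get_params()

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            CentroidRegressor().predict([np.zeros((2, 32, 32))])
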