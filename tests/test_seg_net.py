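import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthotrack.drr import DRRImage, Mask2D, ProjectionGeometry
from orthotrack.seg_net import (
    SegLossConfig,
    SegModelConfig,
    SegNet,
    SegTrainConfig,
    TumorSegmenter,
    bce_loss,
    build_seg_model,
    dice_loss,
    predict_mask,
    seg_loss,
    train_segmentation,
)


class TestLosses:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((16, 16))
        t[4:10, 4:10] = 1.0
        assert dice_loss(t, t) < 1e-5
        assert bce_loss(t, t) < 1e-4
        assert seg_loss(t, t) < 1e-4

    def test_dice_total_mismatch(self):
        pred = np.ones((8, 8))
        target = np.zeros((8, 8))
        assert dice_loss(pred, target) == pytest.approx(1.0, abs=1e-6)

    def test_dice_uniform_half_closed_form(self):
        # pred 0.5 everywhere, targets half ones on 2N pixels -> 1/3
        pred = np.full((10, 10), 0.5)
        target = np.zeros((10, 10))
        target[:5] = 1.0
        assert dice_loss(pred, target) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_bce_uniform_half_is_ln2(self):
        pred = np.full((12, 12), 0.5)
        target = (np.arange(144).reshape(12, 12) % 3 == 0).astype(float)
        assert bce_loss(pred, target) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_composite_weighting(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(0.01, 0.99, (8, 8))
        target = (rng.random((8, 8)) > 0.5).astype(float)
        composite = seg_loss(pred, target, SegLossConfig())
        manual = 0.6 * dice_loss(pred, target) + 0.4 * bce_loss(pred, target)
        assert composite == pytest.approx(manual, rel=1e-12)
        only_dice = seg_loss(pred, target, SegLossConfig(beta1=1.0, beta2=0.0))
        assert only_dice == pytest.approx(dice_loss(pred, target), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))
        with pytest.raises(ValueError):
            bce_loss(np.zeros((4, 4)), np.zeros((5, 4)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_joint_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.uniform(0, 1, 36)
        target = (rng.random(36) > 0.5).astype(float)
        perm = rng.permutation(36)
        assert bce_loss(pred, target) == pytest.approx(
            bce_loss(pred[perm], target[perm]), rel=1e-12
        )
        assert dice_loss(pred, target) == pytest.approx(
            dice_loss(pred[perm], target[perm]), rel=1e-12
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_seg_loss_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.uniform(0, 1, (6, 6))
        target = (rng.random((6, 6)) > 0.5).astype(float)
        assert seg_loss(pred, target) >= 0.0

    def test_dice_monotone_in_overlap(self):
        # raising sum(p*g) at fixed sum(p^2), sum(g^2) lowers the loss
        target = np.array([1.0, 1.0, 0.0, 0.0])
        low = np.array([0.0, 0.6, 0.8, 0.0])  # overlap 0.6
        high = np.array([0.8, 0.6, 0.0, 0.0])  # same |p|^2, overlap 1.4
        assert dice_loss(high, target) < dice_loss(low, target)


TINY = dict(
    preset="tiny",
    input_size=32,
    encoder_channels=(4, 6, 8),
    transformer_layers=1,
    transformer_heads=2,
    transformer_dim=8,
)


class TestModel:
    def test_output_shape_and_range(self):
        model = build_seg_model(SegModelConfig(**TINY, seed=0))
        x = np.random.default_rng(0).normal(size=(2, 1, 32, 32)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (2, 1, 32, 32)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_seeded_builds_identical(self):
        a = build_seg_model(SegModelConfig(**TINY, seed=5))
        b = build_seg_model(SegModelConfig(**TINY, seed=5))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_full_preset_accepts_224(self):
        model = build_seg_model(SegModelConfig.full(seed=0))
        x = np.zeros((1, 1, 224, 224), np.float32)
        model.set_training(False)
        y = model.forward(x)
        assert y.shape == (1, 1, 224, 224)

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValueError):
            SegModelConfig(preset="tiny", input_size=100)


@pytest.fixture(scope="module")
def blob_pairs():
    """Synthetic DRR/mask pairs: bright discs on noisy backgrounds."""
    geom = ProjectionGeometry(detector_shape=(32, 32), pixel_spacing=(1, 1))
    rng = np.random.default_rng(7)
    pairs = []
    for _ in range(8):
        cx, cy = rng.uniform(10, 22, 2)
        yy, xx = np.mgrid[0:32, 0:32]
        disc = ((xx - cx) ** 2 + (yy - cy) ** 2) <= 5**2
        img = rng.normal(2.0, 0.3, (32, 32)).astype(np.float32)
        img[disc] += 4.0
        pairs.append(
            (DRRImage(img, geom, 45.0), Mask2D(disc.astype(np.uint8), geom, 45.0))
        )
    return pairs


class TestTraining:
    def test_loss_decreases(self, blob_pairs):
        cfg = SegTrainConfig(epochs=8, batch_size=4, seed=0)
        _, hist = train_segmentation(blob_pairs, cfg, SegModelConfig(**TINY, seed=0))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_overfit_single_pair_reproduces_mask(self, blob_pairs):
        pair = [blob_pairs[0]]
        cfg = SegTrainConfig(epochs=60, batch_size=1, seed=0)
        model, _ = train_segmentation(pair, cfg, SegModelConfig(**TINY, seed=0))
        pred = predict_mask(model, pair[0][0])
        gt = pair[0][1].pixels
        inter = int((pred.pixels & gt).sum())
        dsc = 2 * inter / (pred.pixels.sum() + gt.sum())
        assert dsc > 0.95

    def test_predicted_mask_contract(self, blob_pairs):
        cfg = SegTrainConfig(epochs=2, batch_size=4, seed=0)
        model, _ = train_segmentation(blob_pairs, cfg, SegModelConfig(**TINY, seed=0))
        out = predict_mask(model, blob_pairs[0][0])
        assert out.pixels.shape == (32, 32)
        assert set(np.unique(out.pixels)) <= {0, 1}

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_segmentation([], SegTrainConfig(epochs=1), SegModelConfig(**TINY))

    def test_training_deterministic(self, blob_pairs):
        cfg = SegTrainConfig(epochs=2, batch_size=4, seed=3)
        m1, h1 = train_segmentation(blob_pairs, cfg, SegModelConfig(**TINY, seed=3))
        m2, h2 = train_segmentation(blob_pairs, cfg, SegModelConfig(**TINY, seed=3))
        assert h1 == h2
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        seg = TumorSegmenter(epochs=5, seed=2)
        params = seg.get_params()
        assert params["epochs"] == 5
        clone = TumorSegmenter(**params)
        assert clone.get_params() == params

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            TumorSegmenter().predict([np.zeros((32, 32))])

    def test_fit_predict_arrays(self, blob_pairs):
        X = [p[0].pixels for p in blob_pairs]
        y = [p[1].pixels for p in blob_pairs]
        seg = TumorSegmenter(preset="tiny", input_size=32, epochs=2, batch_size=4, seed=0)
        seg.model_, seg.history_ = train_segmentation(
            blob_pairs, SegTrainConfig(epochs=2, batch_size=4, seed=0),
            SegModelConfig(**TINY, seed=0),
        )
        out = seg.predict(X[:2])
        assert out.shape == (2, 32, 32)
        proba = seg.predict_proba(X[:2])
        assert proba.min() >= 0 and proba.max() <= 1
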