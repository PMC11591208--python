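"""Dual-view 3D tumor localization.

Maps the pair of orthogonal 2D tumor masks to a 3D centroid in mm relative
to the isocenter, two ways:

* :class:`RegNet` / :class:`CentroidRegressor` — a residual CNN regressor
  (7x7 stride-2 stem, 3x3 stride-2 max pool, residual stages, 3-node
  output) trained with an MSE loss on (mask pair, position) samples.
* :func:`triangulate_centroid` — a closed-form geometric triangulation for
  parallel-beam orthogonal views.  This is engineering plumbing, not part
  of the learned method: it provides a learning-free fallback and an exact
  oracle the regressor can be validated against.

Network inputs are the two view masks (fixed order: first configured angle,
then the second), resized to the model input size by area averaging and
normalized to unit mass per channel.  Unit-mass normalization makes the
mask centroid an exactly linear functional of the input, which the network
can represent and refine — sub-pixel occupancy fractions survive the
resize, so sub-millimetre regression is learnable at tiny scale.

The ``full`` preset is the full-scale configuration, with global average
pooling before the 3-node head; the ``tiny`` preset flattens the final
feature map instead, keeping explicit spatial information at low capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from ._imageops import resize2d, unit_sum
from .core import TumorState
from .drr import Mask2D, ProjectionGeometry, beam_axes

__all__ = [
    "RegModelConfig",
    "RegTrainConfig",
    "RegNet",
    "build_reg_model",
    "reg_loss",
    "train_regression",
    "predict_position",
    "triangulate_centroid",
    "CentroidRegressor",
]


@dataclass(frozen=True)
class RegModelConfig:
    """Architecture preset for the regression network."""

    preset: str = "tiny"
    input_size: int = 224
    stem_channels: int = 8
    stage_channels: tuple[int, ...] = (16, 32)
    blocks_per_stage: tuple[int, ...] = (1, 1)
    head: str = "flatten"  # "flatten" or "gap"
    stem_pool: str = "none"  # "max" (7x7 conv + 3x3 max pool) or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("full", "tiny"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.head not in ("flatten", "gap"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.stem_pool not in ("max", "none"):
            raise ValueError(f"unknown stem pool {self.stem_pool!r}")
        if len(self.stage_channels) != len(self.blocks_per_stage):
            raise ValueError("need one block count per stage")

    @staticmethod
    def tiny(input_size: int = 64, seed: int = 0) -> "RegModelConfig":
        return RegModelConfig(preset="tiny", input_size=input_size, seed=seed)

    @staticmethod
    def full(seed: int = 0) -> "RegModelConfig":
        return RegModelConfig(
            preset="full",
            input_size=224,
            stem_channels=64,
            stage_channels=(64, 128, 256, 512),
            blocks_per_stage=(2, 2, 2, 2),
            head="gap",
            stem_pool="max",
            seed=seed,
        )


@dataclass(frozen=True)
class RegTrainConfig:
    """Adam training schedule with reduce-on-plateau."""

    learning_rate: float = 0.001
    batch_size: int = 24
    epochs: int = 50
    plateau_factor: float = 0.5
    plateau_patience: int = 8
    # Consistent dual-view translation augmentation: each training pair is
    # shifted by random integer pixel offsets per view (equal vertical
    # shift), which corresponds exactly to one 3D translation of the tumor;
    # targets are adjusted by that translation.  Counters the shrinkage of
    # trajectory extremes in the hybrid-deformation training distribution.
    shift_augment_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")


class _BasicBlock(nn.Module):
    """Two 3x3 convs with BN and an identity/projection shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, rng) -> None:
        self.c1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.b2 = nn.BatchNorm2d(cout)
        self.proj = None
        if cin != cout or stride != 1:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        self.out_act = nn.ReLU()

    def forward(self, x):
        h = self.b2.forward(
            self.c2.forward(self.r1.forward(self.b1.forward(self.c1.forward(x))))
        )
        s = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x))
        return self.out_act.forward(h + s)

    def backward(self, dy):
        dy = self.out_act.backward(dy)
        dh = self.c1.backward(
            self.b1.backward(self.r1.backward(self.c2.backward(self.b2.backward(dy))))
        )
        if self.proj is None:
            return dh + dy
        return dh + self.proj.backward(self.proj_bn.backward(dy))


class RegNet(nn.Module):
    """Residual CNN mapping a 2-channel mask stack to (x_lr, y_ap, z_si) mm."""

    def __init__(self, cfg: RegModelConfig) -> None:
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        layers: list[nn.Module] = [
            nn.Conv2d(2, cfg.stem_channels, 7, stride=2, padding=3, bias=False, rng=rng),
            nn.BatchNorm2d(cfg.stem_channels),
            nn.ReLU(),
        ]
        res = cfg.input_size // 2
        if cfg.stem_pool == "max":
            layers.append(nn.MaxPool2d(3, 2, 1))
            res //= 2
        cin = cfg.stem_channels
        for cout, blocks in zip(cfg.stage_channels, cfg.blocks_per_stage):
            for b in range(blocks):
                stride = 2 if b == 0 else 1
                layers.append(_BasicBlock(cin, cout, stride, rng))
                cin = cout
            res //= 2
        self.body = nn.Sequential(*layers)
        if cfg.head == "gap":
            self.pool: nn.Module = nn.GlobalAvgPool2d()
            fc_in = cin
        else:
            self.pool = nn.Flatten()
            fc_in = cin * res * res
        self.fc = nn.Linear(fc_in, 3, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc.forward(self.pool.forward(self.body.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(self.pool.backward(self.fc.backward(dy)))


def build_reg_model(cfg: RegModelConfig) -> RegNet:
    return RegNet(cfg)


def reg_loss(
    pred: Sequence[TumorState] | np.ndarray, true: Sequence[TumorState] | np.ndarray
) -> float:
    """MSE over samples: mean of squared 3D offsets (mm^2)."""
    p = np.asarray([s.as_array() if isinstance(s, TumorState) else s for s in pred])
    t = np.asarray([s.as_array() if isinstance(s, TumorState) else s for s in true])
    if len(p) == 0 or p.shape != t.shape:
        raise ValueError("prediction and truth must be equal-length, nonempty")
    return float(((p - t) ** 2).sum(axis=1).mean())


def _prep_pair(masks, size: int) -> np.ndarray:
    """Stack and normalize one orthogonal view pair.

    Binary masks are area-resized and normalized to unit mass (making the
    centroid a linear functional of the input); grayscale DRR images (the
    segmentation-free ablation arm) are z-score normalized instead.
    """
    from .drr import DRRImage
    from ._imageops import zscore

    if isinstance(masks, np.ndarray):
        items = [masks[0], masks[1]]
    else:
        items = list(masks)
    chans = []
    for it in items:
        if isinstance(it, DRRImage):
            chans.append(zscore(resize2d(it.pixels, size, order=1)))
        else:
            a = it.pixels if isinstance(it, Mask2D) else np.asarray(it)
            chans.append(unit_sum(resize2d(a.astype(np.float32), size, order=1)))
    return np.stack(chans)


def train_regression(
    samples: Sequence[tuple[tuple[Mask2D, Mask2D], TumorState]],
    cfg: RegTrainConfig | None = None,
    model_cfg: RegModelConfig | None = None,
    val_samples: Sequence[tuple[tuple[Mask2D, Mask2D], TumorState]] | None = None,
    model: RegNet | None = None,
) -> tuple[RegNet, dict]:
    """Train the 3D regressor; returns (best model, loss history).

    Targets are mm offsets from the isocenter.  The best-validation
    checkpoint is restored before returning; deterministic given seeds.
    """
    cfg = cfg or RegTrainConfig()
    model_cfg = model_cfg or RegModelConfig()
    if len(samples) == 0:
        raise ValueError("training set is empty")
    if val_samples is None or len(val_samples) == 0:
        val_samples = samples

    size = model_cfg.input_size
    X = np.stack([_prep_pair(m, size) for m, _ in samples])
    Y = np.stack([t.as_array() for _, t in samples]).astype(np.float32)
    Xv = np.stack([_prep_pair(m, size) for m, _ in val_samples])
    Yv = np.stack([t.as_array() for _, t in val_samples]).astype(np.float32)

    shift_px = cfg.shift_augment_px
    use_shift = shift_px > 0 and all(
        isinstance(m, Mask2D) for pair, _ in samples for m in pair
    )
    if use_shift:
        geom = samples[0][0][0].geometry
        raw = np.stack(
            [[m.pixels.astype(np.float32) for m in pair] for pair, _ in samples]
        )
        angles = [samples[0][0][vi].angle_deg for vi in range(2)]
        A = np.array([beam_axes(a)[0][:2] for a in angles])
        A_inv = np.linalg.inv(A)
        su, sv = geom.pixel_spacing

    model = model or build_reg_model(model_cfg)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    sched = nn.ReduceLROnPlateau(
        opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience
    )
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, model.get_state())
    for _ in range(cfg.epochs):
        model.set_training(True)
        order = rng.permutation(len(X))
        losses = []
        for s in range(0, len(X), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            if use_shift:
                xb, yb = [], []
                for i in idx:
                    a, b, c = rng.integers(-shift_px, shift_px + 1, size=3)
                    m0 = np.roll(raw[i, 0], (int(a), int(c)), axis=(0, 1))
                    m1 = np.roll(raw[i, 1], (int(b), int(c)), axis=(0, 1))
                    dxy = A_inv @ np.array([a * su, b * su])
                    xb.append(_prep_pair(np.stack([m0, m1]), size))
                    yb.append(Y[i] + np.array([dxy[0], dxy[1], c * sv]))
                xbatch = np.stack(xb).astype(np.float32)
                ybatch = np.stack(yb).astype(np.float32)
            else:
                xbatch, ybatch = X[idx], Y[idx]
            opt.zero_grad()
            pred = model.forward(xbatch)
            diff = pred - ybatch
            loss = float((diff**2).sum(axis=1).mean())
            model.backward((2.0 * diff / len(idx)).astype(np.float32))
            opt.step()
            losses.append(loss)
        model.set_training(False)
        pv = model.forward(Xv)
        val = float(((pv - Yv) ** 2).sum(axis=1).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val)
        sched.step(val)
        if val < best[0]:
            best = (val, model.get_state())
    model.set_state(best[1])
    model.set_training(False)
    return model, history


def predict_position(
    model: RegNet, masks: tuple[Mask2D, Mask2D], return_meta: bool = False
):
    """Predict the 3D centroid (mm from isocenter) for one mask pair.

    Empty masks still produce an output; the optional metadata flags it as
    low-confidence.
    """
    if not isinstance(model, RegNet):
        raise TypeError("model must be a trained RegNet")
    model.set_training(False)
    x = _prep_pair(masks, model.cfg.input_size)[None]
    out = model.forward(x)[0]
    state = TumorState(float(out[0]), float(out[1]), float(out[2]))
    if return_meta:
        empty = [not bool(np.any(m.pixels)) for m in masks]
        return state, {"low_confidence": any(empty), "empty_views": empty}
    return state


# ---------------------------------------------------------------------------
# Geometric triangulation (learning-free oracle / fallback)
# ---------------------------------------------------------------------------


def triangulate_centroid(
    masks: tuple[Mask2D, Mask2D], geom: ProjectionGeometry
) -> TumorState:
    """Closed-form dual-view centroid for parallel-beam orthogonal views.

    The in-plane detector coordinate of a world point at angle ``t`` is
    ``u = x cos(t) - y sin(t)`` and its vertical coordinate is ``v = z``;
    the two u-centroids give a 2x2 linear system for (x, y), and z is the
    mean of the two v-centroids.
    """
    if geom.beam_model != "parallel":
        raise ValueError("triangulation requires the parallel beam model")
    m1, m2 = masks
    if not (m1.pixels.any() and m2.pixels.any()):
        raise ValueError("triangulation needs nonempty masks in both views")
    a1, a2 = m1.angle_deg, m2.angle_deg
    if abs(((a1 - a2) % 180.0) - 90.0) > 1e-6:
        raise ValueError("view angles must be 90 degrees apart")
    u1, v1 = m1.centroid_uv()
    u2, v2 = m2.centroid_uv()
    rows = []
    for a in (a1, a2):
        u_hat, _, _ = beam_axes(a)
        rows.append(u_hat[:2])
    A = np.asarray(rows)
    xy = np.linalg.solve(A, np.array([u1, u2]))
    return TumorState(float(xy[0]), float(xy[1]), float((v1 + v2) / 2.0))


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class CentroidRegressor(BaseEstimator):
    """3D centroid regression from orthogonal mask pairs, sklearn style.

    ``X`` is (n, 2, H, W) mask stacks (first view, second view) or a list of
    Mask2D pairs; ``y`` is (n, 3) mm offsets from the isocenter or a list of
    :class:`TumorState`.  Fitted state lives in ``model_`` / ``history_``.
    """

    def __init__(
        self,
        preset: str = "tiny",
        input_size: int = 64,
        learning_rate: float = 0.01,
        batch_size: int = 24,
        epochs: int = 150,
        shift_augment_px: int = 6,
        seed: int = 0,
    ) -> None:
        self.preset = preset
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.shift_augment_px = shift_augment_px
        self.seed = seed

    def _configs(self) -> tuple[RegModelConfig, RegTrainConfig]:
        if self.preset == "full":
            model_cfg = RegModelConfig.full(seed=self.seed)
        else:
            model_cfg = RegModelConfig.tiny(input_size=self.input_size, seed=self.seed)
        return model_cfg, RegTrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            shift_augment_px=self.shift_augment_px,
            seed=self.seed,
        )

    @staticmethod
    def _as_state(t) -> TumorState:
        return t if isinstance(t, TumorState) else TumorState.from_array(t)

    def fit(self, X, y, X_val=None, y_val=None) -> "CentroidRegressor":
        model_cfg, train_cfg = self._configs()
        samples = [(m, self._as_state(t)) for m, t in zip(X, y)]
        val = (
            [(m, self._as_state(t)) for m, t in zip(X_val, y_val)]
            if X_val is not None
            else None
        )
        self.model_, self.history_ = train_regression(samples, train_cfg, model_cfg, val)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("CentroidRegressor is not fitted")
        self.model_.set_training(False)
        xs = np.stack([_prep_pair(m, self.model_.cfg.input_size) for m in X])
        return self.model_.forward(xs)
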