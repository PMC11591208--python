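"""2D tumor segmentation: hybrid CNN-Transformer network, losses, training.

The network follows the TransUNet pattern: a convolutional encoder extracts
multi-scale local features, a Transformer bottleneck on the coarsest
feature map captures global context, and a decoder with skip connections
(down to the raw input resolution) restores a full-resolution per-pixel
tumor probability map.

Two presets are provided.  ``full`` is the full-scale configuration — a
ResNet-50-style stem plus three bottleneck stages (output stride 16) under
a 12-layer, 12-head, 768-dim Transformer.  ``tiny`` is a 3-stage encoder
with a 2-layer, 2-head, 48-dim bottleneck sized for CPU training on the
small phantom.

The training loss is the weighted composite ``beta1 * Dice + beta2 * BCE``
with beta defaults 0.6/0.4; optimization is SGD with momentum (lr 0.01,
momentum 0.9, weight decay 1e-4 by default).

Everything is also available through the sklearn-style
:class:`TumorSegmenter` estimator (``fit`` / ``predict`` /
``predict_proba``), which is the recommended interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from ._imageops import resize2d, zscore
from .drr import DRRImage, Mask2D

__all__ = [
    "SegModelConfig",
    "SegLossConfig",
    "SegTrainConfig",
    "SegNet",
    "build_seg_model",
    "dice_loss",
    "bce_loss",
    "seg_loss",
    "train_segmentation",
    "predict_mask",
    "TumorSegmenter",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture preset for the segmentation network."""

    preset: str = "tiny"
    input_size: int = 224
    encoder_channels: tuple[int, ...] = (8, 16, 32)
    transformer_layers: int = 2
    transformer_heads: int = 2
    transformer_dim: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("full", "tiny"):
            raise ValueError(f"unknown preset {self.preset!r}")
        # total downsampling is 2^(stages+1) with the extra bottleneck stride
        factor = 16 if self.preset == "full" else 2 ** (len(self.encoder_channels) + 1)
        if self.input_size % factor:
            raise ValueError(
                f"input size {self.input_size} not divisible by the "
                f"downsampling factor {factor}"
            )

    @staticmethod
    def tiny(input_size: int = 128, seed: int = 0) -> "SegModelConfig":
        return SegModelConfig(preset="tiny", input_size=input_size, seed=seed)

    @staticmethod
    def full(seed: int = 0) -> "SegModelConfig":
        return SegModelConfig(
            preset="full",
            input_size=224,
            encoder_channels=(64, 256, 512, 1024),
            transformer_layers=12,
            transformer_heads=12,
            transformer_dim=768,
            seed=seed,
        )


@dataclass(frozen=True)
class SegLossConfig:
    """Composite-loss weights: beta1 * Dice + beta2 * BCE."""

    beta1: float = 0.6
    beta2: float = 0.4
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta1 <= 1.0 and 0.0 <= self.beta2 <= 1.0):
            raise ValueError("loss weights must lie in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass(frozen=True)
class SegTrainConfig:
    """SGD training schedule."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 12
    epochs: int = 100
    loss: SegLossConfig = field(default_factory=SegLossConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class _ConvBNReLU(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int, rng) -> None:
        self.conv = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))


class _Bottleneck(nn.Module):
    """ResNet-style 1x1 -> 3x3 -> 1x1 bottleneck with identity/projection skip."""

    def __init__(self, cin: int, cout: int, stride: int, rng) -> None:
        mid = cout // 4
        self.c1 = nn.Conv2d(cin, mid, 1, rng=rng, bias=False)
        self.b1 = nn.BatchNorm2d(mid)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1, rng=rng, bias=False)
        self.b2 = nn.BatchNorm2d(mid)
        self.r2 = nn.ReLU()
        self.c3 = nn.Conv2d(mid, cout, 1, rng=rng, bias=False)
        self.b3 = nn.BatchNorm2d(cout)
        self.proj = None
        if cin != cout or stride != 1:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, rng=rng, bias=False)
            self.proj_bn = nn.BatchNorm2d(cout)
        self.out_act = nn.ReLU()

    def forward(self, x):
        h = self.r1.forward(self.b1.forward(self.c1.forward(x)))
        h = self.r2.forward(self.b2.forward(self.c2.forward(h)))
        h = self.b3.forward(self.c3.forward(h))
        s = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x))
        return self.out_act.forward(h + s)

    def backward(self, dy):
        dy = self.out_act.backward(dy)
        dh = self.c1.backward(
            self.b1.backward(
                self.r1.backward(
                    self.c2.backward(
                        self.b2.backward(
                            self.r2.backward(self.c3.backward(self.b3.backward(dy)))
                        )
                    )
                )
            )
        )
        if self.proj is None:
            return dh + dy
        return dh + self.proj.backward(self.proj_bn.backward(dy))


class _TransformerBottleneck(nn.Module):
    """Tokenize a (N, C, h, w) map, run Transformer blocks, map back to C."""

    def __init__(self, channels: int, dim: int, layers: int, heads: int, n_tokens: int, rng) -> None:
        self.embed = nn.Linear(channels, dim, rng=rng)
        self.pos = nn.Parameter(
            rng.normal(0.0, 0.02, size=(n_tokens, dim)), "pos_embedding"
        )
        self.blocks = [nn.TransformerBlock(dim, heads, rng=rng) for _ in range(layers)]
        self.norm = nn.LayerNorm(dim)
        self.unembed = nn.Linear(dim, channels, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        self._hw = (h, w)
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        t = self.embed.forward(tokens) + self.pos.data
        for blk in self.blocks:
            t = blk.forward(t)
        t = self.unembed.forward(self.norm.forward(t))
        return np.ascontiguousarray(
            t.transpose(0, 2, 1).reshape(n, c, h, w), dtype=np.float32
        )

    def backward(self, dy):
        n, c, h, w = dy.shape
        dt = dy.reshape(n, c, h * w).transpose(0, 2, 1)
        dt = self.norm.backward(self.unembed.backward(dt))
        for blk in reversed(self.blocks):
            dt = blk.backward(dt)
        self.pos.grad += dt.sum(axis=0)
        dtok = self.embed.backward(dt)
        return np.ascontiguousarray(
            dtok.transpose(0, 2, 1).reshape(n, c, h, w), dtype=np.float32
        )


class _DecoderBlock(nn.Module):
    """Upsample 2x, concatenate a skip feature, fuse with Conv-BN-ReLU."""

    def __init__(self, cin: int, c_skip: int, cout: int, rng) -> None:
        self.up = nn.Upsample2x()
        self.fuse = _ConvBNReLU(cin + c_skip, cout, 1, rng)
        self.c_skip = c_skip

    def forward(self, x, skip):
        u = self.up.forward(x)
        self._split = u.shape[1]
        return self.fuse.forward(np.concatenate([u, skip], axis=1))

    def backward(self, dy):
        d = self.fuse.backward(dy)
        du, dskip = d[:, : self._split], d[:, self._split :]
        return self.up.backward(du), dskip


class SegNet(nn.Module):
    """Encoder + Transformer bottleneck + skip-connected decoder."""

    def __init__(self, cfg: SegModelConfig) -> None:
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        ch = cfg.encoder_channels
        if cfg.preset == "full":
            # ResNet-50 stem and first three bottleneck stages (stride 16)
            stem = nn.Sequential(
                nn.Conv2d(1, ch[0], 7, stride=2, padding=3, bias=False, rng=rng),
                nn.BatchNorm2d(ch[0]),
                nn.ReLU(),
            )
            def stage(cin, cout, blocks, stride):
                mods = [_Bottleneck(cin, cout, stride, rng)]
                mods += [_Bottleneck(cout, cout, 1, rng) for _ in range(blocks - 1)]
                return nn.Sequential(*mods)

            self.encoder = [
                stem,
                nn.Sequential(nn.MaxPool2d(3, 2, 1), stage(ch[0], ch[1], 3, 1)),
                stage(ch[1], ch[2], 4, 2),
                stage(ch[2], ch[3], 6, 2),
            ]
        else:
            self.encoder = [
                _ConvBNReLU(1, ch[0], 2, rng),
                nn.Sequential(_ConvBNReLU(ch[0], ch[1], 2, rng), _ConvBNReLU(ch[1], ch[1], 1, rng)),
                nn.Sequential(_ConvBNReLU(ch[1], ch[2], 2, rng), _ConvBNReLU(ch[2], ch[2], 1, rng)),
                _ConvBNReLU(ch[-1], ch[-1], 2, rng),
            ]
        bottleneck_ch = ch[-1]
        n_tok = (cfg.input_size // 16) ** 2
        self.transformer = _TransformerBottleneck(
            bottleneck_ch,
            cfg.transformer_dim,
            cfg.transformer_layers,
            cfg.transformer_heads,
            n_tok,
            rng,
        )
        # skip channels, finest first: raw input + encoder taps except the last
        if cfg.preset == "full":
            skip_ch = [1, ch[0], ch[1], ch[2]]
            dec_out = [16, ch[0], ch[1] // 2, ch[2] // 2]  # finest first
        else:
            skip_ch = [1, ch[0], ch[1], ch[2]]
            dec_out = [ch[0], ch[0], ch[1], ch[2]]
        self.decoder = []
        cin = bottleneck_ch
        for s, o in zip(reversed(skip_ch), reversed(dec_out)):
            self.decoder.append(_DecoderBlock(cin, s, o, rng))
            cin = o
        self.head = nn.Conv2d(dec_out[0], 1, 1, rng=rng)
        self.out_act = nn.Sigmoid()

    # -- forward/backward over the U-shaped wiring --------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) float input -> (N, 1, H, W) probabilities."""
        skips = [x]
        h = x
        for stage in self.encoder:
            h = stage.forward(h)
            skips.append(h)
        h = self.transformer.forward(skips.pop())
        self._n_skips = len(skips)
        for dec, skip in zip(self.decoder, reversed(skips)):
            h = dec.forward(h, skip)
        return self.out_act.forward(self.head.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(self.out_act.backward(dy))
        skip_grads = []
        # reversed(decoder) walks fine -> coarse, so grads land in skip order
        # (raw input first, matching the forward `skips` list)
        for dec in reversed(self.decoder):
            d, dskip = dec.backward(d)
            skip_grads.append(dskip)
        d = self.transformer.backward(d)
        for i in range(len(self.encoder) - 1, -1, -1):
            if i + 1 < self._n_skips:
                d = d + skip_grads[i + 1]
            d = self.encoder[i].backward(d)
        return d + skip_grads[0]


def build_seg_model(cfg: SegModelConfig) -> SegNet:
    """Construct the segmentation network for a configuration."""
    return SegNet(cfg)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _check_pair(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss: ``1 - (2 sum(p g) + eps) / (sum(p^2) + sum(g^2) + eps)``."""
    pred, target = _check_pair(pred, target)
    num = 2.0 * float((pred * target).sum()) + eps
    den = float((pred**2).sum() + (target**2).sum()) + eps
    return 1.0 - num / den


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> float:
    """Binary cross-entropy, predictions clipped to [eps, 1-eps]."""
    pred, target = _check_pair(pred, target)
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def seg_loss(
    pred: np.ndarray, target: np.ndarray, cfg: SegLossConfig | None = None
) -> float:
    """Composite segmentation loss ``beta1 * Dice + beta2 * BCE``."""
    cfg = cfg or SegLossConfig()
    return cfg.beta1 * dice_loss(pred, target, cfg.eps) + cfg.beta2 * bce_loss(
        pred, target, cfg.eps
    )


def _seg_loss_batch_grad(
    pred: np.ndarray, target: np.ndarray, cfg: SegLossConfig
) -> tuple[float, np.ndarray]:
    """Batched composite loss (mean over images) and its gradient wrt pred."""
    n = pred.shape[0]
    p = pred.reshape(n, -1).astype(np.float64)
    g = target.reshape(n, -1).astype(np.float64)
    eps = cfg.eps

    num = 2.0 * (p * g).sum(axis=1) + eps
    den = (p**2).sum(axis=1) + (g**2).sum(axis=1) + eps
    dice = 1.0 - num / den
    # d dice / dp = -(2 g den - num 2 p) / den^2
    ddice = -(2.0 * g * den[:, None] - num[:, None] * 2.0 * p) / den[:, None] ** 2

    pc = np.clip(p, eps, 1.0 - eps)
    bce = -(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean(axis=1)
    dbce = (-g / pc + (1.0 - g) / (1.0 - pc)) / p.shape[1]

    loss = float(cfg.beta1 * dice.mean() + cfg.beta2 * bce.mean())
    grad = (cfg.beta1 * ddice + cfg.beta2 * dbce) / n
    return loss, grad.reshape(pred.shape).astype(np.float32)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------


def _prep_image(img: DRRImage | np.ndarray, size: int) -> np.ndarray:
    pix = img.pixels if isinstance(img, DRRImage) else np.asarray(img)
    return zscore(resize2d(pix, size, order=1))


def _prep_target(m: Mask2D | np.ndarray, size: int) -> np.ndarray:
    pix = m.pixels if isinstance(m, Mask2D) else np.asarray(m)
    return (resize2d(pix.astype(np.float32), size, order=0) > 0.5).astype(np.float32)


def train_segmentation(
    pairs: Sequence[tuple[DRRImage, Mask2D]],
    cfg: SegTrainConfig | None = None,
    model_cfg: SegModelConfig | None = None,
    val_pairs: Sequence[tuple[DRRImage, Mask2D]] | None = None,
    model: SegNet | None = None,
) -> tuple[SegNet, dict]:
    """Train the segmentation network; returns (best model, loss history).

    Inputs are resized to the model's input size and z-score normalized per
    image.  The checkpoint with the best validation loss is restored before
    returning.  Deterministic given the config seeds.
    """
    cfg = cfg or SegTrainConfig()
    model_cfg = model_cfg or SegModelConfig()
    if len(pairs) == 0:
        raise ValueError("training set is empty")
    if val_pairs is None or len(val_pairs) == 0:
        val_pairs = pairs

    size = model_cfg.input_size
    X = np.stack([_prep_image(img, size) for img, _ in pairs])[:, None]
    Y = np.stack([_prep_target(m, size) for _, m in pairs])[:, None]
    Xv = np.stack([_prep_image(img, size) for img, _ in val_pairs])[:, None]
    Yv = np.stack([_prep_target(m, size) for _, m in val_pairs])[:, None]

    model = model or build_seg_model(model_cfg)
    opt = nn.SGD(
        model.parameters(),
        lr=cfg.learning_rate,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
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
            opt.zero_grad()
            prob = model.forward(X[idx])
            loss, grad = _seg_loss_batch_grad(prob, Y[idx], cfg.loss)
            model.backward(grad)
            opt.step()
            losses.append(loss)
        model.set_training(False)
        val_losses = []
        for s in range(0, len(Xv), cfg.batch_size):
            prob = model.forward(Xv[s : s + cfg.batch_size])
            val_losses.append(
                _seg_loss_batch_grad(prob, Yv[s : s + cfg.batch_size], cfg.loss)[0]
                * len(prob)
            )
        val = float(np.sum(val_losses) / len(Xv))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val)
        if val < best[0]:
            best = (val, model.get_state())
    model.set_state(best[1])
    model.set_training(False)
    return model, history


def _postprocess_binary(binary: np.ndarray) -> np.ndarray:
    """Single-target cleanup: fill holes, keep the largest component."""
    from scipy import ndimage as _ndi

    if not binary.any():
        return binary
    filled = _ndi.binary_fill_holes(binary)
    labels, n = _ndi.label(filled)
    if n > 1:
        sizes = _ndi.sum(filled, labels, range(1, n + 1))
        filled = labels == (int(np.argmax(sizes)) + 1)
    return filled.astype(np.uint8)


def predict_mask(model: SegNet, img: DRRImage) -> Mask2D:
    """Segment one DRR: forward pass, threshold 0.5, restore detector size.

    The thresholded map is cleaned for the single-target setting (holes
    filled, largest connected component kept), which stabilizes the mask
    centroid under image noise.
    """
    if not isinstance(model, SegNet):
        raise TypeError("model must be a trained SegNet")
    size = model.cfg.input_size
    model.set_training(False)
    x = _prep_image(img, size)[None, None]
    prob = model.forward(x)[0, 0]
    binary = _postprocess_binary((prob > 0.5).astype(np.uint8))
    det = img.geometry.detector_shape[0]
    if det != size:
        binary = (resize2d(binary.astype(np.float32), det, order=0) > 0.5).astype(
            np.uint8
        )
    return Mask2D(binary, img.geometry, img.angle_deg)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class TumorSegmenter(BaseEstimator):
    """Tumor segmentation of projection images, sklearn style.

    Parameters mirror :class:`SegModelConfig` / :class:`SegTrainConfig`;
    fitted state lives in ``model_`` and ``history_``.

    Examples
    --------
    >>> seg = TumorSegmenter(preset="tiny", input_size=128, epochs=10, seed=0)
    >>> seg.fit(train_images, train_masks)          # doctest: +SKIP
    >>> masks = seg.predict(test_images)            # doctest: +SKIP
    """

    def __init__(
        self,
        preset: str = "tiny",
        input_size: int = 128,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
        batch_size: int = 12,
        epochs: int = 100,
        beta1: float = 0.6,
        beta2: float = 0.4,
        seed: int = 0,
    ) -> None:
        self.preset = preset
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.beta1 = beta1
        self.beta2 = beta2
        self.seed = seed

    def _configs(self) -> tuple[SegModelConfig, SegTrainConfig]:
        if self.preset == "full":
            model_cfg = SegModelConfig.full(seed=self.seed)
        else:
            model_cfg = SegModelConfig.tiny(input_size=self.input_size, seed=self.seed)
        train_cfg = SegTrainConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            epochs=self.epochs,
            loss=SegLossConfig(beta1=self.beta1, beta2=self.beta2),
            seed=self.seed,
        )
        return model_cfg, train_cfg

    def fit(self, X, y, X_val=None, y_val=None) -> "TumorSegmenter":
        """Fit on images X (n, H, W) or DRRImages, binary masks y."""
        model_cfg, train_cfg = self._configs()
        pairs = list(zip(X, y))
        val_pairs = list(zip(X_val, y_val)) if X_val is not None else None
        self.model_, self.history_ = train_segmentation(
            pairs, train_cfg, model_cfg, val_pairs
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel tumor probability maps at the model input size."""
        if not hasattr(self, "model_"):
            raise AttributeError("TumorSegmenter is not fitted")
        size = self.model_.cfg.input_size
        self.model_.set_training(False)
        out = []
        for img in X:
            x = _prep_image(img, size)[None, None]
            out.append(self.model_.forward(x)[0, 0])
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        """Binary masks at the input image resolution."""
        if not hasattr(self, "model_"):
            raise AttributeError("TumorSegmenter is not fitted")
        out = []
        for img in X:
            pix = img.pixels if isinstance(img, DRRImage) else np.asarray(img)
            size = self.model_.cfg.input_size
            x = _prep_image(pix, size)[None, None]
            prob = self.model_.forward(x)[0, 0]
            binary = _postprocess_binary((prob > 0.5).astype(np.uint8))
            if pix.shape[0] != size:
                binary = (
                    resize2d(binary.astype(np.float32), pix.shape[0], order=0) > 0.5
                ).astype(np.uint8)
            out.append(binary)
        return np.stack(out)
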