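"""Evaluation statistics and experiment harnesses.

Implements the full evaluation suite: Dice similarity (DSC), intersection
over union (IoU), the 95th-percentile symmetric boundary distance (HD95),
per-axis and combined centroid RMSE, the tracking success rate (TSR),
phase-binned evaluation reports, the Gaussian-noise robustness sweep and
the with/without-segmentation ablation.

Conventions
-----------
* DSC and IoU of two empty masks are defined as 1.0 (vacuous agreement).
* HD95 of an empty mask is undefined and raises; harness code treats such
  frames as missing values for boundary metrics and as failures for TSR.
* The TSR threshold is configurable (default 2 mm on the 3D centroid
  error); a success additionally requires a nonempty predicted mask in
  both views.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import TumorState
from .drr import DRRImage, Mask2D, NoiseModel, add_gaussian_noise

__all__ = [
    "EvalReport",
    "NoiseSweepReport",
    "dsc",
    "iou",
    "hd95",
    "rmse3d",
    "tracking_success_rate",
    "evaluate_tracking",
    "noise_robustness_sweep",
    "ablate_segmentation",
]

PHASE_BINS = ("[0-20%]", "[20-40%]", "[40-60%]", "[60-80%]", "[80-100%]")


def _as_binary(x) -> np.ndarray:
    if isinstance(x, Mask2D):
        return x.pixels.astype(bool)
    if hasattr(x, "values"):  # Mask3D
        return np.asarray(x.values).astype(bool)
    return np.asarray(x).astype(bool)


def dsc(X, Y) -> float:
    """Dice similarity coefficient ``2|X ∩ Y| / (|X| + |Y|)``."""
    a, b = _as_binary(X), _as_binary(Y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def iou(X, Y) -> float:
    """Intersection over union ``|X ∩ Y| / |X ∪ Y|``."""
    a, b = _as_binary(X), _as_binary(Y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def hd95(X, Y, spacing: Sequence[float] | float = 1.0) -> float:
    """95th-percentile symmetric Hausdorff boundary distance, in mm.

    Boundary pixels are extracted by erosion; the directed distance is the
    95th percentile (linear interpolation between order statistics) of
    nearest-neighbour distances between the boundary point sets, and the
    symmetric value is the max of the two directions.
    """
    a, b = _as_binary(X), _as_binary(Y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("HD95 is undefined for empty masks")
    sp = np.broadcast_to(np.atleast_1d(np.asarray(spacing, dtype=float)), (a.ndim,))
    pa = np.argwhere(_boundary(a)) * sp
    pb = np.argwhere(_boundary(b)) * sp
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(
        max(np.percentile(d_ab, 95.0), np.percentile(d_ba, 95.0))
    )


def rmse3d(errors: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """Per-axis RMS errors and the combined ``sqrt((eLR²+eAP²+eSI²)/3)``."""
    e = np.atleast_2d(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise ValueError("error list is empty")
    if e.shape[1] != 3:
        raise ValueError("errors must be (n, 3) per-axis triples")
    per_axis = np.sqrt((e**2).mean(axis=0))
    combined = float(np.sqrt((per_axis**2).sum() / 3.0))
    return (float(per_axis[0]), float(per_axis[1]), float(per_axis[2]), combined)


def tracking_success_rate(
    errors_3d: Sequence[float],
    threshold: float = 2.0,
    valid: Sequence[bool] | None = None,
) -> float:
    """Percentage of frames tracked within ``threshold`` mm.

    A frame counts as a success when its 3D centroid error is at most the
    threshold AND (if ``valid`` flags are given) the predicted masks were
    nonempty in both views.
    """
    e = np.asarray(errors_3d, dtype=float)
    if e.size == 0:
        raise ValueError("error list is empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ok = e <= threshold
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    return float(100.0 * ok.mean())


@dataclass
class EvalReport:
    """Phase-binned tracking evaluation (per-phase rows + global means)."""

    per_phase: pd.DataFrame
    per_frame: pd.DataFrame
    global_means: dict
    tsr_threshold_mm: float


@dataclass
class NoiseSweepReport:
    """One row per requested noise variance level."""

    table: pd.DataFrame
    tsr_threshold_mm: float


def _phase_bin(fraction: float) -> str:
    idx = min(int(float(fraction) * 5.0), 4)
    return PHASE_BINS[idx]


def evaluate_tracking(
    pred_masks: Sequence[tuple[Mask2D, Mask2D]],
    gt_masks: Sequence[tuple[Mask2D, Mask2D]],
    pred_states: Sequence[TumorState],
    gt_states: Sequence[TumorState],
    phase_labels: Sequence[float],
    tsr_threshold: float = 2.0,
) -> EvalReport:
    """Build the phase-binned report: DSC/HD95 (view-averaged), RMSE, TSR.

    ``phase_labels`` are respiratory-phase fractions in [0, 1); frames are
    grouped into the five 20% bins.  Frames with an empty predicted mask in
    either view are excluded from the DSC/HD95 means but count as TSR
    failures.
    """
    n = len(pred_states)
    if not (
        len(pred_masks) == len(gt_masks) == len(gt_states) == len(phase_labels) == n
    ):
        raise ValueError("all per-frame lists must be aligned and equal length")

    rows = []
    for i in range(n):
        pm, gm = pred_masks[i], gt_masks[i]
        err = pred_states[i].as_array() - gt_states[i].as_array()
        nonempty = all(bool(np.any(m.pixels)) for m in pm)
        dscs, hds, ious = [], [], []
        for p, g in zip(pm, gm):
            dscs.append(dsc(p, g))
            ious.append(iou(p, g))
            if np.any(p.pixels) and np.any(g.pixels):
                hds.append(hd95(p, g, spacing=p.geometry.pixel_spacing))
        rows.append(
            {
                "frame": i,
                "phase": _phase_bin(phase_labels[i]),
                "dsc": float(np.mean(dscs)),
                "iou": float(np.mean(ious)),
                "hd95_mm": float(np.mean(hds)) if hds else np.nan,
                "e_lr": float(err[0]),
                "e_ap": float(err[1]),
                "e_si": float(err[2]),
                "error_3d": float(np.linalg.norm(err)),
                "pred_nonempty": nonempty,
            }
        )
    per_frame = pd.DataFrame(rows)

    phase_rows = []
    for label in PHASE_BINS:
        sub = per_frame[per_frame["phase"] == label]
        if len(sub) == 0:
            continue
        ok = sub[sub["pred_nonempty"]]
        e_lr, e_ap, e_si, comb = rmse3d(sub[["e_lr", "e_ap", "e_si"]].to_numpy())
        phase_rows.append(
            {
                "phase": label,
                "n_frames": len(sub),
                "dsc": float(ok["dsc"].mean()) if len(ok) else np.nan,
                "hd95_mm": float(ok["hd95_mm"].mean()) if len(ok) else np.nan,
                "e_lr": e_lr,
                "e_ap": e_ap,
                "e_si": e_si,
                "rmse3d_mm": comb,
            }
        )
    per_phase = pd.DataFrame(phase_rows)

    ok = per_frame[per_frame["pred_nonempty"]]
    e_lr, e_ap, e_si, comb = rmse3d(per_frame[["e_lr", "e_ap", "e_si"]].to_numpy())
    global_means = {
        "dsc": float(ok["dsc"].mean()) if len(ok) else np.nan,
        "hd95_mm": float(ok["hd95_mm"].mean()) if len(ok) else np.nan,
        "e_lr": e_lr,
        "e_ap": e_ap,
        "e_si": e_si,
        "rmse3d_mm": comb,
        "mean_error_3d_mm": float(per_frame["error_3d"].mean()),
        "tsr_percent": tracking_success_rate(
            per_frame["error_3d"], tsr_threshold, per_frame["pred_nonempty"]
        ),
    }
    return EvalReport(per_phase, per_frame, global_means, tsr_threshold)


def noise_robustness_sweep(
    seg_model,
    reg_model,
    test_set: Sequence[tuple[tuple[DRRImage, DRRImage], tuple[Mask2D, Mask2D], TumorState]],
    levels: Sequence[float] = (0.0, 5.0, 15.0, 25.0),
    seed: int = 0,
    tsr_threshold: float = 2.0,
) -> NoiseSweepReport:
    """Corrupt the test DRRs at each noise variance and re-run the pipeline.

    Reports, per level: mean 3D centroid error, mean 2D IoU of the
    predicted masks against the ground-truth silhouettes, and the TSR.
    Deterministic given ``seed`` (each frame/view/level gets its own
    substream).
    """
    from .seg_net import predict_mask
    from .regression3d import predict_position

    if len(test_set) == 0:
        raise ValueError("test set is empty")
    rows = []
    for li, s2 in enumerate(levels):
        errors, ious, valid = [], [], []
        for fi, (imgs, gt_mask_pair, gt_state) in enumerate(test_set):
            pred_pair = []
            for vi, img in enumerate(imgs):
                noise = NoiseModel(
                    variance=float(s2),
                    seed=int(np.random.SeedSequence([seed, li, fi, vi]).generate_state(1)[0] % (2**31)),
                )
                noisy = add_gaussian_noise(img, noise)
                pred_pair.append(predict_mask(seg_model, noisy))
            state = predict_position(reg_model, tuple(pred_pair))
            errors.append(
                float(np.linalg.norm(state.as_array() - gt_state.as_array()))
            )
            ious.append(
                float(np.mean([iou(p, g) for p, g in zip(pred_pair, gt_mask_pair)]))
            )
            valid.append(all(bool(np.any(p.pixels)) for p in pred_pair))
        rows.append(
            {
                "s2": float(s2),
                "center_error_mm": float(np.mean(errors)),
                "iou": float(np.mean(ious)),
                "tsr_percent": tracking_success_rate(errors, tsr_threshold, valid),
            }
        )
    return NoiseSweepReport(pd.DataFrame(rows), tsr_threshold)


def ablate_segmentation(
    gray_reg_model,
    mask_pipeline: tuple,
    test_set: Sequence[tuple[tuple[DRRImage, DRRImage], TumorState]],
) -> pd.DataFrame:
    """Compare localization with and without the segmentation stage.

    ``gray_reg_model`` regresses positions directly from the grayscale DRR
    pair (the "without" arm); ``mask_pipeline`` is a (seg_model, reg_model)
    tuple forming the full cascade (the "with" arm).  Both arms see the
    identical frames; the result has per-frame per-axis errors and a
    summary row of per-axis RMS plus the combined 3D value per arm.
    """
    from .seg_net import predict_mask
    from .regression3d import predict_position

    if len(test_set) == 0:
        raise ValueError("test set is empty")
    seg_model, reg_model = mask_pipeline
    rows = []
    for fi, (imgs, gt_state) in enumerate(test_set):
        gt = gt_state.as_array()
        masks = tuple(predict_mask(seg_model, img) for img in imgs)
        with_err = predict_position(reg_model, masks).as_array() - gt
        without_err = (
            predict_position(gray_reg_model, tuple(imgs)).as_array() - gt
        )
        rows.append(
            {
                "frame": fi,
                "with_x_lr": abs(with_err[0]),
                "with_y_ap": abs(with_err[1]),
                "with_z_si": abs(with_err[2]),
                "with_3d": float(np.linalg.norm(with_err)),
                "without_x_lr": abs(without_err[0]),
                "without_y_ap": abs(without_err[1]),
                "without_z_si": abs(without_err[2]),
                "without_3d": float(np.linalg.norm(without_err)),
            }
        )
    return pd.DataFrame(rows)
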