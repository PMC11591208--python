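"""End-to-end orchestration: phantom -> augment -> project -> train -> evaluate.

Each stage is cached on disk under the run directory, keyed by a hash of
the configuration subtree it depends on (plus the master seed); re-running
with an identical configuration skips completed stages, and a changed
configuration invalidates downstream caches.  Every artifact is recorded
in a manifest with its stage hash.

All randomness derives from the single master seed through named
substreams, so a run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augmentation import (
    RegistrationConfig,
    TPSConfig,
    build_augmented_dataset,
    register_phases,
)
from .drr import DRRImage, Mask2D, ProjectionGeometry, project_drr, project_tumor_mask
from .metrics_eval import (
    EvalReport,
    NoiseSweepReport,
    dsc,
    evaluate_tracking,
    noise_robustness_sweep,
)
from .phantom import PhantomConfig, generate_phantom_4dct
from .regression3d import CentroidRegressor, predict_position, triangulate_centroid
from .seg_net import TumorSegmenter, predict_mask

__all__ = ["RunConfig", "validate_config", "run_end_to_end"]


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of an end-to-end run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tps: TPSConfig = field(default_factory=TPSConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    geometry: ProjectionGeometry = field(default_factory=ProjectionGeometry)
    n_samples: int = 7500
    split_fractions: tuple[float, float, float] = (0.92, 0.04, 0.04)
    seg_preset: str = "full"
    seg_input_size: int = 224
    seg_epochs: int = 100
    seg_learning_rate: float = 0.01
    seg_batch_size: int = 12
    reg_preset: str = "full"
    reg_input_size: int = 224
    reg_epochs: int = 50
    reg_learning_rate: float = 0.001
    reg_batch_size: int = 24
    noise_levels: tuple[float, ...] = (0.0, 5.0, 15.0, 25.0)
    tsr_threshold: float = 2.0
    seed: int = 17

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {self.split_fractions}"
            )
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples to split")
        if min(self.seg_learning_rate, self.reg_learning_rate) <= 0:
            raise ValueError("learning rates must be positive")
        if any(s2 < 0 for s2 in self.noise_levels):
            raise ValueError("noise variances must be >= 0")
        if self.tsr_threshold <= 0:
            raise ValueError("TSR threshold must be positive")

    @staticmethod
    def tiny(seed: int = 17, n_samples: int = 200) -> "RunConfig":
        """The desk-scale study: 64^3 phantom, 128^2 detector, tiny nets."""
        return RunConfig(
            phantom=PhantomConfig.tiny(seed=seed),
            tps=TPSConfig.tiny(),
            geometry=ProjectionGeometry.tiny(),
            n_samples=n_samples,
            seg_preset="tiny",
            seg_input_size=128,
            seg_epochs=18,
            reg_preset="tiny",
            reg_input_size=64,
            reg_epochs=150,
            reg_learning_rate=0.01,
            seed=seed,
        )

    def splits(self) -> tuple[int, int, int]:
        n_tr = int(round(self.n_samples * self.split_fractions[0]))
        n_va = int(round(self.n_samples * self.split_fractions[1]))
        n_te = self.n_samples - n_tr - n_va
        if min(n_tr, n_va, n_te) < 1:
            raise ValueError("every split must contain at least one sample")
        return n_tr, n_va, n_te


def _config_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _config_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_config_dict(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(_config_dict(payload), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take the package defaults; unknown keys and invalid values
    are rejected with a message listing every problem found.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a YAML mapping")
    problems = []
    kwargs = {}
    sub_types = {
        "phantom": PhantomConfig,
        "tps": TPSConfig,
        "registration": RegistrationConfig,
        "geometry": ProjectionGeometry,
    }
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in valid:
            problems.append(f"unknown key: {key}")
            continue
        if key in sub_types:
            cls = sub_types[key]
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - names
            if bad:
                problems.append(f"unknown keys under {key}: {sorted(bad)}")
                continue
            if "grid" in value and key == "phantom":
                from .core import Grid3D

                value = dict(value)
                value["grid"] = Grid3D(**value["grid"])
            try:
                kwargs[key] = cls(**{k: _tupled(v) for k, v in value.items()})
            except (TypeError, ValueError) as err:
                problems.append(f"{key}: {err}")
        else:
            kwargs[key] = _tupled(value)
    if problems:
        raise ValueError("invalid run configuration:\n  " + "\n  ".join(problems))
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid run configuration: {err}") from err


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


class _StageCache:
    def __init__(self, root: Path, manifest: dict) -> None:
        self.root = Path(root)
        self.manifest = manifest

    def path(self, stage: str) -> Path:
        p = self.root / stage
        p.mkdir(parents=True, exist_ok=True)
        return p

    def fresh(self, stage: str, key: str) -> bool:
        mark = self.root / stage / "stage.json"
        if not mark.exists():
            return False
        return json.loads(mark.read_text()).get("hash") == key

    def mark(self, stage: str, key: str, files: list[str]) -> None:
        payload = {"hash": key, "files": files, "time": time.time()}
        (self.root / stage / "stage.json").write_text(json.dumps(payload, indent=1))
        self.manifest["stages"][stage] = payload


def run_end_to_end(
    cfg: RunConfig, out_dir: str | Path, force: bool = False
) -> tuple[EvalReport, NoiseSweepReport, dict]:
    """Run the full study and return (evaluation, noise sweep, manifest).

    The evaluation report covers the phantom's respiratory phase frames
    (the tracking trajectory); the manifest additionally carries metrics on
    the held-out augmented test split and the triangulation cross-check.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _hash(cfg), "stages": {}, "metrics": {}}
    cache = _StageCache(out, manifest)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["augment", "seg", "reg", "noise"], ss.spawn(4)
        )
    }

    # ---- phantom + augmentation + projection ------------------------------
    data_key = _hash(
        (cfg.phantom, cfg.tps, cfg.registration, cfg.geometry, cfg.n_samples, cfg.seed)
    )
    data_file = cache.path("data") / "arrays.npz"
    phantom = generate_phantom_4dct(cfg.phantom)
    geom = cfg.geometry
    angles = geom.gantry_angles_deg
    if force or not (cache.fresh("data", data_key) and data_file.exists()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fields = [
                register_phases(phantom.phases[0], phantom.phases[k], cfg.registration)
                for k in range(1, phantom.n_phases)
            ]
            samples = build_augmented_dataset(
                phantom,
                cfg.n_samples,
                cfg.tps,
                seed=seeds["augment"],
                interphase_fields=fields,
            )
        imgs, masks, cents = [], [], []
        for s in samples:
            imgs.append([project_drr(s.sct, geom, a).pixels for a in angles])
            masks.append([project_tumor_mask(s.sseg, geom, a).pixels for a in angles])
            cents.append(s.gt_centroid.as_array())
        ph_imgs = [
            [project_drr(v, geom, a).pixels for a in angles] for v in phantom.phases
        ]
        ph_masks = [
            [project_tumor_mask(m, geom, a).pixels for a in angles]
            for m in phantom.masks
        ]
        np.savez_compressed(
            data_file,
            imgs=np.asarray(imgs, dtype=np.float32),
            masks=np.asarray(masks, dtype=np.uint8),
            cents=np.asarray(cents),
            ph_imgs=np.asarray(ph_imgs, dtype=np.float32),
            ph_masks=np.asarray(ph_masks, dtype=np.uint8),
        )
        cache.mark("data", data_key, [str(data_file)])
    d = np.load(data_file)
    imgs, masks, cents = d["imgs"], d["masks"], d["cents"]
    ph_imgs, ph_masks = d["ph_imgs"], d["ph_masks"]

    n_tr, n_va, n_te = cfg.splits()
    sl_tr = slice(0, n_tr)
    sl_va = slice(n_tr, n_tr + n_va)
    sl_te = slice(n_tr + n_va, cfg.n_samples)

    def drr(arr, vi):
        return DRRImage(arr, geom, angles[vi])

    def m2d(arr, vi):
        return Mask2D(arr, geom, angles[vi])

    def flat_pairs(sl):
        X, Y = [], []
        for s in range(*sl.indices(cfg.n_samples)):
            for vi in range(2):
                X.append(drr(imgs[s, vi], vi))
                Y.append(m2d(masks[s, vi], vi))
        return X, Y

    # ---- segmentation training -------------------------------------------
    seg = TumorSegmenter(
        preset=cfg.seg_preset,
        input_size=cfg.seg_input_size,
        epochs=cfg.seg_epochs,
        learning_rate=cfg.seg_learning_rate,
        batch_size=cfg.seg_batch_size,
        seed=seeds["seg"],
    )
    seg_key = _hash((data_key, seg.get_params()))
    seg_file = cache.path("seg_model") / "state.npz"
    model_cfg, _ = seg._configs()
    from .seg_net import build_seg_model

    if not force and cache.fresh("seg_model", seg_key) and seg_file.exists():
        seg.model_ = build_seg_model(model_cfg)
        state = np.load(seg_file)
        seg.model_.set_state([state[k] for k in state.files])
        seg.history_ = json.loads((cache.path("seg_model") / "history.json").read_text())
    else:
        Xtr, Ytr = flat_pairs(sl_tr)
        Xva, Yva = flat_pairs(sl_va)
        seg.fit(Xtr, Ytr, Xva, Yva)
        np.savez_compressed(seg_file, *seg.model_.get_state())
        (cache.path("seg_model") / "history.json").write_text(
            json.dumps(seg.history_)
        )
        cache.mark("seg_model", seg_key, [str(seg_file)])

    # ---- regression training ----------------------------------------------
    reg = CentroidRegressor(
        preset=cfg.reg_preset,
        input_size=cfg.reg_input_size,
        epochs=cfg.reg_epochs,
        learning_rate=cfg.reg_learning_rate,
        batch_size=cfg.reg_batch_size,
        seed=seeds["reg"],
    )
    reg_key = _hash((data_key, reg.get_params()))
    reg_file = cache.path("reg_model") / "state.npz"
    reg_model_cfg, _ = reg._configs()
    from .regression3d import build_reg_model

    def mask_pair(arrs):
        return tuple(m2d(arrs[vi], vi) for vi in range(2))

    if not force and cache.fresh("reg_model", reg_key) and reg_file.exists():
        reg.model_ = build_reg_model(reg_model_cfg)
        state = np.load(reg_file)
        reg.model_.set_state([state[k] for k in state.files])
        reg.history_ = json.loads((cache.path("reg_model") / "history.json").read_text())
    else:
        Xtr = [mask_pair(masks[s]) for s in range(*sl_tr.indices(cfg.n_samples))]
        Ytr = [cents[s] for s in range(*sl_tr.indices(cfg.n_samples))]
        Xva = [mask_pair(masks[s]) for s in range(*sl_va.indices(cfg.n_samples))]
        Yva = [cents[s] for s in range(*sl_va.indices(cfg.n_samples))]
        reg.fit(Xtr, Ytr, Xva, Yva)
        np.savez_compressed(reg_file, *reg.model_.get_state())
        (cache.path("reg_model") / "history.json").write_text(
            json.dumps(reg.history_)
        )
        cache.mark("reg_model", reg_key, [str(reg_file)])

    # ---- evaluation on the phase trajectory --------------------------------
    n_phases = phantom.n_phases
    pred_masks, gt_mask_pairs, pred_states, gt_states, labels = [], [], [], [], []
    for k in range(n_phases):
        pair = tuple(drr(ph_imgs[k, vi], vi) for vi in range(2))
        gt_pair = mask_pair(ph_masks[k])
        pm = tuple(predict_mask(seg.model_, img) for img in pair)
        pred_masks.append(pm)
        gt_mask_pairs.append(gt_pair)
        pred_states.append(predict_position(reg.model_, pm))
        gt_states.append(phantom.gt_centroids[k])
        labels.append(k / n_phases)
    report = evaluate_tracking(
        pred_masks, gt_mask_pairs, pred_states, gt_states, labels,
        tsr_threshold=cfg.tsr_threshold,
    )
    report.per_phase.to_csv(out / "evaluation_per_phase.csv", index=False)
    report.per_frame.to_csv(out / "evaluation_per_frame.csv", index=False)

    # ---- noise sweep --------------------------------------------------------
    test_frames = [
        (
            tuple(drr(ph_imgs[k, vi], vi) for vi in range(2)),
            mask_pair(ph_masks[k]),
            phantom.gt_centroids[k],
        )
        for k in range(n_phases)
    ]
    sweep = noise_robustness_sweep(
        seg.model_,
        reg.model_,
        test_frames,
        levels=cfg.noise_levels,
        seed=seeds["noise"],
        tsr_threshold=cfg.tsr_threshold,
    )
    sweep.table.to_csv(out / "noise_sweep.csv", index=False)

    # ---- held-out augmented split metrics ----------------------------------
    test_idx = range(*sl_te.indices(cfg.n_samples))
    dscs, reg_errs, tri_diffs = [], [], []
    for s in test_idx:
        for vi in range(2):
            pm = predict_mask(seg.model_, drr(imgs[s, vi], vi))
            dscs.append(dsc(pm, m2d(masks[s, vi], vi)))
        gt_pair = mask_pair(masks[s])
        p = predict_position(reg.model_, gt_pair).as_array()
        reg_errs.append(float(np.linalg.norm(p - cents[s])))
    # regressor vs triangulation oracle on the phase ground-truth masks
    for k in range(n_phases):
        gt_pair = mask_pair(ph_masks[k])
        p = predict_position(reg.model_, gt_pair).as_array()
        t = triangulate_centroid(gt_pair, geom).as_array()
        tri_diffs.append(float(np.linalg.norm(p - t)))
    manifest["metrics"] = {
        "test_split_dsc_mean": float(np.mean(dscs)),
        "test_split_reg_rmse_mm": float(np.sqrt(np.mean(np.square(reg_errs)))),
        "phase_noiseless_rmse3d_mm": report.global_means["rmse3d_mm"],
        "phase_noiseless_mean_error_mm": report.global_means["mean_error_3d_mm"],
        "regressor_vs_oracle_rmse_mm": float(np.sqrt(np.mean(np.square(tri_diffs)))),
        "noise_sweep": sweep.table.to_dict("records"),
        "tsr_threshold_mm": cfg.tsr_threshold,
        "seg_history_final": seg.history_["val_loss"][-1],
        "reg_history_final": reg.history_["val_loss"][-1],
    }
    manifest["seeds"] = seeds
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "global_means.json").write_text(json.dumps(report.global_means, indent=1))
    return report, sweep, manifest
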