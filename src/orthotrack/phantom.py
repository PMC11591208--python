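"""Synthetic 4D CT respiratory phantom.

Generates a 10-phase thorax-like dataset — body and lung ellipsoids, rib-like
arcs, a breathing diaphragm dome and a bright ellipsoidal tumor displaced
along a smooth 1-cos respiratory trajectory — together with the one-phase
tumor mask and the analytic ground-truth centroid trajectory.  Phase 0 is
end-exhale and serves as the moving/reference image for registration and
augmentation.

Intensities are arbitrary CT-like attenuation units (air 0, lung low, soft
tissue mid, ribs high); the tumor is brighter than lung so it carries clear
contrast into the projections.  Texture noise is added to intensities only,
never to masks or centroids, so the ground truth stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import Grid3D, Mask3D, TumorState, Volume3D

__all__ = [
    "PhantomConfig",
    "PhantomDataset",
    "respiratory_trajectory",
    "rasterize_tumor",
    "generate_phantom_4dct",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the synthetic respiratory phantom.

    Default amplitudes follow typical lung-tumor motion: dominantly
    superior-inferior (10 mm) with small AP/LR components.
    """

    grid: Grid3D = field(default_factory=lambda: Grid3D.centered((128, 128, 128)))
    tumor_radii: tuple[float, float, float] = (15.0, 15.0, 15.0)
    tumor_center: tuple[float, float, float] = (-28.0, 0.0, -14.0)
    tumor_intensity: float = 0.50
    body_intensity: float = 0.30
    lung_intensity: float = 0.05
    background_intensity: float = 0.0
    rib_intensity: float = 0.60
    si_amplitude: float = 10.0
    ap_amplitude: float = 3.0
    lr_amplitude: float = 2.0
    noise_sigma: float = 0.01
    vessel_sigma: float = 0.05  # amplitude (std) of parenchymal texture
    vessel_scale_mm: float = 3.0  # correlation length of the texture
    n_phases: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError("tumor radii must be positive")
        if min(self.si_amplitude, self.ap_amplitude, self.lr_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_phases < 2:
            raise ValueError("need at least 2 respiratory phases")

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.lr_amplitude, self.ap_amplitude, self.si_amplitude)

    @staticmethod
    def tiny(seed: int = 0, **overrides) -> "PhantomConfig":
        """A 64^3 @ 1 mm preset sized for CPU tests (16 mm tumor)."""
        cfg = PhantomConfig(
            grid=Grid3D.centered((64, 64, 64)),
            tumor_radii=(8.0, 8.0, 8.0),
            tumor_center=(-14.0, 0.0, -7.0),
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @staticmethod
    def small_tumor(seed: int = 0) -> "PhantomConfig":
        """Small-lesion preset (6 mm radius) at the default 128^3 grid."""
        return PhantomConfig(tumor_radii=(6.0, 6.0, 6.0), seed=seed)


@dataclass
class PhantomDataset:
    """A generated 4D phantom: phase volumes, masks and ground truth."""

    phases: list[Volume3D]
    mask_phase0: Mask3D
    gt_centroids: list[TumorState]
    config: PhantomConfig
    masks: list[Mask3D] = field(default_factory=list)  # per-phase analytic masks

    @property
    def n_phases(self) -> int:
        return len(self.phases)


def respiratory_trajectory(
    phase_fraction: float, amplitudes: Sequence[float]
) -> np.ndarray:
    """Displacement (mm) of the tumor at respiratory phase ``t`` in [0, 1).

    Per axis: ``A * (1 - cos(2 pi t)) / 2`` — zero at end-exhale (t=0),
    maximal (= A) at end-inhale (t=0.5), periodic.
    """
    t = float(phase_fraction)
    if not 0.0 <= t < 1.0:
        raise ValueError(f"phase fraction must lie in [0, 1), got {t}")
    amp = np.asarray(amplitudes, dtype=float)
    return amp * (1.0 - np.cos(2.0 * np.pi * t)) / 2.0


def _ellipsoid(grid_world: np.ndarray, center: Sequence[float], radii: Sequence[float]) -> np.ndarray:
    """Normalized squared ellipsoid coordinate; inside where <= 1."""
    d = (grid_world - np.asarray(center, dtype=float)) / np.asarray(radii, dtype=float)
    return np.einsum("...i,...i->...", d, d)


def rasterize_tumor(
    center: Sequence[float], radii: Sequence[float], grid: Grid3D
) -> Mask3D:
    """Binary ellipsoid mask: voxels whose world center lies inside the ellipsoid."""
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    inside = _ellipsoid(grid.world_grid(), center, radii) <= 1.0
    return Mask3D(grid, inside.astype(np.uint8))


def _anatomy_background(cfg: PhantomConfig, world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Static anatomy (body, lungs, ribs) and the lung region mask."""
    half = cfg.grid.extent / 2.0
    iso = cfg.grid.isocenter

    vol = np.full(cfg.grid.shape, cfg.background_intensity, dtype=np.float32)

    body_radii = half * np.array([0.82, 0.68, 0.95])
    body_q = _ellipsoid(world, iso, body_radii)
    body = body_q <= 1.0
    vol[body] = cfg.body_intensity

    # Rib-like arcs: a thin shell just inside the body surface, modulated into
    # periodic bands along SI and restricted to the anterior/posterior flanks.
    shell = (body_q > 0.80) & (body_q <= 0.95)
    z_rel = (world[..., 2] - iso[2]) / half[2]
    bands = np.cos(np.pi * 5.0 * z_rel) > 0.2
    vol[shell & bands] = cfg.rib_intensity

    lung_radii = half * np.array([0.30, 0.42, 0.62])
    lungs = np.zeros(cfg.grid.shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = iso + np.array([side * half[0] * 0.38, 0.0, half[2] * 0.05])
        lungs |= _ellipsoid(world, c, lung_radii) <= 1.0
    lungs &= body
    vol[lungs] = cfg.lung_intensity
    return vol, lungs


def generate_phantom_4dct(cfg: PhantomConfig) -> PhantomDataset:
    """Generate the full 4D dataset; deterministic given ``cfg.seed``."""
    world = cfg.grid.world_grid()
    background, lungs = _anatomy_background(cfg, world)
    iso = cfg.grid.isocenter
    half = cfg.grid.extent / 2.0

    # Validate that the tumor stays inside the grid at every phase.
    for k in range(cfg.n_phases):
        disp = respiratory_trajectory(k / cfg.n_phases, cfg.amplitudes)
        c = np.asarray(cfg.tumor_center) + disp
        lo = c - cfg.tumor_radii
        hi = c + cfg.tumor_radii
        if np.any(lo < iso - half) or np.any(hi > iso + half):
            raise ValueError(
                f"tumor leaves the grid at phase {k}: center {c}, radii {cfg.tumor_radii}"
            )

    ss = np.random.SeedSequence(cfg.seed)
    texture_seed, *phase_seeds = ss.spawn(cfg.n_phases + 1)
    phase_rngs = [np.random.default_rng(s) for s in phase_seeds]

    # Vessel-like parenchymal texture: a fixed smooth random field inside the
    # lungs that translates with the respiratory displacement, like vessels
    # and bronchi in real parenchyma.  It is what makes the phases
    # registrable away from organ boundaries.
    texture = None
    if cfg.vessel_sigma > 0:
        from scipy import ndimage as _ndi

        t_rng = np.random.default_rng(texture_seed)
        raw = t_rng.normal(size=cfg.grid.shape)
        sig_vox = np.asarray(cfg.vessel_scale_mm) / np.asarray(cfg.grid.spacing)
        smooth = _ndi.gaussian_filter(raw, sigma=sig_vox)
        texture = (smooth / smooth.std() * cfg.vessel_sigma).astype(np.float32)

    dia_base = iso[2] - half[2] * 0.42
    dia_bowl = (world[..., 0] - iso[0]) ** 2 + (world[..., 1] - iso[1]) ** 2

    phases: list[Volume3D] = []
    masks: list[Mask3D] = []
    centroids: list[TumorState] = []
    for k in range(cfg.n_phases):
        disp = respiratory_trajectory(k / cfg.n_phases, cfg.amplitudes)
        vol = background.copy()

        # Breathing diaphragm: a soft-tissue dome filling the lung bases,
        # rising/falling with the SI component of the trajectory.
        dome_z = dia_base + disp[2] - dia_bowl / (6.0 * half[0])
        dia = lungs & (world[..., 2] < dome_z)
        vol[dia] = cfg.body_intensity

        if texture is not None:
            from scipy import ndimage as _ndi

            # pull-back shift of the texture by the phase displacement
            idx = [
                np.arange(cfg.grid.shape[a]) - disp[a] / cfg.grid.spacing[a]
                for a in range(3)
            ]
            ix, iy, iz = np.meshgrid(*idx, indexing="ij")
            shifted = _ndi.map_coordinates(
                texture, [ix, iy, iz], order=1, mode="nearest"
            )
            region = lungs & ~dia
            vol[region] = np.clip(vol[region] + shifted[region], 0.0, None)

        center_k = np.asarray(cfg.tumor_center) + disp
        tumor = rasterize_tumor(center_k, cfg.tumor_radii, cfg.grid)
        vol[tumor.values > 0] = cfg.tumor_intensity

        if cfg.noise_sigma > 0:
            vol = vol + phase_rngs[k].normal(
                0.0, cfg.noise_sigma, size=vol.shape
            ).astype(np.float32)
            np.clip(vol, 0.0, None, out=vol)

        phases.append(Volume3D(cfg.grid, vol))
        masks.append(tumor)
        centroids.append(TumorState.from_array(center_k - iso))

    return PhantomDataset(
        phases=phases,
        mask_phase0=masks[0],
        gt_centroids=centroids,
        config=cfg,
        masks=masks,
    )
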