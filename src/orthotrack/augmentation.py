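"""Hybrid deformable data augmentation for 4D CT.

The augmentation recipe has two sources of deformation:

* **Inter-phase motion**: the end-exhale phase is registered to each of the
  other respiratory phases with a conventional intensity-based deformable
  registration, giving dense displacement fields ``phi_i``.  Random convex
  combinations ``phi1 = alpha*phi_i + (1-alpha)*phi_j`` simulate respiratory
  states between the measured phases.
* **Intra-phase variation**: a regularized 3D thin-plate spline (TPS) driven
  by 20-60 random control points with displacements up to 30 mm models
  changes of the tumor and surrounding tissue within a phase, giving
  ``phi2``.

Hybrid fields ``phi3 = w1*phi1 + w2*phi2`` (w1, w2 uniform in (0,1)) are
applied to the reference CT volume and its tumor mask by voxelwise vector
ADDITION of displacements (not composition of maps), producing synthetic
volume/mask pairs with exact centroid ground truth.

The TPS uses the 3D kernel U(r) = r with an affine term; the regularized
fit solves the augmented linear system with the smoothing weight ``lambda``
loaded on the kernel diagonal, which minimizes the data term plus
``lambda`` times the bending energy.  ``lambda = 0`` interpolates exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import linalg, ndimage

from .core import DVF3D, Grid3D, Mask3D, TumorState, Volume3D
from .phantom import PhantomDataset

__all__ = [
    "ControlPointSet",
    "TPSConfig",
    "TPSModel",
    "RegistrationConfig",
    "AugmentedSample",
    "register_phases",
    "combine_interphase_dvfs",
    "sample_control_points",
    "tps_fit",
    "tps_to_dvf",
    "bending_energy",
    "hybrid_dvf",
    "warp",
    "build_augmented_dataset",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ControlPointSet:
    """Paired source/target landmarks (mm) driving the TPS."""

    sources: np.ndarray  # (N, 3)
    targets: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if self.sources.shape != self.targets.shape or self.sources.shape[1] != 3:
            raise ValueError("sources and targets must both be (N, 3)")
        if len(self.sources) < 4:
            raise ValueError("a solvable 3D TPS needs at least 4 control points")

    @property
    def displacements(self) -> np.ndarray:
        return self.targets - self.sources

    def __len__(self) -> int:
        return len(self.sources)


@dataclass(frozen=True)
class TPSConfig:
    """Random intra-phase deformation parameters."""

    n_points_range: tuple[int, int] = (20, 60)
    max_displacement: float = 30.0  # mm
    lambda_smooth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_points_range
        if lo > hi or lo < 4:
            raise ValueError("control-point range must satisfy 4 <= low <= high")
        if self.max_displacement < 0:
            raise ValueError("max displacement must be >= 0")
        if self.lambda_smooth < 0:
            raise ValueError("lambda must be >= 0")

    @staticmethod
    def tiny(seed: int = 0) -> "TPSConfig":
        """Intra-phase deformation scaled to the 64 mm tiny phantom.

        The default 30 mm displacement range belongs to full-size thoraces
        (~350-450 mm across); on the tiny phantom the same proportion of the
        anatomy corresponds to about one tumor radius (8 mm), keeping the
        simulated variations 'small' relative to the anatomy as intended.
        """
        return TPSConfig(max_displacement=8.0, seed=seed)


@dataclass
class TPSModel:
    """Fitted regularized 3D TPS: radial kernel phi(r) = -r plus an affine part.

    The 3D thin-plate (biharmonic) radial basis is linear in r; the sign is
    chosen so the kernel is conditionally positive definite of order 2, which
    makes the lambda-loaded system below the classical smoothing spline.
    """

    sources: np.ndarray  # (N, 3) control sources
    kernel_weights: np.ndarray  # (N, 3)
    affine: np.ndarray  # (4, 3): rows = [const, x, y, z]
    lambda_smooth: float

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Displacement (mm) of the model at world points (M, 3)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((len(points), 3))
        chunk = 65536
        for s in range(0, len(points), chunk):
            p = points[s : s + chunk]
            r = np.linalg.norm(p[:, None, :] - self.sources[None, :, :], axis=-1)
            out[s : s + chunk] = (
                -r @ self.kernel_weights
                + self.affine[0]
                + p @ self.affine[1:]
            )
        return out


@dataclass(frozen=True)
class RegistrationConfig:
    """Deformable registration settings (demons default, B-spline option)."""

    engine: str = "demons"
    levels: int = 3
    iterations: tuple[int, ...] = (100, 80, 50)  # coarse -> fine
    # Fluid-like regularization: smoothing the per-iteration UPDATE field
    # propagates displacement into flat regions without the total-field
    # shrinkage that diffusion-like smoothing causes on piecewise-constant
    # anatomy.
    smooth_update_field: bool = True
    field_smoothing_sigma: float = 2.5  # voxels
    image_smoothing_sigma: float = 1.0  # mm, applied at the finest level
    bspline_grid_spacing: float = 20.0  # mm, B-spline engine
    bspline_iterations: int = 50

    def __post_init__(self) -> None:
        if self.engine not in ("demons", "bspline"):
            raise ValueError(f"unknown registration engine {self.engine!r}")
        if len(self.iterations) != self.levels:
            raise ValueError("need one iteration count per resolution level")


@dataclass
class AugmentedSample:
    """One synthetic CT/mask pair with its deformation provenance."""

    sct: Volume3D
    sseg: Mask3D
    gt_centroid: TumorState
    provenance: dict


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def _to_sitk(v: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(v.values.transpose(2, 1, 0).astype(np.float32))
    img.SetSpacing(tuple(float(s) for s in v.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in v.grid.origin))
    return img


def _field_to_dvf(field: sitk.Image, grid: Grid3D) -> DVF3D:
    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3), components (x, y, z) mm
    return DVF3D(grid, arr.transpose(2, 1, 0, 3).astype(np.float32))


def _demons_multiresolution(
    fixed: sitk.Image, moving: sitk.Image, cfg: RegistrationConfig
) -> sitk.Image:
    shrinks = [2 ** (cfg.levels - 1 - k) for k in range(cfg.levels)]
    disp = None
    for shrink, n_iter in zip(shrinks, cfg.iterations):
        sigma = shrink / 2.0 if shrink > 1 else cfg.image_smoothing_sigma
        f = sitk.SmoothingRecursiveGaussian(fixed, sigma) if sigma > 0 else fixed
        m = sitk.SmoothingRecursiveGaussian(moving, sigma) if sigma > 0 else moving
        if shrink > 1:
            f = sitk.Shrink(f, [shrink] * 3)
            m = sitk.Shrink(m, [shrink] * 3)
        if disp is None:
            disp = sitk.Image(f.GetSize(), sitk.sitkVectorFloat64)
            disp.CopyInformation(f)
        else:
            disp = sitk.Resample(disp, f, sitk.Transform(), sitk.sitkLinear)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(n_iter))
        if cfg.smooth_update_field:
            demons.SetSmoothDisplacementField(False)
            demons.SetSmoothUpdateField(True)
            demons.SetUpdateFieldStandardDeviations(cfg.field_smoothing_sigma)
        else:
            demons.SetSmoothDisplacementField(True)
            demons.SetStandardDeviations(cfg.field_smoothing_sigma)
        disp = demons.Execute(f, m, disp)
    return disp


def _bspline_field(
    fixed: sitk.Image, moving: sitk.Image, cfg: RegistrationConfig
) -> sitk.Image:
    phys = [sz * sp for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())]
    mesh = [max(1, int(round(p / cfg.bspline_grid_spacing))) for p in phys]
    tx = sitk.BSplineTransformInitializer(fixed, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=cfg.bspline_iterations)
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel([2 ** (cfg.levels - 1 - k) for k in range(cfg.levels)])
    reg.SetSmoothingSigmasPerLevel(list(range(cfg.levels - 1, -1, -1)))
    reg.Execute(fixed, moving)
    f2d = sitk.TransformToDisplacementFieldFilter()
    f2d.SetReferenceImage(fixed)
    return f2d.Execute(tx)


def register_phases(
    moving: Volume3D, fixed: Volume3D, reg_cfg: RegistrationConfig | None = None
) -> DVF3D:
    """Dense displacement field ``phi`` with ``warp(moving, phi) ~ fixed``.

    Multi-resolution, mean-squared-intensity-driven; deterministic given the
    configuration.  If the registration fails to reduce the mean-squared
    difference a warning is emitted and the best field is still returned.
    """
    if moving.grid != fixed.grid:
        raise ValueError("moving and fixed volumes must share a grid")
    cfg = reg_cfg or RegistrationConfig()
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    if cfg.engine == "demons":
        disp = _demons_multiresolution(f_img, m_img, cfg)
    else:
        disp = _bspline_field(f_img, m_img, cfg)
    dvf = _field_to_dvf(disp, fixed.grid)

    pre = float(np.mean((moving.values - fixed.values) ** 2))
    post = float(np.mean((warp(moving, dvf).values - fixed.values) ** 2))
    if post >= pre > 0:
        warnings.warn(
            f"registration did not reduce the mean-squared difference "
            f"({pre:.4g} -> {post:.4g}); returning the field anyway",
            stacklevel=2,
        )
    return dvf


# ---------------------------------------------------------------------------
# Field algebra
# ---------------------------------------------------------------------------


def combine_interphase_dvfs(phi_i: DVF3D, phi_j: DVF3D, alpha: float) -> DVF3D:
    """Convex mix of two inter-phase fields: ``alpha*phi_i + (1-alpha)*phi_j``."""
    if phi_i.grid != phi_j.grid:
        raise ValueError("fields must share a grid")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in the open interval (0, 1), got {alpha}")
    return DVF3D(phi_i.grid, alpha * phi_i.vectors + (1.0 - alpha) * phi_j.vectors)


def hybrid_dvf(phi1: DVF3D, phi2: DVF3D, w1: float, w2: float) -> DVF3D:
    """Weighted sum ``w1*phi1 + w2*phi2`` (voxelwise vector addition)."""
    if phi1.grid != phi2.grid:
        raise ValueError("fields must share a grid")
    return DVF3D(phi1.grid, float(w1) * phi1.vectors + float(w2) * phi2.vectors)


# ---------------------------------------------------------------------------
# Thin-plate spline
# ---------------------------------------------------------------------------


def sample_control_points(
    region: Mask3D | Grid3D, cfg: TPSConfig
) -> ControlPointSet:
    """Random control points inside a region with random displacements.

    Sources are uniform inside the region (foreground of a mask, or the full
    grid extent); each target adds a displacement with uniform direction on
    the sphere and uniform magnitude in [0, max_displacement].
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.integers(cfg.n_points_range[0], cfg.n_points_range[1] + 1))

    if isinstance(region, Mask3D):
        fg = np.argwhere(region.values > 0)
        if len(fg) == 0:
            raise ValueError("control-point region is empty")
        grid = region.grid
        picks = fg[rng.integers(0, len(fg), size=n)]
        jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
        sources = np.asarray(grid.origin) + (picks + jitter) * np.asarray(grid.spacing)
    else:
        grid = region
        lo = np.asarray(grid.origin) - np.asarray(grid.spacing) / 2.0
        sources = lo + rng.uniform(0.0, 1.0, size=(n, 3)) * grid.extent

    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    magnitudes = rng.uniform(0.0, cfg.max_displacement, size=(n, 1))
    return ControlPointSet(sources, sources + directions * magnitudes)


def tps_fit(cps: ControlPointSet, lambda_smooth: float = 0.0) -> TPSModel:
    """Closed-form regularized 3D TPS fit.

    Solves the augmented linear system with kernel matrix
    ``K_ij = phi(|p_i - p_j|)``, ``phi(r) = -r``, diagonally loaded by
    ``lambda``, plus an affine block; the solution minimizes the
    control-point data term plus ``lambda`` times the bending energy.
    ``lambda = 0`` gives exact interpolation.  The kernel weights satisfy
    the orthogonality side conditions (zero sum, zero first moments).
    """
    if lambda_smooth < 0:
        raise ValueError("lambda must be >= 0")
    p = cps.sources
    n = len(p)
    K = -np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    P = np.hstack([np.ones((n, 1)), p])  # (N, 4)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + lambda_smooth * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = cps.displacements
    try:
        sol = linalg.solve(A, b)
    except linalg.LinAlgError as err:  # pragma: no cover - exact singularity
        raise np.linalg.LinAlgError(
            f"TPS system is singular ({err}); control points may be coplanar "
            "or duplicated"
        ) from err
    if not np.all(np.isfinite(sol)) or np.linalg.norm(A @ sol - b) > 1e-5 * max(
        1.0, np.linalg.norm(b)
    ):
        raise np.linalg.LinAlgError(
            "TPS system is numerically singular; control points may be "
            "coplanar or duplicated"
        )
    return TPSModel(
        sources=p.copy(),
        kernel_weights=sol[:n],
        affine=sol[n:],
        lambda_smooth=float(lambda_smooth),
    )


def tps_to_dvf(model: TPSModel, grid: Grid3D) -> DVF3D:
    """Evaluate the TPS at every voxel's world position."""
    pts = grid.world_grid().reshape(-1, 3)
    disp = model.evaluate(pts).astype(np.float32)
    return DVF3D(grid, disp.reshape(grid.shape + (3,)))


def bending_energy(dvf: DVF3D) -> float:
    """Discretized bending energy: integral of the squared second derivatives.

    Central second differences; the six terms (three pure, three mixed
    second-order partials, each counted once) are summed per component over
    the interior and scaled by the voxel volume.  Units mm^2 * mm^3.
    """
    if any(s < 3 for s in dvf.grid.shape):
        raise ValueError("bending energy needs at least 3 voxels per axis")
    h = dvf.grid.spacing
    total = 0.0
    for c in range(3):
        f = dvf.vectors[..., c].astype(np.float64)
        # pure second derivatives
        fxx = (f[2:, :, :] - 2 * f[1:-1, :, :] + f[:-2, :, :]) / h[0] ** 2
        fyy = (f[:, 2:, :] - 2 * f[:, 1:-1, :] + f[:, :-2, :]) / h[1] ** 2
        fzz = (f[:, :, 2:] - 2 * f[:, :, 1:-1] + f[:, :, :-2]) / h[2] ** 2
        # mixed second derivatives (central first differences twice)
        fxy = (
            f[2:, 2:, :] - f[2:, :-2, :] - f[:-2, 2:, :] + f[:-2, :-2, :]
        ) / (4 * h[0] * h[1])
        fxz = (
            f[2:, :, 2:] - f[2:, :, :-2] - f[:-2, :, 2:] + f[:-2, :, :-2]
        ) / (4 * h[0] * h[2])
        fyz = (
            f[:, 2:, 2:] - f[:, 2:, :-2] - f[:, :-2, 2:] + f[:, :-2, :-2]
        ) / (4 * h[1] * h[2])
        # restrict every term to the common interior so the sums align
        total += float(np.sum(fxx[:, 1:-1, 1:-1] ** 2))
        total += float(np.sum(fyy[1:-1, :, 1:-1] ** 2))
        total += float(np.sum(fzz[1:-1, 1:-1, :] ** 2))
        total += float(np.sum(fxy[:, :, 1:-1] ** 2))
        total += float(np.sum(fxz[:, 1:-1, :] ** 2))
        total += float(np.sum(fyz[1:-1, :, :] ** 2))
    return total * dvf.grid.voxel_volume


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------


def warp(
    image: Volume3D | Mask3D, dvf: DVF3D, fill_value: float = 0.0
) -> Volume3D | Mask3D:
    """Pull-back resampling: ``out(x) = image(x + phi(x))``.

    Trilinear interpolation for volumes, nearest-neighbour for masks;
    samples falling outside the grid take ``fill_value``.
    """
    if image.grid != dvf.grid:
        raise ValueError("image and displacement field must share a grid")
    grid = image.grid
    world = grid.world_grid() + dvf.vectors
    idx = (world - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    order = 0 if isinstance(image, Mask3D) else 1
    out = ndimage.map_coordinates(
        image.values.astype(np.float32),
        [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order,
        mode="constant",
        cval=fill_value,
    )
    if isinstance(image, Mask3D):
        return Mask3D(grid, (out > 0.5).astype(np.uint8))
    return Volume3D(grid, out.astype(np.float32))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _body_region(volume: Volume3D, frac: float = 0.05) -> Mask3D:
    """Voxels with intensity above background (bottom ``frac`` of the range)."""
    vmin, vmax = float(volume.values.min()), float(volume.values.max())
    thr = vmin + frac * (vmax - vmin)
    return Mask3D(volume.grid, (volume.values > thr).astype(np.uint8))


def build_augmented_dataset(
    phantom: PhantomDataset,
    n_samples: int,
    tps_cfg: TPSConfig | None = None,
    seed: int = 0,
    reg_cfg: RegistrationConfig | None = None,
    interphase_fields: list[DVF3D] | None = None,
    max_redraws: int = 10,
) -> list[AugmentedSample]:
    """Assemble the augmented training set from a 4D phantom.

    Phase 0 is registered to each other phase (one field per fixed phase);
    each sample draws a distinct field pair (i, j), a mixing alpha, a random
    TPS, and hybrid weights (w1, w2), then warps the reference volume and
    mask.  Samples whose warped tumor mask is empty are redrawn (at most
    ``max_redraws`` times).  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if phantom.n_phases < 3:
        raise ValueError("need at least 3 phases for distinct field pairs")
    tps_cfg = tps_cfg or TPSConfig()

    moving = phantom.phases[0]
    mask0 = phantom.mask_phase0
    if interphase_fields is None:
        interphase_fields = [
            register_phases(moving, phantom.phases[k], reg_cfg)
            for k in range(1, phantom.n_phases)
        ]
    n_fields = len(interphase_fields)
    region = _body_region(moving)
    iso = moving.grid.isocenter

    master = np.random.SeedSequence(seed)
    sample_seeds = master.spawn(n_samples)

    samples: list[AugmentedSample] = []
    for s_idx, s_seed in enumerate(sample_seeds):
        rng = np.random.default_rng(s_seed)
        for attempt in range(max_redraws + 1):
            i, j = rng.choice(n_fields, size=2, replace=False)
            alpha = float(rng.uniform(0.0, 1.0))
            w1 = float(rng.uniform(0.0, 1.0))
            w2 = float(rng.uniform(0.0, 1.0))
            tps_seed = int(rng.integers(0, 2**31 - 1))
            cps = sample_control_points(region, replace(tps_cfg, seed=tps_seed))
            phi1 = combine_interphase_dvfs(
                interphase_fields[i], interphase_fields[j], alpha
            )
            phi2 = tps_to_dvf(tps_fit(cps, tps_cfg.lambda_smooth), moving.grid)
            phi3 = hybrid_dvf(phi1, phi2, w1, w2)
            sct = warp(moving, phi3)
            sseg = warp(mask0, phi3)
            if sseg.values.any():
                break
            warnings.warn(
                f"sample {s_idx}: warped tumor mask empty (attempt {attempt + 1}), "
                "redrawing",
                stacklevel=2,
            )
        else:
            raise RuntimeError(
                f"sample {s_idx}: tumor mask empty after {max_redraws} redraws"
            )
        centroid = TumorState.from_array(sseg.center_of_mass() - iso)
        samples.append(
            AugmentedSample(
                sct=sct,
                sseg=sseg,
                gt_centroid=centroid,
                provenance={
                    "i": int(i),
                    "j": int(j),
                    "alpha": alpha,
                    "w1": w1,
                    "w2": w2,
                    "tps_seed": tps_seed,
                    "n_points": len(cps),
                },
            )
        )
    return samples
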