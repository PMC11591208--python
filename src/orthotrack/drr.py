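"""Digitally reconstructed radiographs (DRRs) from 3D volumes.

Projects volumes and tumor masks onto a virtual detector at configurable
gantry angles (default the orthogonal 45/135 degree pair), and injects
test-time Gaussian noise.

Geometry convention
-------------------
The gantry rotates about the SI (z) axis.  The beam direction at angle
``theta`` (degrees, measured in the axial plane from the +y/AP axis toward
+x/LR) is ``d = (sin t, cos t, 0)``; the detector u-axis is the in-plane
normal ``u = (cos t, -sin t, 0)`` and the v-axis is +z (SI).  The detector
is centered on the isocenter, and images are indexed ``pixels[i_u, i_v]``.

The projection is a line integral of intensity (units: intensity * mm),
discretized by trilinear sampling at a step of at most ``min(spacing)/2``.
For a fixed (grid, geometry, angle) the integral is a sparse linear
operator, which is built once and cached, making projection exactly linear
and fast for batches of volumes on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .core import Grid3D, Mask3D, Volume3D

__all__ = [
    "ProjectionGeometry",
    "DRRImage",
    "Mask2D",
    "NoiseModel",
    "project_drr",
    "project_tumor_mask",
    "make_orthogonal_pair",
    "add_gaussian_noise",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Detector and beam geometry for DRR synthesis."""

    gantry_angles_deg: tuple[float, float] = (45.0, 135.0)
    detector_shape: tuple[int, int] = (512, 512)  # (n_u, n_v) pixels
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # mm
    beam_model: str = "parallel"
    source_to_isocenter: float = 1000.0  # cone beam only, mm
    source_to_detector: float = 1500.0  # cone beam only, mm

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gantry_angles_deg", tuple(float(a) for a in self.gantry_angles_deg)
        )
        object.__setattr__(
            self, "detector_shape", tuple(int(s) for s in self.detector_shape)
        )
        object.__setattr__(
            self, "pixel_spacing", tuple(float(s) for s in self.pixel_spacing)
        )
        if any(not 0.0 <= a < 360.0 for a in self.gantry_angles_deg):
            raise ValueError("gantry angles must lie in [0, 360)")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel spacing must be positive")
        if self.beam_model not in ("parallel", "cone"):
            raise ValueError(f"unknown beam model {self.beam_model!r}")
        if self.beam_model == "cone":
            if self.source_to_isocenter <= 0 or self.source_to_detector <= 0:
                raise ValueError("cone-beam source distances must be positive")

    @staticmethod
    def tiny(**overrides) -> "ProjectionGeometry":
        """128x128 @ 0.75 mm detector sized for the 64^3 phantom preset."""
        geom = ProjectionGeometry(detector_shape=(128, 128), pixel_spacing=(0.75, 0.75))
        return replace(geom, **overrides) if overrides else geom

    def pixel_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Detector-plane (u, v) coordinates of pixel centers, in mm."""
        nu, nv = self.detector_shape
        su, sv = self.pixel_spacing
        u = (np.arange(nu) - (nu - 1) / 2.0) * su
        v = (np.arange(nv) - (nv - 1) / 2.0) * sv
        return u, v


def beam_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u_hat, v_hat, d_hat) world unit vectors at a gantry angle."""
    t = np.deg2rad(angle_deg)
    d_hat = np.array([np.sin(t), np.cos(t), 0.0])
    u_hat = np.array([np.cos(t), -np.sin(t), 0.0])
    v_hat = np.array([0.0, 0.0, 1.0])
    return u_hat, v_hat, d_hat


@dataclass
class DRRImage:
    """A 2D projection image with its acquisition geometry."""

    pixels: np.ndarray  # (n_u, n_v) float
    geometry: ProjectionGeometry
    angle_deg: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != self.geometry.detector_shape:
            raise ValueError(
                f"pixel array {self.pixels.shape} does not match detector "
                f"{self.geometry.detector_shape}"
            )


@dataclass
class Mask2D:
    """A binary tumor silhouette on the detector."""

    pixels: np.ndarray  # (n_u, n_v) in {0,1}
    geometry: ProjectionGeometry
    angle_deg: float

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if not np.all(np.isin(np.unique(pix), (0, 1))):
            raise ValueError("Mask2D values must be binary {0, 1}")
        if pix.shape != self.geometry.detector_shape:
            raise ValueError(
                f"pixel array {pix.shape} does not match detector "
                f"{self.geometry.detector_shape}"
            )
        self.pixels = pix.astype(np.uint8)

    def centroid_uv(self) -> np.ndarray:
        """Foreground centroid in detector-plane mm (u, v)."""
        if not self.pixels.any():
            raise ValueError("centroid of an empty mask is undefined")
        iu, iv = np.nonzero(self.pixels)
        u_ax, v_ax = self.geometry.pixel_axes()
        return np.array([u_ax[iu].mean(), v_ax[iv].mean()])


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on a display intensity scale."""

    variance: float = 0.0  # S^2 in display units squared
    intensity_scale: tuple[float, float] = (0.0, 255.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")
        lo, hi = self.intensity_scale
        if not hi > lo:
            raise ValueError("intensity scale must be an increasing interval")


# ---------------------------------------------------------------------------
# Sparse projection operator
# ---------------------------------------------------------------------------

_OPERATOR_CACHE: dict[tuple, sparse.csr_matrix] = {}
_CACHE_LIMIT = 8


def _ray_points(grid: Grid3D, geom: ProjectionGeometry, angle_deg: float):
    """Sample positions along all rays: origins (npix, 3), direction, t steps."""
    u_hat, v_hat, d_hat = beam_axes(angle_deg)
    iso = grid.isocenter
    u_ax, v_ax = geom.pixel_axes()
    uu, vv = np.meshgrid(u_ax, v_ax, indexing="ij")

    step = min(grid.spacing) / 2.0
    # Conservative ray extent: half-diagonal of the volume around the isocenter.
    radius = float(np.linalg.norm(grid.extent)) / 2.0 + step

    if geom.beam_model == "parallel":
        origins = iso + uu[..., None] * u_hat + vv[..., None] * v_hat
        dirs = np.broadcast_to(d_hat, origins.shape)
        t = np.arange(-radius, radius + step / 2, step)
    else:  # cone
        src = iso - geom.source_to_isocenter * d_hat
        det_center = iso + (geom.source_to_detector - geom.source_to_isocenter) * d_hat
        pix = det_center + uu[..., None] * u_hat + vv[..., None] * v_hat
        rays = pix - src
        norms = np.linalg.norm(rays, axis=-1, keepdims=True)
        dirs = rays / norms
        origins = np.broadcast_to(src, pix.shape)
        t = np.arange(
            geom.source_to_isocenter - radius,
            geom.source_to_isocenter + radius + step / 2,
            step,
        )
    return origins.reshape(-1, 3), dirs.reshape(-1, 3), t, step


def _projection_operator(
    grid: Grid3D, geom: ProjectionGeometry, angle_deg: float
) -> sparse.csr_matrix:
    """Sparse (n_pixels, n_voxels) trilinear line-integral operator (cached)."""
    key = (grid, geom, float(angle_deg))
    op = _OPERATOR_CACHE.get(key)
    if op is not None:
        return op

    origins, dirs, t, step = _ray_points(grid, geom, angle_deg)
    npix = origins.shape[0]
    shape = np.asarray(grid.shape)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    nvox = int(np.prod(shape))
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)

    rows_all, cols_all, vals_all = [], [], []
    pix_index = np.arange(npix, dtype=np.int64)
    chunk = max(1, int(4e6 // npix) or 1)
    offsets = np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
    )
    for s0 in range(0, t.size, chunk):
        ts = t[s0 : s0 + chunk]
        # points: (npix, nt, 3) in fractional voxel coordinates
        pts = (
            origins[:, None, :] + dirs[:, None, :] * ts[None, :, None] - origin
        ) / spacing
        f = np.floor(pts).astype(np.int64)
        frac = (pts - f).astype(np.float32)
        # keep only samples whose 8-neighbourhood can intersect the grid
        keep = np.all((f >= -1) & (f <= shape - 1), axis=-1)
        if not keep.any():
            continue
        f = f[keep]
        frac = frac[keep]
        rows = np.broadcast_to(pix_index[:, None], keep.shape)[keep]
        for off in offsets:
            corner = f + off
            w = np.prod(
                np.where(off == 1, frac, 1.0 - frac), axis=-1, dtype=np.float32
            )
            valid = np.all((corner >= 0) & (corner < shape), axis=-1) & (w > 0)
            if not valid.any():
                continue
            cols_all.append((corner[valid] * strides).sum(axis=-1))
            rows_all.append(rows[valid])
            vals_all.append(w[valid] * np.float32(step))

    if rows_all:
        op = sparse.coo_matrix(
            (
                np.concatenate(vals_all),
                (np.concatenate(rows_all), np.concatenate(cols_all)),
            ),
            shape=(npix, nvox),
        ).tocsr()
    else:
        op = sparse.csr_matrix((npix, nvox), dtype=np.float32)

    if len(_OPERATOR_CACHE) >= _CACHE_LIMIT:
        _OPERATOR_CACHE.pop(next(iter(_OPERATOR_CACHE)))
    _OPERATOR_CACHE[key] = op
    return op


def project_drr(v: Volume3D, geom: ProjectionGeometry, angle_deg: float) -> DRRImage:
    """Line-integral projection of a volume onto the detector at one angle."""
    if not np.all(np.isfinite(v.values)):
        raise ValueError("volume intensities must be finite")
    op = _projection_operator(v.grid, geom, float(angle_deg))
    pix = op @ v.values.reshape(-1).astype(np.float32)
    return DRRImage(pix.reshape(geom.detector_shape), geom, float(angle_deg))


def project_tumor_mask(m: Mask3D, geom: ProjectionGeometry, angle_deg: float) -> Mask2D:
    """Binary silhouette: any ray touching the tumor is foreground."""
    img = project_drr(Volume3D(m.grid, m.values.astype(np.float32)), geom, angle_deg)
    return Mask2D((img.pixels > 1e-6).astype(np.uint8), geom, float(angle_deg))


def make_orthogonal_pair(
    v: Volume3D, m: Mask3D | None, geom: ProjectionGeometry
) -> tuple[DRRImage, DRRImage, Mask2D | None, Mask2D | None]:
    """Project a volume (and optional tumor mask) at both configured angles."""
    if len(geom.gantry_angles_deg) != 2:
        raise ValueError("orthogonal projection requires exactly 2 gantry angles")
    a1, a2 = geom.gantry_angles_deg
    img1 = project_drr(v, geom, a1)
    img2 = project_drr(v, geom, a2)
    m1 = project_tumor_mask(m, geom, a1) if m is not None else None
    m2 = project_tumor_mask(m, geom, a2) if m is not None else None
    return img1, img2, m1, m2


def add_gaussian_noise(img: DRRImage, noise: NoiseModel) -> DRRImage:
    """Add i.i.d. Gaussian noise of variance S^2 on the display scale.

    The image is affinely mapped onto ``intensity_scale`` (an image with no
    dynamic range is taken to be on the display scale already), noise is
    added, values are clipped to the scale, and the map is inverted.
    ``variance == 0`` returns the image bit-identically.
    """
    if noise.variance == 0.0:
        return DRRImage(img.pixels.copy(), img.geometry, img.angle_deg)
    lo, hi = noise.intensity_scale
    pmin = float(img.pixels.min())
    pmax = float(img.pixels.max())
    if pmax > pmin:
        scale = (hi - lo) / (pmax - pmin)
        disp = lo + (img.pixels.astype(np.float64) - pmin) * scale
    else:
        scale = None
        disp = img.pixels.astype(np.float64)
    rng = np.random.default_rng(noise.seed)
    disp = disp + rng.normal(0.0, np.sqrt(noise.variance), size=disp.shape)
    np.clip(disp, lo, hi, out=disp)
    if scale is not None:
        out = pmin + (disp - lo) / scale
    else:
        out = disp
    return DRRImage(out.astype(np.float32), img.geometry, img.angle_deg)
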