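"""Small 2D image helpers shared by the two networks."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def resize2d(img: np.ndarray, size: int, order: int = 1) -> np.ndarray:
    """Resize a 2D array to (size, size).

    Integer down-scaling uses block averaging (area interpolation), which
    preserves fractional occupancy of binary masks; everything else goes
    through spline interpolation of the given order.
    """
    h, w = img.shape
    if (h, w) == (size, size):
        return img.astype(np.float32, copy=True)
    if h == w and h % size == 0 and order > 0:
        f = h // size
        return (
            img.reshape(size, f, size, f).mean(axis=(1, 3)).astype(np.float32)
        )
    zoom = (size / h, size / w)
    return ndimage.zoom(img.astype(np.float32), zoom, order=order).astype(np.float32)


def zscore(img: np.ndarray) -> np.ndarray:
    """Per-image zero-mean/unit-variance normalization (std floor 1e-6)."""
    std = float(img.std())
    return ((img - img.mean()) / max(std, 1e-6)).astype(np.float32)


def unit_sum(img: np.ndarray) -> np.ndarray:
    """Scale a non-negative image to unit total mass (empty images untouched)."""
    s = float(img.sum())
    if s <= 0:
        return img.astype(np.float32, copy=True)
    return (img / s).astype(np.float32)
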