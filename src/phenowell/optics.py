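"""Radial lens ("fish-eye") distortion and its correction.

The single-coefficient *division model* is used: a distorted image point
``p_d`` at radius ``r_d`` from the distortion centre maps to the undistorted
point ``p_u = c + (p_d - c) / (1 + k * r_d**2)``.  The model is attractive
because undistortion is algebraic and the forward (distorting) map has a
closed-form inverse, so a synthetic image can be distorted and corrected
with exactly matched models.  ``k`` is in units of px^-2; typical barrel
distortion for this kind of camera is of order 1e-8..1e-7.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["undistort_points", "distort_points", "correct_fisheye", "max_invertible_k"]


def max_invertible_k(image_shape: tuple[int, int],
                     center: tuple[float, float] | None = None) -> float:
    """Largest k for which the forward map is real over the whole raster.

    The forward solve requires ``1 - 4 k r_u**2 >= 0`` at the most distant
    undistorted corner; beyond that the model folds and is not invertible.
    """
    h, w = image_shape[:2]
    cx, cy = center if center is not None else ((w - 1) / 2, (h - 1) / 2)
    r2 = max((cx - x) ** 2 + (cy - y) ** 2 for x in (0, w - 1) for y in (0, h - 1))
    return 1.0 / (4.0 * r2)


def undistort_points(pts: np.ndarray, k: float, center: tuple[float, float]) -> np.ndarray:
    """Map distorted pixel coordinates (x, y) to undistorted ones."""
    pts = np.asarray(pts, dtype=float)
    d = pts - np.asarray(center, dtype=float)
    r2 = np.sum(d * d, axis=-1, keepdims=True)
    denom = 1.0 + k * r2
    if np.any(denom <= 0):
        raise ValueError("distortion not invertible over these points (1 + k r^2 <= 0)")
    return np.asarray(center) + d / denom


def distort_points(pts: np.ndarray, k: float, center: tuple[float, float]) -> np.ndarray:
    """Map undistorted pixel coordinates (x, y) to distorted ones.

    Closed-form inverse of :func:`undistort_points`: with ``r_u = |p_u - c|``,
    the distorted radius solves ``k r_u r_d^2 - r_d + r_u = 0``; the root
    continuous at k = 0 is taken.
    """
    pts = np.asarray(pts, dtype=float)
    if k == 0:
        return pts.copy()
    d = pts - np.asarray(center, dtype=float)
    ru = np.sqrt(np.sum(d * d, axis=-1, keepdims=True))
    disc = 1.0 - 4.0 * k * ru**2
    if np.any(disc < 0):
        raise ValueError("distortion coefficient too large: forward map is complex")
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(ru > 0, (1.0 - np.sqrt(disc)) / (2.0 * k * ru**2), 1.0)
    return np.asarray(center) + d * scale


def correct_fisheye(image: np.ndarray, k: float,
                    center: tuple[float, float] | None = None) -> np.ndarray:
    """Undo radial division-model distortion.

    Each output (undistorted) pixel samples the input at its forward-distorted
    position by bilinear interpolation; the raster dimensions are unchanged
    and k = 0 returns an identical copy.  The distortion centre defaults to
    the image centre (the centre pixel is a fixed point for any k).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if center is None:
        center = ((w - 1) / 2, (h - 1) / 2)
    if k == 0:
        return image.copy()
    if k > max_invertible_k(image.shape, center):
        raise ValueError("distortion coefficient too large for this image size")
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = distort_points(np.stack([xx.ravel(), yy.ravel()], axis=1), k, center)
    # map_coordinates expects (row, col) = (y, x)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    if image.ndim == 2:
        out = ndimage.map_coordinates(image.astype(float), coords, order=1, mode="nearest")
    else:
        out = np.stack(
            [ndimage.map_coordinates(image[..., c].astype(float), coords, order=1,
                                     mode="nearest")
             for c in range(image.shape[2])], axis=-1)
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out
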