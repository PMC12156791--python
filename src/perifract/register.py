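"""Rigid intensity-based registration of serial radiographs.

Each follow-up image is aligned to its patient's baseline with a rigid-body
transform (translation + rotation about the image center), found by
minimizing the mean squared intensity difference over a coarse-to-fine
image pyramid.  Serial periapical films taken with a paralleling device
differ by small in-plane shifts and rotations, so the rigid family is the
appropriate one; scaling and shear are deliberately excluded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .datatypes import Radiograph, RigidTransform
from .errors import InputError, RegistrationError

__all__ = ["register_rigid", "resample", "mean_squared_difference"]


def _sample_coords(shape: tuple[int, int], transform: RigidTransform) -> np.ndarray:
    """Pull-warp coordinates: for each output pixel, where to sample the input.

    The forward map sends input point p to ``R(theta)(p - c) + c + t``; the
    output image therefore samples the input at the inverse map.
    """
    h, w = shape
    inv = transform.inverse()
    yy, xx = np.mgrid[0:h, 0:w]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    src = inv.apply(pts, center)
    return src.reshape(h, w, 2)


def resample(
    moving: Radiograph, transform: RigidTransform, *, return_valid: bool = False
):
    """Apply a rigid transform to a radiograph by bilinear interpolation.

    Out-of-support pixels are filled with 0; ``return_valid`` additionally
    returns the boolean mask of pixels whose value came from inside the
    source image.  Metadata is preserved.
    """
    h, w = moving.shape
    if transform.is_identity():
        out = moving.pixels.copy()
        valid = np.ones((h, w), dtype=bool)
    else:
        src = _sample_coords((h, w), transform)
        sx, sy = src[..., 0], src[..., 1]
        vals = ndimage.map_coordinates(
            moving.pixels.astype(float), [sy, sx], order=1, mode="constant", cval=0.0
        )
        valid = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
        out = np.round(np.clip(vals, 0, 255)).astype(np.uint8)
        out[~valid] = 0
    result = moving.with_pixels(out)
    if return_valid:
        return result, valid
    return result


def mean_squared_difference(a: np.ndarray, b: np.ndarray, valid=None) -> float:
    """MSE between two images, optionally restricted to a validity mask."""
    d = a.astype(float) - b.astype(float)
    if valid is not None:
        d = d[valid]
    if d.size == 0:
        return float("inf")
    return float(np.mean(d * d))


def _downsample(img: np.ndarray) -> np.ndarray:
    """2x2 block-mean downsampling (odd trailing row/col dropped)."""
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return img.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def _pyramid(img: np.ndarray, min_size: int = 32) -> list[np.ndarray]:
    levels = [img.astype(float)]
    while min(levels[-1].shape) // 2 >= min_size:
        levels.append(_downsample(levels[-1]))
    return levels  # levels[0] is full resolution


def _cost(params, moving: np.ndarray, fixed: np.ndarray) -> float:
    dx, dy, theta = params
    t = RigidTransform(dx=dx, dy=dy, theta=theta)
    src = _sample_coords(moving.shape, t)
    sx, sy = src[..., 0], src[..., 1]
    vals = ndimage.map_coordinates(moving, [sy, sx], order=1, mode="constant", cval=0.0)
    h, w = moving.shape
    valid = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    if valid.sum() < 0.25 * valid.size:
        return float("inf")
    return mean_squared_difference(vals, fixed, valid)


def register_rigid(
    moving: Radiograph,
    fixed: Radiograph,
    *,
    min_pyramid_size: int = 32,
    xtol: float = 1e-4,
) -> RigidTransform:
    """Find the rigid transform aligning ``moving`` onto ``fixed``.

    Coarse-to-fine: the translation/rotation is estimated on 2x-downsampled
    pyramid levels (coarsest level at least ``min_pyramid_size`` px on its
    short side) and refined at each finer level by Powell minimization of
    the mean squared difference.  The optimum's objective value is attached
    to the returned transform for before/after comparisons.

    Raises :class:`RegistrationError` for constant images and
    :class:`InputError` on dimension mismatch.
    """
    if moving.shape != fixed.shape:
        raise InputError("moving and fixed images must have identical dimensions")
    if moving.pixels.std() == 0 or fixed.pixels.std() == 0:
        raise RegistrationError("registration is undefined for a constant image")

    mov_pyr = _pyramid(moving.pixels, min_pyramid_size)
    fix_pyr = _pyramid(fixed.pixels, min_pyramid_size)
    est = np.zeros(3)
    for level in range(len(mov_pyr) - 1, -1, -1):
        scale = 2**level
        start = est.copy()
        start[:2] /= scale  # translation shrinks with downsampling; angle does not
        res = optimize.minimize(
            _cost, start, args=(mov_pyr[level], fix_pyr[level]),
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-8, "maxiter": 200},
        )
        est = res.x.copy()
        est[:2] *= scale
    objective = _cost(est, mov_pyr[0], fix_pyr[0])
    return RigidTransform(
        dx=float(est[0]), dy=float(est[1]), theta=float(est[2]), objective=objective
    )
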