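"""The preprocessing chain: ROI patch -> binary skeletonized trabecular pattern.

The chain is the classic local-brightness-correction recipe for trabecular
texture on intraoral radiographs:

1. blur the patch with a large Gaussian (35x35 kernel) to capture the slow
   brightness field (soft-tissue thickness, exposure gradients);
2. subtract the blurred image from the original and add 128, leaving a
   brightness-standardized high-pass residual centred on mid-gray;
3. binarize at 128 — foreground is the locally-bright phase, i.e. trabeculae;
4. erode then dilate once (3x3 opening) to remove speckle noise;
5. outline the binary pattern and skeletonize it to 1-px-wide centerlines.

Steps 1-2 make the output invariant to any global brightness shift of the
input (up to saturation), which is what lets serial films with different
exposures be compared at all.  All intermediate stages are computed in
floating point; quantization happens only at the binarization step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _zhang_skeletonize

from .datatypes import CHAIN_STEPS, RoiPatch, SkeletonMask
from .errors import InputError

__all__ = [
    "ChainParams",
    "gaussian_blur",
    "subtract_and_offset",
    "binarize",
    "erode_then_dilate",
    "outline",
    "outline_and_skeletonize",
    "run_chain",
]

#: decimals kept before the threshold comparison.  The Gaussian kernel's
#: weights sum to 1 only to ~1e-16, so a global brightness shift c leaks
#: into the residual at ~c*1e-15; rounding far above that noise floor (but
#: far below any real intensity difference) makes binarization exactly
#: shift-invariant.
_THRESHOLD_DECIMALS = 6


@dataclass(frozen=True)
class ChainParams:
    """Tunable parameters of the chain.

    ``kernel_size`` is the Gaussian kernel's full width in pixels.  ``sigma``
    defaults to ``kernel_size / 6`` — the convention that a Gaussian's
    effective support is +-3 sigma; legacy reimplementations disagree on
    this mapping, so sigma is exposed directly.  ``threshold`` is the gray
    level at which the offset residual is binarized; values >= threshold are
    foreground (so an exactly flat field at 128 is foreground).
    """

    kernel_size: int = 35
    sigma: float | None = None
    threshold: float = 128.0
    selem: tuple[int, int] = (3, 3)

    @property
    def effective_sigma(self) -> float:
        return self.kernel_size / 6.0 if self.sigma is None else self.sigma

    @property
    def radius(self) -> int:
        return (self.kernel_size - 1) // 2

    def to_dict(self) -> dict:
        return {
            "kernel_size": self.kernel_size,
            "sigma": self.effective_sigma,
            "threshold": self.threshold,
            "selem": list(self.selem),
        }


def _as_float(patch) -> np.ndarray:
    px = patch.pixels if isinstance(patch, RoiPatch) else np.asarray(patch)
    if px.ndim != 2 or px.size == 0:
        raise InputError("patch must be a non-empty 2-D array")
    return px.astype(float)


def gaussian_blur(patch, params: ChainParams = ChainParams()) -> np.ndarray:
    """Gaussian smoothing with a ``kernel_size`` x ``kernel_size`` discrete
    kernel, reflective borders; output kept at full precision for the
    subtraction step."""
    px = _as_float(patch)
    return ndimage.gaussian_filter(
        px, sigma=params.effective_sigma, mode="reflect", radius=params.radius
    )


def subtract_and_offset(original, blurred) -> np.ndarray:
    """``original - blurred + 128``: the brightness-standardized residual.

    Kept unclipped in floating point; its mean is ~128 for large patches.
    """
    orig = _as_float(original)
    blur = np.asarray(blurred, dtype=float)
    if orig.shape != blur.shape:
        raise InputError("original and blurred patches must have the same shape")
    return orig - blur + 128.0


def binarize(offset_patch: np.ndarray, params: ChainParams = ChainParams()) -> np.ndarray:
    """Threshold the residual at 128 gray levels: ``value >= 128`` is
    foreground (locally-bright phase = trabeculae)."""
    v = np.round(np.asarray(offset_patch, dtype=float), _THRESHOLD_DECIMALS)
    return v >= params.threshold


def erode_then_dilate(binary: np.ndarray, params: ChainParams = ChainParams()) -> np.ndarray:
    """One erosion then one dilation with a 3x3 square structuring element —
    a morphological opening that removes isolated speckle pixels."""
    selem = np.ones(params.selem, dtype=bool)
    eroded = ndimage.binary_erosion(binary, selem, border_value=0)
    return ndimage.binary_dilation(eroded, selem, border_value=0)


def outline(binary: np.ndarray) -> np.ndarray:
    """Perimeter extraction: foreground pixels with at least one background
    4-neighbor (pixels beyond the border count as background)."""
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(binary, cross, border_value=0)
    return binary & ~interior


def _prune_square_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove the rare 2x2 all-foreground blocks thinning can leave behind.

    Deleting the corner pixel of such a block never disconnects the pattern:
    its two block-neighbors stay 8-connected through the diagonal pixel.
    Scanning order (top-left to bottom-right, deleting the bottom-right
    corner) makes the cleanup deterministic.
    """
    skel = skel.copy()
    while True:
        blocks = skel[:-1, :-1] & skel[:-1, 1:] & skel[1:, :-1] & skel[1:, 1:]
        ys, xs = np.nonzero(blocks)
        if ys.size == 0:
            return skel
        skel[ys[0] + 1, xs[0] + 1] = False


def outline_and_skeletonize(binary: np.ndarray) -> np.ndarray:
    """Outline the binary pattern, then thin it to 1-px-wide centerlines
    (Zhang–Suen thinning, with a deterministic cleanup guaranteeing no 2x2
    foreground block survives)."""
    ol = outline(np.asarray(binary, dtype=bool))
    skel = _zhang_skeletonize(ol, method="zhang")
    return _prune_square_blocks(skel)


def run_chain(patch, params: ChainParams = ChainParams()) -> SkeletonMask:
    """Run the full chain on an ROI patch and return the skeleton mask with
    its provenance (the canonical step list and active parameters)."""
    px = _as_float(patch)
    blurred = gaussian_blur(px, params)
    residual = subtract_and_offset(px, blurred)
    binary = binarize(residual, params)
    opened = erode_then_dilate(binary, params)
    skel = outline_and_skeletonize(opened)
    return SkeletonMask(
        pixels=skel, provenance=list(CHAIN_STEPS), params=params.to_dict()
    )
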