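"""The preprocessing chain: stage-by-stage oracles and the invariances the
method's robustness rests on."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from perifract.datatypes import CHAIN_STEPS
from perifract.errors import InputError
from perifract.preprocess import (
    ChainParams,
    binarize,
    erode_then_dilate,
    gaussian_blur,
    outline,
    outline_and_skeletonize,
    run_chain,
    subtract_and_offset,
)


def _direct_gaussian_conv(img: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    """Independent oracle: separable sampled-Gaussian convolution with
    reflect padding, written as explicit sums."""
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    k /= k.sum()
    pad = np.pad(img.astype(float), radius, mode="reflect")
    rows = np.zeros((img.shape[0], pad.shape[1]))
    for i in range(img.shape[0]):
        for j in range(pad.shape[1]):
            rows[i, j] = (pad[i : i + 2 * radius + 1, j] * k).sum()
    out = np.zeros(img.shape)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = (rows[i, j : j + 2 * radius + 1] * k).sum()
    return out


def _brute_opening(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: 3x3 erosion then dilation by set arithmetic."""
    h, w = mask.shape
    padded = np.pad(mask, 1, constant_values=False)
    eroded = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            eroded[i, j] = padded[i : i + 3, j : j + 3].all()
    padded = np.pad(eroded, 1, constant_values=False)
    dilated = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            dilated[i, j] = padded[i : i + 3, j : j + 3].any()
    return dilated


class TestBlur:
    def test_constant_patch_unchanged(self):
        patch = np.full((30, 10), 80, np.uint8)
        out = gaussian_blur(patch)
        assert np.allclose(out, 80.0)

    def test_single_bright_pixel_matches_direct_convolution(self):
        img = np.zeros((24, 24))
        img[12, 12] = 255.0
        params = ChainParams(kernel_size=11)
        got = gaussian_blur(img, params)
        want = _direct_gaussian_conv(img, params.effective_sigma, params.radius)
        assert np.allclose(got, want, atol=1e-9)
        assert got.sum() == pytest.approx(255.0, abs=1e-6)  # mass conserved

    def test_checkerboard_flattens_to_mean(self):
        patch = np.indices((30, 10)).sum(axis=0) % 2 * 50 + 50
        out = gaussian_blur(patch.astype(np.uint8))
        assert np.ptp(out) < 1.0
        assert out.mean() == pytest.approx(75.0, abs=1.0)

    def test_default_sigma_is_kernel_over_six(self):
        assert ChainParams().effective_sigma == pytest.approx(35 / 6)
        assert ChainParams(sigma=35.0).effective_sigma == 35.0


class TestSubtractAndThreshold:
    def test_constant_input_gives_uniform_128(self):
        patch = np.full((30, 10), 93.0)
        out = subtract_and_offset(patch, gaussian_blur(patch))
        assert np.allclose(out, 128.0)
        assert binarize(out).all()  # 128 itself is foreground

    def test_uniform_positive_residual(self):
        orig = np.full((30, 10), 60.0)
        out = subtract_and_offset(orig, orig - 10.0)
        assert np.allclose(out, 138.0)

    def test_just_below_threshold_is_background(self):
        assert not binarize(np.full((5, 5), 127.9)).any()

    def test_stripes_preserved_exactly(self):
        offset = np.where(np.arange(10)[None, :] % 2 == 0, 120.0, 136.0)
        offset = np.broadcast_to(offset, (30, 10))
        out = binarize(offset)
        assert np.array_equal(out, offset >= 128)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            subtract_and_offset(np.zeros((10, 10)), np.zeros((5, 5)))


class TestOpening:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((15, 15), bool)
        mask[7, 7] = True
        assert not erode_then_dilate(mask).any()

    def test_large_square_preserved(self):
        mask = np.zeros((15, 15), bool)
        mask[5:10, 5:10] = True
        assert np.array_equal(erode_then_dilate(mask), mask)

    def test_random_speckle_matches_set_arithmetic_oracle(self, rng):
        mask = rng.random((20, 14)) < 0.4
        assert np.array_equal(erode_then_dilate(mask), _brute_opening(mask))


class TestOutlineSkeleton:
    def test_empty_in_empty_out(self):
        assert not outline_and_skeletonize(np.zeros((20, 20), bool)).any()

    def test_disc_outline_skeleton_is_closed_ring(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disc = (yy - 16) ** 2 + (xx - 16) ** 2 <= 8**2
        skel = outline_and_skeletonize(disc)
        # closed curve: every skeleton pixel has exactly two 8-neighbors
        padded = np.pad(skel, 1)
        for i, j in zip(*np.nonzero(skel)):
            neigh = padded[i : i + 3, j : j + 3].sum() - 1
            assert neigh == 2
        # and the interior/exterior stay separated (a genuine cycle);
        # 4-connected background is the topological dual of the
        # 8-connected curve
        from scipy import ndimage
        _, n = ndimage.label(~skel)
        assert n == 2

    def test_thin_line_unchanged(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 3:17] = True
        assert np.array_equal(outline_and_skeletonize(mask), mask)

    def test_outline_is_pixels_with_background_4_neighbor(self, rng):
        mask = rng.random((18, 12)) < 0.6
        got = outline(mask)
        padded = np.pad(mask, 1, constant_values=False)
        for i in range(18):
            for j in range(12):
                four = [padded[i, j + 1], padded[i + 2, j + 1],
                     padded[i + 1, j], padded[i + 1, j + 2]]
                assert got[i, j] == (mask[i, j] and not all(four))


class TestRunChain:
    def test_constant_patch_yields_thin_frame(self):
        mask = run_chain(np.full((30, 10), 90, np.uint8))
        px = mask.pixels
        assert px.sum() > 0
        assert px[0, 1:-1].all() or px[1, 1:-1].all()  # top frame edge survives
        blocks = px[:-1, :-1] & px[:-1, 1:] & px[1:, :-1] & px[1:, 1:]
        assert not blocks.any()

    def test_provenance_is_canonical_order(self, trabecular_patch):
        mask = run_chain(trabecular_patch)
        assert tuple(mask.provenance) == CHAIN_STEPS
        assert mask.params["kernel_size"] == 35

    @given(c=st.integers(-20, 20))
    def test_brightness_shift_invariance(self, c):
        from perifract.synth import TrabecularPhantomParams, make_phantom

        img = make_phantom(
            TrabecularPhantomParams(width=96, height=96, hurst=0.4, seed=7,
                                    mean_gray=120, contrast=25, noise_sd=2)
        )
        patch = img.pixels[20:50, 30:40].astype(int) + c
        assert patch.min() >= 0 and patch.max() <= 255
        ref = run_chain(img.pixels[20:50, 30:40])
        shifted = run_chain(patch.astype(np.uint8))
        assert np.array_equal(ref.pixels, shifted.pixels)

    def test_skeleton_has_no_2x2_blocks(self):
        from perifract.synth import TrabecularPhantomParams, make_phantom

        for seed in range(8):
            img = make_phantom(
                TrabecularPhantomParams(width=96, height=96, hurst=0.3, seed=seed)
            )
            px = run_chain(img.pixels[:64, :64]).pixels
            blocks = px[:-1, :-1] & px[:-1, 1:] & px[1:, :-1] & px[1:, 1:]
            assert not blocks.any()

    def test_rougher_texture_yields_more_skeleton(self):
        from perifract.synth import TrabecularPhantomParams, make_phantom

        counts = {}
        for hurst in (0.3, 0.8):
            n = []
            for seed in range(20):
                img = make_phantom(
                    TrabecularPhantomParams(width=96, height=96, hurst=hurst,
                                            seed=seed)
                )
                n.append(run_chain(img.pixels[:64, :64]).n_foreground())
            counts[hurst] = np.median(n)
        assert counts[0.3] > counts[0.8]
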