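"""Generator contracts: determinism, phantom structure, panel realism,
exact-dimension fixtures."""

import math

import numpy as np
import pytest

from perifract.datatypes import RigidTransform
from perifract.errors import ConfigurationError, SizingError
from perifract.synth import (
    DEFAULT_STUDY_PANEL,
    ImplantGeometry,
    LongitudinalScenario,
    TrabecularPhantomParams,
    make_exact_fractal,
    make_jittered_view,
    make_phantom,
    make_series,
    simulate_fd_records,
)


class TestPhantom:
    def test_zero_variance_texture_is_constant(self):
        p = TrabecularPhantomParams(width=96, height=96, contrast=0, noise_sd=0,
                                    mean_gray=90)
        img = make_phantom(p)
        assert np.all(img.pixels == 90)

    def test_same_params_same_seed_bit_identical(self):
        p = TrabecularPhantomParams(width=96, height=96, hurst=0.3, seed=42)
        a, b = make_phantom(p), make_phantom(p)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self):
        base = dict(width=96, height=96, hurst=0.3)
        a = make_phantom(TrabecularPhantomParams(seed=1, **base))
        b = make_phantom(TrabecularPhantomParams(seed=2, **base))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_implant_renders_near_saturated_column(self):
        geo = ImplantGeometry(axis_x=48, top_row=10, radius=6)
        p = TrabecularPhantomParams(width=96, height=96, implant=geo, noise_sd=0)
        img = make_phantom(p)
        assert np.all(img.pixels[40:80, 46:51] >= 245)

    @pytest.mark.parametrize("w,h", [(95, 128), (128, 64)])
    def test_too_small_for_rois_rejected(self, w, h):
        with pytest.raises(SizingError):
            TrabecularPhantomParams(width=w, height=h).validate()

    @pytest.mark.parametrize("hurst", [0.0, 1.0, -0.2])
    def test_hurst_out_of_range_rejected(self, hurst):
        with pytest.raises(ConfigurationError):
            TrabecularPhantomParams(hurst=hurst).validate()

    def test_jittered_view_has_no_empty_border(self):
        p = TrabecularPhantomParams(width=96, height=96, hurst=0.5, seed=9, noise_sd=0)
        img = make_jittered_view(p, RigidTransform(dx=8, dy=-6, theta=4))
        # zero-filled wedges would put exact-0 runs in the corners
        assert (img.pixels == 0).sum() == 0


class TestSeries:
    def test_flat_scenario_visits_identical(self):
        sc = LongitudinalScenario(
            n_patients=2, misalignment_sd=(0, 0), brightness_jitter_sd=0,
            complexity_trajectory={}, noise_sd=0, image_size=(96, 96), seed=1,
        )
        images, truth = make_series(sc)
        by_pid = {}
        for img in images:
            by_pid.setdefault(img.patient_id, []).append(img.pixels)
        for pixels in by_pid.values():
            for px in pixels[1:]:
                assert np.array_equal(px, pixels[0])

    def test_study_panel_counts(self):
        sc = LongitudinalScenario(panel=DEFAULT_STUDY_PANEL, seed=0)
        schedules = sc.schedules()
        assert len(schedules) == 77
        assert sum(len(s) for s in schedules) == 215
        months = [m for s in schedules for m in s]
        assert [months.count(m) for m in (0, 3, 6, 12)] == [77, 31, 64, 43]

    def test_ground_truth_tracks_complexity_offsets(self):
        sc = LongitudinalScenario(
            n_patients=3, complexity_trajectory={12: 0.15}, image_size=(96, 96),
            misalignment_sd=(0, 0), brightness_jitter_sd=0, seed=2,
        )
        _, truth = make_series(sc)
        base = truth.loc[truth.timepoint_months == 0, "true_hurst"]
        month12 = truth.loc[truth.timepoint_months == 12, "true_hurst"]
        assert month12.mean() < base.mean()
        assert (truth.loc[truth.timepoint_months == 12, "true_offset"] == 0.15).all()

    def test_series_deterministic(self):
        sc = LongitudinalScenario(n_patients=2, image_size=(96, 96), seed=11)
        (ia, ta), (ib, tb) = make_series(sc), make_series(sc)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(ia, ib))
        assert ta.equals(tb)

    def test_schedule_without_baseline_rejected(self):
        with pytest.raises(ConfigurationError):
            LongitudinalScenario(panel=((2, (3, 6)),)).schedules()

    def test_schedule_without_followup_rejected(self):
        with pytest.raises(ConfigurationError):
            LongitudinalScenario(panel=((1, (0,)),)).schedules()

    def test_empty_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            LongitudinalScenario(panel=((1, ()),)).schedules()


def _carpet_membership(row: int, col: int, level: int) -> bool:
    """Independent oracle: a pixel is in the Sierpinski carpet iff no base-3
    digit position has both coordinates equal to 1."""
    for _ in range(level):
        if row % 3 == 1 and col % 3 == 1:
            return False
        row //= 3
        col //= 3
    return True


class TestExactFractals:
    def test_point_fixture(self):
        mask, dim = make_exact_fractal("point", 64)
        assert mask.n_foreground() == 1
        assert dim == 0.0

    def test_filled_rect_fixture(self):
        mask, dim = make_exact_fractal("filled_rect", 64)
        assert mask.n_foreground() == 64 * 64
        assert dim == 2.0

    def test_line_fixture(self):
        mask, dim = make_exact_fractal("line", 64)
        assert mask.n_foreground() == 64
        assert dim == 1.0

    def test_carpet_count_and_membership_against_digit_oracle(self):
        mask, dim = make_exact_fractal("sierpinski_carpet", 243, 5)
        assert mask.n_foreground() == 8**5
        assert dim == pytest.approx(math.log(8) / math.log(3))
        rng = np.random.default_rng(0)
        for r, c in rng.integers(0, 243, size=(200, 2)):
            assert mask.pixels[r, c] == _carpet_membership(int(r), int(c), 5)

    def test_carpet_size_level_mismatch_rejected(self):
        with pytest.raises(SizingError):
            make_exact_fractal("sierpinski_carpet", 100, 4)


class TestRecordSimulator:
    def test_panel_structure_and_determinism(self):
        a = simulate_fd_records(DEFAULT_STUDY_PANEL, seed=5)
        b = simulate_fd_records(DEFAULT_STUDY_PANEL, seed=5)
        assert a.equals(b)
        assert a["patient_id"].nunique() == 77
        assert len(a) == 215

    def test_injected_effects_shift_group_means(self):
        df = simulate_fd_records(
            ((60, (0, 12)),), time_effects={12: 0.3}, jaw_effect=0.4,
            within_sd=0.01, between_sd=0.01, seed=3,
        )
        by_t = df.groupby("timepoint_months")["fd_mean"].mean()
        assert by_t[12] - by_t[0] == pytest.approx(0.3, abs=0.02)
        by_j = df.groupby("jaw")["fd_mean"].mean()
        assert by_j["mandible"] - by_j["maxilla"] == pytest.approx(0.4, abs=0.05)
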