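import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dcfseg import (
    GrayImage,
    average_binarize,
    fuzzy_membership,
    fuzzy_sigma_binarize,
    fuzzy_sigma_params,
    otsu_binarize,
    otsu_threshold,
)

from oracles import otsu_bruteforce


def two_level_image(lo, hi):
    """Smallest image whose min/max are (lo, hi)."""
    return GrayImage(np.array([[lo, hi]], dtype=np.uint8))


class TestAverage:
    def test_half_and_half(self):
        img = GrayImage(np.array([[0, 255], [0, 255]], dtype=np.uint8))
        assert np.array_equal(average_binarize(img),
                              np.array([[0, 255], [0, 255]], dtype=np.uint8))

    def test_constant_is_all_foreground(self):
        img = GrayImage(np.full((3, 3), 9, dtype=np.uint8))
        assert np.all(average_binarize(img) == 255)

    def test_threshold_is_mean(self):
        img = GrayImage(np.array([[10, 20, 30]], dtype=np.uint8))
        assert np.array_equal(average_binarize(img),
                              np.array([[0, 255, 255]], dtype=np.uint8))


class TestOtsu:
    def test_bimodal_split(self):
        pixels = np.concatenate([np.full(128, 10), np.full(128, 200)]).astype(np.uint8)
        out = otsu_binarize(GrayImage(pixels.reshape(16, 16)))
        assert np.array_equal(out == 255, pixels.reshape(16, 16) == 200)

    def test_binary_input(self):
        pixels = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        assert np.array_equal(otsu_binarize(GrayImage(pixels)) == 255, pixels == 255)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            otsu_binarize(GrayImage(np.full((4, 4), 5, dtype=np.uint8)))

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pixels = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            assert otsu_threshold(GrayImage(pixels)) == otsu_bruteforce(pixels)


class TestFuzzyParams:
    # Hand traces of Steps 1-4 for three intensity windows.
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (50, 200, dict(p_mid=125.0, p_min_f=75.0, p_max_f=75.0, p_mid_f=125.0,
                           beta=75.0, p_min_new=50.0, p_max_new=200.0)),
            (0, 255, dict(p_mid=127.5, p_min_f=127.5, p_max_f=127.5, p_mid_f=127.5,
                          beta=127.5, p_min_new=0.0, p_max_new=255.0)),
            (200, 240, dict(p_mid=220.0, p_min_f=20.0, p_max_f=20.0, p_mid_f=220.0,
                            beta=20.0, p_min_new=200.0, p_max_new=240.0)),
        ],
    )
    def test_hand_traced_windows(self, lo, hi, expected):
        p = fuzzy_sigma_params(two_level_image(lo, hi))
        for key, val in expected.items():
            assert getattr(p, key) == val, key

    def test_bright_compensation_never_fires_for_midpoint_mid(self):
        # With p_mid defined as the min/max midpoint, the Step 2 condition
        # p_mid > p_min + 0.75 (p_max - p_min) is structurally false (it
        # reduces to 0.5 > 0.75), so p_mid_f always equals p_mid.  This
        # documents that the bright-compensation branch is dormant under the
        # midpoint definition (see docs/methods.md).
        rng = np.random.default_rng(11)
        for _ in range(300):
            lo = int(rng.integers(0, 256))
            hi = int(rng.integers(lo, 256))
            p = fuzzy_sigma_params(two_level_image(lo, hi))
            assert p.p_mid_f == p.p_mid

    def test_step3_equals_min_selection(self):
        # The nested conditional reduces to min(p_mid_f, p_max_f) in the else
        # branch and min(p_min_f, p_mid_f) in the if branch.
        rng = np.random.default_rng(5)
        for _ in range(200):
            lo = int(rng.integers(0, 255))
            hi = int(rng.integers(lo + 1, 256)) if lo < 255 else 255
            p = fuzzy_sigma_params(two_level_image(lo, hi))
            if p.p_mid_f > p.p_max_f:
                assert p.beta == min(p.p_min_f, p.p_mid_f)
            else:
                assert p.beta == min(p.p_max_f, p.p_mid_f)
            assert p.p_min_new == p.p_mid - p.beta
            assert p.p_max_new == p.p_mid + p.beta

    def test_constant_image_degenerates_to_step(self):
        p = fuzzy_sigma_params(GrayImage(np.full((3, 3), 100, dtype=np.uint8)))
        assert p.beta == 0.0
        assert fuzzy_membership(99.9, p) == 0.0
        assert fuzzy_membership(100.0, p) == 1.0

    def test_alpha_cut_validated(self):
        with pytest.raises(ValueError):
            fuzzy_sigma_params(two_level_image(0, 255), alpha_cut=1.5)


class TestMembership:
    def test_boundary_values(self):
        p = fuzzy_sigma_params(two_level_image(50, 200))
        assert fuzzy_membership(50.0, p) == 0.0       # p_min_new
        assert fuzzy_membership(125.0, p) == 1.0      # p_mid
        assert fuzzy_membership(87.5, p) == 0.5       # midpoint of the ramp

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 254), st.integers(1, 255))
    def test_monotone_and_bounded(self, lo, span):
        hi = min(lo + span, 255)
        p = fuzzy_sigma_params(two_level_image(lo, hi))
        xs = np.linspace(0, 255, 256)
        u = fuzzy_membership(xs, p)
        assert np.all(u >= 0) and np.all(u <= 1)
        assert np.all(np.diff(u) >= -1e-12)


class TestFuzzyBinarize:
    def test_alpha_half_on_known_window(self):
        img = GrayImage(np.array([[50, 80, 100, 200]], dtype=np.uint8))
        out = fuzzy_sigma_binarize(img, 0.5)
        # u(80) = 0.4 -> 0 ; u(100) = 2/3 -> 255
        assert list(out[0]) == [0, 0, 255, 255]

    def test_alpha_limits(self):
        img = GrayImage(np.array([[50, 80, 125, 200]], dtype=np.uint8))
        assert np.all(fuzzy_sigma_binarize(img, 0.0) == 255)
        out1 = fuzzy_sigma_binarize(img, 1.0)
        assert list(out1[0]) == [0, 0, 255, 255]  # foreground is exactly p >= p_mid

    @settings(max_examples=25, derandomize=True)
    @given(hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 255)),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_raising_alpha_never_grows_foreground(self, pixels, a1, a2):
        lo, hi = sorted((a1, a2))
        img = GrayImage(pixels)
        fg_lo = fuzzy_sigma_binarize(img, lo) == 255
        fg_hi = fuzzy_sigma_binarize(img, hi) == 255
        assert np.all(fg_hi <= fg_lo)
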