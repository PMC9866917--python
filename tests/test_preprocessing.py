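import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcquant.core_io import image_checksum
from ihcquant.preprocessing import (
    apply_gain,
    average_brightness,
    compute_mse,
    compute_psnr,
    median_filter,
    preprocess,
    preprocess_stages,
    select_alpha,
    select_filter_window,
)
from ihcquant.synthetic import FixtureSpec, add_impulse_noise, make_ihc_image

from conftest import uniform_image
from oracles import luma_mean_loop, median_filter_loop, mse_loop, psnr_from_mse


class TestComputeMse:
    def test_identical_images_zero(self):
        img = uniform_image(4, 4, (10, 20, 30))
        assert compute_mse(img, img) == 0.0

    def test_unit_difference_everywhere(self):
        a = uniform_image(4, 4, (10, 10, 10))
        b = uniform_image(4, 4, (11, 11, 11))
        assert compute_mse(a, b) == 1.0

    def test_matches_naive_loop(self, random_pair):
        a, b = random_pair
        assert compute_mse(a, b) == pytest.approx(mse_loop(a, b), abs=1e-9)

    def test_symmetry(self, random_pair):
        a, b = random_pair
        assert compute_mse(a, b) == compute_mse(b, a)

    def test_dimension_mismatch(self):
        a = uniform_image(4, 4, (0, 0, 0))
        b = uniform_image(4, 5, (0, 0, 0))
        with pytest.raises(ValueError, match="mismatch"):
            compute_mse(a, b)


class TestComputePsnr:
    def test_identical_images_infinite(self):
        img = uniform_image(4, 4, (7, 7, 7))
        assert math.isinf(compute_psnr(img, img))

    def test_maximal_difference_zero_db(self):
        a = uniform_image(4, 4, (0, 0, 0))
        b = uniform_image(4, 4, (255, 255, 255))
        assert compute_psnr(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self, random_pair):
        a, b = random_pair
        expected = psnr_from_mse(mse_loop(a, b))
        assert compute_psnr(a, b) == pytest.approx(expected, abs=1e-9)


class TestSelectFilterWindow:
    @pytest.mark.parametrize(
        "psnr,side", [(18.0, 5), (35.0, 3), (20.0, 5), (0.0, 5), (math.inf, 3)]
    )
    def test_rule(self, psnr, side):
        assert select_filter_window(psnr) == side

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            select_filter_window(-1.0)


class TestMedianFilter:
    def test_constant_image_identity(self):
        img = uniform_image(9, 9, (42, 43, 44))
        assert np.array_equal(median_filter(img, 3), img)

    def test_isolated_salt_pixel_removed(self):
        img = uniform_image(9, 9, (0, 0, 0))
        img[4, 4] = 255
        out = median_filter(img, 3)
        assert out[4, 4].tolist() == [0, 0, 0]

    @pytest.mark.parametrize("side", [3, 5])
    def test_matches_naive_oracle(self, rng, side):
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        assert np.array_equal(median_filter(img, side), median_filter_loop(img, side))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(uniform_image(4, 4, (0, 0, 0)), 4)


class TestAverageBrightness:
    def test_black(self):
        assert average_brightness(uniform_image(4, 4, (0, 0, 0))) == 0.0

    def test_white(self):
        assert average_brightness(uniform_image(4, 4, (255, 255, 255))) == pytest.approx(255.0)

    def test_matches_naive_loop(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        assert average_brightness(img) == pytest.approx(luma_mean_loop(img), abs=1e-9)


class TestSelectAlpha:
    @pytest.mark.parametrize(
        "y,alpha",
        [(5, 20), (10, 20), (10.5, 12), (40, 12), (100, 8), (150, 8), (180, 6), (200, 6), (250, 4)],
    )
    def test_table(self, y, alpha):
        assert select_alpha(y) == alpha

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            select_alpha(-1)
        with pytest.raises(ValueError):
            select_alpha(256)

    @given(st.floats(min_value=0, max_value=255, allow_nan=False))
    def test_non_increasing(self, y):
        if y < 255:
            assert select_alpha(y) >= select_alpha(min(255.0, y + 1.0))


class TestApplyGain:
    def test_identity_gain(self):
        img = uniform_image(4, 4, (13, 99, 201))
        assert np.array_equal(apply_gain(img, 1), img)

    def test_clipping(self):
        img = uniform_image(4, 4, (128, 128, 128))
        assert np.array_equal(apply_gain(img, 4), uniform_image(4, 4, (255, 255, 255)))

    def test_exact_product(self):
        img = uniform_image(4, 4, (10, 10, 10))
        assert np.array_equal(apply_gain(img, 8), uniform_image(4, 4, (80, 80, 80)))

    def test_half_up_rounding(self):
        img = uniform_image(1, 1, (1, 1, 1))
        assert apply_gain(img, 2.5)[0, 0, 0] == 3  # 2.5 rounds up

    def test_non_positive_alpha_rejected(self):
        with pytest.raises(ValueError):
            apply_gain(uniform_image(2, 2, (0, 0, 0)), 0)

    @given(st.integers(min_value=0, max_value=255), st.sampled_from([4, 6, 8, 12, 20]))
    def test_output_in_range(self, value, alpha):
        out = apply_gain(uniform_image(2, 2, (value, value, value)), alpha)
        assert out.min() >= 0 and out.max() <= 255


class TestPreprocess:
    def test_clean_constant_image(self):
        img = uniform_image(16, 16, (50, 50, 50))
        out, record = preprocess(img)
        assert math.isinf(record.probe_psnr_db)
        assert record.selected_window == 3
        # Y = 50 -> alpha = 8 -> 400 clipped to 255
        assert record.selected_alpha == 8
        assert np.array_equal(out, uniform_image(16, 16, (255, 255, 255)))

    def test_heavy_noise_selects_wide_window(self):
        spec = FixtureSpec(height=64, width=64, positive_fraction=0.2, seed=3,
                           nucleus_radius_px=(6.0, 1.0), negative_count=4,
                           impulse_noise_density=0.2)
        img, _ = make_ihc_image(spec)
        _, record = preprocess(img)
        assert record.probe_psnr_db <= 20
        assert record.selected_window == 5

    def test_stage_checksums_match_recomputed_chain(self, rng):
        from ihcquant.preprocessing import compute_psnr as psnr_op

        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        result = preprocess_stages(img)
        ii = median_filter(img, 3)
        window = select_filter_window(psnr_op(ii, img))
        iii = median_filter(ii, window)
        alpha = select_alpha(average_brightness(iii))
        iiii = apply_gain(iii, alpha)
        assert result.record.stage_checksums == {
            "I": image_checksum(img),
            "II": image_checksum(ii),
            "III": image_checksum(iii),
            "IIII": image_checksum(iiii),
        }

    def test_record_fully_populated(self, rng):
        img = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        _, record = preprocess(img)
        d = record.to_dict()
        assert set(d["stage_checksums"]) == {"I", "II", "III", "IIII"}
        assert all(v is not None for k, v in d.items() if k != "probe_psnr_db")


@settings(deadline=None, max_examples=10)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_filtering_improves_psnr_on_noisy_fixture(seed):
    """PSNR(filtered vs clean) > PSNR(noisy vs clean) for >=1% impulse noise."""
    spec = FixtureSpec(height=64, width=64, positive_fraction=0.15, seed=seed,
                       nucleus_radius_px=(6.0, 1.0), negative_count=3)
    clean, _ = make_ihc_image(spec)
    noisy = add_impulse_noise(clean, 0.05, seed=seed + 1)
    filtered = median_filter(noisy, 3)
    assert compute_psnr(filtered, clean) > compute_psnr(noisy, clean)
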