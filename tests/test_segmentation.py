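import numpy as np
import pytest

from ihcquant.core_io import BiomarkerKind
from ihcquant.segmentation import (
    MorphologySettings,
    ThresholdPair,
    select_thresholds,
    segment,
    threshold_band,
    watershed_segment,
)
from ihcquant.synthetic import BACKGROUND_RGB, FixtureSpec, color_for_luma, make_ihc_image

from conftest import uniform_image


class TestSelectThresholds:
    @pytest.mark.parametrize(
        "kind,lower,upper",
        [
            (BiomarkerKind.PR, 160, 180),
            (BiomarkerKind.ER, 180, 210),
            (BiomarkerKind.HER2, 40, 230),
            (BiomarkerKind.KI67, 160, 180),
        ],
    )
    def test_published_table(self, kind, lower, upper):
        tp = select_thresholds(kind)
        assert (tp.lower, tp.upper) == (lower, upper)
        assert tp.biomarker is kind

    def test_alias_accepted(self):
        assert select_thresholds("estrogen").upper == 210

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            select_thresholds("nonsense")

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPair(lower=200, upper=100)


class TestThresholdBand:
    def test_uniform_inside_band(self):
        img = uniform_image(8, 8, color_for_luma(195.0))
        tp = select_thresholds(BiomarkerKind.ER)
        assert threshold_band(img, tp).all()

    def test_uniform_outside_band(self):
        img = uniform_image(8, 8, (255, 255, 255))
        tp = select_thresholds(BiomarkerKind.ER)
        assert not threshold_band(img, tp).any()

    def test_two_tone_exact_region(self):
        img = uniform_image(8, 8, (255, 255, 255))
        img[2:5, 3:6] = color_for_luma(195.0)
        tp = select_thresholds(BiomarkerKind.ER)
        expected = np.zeros((8, 8), dtype=bool)
        expected[2:5, 3:6] = True
        assert np.array_equal(threshold_band(img, tp), expected)

    def test_band_inclusive(self):
        tp = ThresholdPair(lower=100, upper=100)
        img = uniform_image(2, 2, (100, 100, 100))  # luma exactly 100
        assert threshold_band(img, tp).all()

    def test_candidate_monotone_in_band_width(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        narrow = threshold_band(img, ThresholdPair(lower=100, upper=150))
        wide = threshold_band(img, ThresholdPair(lower=80, upper=180))
        assert (wide | narrow == wide).all()  # narrow is a subset of wide


class TestWatershedSegment:
    def test_empty_candidate(self, background_image):
        mask = np.zeros(background_image.shape[:2], dtype=bool)
        result = watershed_segment(background_image, mask)
        assert result.positive_area_sp == 0
        assert result.labels.max() == 0
        assert result.window_area_sw == 32 * 32

    def test_single_disk_area(self, stained_disk_image):
        img, analytic_area = stained_disk_image
        tp = select_thresholds(BiomarkerKind.ER)
        result = watershed_segment(img, threshold_band(img, tp))
        assert result.labels.max() == 1
        assert result.positive_area_sp == pytest.approx(analytic_area, rel=0.05)

    def test_two_tangent_disks_split(self):
        from skimage.draw import disk

        img = uniform_image(96, 128, BACKGROUND_RGB)
        for center in ((48, 40), (48, 81)):
            rr, cc = disk(center, 20)
            img[rr, cc] = color_for_luma(195.0)
        tp = select_thresholds(BiomarkerKind.ER)
        result = watershed_segment(img, threshold_band(img, tp))
        assert result.labels.max() == 2

    def test_small_objects_removed(self):
        img = uniform_image(32, 32, BACKGROUND_RGB)
        img[4:7, 4:7] = color_for_luma(195.0)  # 9 px < default min_object_px
        tp = select_thresholds(BiomarkerKind.ER)
        result = watershed_segment(img, threshold_band(img, tp))
        assert result.positive_area_sp == 0

    def test_mask_is_subset_of_dilated_candidate(self, stained_disk_image):
        from scipy import ndimage as ndi

        img, _ = stained_disk_image
        tp = select_thresholds(BiomarkerKind.ER)
        candidate = threshold_band(img, tp)
        result = watershed_segment(img, candidate)
        allowed = ndi.binary_dilation(candidate, iterations=5)
        assert not (result.foreground_mask & ~allowed).any()

    def test_labels_are_4_connected(self, stained_disk_image):
        from scipy import ndimage as ndi

        img, _ = stained_disk_image
        tp = select_thresholds(BiomarkerKind.ER)
        result = watershed_segment(img, threshold_band(img, tp))
        for label_id in range(1, result.labels.max() + 1):
            _, n = ndi.label(result.labels == label_id)
            assert n == 1

    def test_dimension_mismatch(self, background_image):
        with pytest.raises(ValueError, match="shape"):
            watershed_segment(background_image, np.zeros((4, 4), dtype=bool))


class TestSegment:
    def test_all_white_er(self):
        img = uniform_image(32, 32, (255, 255, 255))
        result = segment(img, BiomarkerKind.ER)
        assert result.positive_area_sp == 0

    def test_er_fixture_recovers_fraction(self):
        spec = FixtureSpec(height=192, width=192, positive_fraction=0.25,
                           positive_luma=195.0, nucleus_radius_px=(12.0, 2.0),
                           negative_count=5, seed=11)
        img, truth = make_ihc_image(spec)
        result = segment(img, BiomarkerKind.ER)
        delta = result.positive_area_sp / result.window_area_sw
        assert 0.20 <= delta <= 0.30

    def test_params_echo_threshold_table(self, background_image):
        result = segment(background_image, BiomarkerKind.ER)
        assert result.params_used["thresholds"]["lower"] == 180
        assert result.params_used["thresholds"]["upper"] == 210

    def test_sp_monotone_in_band_width(self):
        spec = FixtureSpec(height=128, width=128, positive_fraction=0.2,
                           positive_luma=195.0, nucleus_radius_px=(10.0, 2.0),
                           negative_count=4, seed=21)
        img, _ = make_ihc_image(spec)
        sp = []
        for lower, upper in [(190, 200), (185, 205), (180, 210), (170, 220)]:
            result = segment(img, BiomarkerKind.ER,
                             thresholds=ThresholdPair(lower=lower, upper=upper))
            sp.append(result.positive_area_sp)
        assert sp == sorted(sp)

    def test_morphology_settings_respected(self, stained_disk_image):
        img, _ = stained_disk_image
        loose = MorphologySettings(min_object_px=1)
        result = segment(img, BiomarkerKind.ER, morphology=loose)
        assert result.params_used["morphology"]["min_object_px"] == 1
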