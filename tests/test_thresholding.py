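"""Binarization: Bernsen vs brute force, Tsai moments, calibration rule."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bernsen_oracle, linear_scan_calibration, moments_oracle_threshold
from conftest import make_image
from netquant.errors import CalibrationError, ConfigurationError, DegenerateImageError
from netquant.synth import calibration_field, generate_field, get_preset
from netquant.thresholding import (
    bernsen_binarize,
    calibrate_chromatin_threshold,
    global_binarize,
    moments_threshold,
)


class TestBernsen:
    def test_flat_dark_image_is_background(self):
        img = make_image(np.zeros((32, 32), dtype=np.uint8))
        assert not bernsen_binarize(img, 15, 35).pixels.any()

    def test_flat_bright_image_is_foreground(self):
        img = make_image(np.full((32, 32), 200, dtype=np.uint8))
        assert bernsen_binarize(img, 15, 35).pixels.all()

    def test_low_contrast_rule_at_half_range_16bit(self):
        img = make_image(np.full((8, 8), 32768, dtype=np.uint16), bit_depth=16)
        assert bernsen_binarize(img, 3, 35).pixels.all()
        img = make_image(np.full((8, 8), 32767, dtype=np.uint16), bit_depth=16)
        assert not bernsen_binarize(img, 3, 35).pixels.any()

    @pytest.mark.parametrize("radius", [1, 3, 7, 15])
    def test_matches_brute_force_oracle_on_random_images(self, radius):
        rng = np.random.default_rng(42 + radius)
        for _ in range(5):
            px = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
            img = make_image(px)
            got = bernsen_binarize(img, radius, 35.0).pixels
            want = bernsen_oracle(px, radius, 35.0, 8)
            assert np.array_equal(got, want)

    def test_oracle_agreement_holds_for_16bit(self):
        rng = np.random.default_rng(7)
        px = rng.integers(0, 65536, size=(24, 24)).astype(np.uint16)
        img = make_image(px, bit_depth=16)
        got = bernsen_binarize(img, 5, 35.0).pixels
        assert np.array_equal(got, bernsen_oracle(px, 5, 35.0, 16))

    def test_radius_exceeding_both_dimensions_rejected(self):
        img = make_image(np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(ConfigurationError, match="exceeds both"):
            bernsen_binarize(img, 11, 35)
        # exceeding only one dimension is allowed (truncated neighborhoods)
        bernsen_binarize(make_image(np.zeros((5, 64), dtype=np.uint8)), 10, 35)


class TestGlobal:
    def test_threshold_is_inclusive(self):
        px = np.array([[50, 100, 150]], dtype=np.uint8)
        mask = global_binarize(make_image(px, channel="chromatin"), 100)
        assert mask.pixels.tolist() == [[False, True, True]]

    def test_all_zero_and_saturated_edges(self):
        zeros = make_image(np.zeros((4, 4), dtype=np.uint8), channel="chromatin")
        assert not global_binarize(zeros, 1).pixels.any()
        sat = make_image(np.full((4, 4), 255, dtype=np.uint8), channel="chromatin")
        assert global_binarize(sat, 255).pixels.all()

    def test_threshold_outside_range_rejected(self):
        img = make_image(np.zeros((4, 4), dtype=np.uint8), channel="chromatin")
        for bad in (0, 256):
            with pytest.raises(ConfigurationError):
                global_binarize(img, bad)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_foreground_shrinks_as_threshold_grows(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        img = make_image(px, channel="chromatin")
        t1, t2 = sorted(rng.integers(1, 256, size=2))
        fg1 = global_binarize(img, int(t1)).pixels
        fg2 = global_binarize(img, int(max(t2, t1 + 1))).pixels
        assert not (fg2 & ~fg1).any()  # foreground(t2) subset of foreground(t1)


class TestMoments:
    def test_bimodal_half_half_splits_at_lower_mode(self):
        px = np.concatenate([np.full(128, 50), np.full(128, 200)]).astype(np.uint8)
        t = moments_threshold(make_image(px.reshape(16, 16), channel="chromatin"))
        assert 50 <= t < 200
        # exactly half the pixels fall at/below t (p0 = 0.5)
        assert (px <= t).mean() == pytest.approx(0.5)

    def test_constant_image_is_degenerate(self):
        img = make_image(np.full((8, 8), 7, dtype=np.uint8), channel="chromatin")
        with pytest.raises(DegenerateImageError):
            moments_threshold(img)

    def test_matches_linear_algebra_oracle_on_random_images(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            px = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
            img = make_image(px, channel="chromatin")
            assert moments_threshold(img) == moments_oracle_threshold(px, 256)

    def test_invariant_under_pixel_permutation(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        shuffled = rng.permutation(px.ravel()).reshape(16, 16)
        t1 = moments_threshold(make_image(px, channel="chromatin"))
        t2 = moments_threshold(make_image(shuffled, channel="chromatin"))
        assert t1 == t2


class TestCalibration:
    def test_empty_image_calibrates_to_one(self):
        img = make_image(np.zeros((64, 64), dtype=np.uint8), channel="chromatin")
        res = calibrate_chromatin_threshold(img, net_area_cutoff=75)
        assert res.threshold == 1
        assert res.largest_object_area_at_threshold == 0

    def test_single_square_forces_threshold_above_its_level(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[10:20, 10:20] = 100  # 100 px object
        res = calibrate_chromatin_threshold(
            make_image(px, channel="chromatin"), net_area_cutoff=75
        )
        assert res.threshold == 101

    def test_tolerated_count_accepts_spontaneous_nets(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[10:20, 10:20] = 100
        res = calibrate_chromatin_threshold(
            make_image(px, channel="chromatin"),
            net_area_cutoff=75,
            tolerated_large_object_count=1,
        )
        assert res.threshold == 1  # the one big object is tolerated

    def test_impossible_calibration_names_achievable_count(self):
        px = np.full((64, 64), 255, dtype=np.uint8)  # saturated blob at every level
        with pytest.raises(CalibrationError) as err:
            calibrate_chromatin_threshold(make_image(px, channel="chromatin"))
        assert err.value.smallest_achievable_count == 1

    def test_matches_exhaustive_linear_scan_on_synthetic_fields(self):
        for seed in range(5):
            chrom = calibration_field(seed=seed, shape=(256, 256))
            res = calibrate_chromatin_threshold(chrom)
            want = linear_scan_calibration(chrom.pixels, 75, 8, 0, 255)
            assert res.threshold == want

    def test_max_object_area_monotone_in_threshold(self):
        spec = dataclasses.replace(get_preset("pma_2h"), shape=(256, 256),
                                   n_resting=8, n_netotic=4, seed=2)
        _, chrom, _ = generate_field(spec)
        from netquant.thresholding import _count_large_objects

        last = None
        for t in range(1, 256, 8):
            _, max_area = _count_large_objects(chrom.pixels >= t, 75, 8)
            if last is not None:
                assert max_area <= last
            last = max_area
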