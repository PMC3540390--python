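"""The headline pipeline: channel counts, NET-rate, aggregation, overlays."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import make_image
from netquant.errors import (
    ChannelMismatchError,
    ConfigurationError,
    DimensionMismatchError,
    UndefinedRateError,
)
from netquant.image_model import SegmentationParams
from netquant.quantify import (
    FieldResult,
    count_net_events,
    count_nuclei,
    net_rate,
    quantify_field,
    quantify_specimen,
    render_overlay,
)
from netquant.synth import SceneSpec, generate_field, get_preset


class TestNetRate:
    def test_formula(self):
        assert net_rate(40, 100) == 40.0
        assert net_rate(0, 250) == 0.0

    def test_not_clamped_above_100(self):
        assert net_rate(120, 100) == 120.0

    def test_zero_nuclei_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            net_rate(5, 0)


class TestSpecimenAggregation:
    def make_fields(self, rates, specimen="s1"):
        return [
            FieldResult(f"f{i}", specimen, 100, int(r), float(r)) for i, r in enumerate(rates)
        ]

    def test_constant_rates_have_zero_sd(self):
        res = quantify_specimen(self.make_fields([10, 10, 10, 10, 10]))
        assert res.mean_rate_pct == 10.0
        assert res.sd_rate_pct == 0.0
        assert res.n_fields == 5

    def test_sample_sd_uses_n_minus_1(self):
        res = quantify_specimen(self.make_fields([0, 20]))
        assert res.mean_rate_pct == 10.0
        assert res.sd_rate_pct == pytest.approx(math.sqrt(200))

    def test_single_field_reports_missing_sd(self):
        res = quantify_specimen(self.make_fields([37.0]))
        assert res.mean_rate_pct == 37.0
        assert res.sd_rate_pct is None
        assert res.n_fields == 1

    def test_mixed_specimens_rejected(self):
        fields = self.make_fields([10], "a") + self.make_fields([20], "b")
        with pytest.raises(ValueError, match="mixed specimen"):
            quantify_specimen(fields)


class TestChannelCounts:
    def test_blank_dna_field_has_zero_nuclei(self, calibrated_params):
        blank = make_image(np.zeros((64, 64), dtype=np.uint8), channel="dna")
        count, _ = count_nuclei(blank, calibrated_params)
        assert count == 0

    def test_blank_chromatin_field_has_zero_events(self, calibrated_params):
        blank = make_image(np.zeros((64, 64), dtype=np.uint8), channel="chromatin")
        count, _ = count_net_events(blank, calibrated_params)
        assert count == 0

    def test_channel_tags_are_enforced(self, calibrated_params):
        blank = make_image(np.zeros((64, 64), dtype=np.uint8), channel="chromatin")
        with pytest.raises(ChannelMismatchError):
            count_nuclei(blank, calibrated_params)
        with pytest.raises(ChannelMismatchError):
            count_net_events(
                make_image(np.zeros((64, 64), dtype=np.uint8), channel="dna"),
                calibrated_params,
            )

    def test_unset_chromatin_threshold_is_a_configuration_error(self):
        blank = make_image(np.zeros((64, 64), dtype=np.uint8), channel="chromatin")
        with pytest.raises(ConfigurationError, match="chromatin_threshold"):
            count_net_events(blank, SegmentationParams())

    def test_counts_recover_constructed_ground_truth(self, small_scene, calibrated_params):
        dna, chrom, truth = generate_field(small_scene)
        nuclei, _ = count_nuclei(dna, calibrated_params)
        events, _ = count_net_events(chrom, calibrated_params)
        assert nuclei == truth.n_resting + truth.n_netotic == 50
        assert events == truth.n_netotic == 15


class TestQuantifyField:
    def test_full_field_recovers_truth(self, small_scene, calibrated_params):
        dna, chrom, _ = generate_field(small_scene, field_id="f1", specimen_id="s1")
        res = quantify_field(dna, chrom, calibrated_params)
        assert res.nuclei_count == 50
        assert res.net_event_count == 15
        assert res.net_rate_pct == pytest.approx(30.0)
        assert res.params is not None and res.params is not calibrated_params

    def test_all_netotic_field_reaches_100pct(self, calibrated_params):
        spec = SceneSpec(shape=(512, 512), n_resting=0, n_netotic=12, seed=5)
        dna, chrom, _ = generate_field(spec, field_id="f", specimen_id="s")
        res = quantify_field(dna, chrom, calibrated_params)
        assert res.net_rate_pct == pytest.approx(100.0)

    def test_blank_field_raises_undefined_rate(self, calibrated_params):
        dna = make_image(np.zeros((64, 64), dtype=np.uint8), channel="dna", field_id="f")
        chrom = make_image(np.zeros((64, 64), dtype=np.uint8), channel="chromatin", field_id="f")
        with pytest.raises(UndefinedRateError, match="f"):
            quantify_field(dna, chrom, calibrated_params)

    def test_dimension_mismatch_rejected(self, calibrated_params):
        dna = make_image(np.zeros((64, 64), dtype=np.uint8), channel="dna")
        chrom = make_image(np.zeros((32, 32), dtype=np.uint8), channel="chromatin")
        with pytest.raises(DimensionMismatchError):
            quantify_field(dna, chrom, calibrated_params)

    def test_determinism_across_runs(self, small_scene, calibrated_params):
        results = []
        for _ in range(2):
            dna, chrom, _ = generate_field(small_scene, field_id="f1", specimen_id="s1")
            results.append(quantify_field(dna, chrom, calibrated_params))
        assert results[0] == results[1]

    def test_confluence_never_increases_rate(self, calibrated_params):
        base = SceneSpec(shape=(768, 768), n_resting=45, n_netotic=30, seed=77)
        dna_n, chrom_n, _ = generate_field(base, field_id="f", specimen_id="s")
        confluent = dataclasses.replace(base, confluent_nets=True)
        dna_c, chrom_c, _ = generate_field(confluent, field_id="f", specimen_id="s")
        rate_n = quantify_field(dna_n, chrom_n, calibrated_params).net_rate_pct
        rate_c = quantify_field(dna_c, chrom_c, calibrated_params).net_rate_pct
        assert rate_c <= rate_n


class TestOverlay:
    def test_blank_inputs_give_black_image(self, tmp_path):
        from netquant.particles import label_particles
        from netquant.thresholding import BinaryMask

        blank = make_image(np.zeros((16, 16), dtype=np.uint8), channel="dna")
        blank_c = make_image(np.zeros((16, 16), dtype=np.uint8), channel="chromatin")
        empty = label_particles(BinaryMask(np.zeros((16, 16), dtype=bool)), 8)
        path = tmp_path / "o.png"
        render_overlay(blank, blank_c, empty, empty, path)
        import imageio.v3 as iio

        rgb = iio.imread(path)
        assert rgb.shape == (16, 16, 3) and not rgb.any()

    def test_outline_drawn_around_object(self, tmp_path):
        from netquant.particles import label_particles
        from netquant.thresholding import BinaryMask

        m = np.zeros((16, 16), dtype=bool)
        m[5:10, 5:10] = True
        pset = label_particles(BinaryMask(m), 8)
        dna = make_image((m * 200).astype(np.uint8), channel="dna")
        chrom = make_image(np.zeros((16, 16), dtype=np.uint8), channel="chromatin")
        empty = label_particles(BinaryMask(np.zeros((16, 16), dtype=bool)), 8)
        path = tmp_path / "o.png"
        render_overlay(dna, chrom, pset, empty, path)
        import imageio.v3 as iio

        rgb = iio.imread(path)
        # the pixel just outside the square carries the DNA outline color (cyan)
        assert tuple(rgb[4, 5]) == (0, 255, 255)
        # pixels well inside stay un-outlined
        assert tuple(rgb[7, 7]) != (0, 255, 255)

    def test_full_field_overlay_smoke(self, tmp_path, small_scene, calibrated_params):
        dna, chrom, _ = generate_field(small_scene)
        _, dna_p = count_nuclei(dna, calibrated_params)
        _, net_p = count_net_events(chrom, calibrated_params)
        path = tmp_path / "field.png"
        render_overlay(dna, chrom, dna_p, net_p, path)
        import imageio.v3 as iio

        assert iio.imread(path).shape == (*small_scene.shape, 3)
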