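"""Hematocrit imaging pipeline: each stage plus end-to-end recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spinsense as ss
from spinsense import hct
from spinsense.errors import DegenerateHistogramError, InvalidArgument


@pytest.fixture
def clean_image():
    img, truth = ss.make_channel_image(ss.ChannelImageSpec(hct_fraction=40.0), seed=0)
    return img, truth


class TestToGrayscale:
    def test_idempotent_on_grayscale(self):
        arr = np.random.default_rng(0).uniform(0, 1, (20, 30))
        out = hct.to_grayscale(arr)
        assert np.array_equal(out.pixels, arr)

    def test_pure_white_rgb(self):
        out = hct.to_grayscale(np.ones((5, 5, 3)))
        assert np.allclose(out.pixels, 1.0)

    def test_luminance_weights(self):
        # BT.709: 0.2126 R + 0.7152 G + 0.0722 B
        rgb = np.empty((4, 4, 3))
        rgb[..., 0], rgb[..., 1], rgb[..., 2] = 0.2, 0.5, 0.1
        out = hct.to_grayscale(rgb)
        expect = 0.2 * 0.2126 + 0.5 * 0.7152 + 0.1 * 0.0722
        assert np.allclose(out.pixels, expect, atol=1e-4)

    def test_uint8_scaling(self):
        out = hct.to_grayscale(np.full((4, 4), 255, dtype=np.uint8))
        assert np.allclose(out.pixels, 1.0) and out.bit_depth == 8

    def test_bad_channel_count(self):
        with pytest.raises(InvalidArgument):
            hct.to_grayscale(np.zeros((4, 4, 2)))


class TestCorrectBackground:
    def test_identity_on_clean_image(self, clean_image):
        img, _ = clean_image
        out = hct.correct_background(img)
        assert np.allclose(out.pixels, img.pixels, atol=1e-6)

    def test_tilt_reduced_fivefold(self):
        img, _ = ss.make_channel_image(
            ss.ChannelImageSpec(hct_fraction=40.0, illumination_gradient=0.2), seed=1
        )
        bg = ~img.channel_mask
        before = img.pixels[bg].std()
        after = hct.correct_background(img).pixels[bg].std()
        assert after * 5 <= before

    def test_stray_marks_removed(self):
        img, _ = ss.make_channel_image(
            ss.ChannelImageSpec(hct_fraction=40.0, stray_mark_density=8.0), seed=2
        )
        out = hct.correct_background(img)
        bg_vals = out.pixels[~out.channel_mask]
        assert np.abs(bg_vals - bg_vals.mean()).max() <= 3 * bg_vals.std() + 1e-9

    def test_output_in_unit_interval(self):
        img, _ = ss.make_channel_image(
            ss.ChannelImageSpec(
                hct_fraction=70.0, noise_sd=0.1, illumination_gradient=0.3
            ),
            seed=3,
        )
        out = hct.correct_background(img)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_too_few_background_pixels(self):
        mask = np.ones((20, 20), dtype=bool)
        mask[0, :10] = False
        img = ss.DiscImage(np.random.default_rng(0).uniform(0, 1, (20, 20)), mask)
        with pytest.raises(InvalidArgument):
            hct.correct_background(img)


class TestFlattenProfile:
    def test_constant_channel_constant_profile(self, clean_image):
        img, _ = clean_image
        flat = ss.DiscImage(np.full_like(img.pixels, 0.6), img.channel_mask)
        prof = hct.flatten_profile(flat)
        assert np.allclose(prof, 0.6)

    def test_cubic_preserved_exactly(self):
        # Savitzky-Golay of order >= 3 passes cubics through unchanged
        mask = np.ones((60, 20), dtype=bool)
        rows = np.arange(60) / 59.0
        cubic = 0.2 + 0.5 * rows - 0.4 * rows**2 + 0.3 * rows**3
        img = ss.DiscImage(np.tile(cubic[:, None], (1, 20)), mask)
        prof = hct.flatten_profile(img, window=11, order=3)
        assert np.allclose(prof, cubic, atol=1e-9)

    def test_step_edge_shift_below_half_window(self):
        mask = np.ones((100, 20), dtype=bool)
        px = np.full((100, 20), 0.8)
        px[60:] = 0.2  # edge at row 60
        img = ss.DiscImage(px, mask)
        prof = hct.flatten_profile(img, window=11, order=3)
        half = 0.5 * (0.8 + 0.2)
        crossing = np.argmax(prof < half)
        assert abs(crossing - 60) < 11 / 2

    def test_window_validation(self, clean_image):
        img, _ = clean_image
        with pytest.raises(InvalidArgument):
            hct.flatten_profile(img, window=10)
        with pytest.raises(InvalidArgument):
            hct.flatten_profile(img, window=11, order=11)
        with pytest.raises(InvalidArgument):
            hct.flatten_profile(img, window=999)


class TestComputeThreshold:
    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
        img = ss.DiscImage(vals.reshape(25, 40), np.ones((25, 40), bool))
        thr = hct.compute_threshold(img)
        assert 0.2 < thr < 0.8

    def test_symmetric_gaussians_threshold_at_midpoint(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(0.25, 0.03, 2000), rng.normal(0.75, 0.03, 2000)]
        )
        img = ss.DiscImage(vals.reshape(40, 100), np.ones((40, 100), bool))
        assert hct.compute_threshold(img) == pytest.approx(0.50, abs=0.02)

    def test_otsu_matches_exhaustive_search(self):
        """Oracle: exhaustive between-class-variance maximization, 256 bins."""
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.normal(0.3, 0.05, 1500), rng.normal(0.7, 0.08, 2500)]
        ).clip(0, 1)
        img = ss.DiscImage(vals.reshape(40, 100), np.ones((40, 100), bool))
        thr = hct.compute_threshold(img)

        counts, edges = np.histogram(vals, bins=256, range=(vals.min(), vals.max()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        variances = np.full(256, -1.0)
        for i in range(1, 256):
            w0, w1 = counts[:i].sum(), counts[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[:i] * centers[:i]).sum() / w0
            m1 = (counts[i:] * centers[i:]).sum() / w1
            variances[i] = w0 * w1 * (m0 - m1) ** 2
        best = variances.max()
        plateau = np.nonzero(variances >= best * (1 - 1e-12))[0]
        bin_width = edges[1] - edges[0]
        # any cut in the maximizing plateau is an Otsu threshold
        assert edges[plateau.min()] - bin_width <= thr <= edges[plateau.max()] + bin_width

    def test_constant_region_degenerate(self):
        img = ss.DiscImage(np.full((10, 10), 0.5), np.ones((10, 10), bool))
        with pytest.raises(DegenerateHistogramError):
            hct.compute_threshold(img)


class TestQuantifyHematocrit:
    def test_supplied_threshold_extremes(self, clean_image):
        img, _ = clean_image
        assert hct.quantify_hematocrit(img, threshold=0.01).hct_percent == 0.0
        assert hct.quantify_hematocrit(img, threshold=0.99).hct_percent == 100.0

    def test_recovers_ground_truth(self, clean_image):
        img, truth = clean_image
        r = hct.quantify_hematocrit(img)
        assert r.hct_percent == pytest.approx(truth.hct_percent, abs=0.5)
        assert r.hct_percent == 100.0 * r.dark_pixels / r.total_pixels

    def test_monotone_in_threshold(self, clean_image):
        img, _ = clean_image
        fracs = [
            hct.quantify_hematocrit(img, threshold=t).hct_percent
            for t in np.linspace(0.05, 0.95, 10)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_rescaling_invariance_with_auto_threshold(self):
        """Otsu scales with the histogram, so a global intensity rescale
        leaves the dark-pixel fraction unchanged."""
        img, truth = ss.make_channel_image(
            ss.ChannelImageSpec(hct_fraction=35.0, noise_sd=0.02), seed=4
        )
        base = hct.quantify_hematocrit(img).hct_percent
        for scale in (0.5, 0.8):
            scaled = ss.DiscImage(img.pixels * scale, img.channel_mask)
            assert hct.quantify_hematocrit(scaled).hct_percent == pytest.approx(
                base, abs=0.2
            )

    def test_degenerate_propagates(self):
        img = ss.DiscImage(np.full((10, 10), 0.5), np.ones((10, 10), bool))
        with pytest.raises(DegenerateHistogramError):
            hct.quantify_hematocrit(img)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("true_hct", list(range(10, 100, 20)))
    def test_noiseless_within_one_point(self, true_hct):
        img, truth = ss.make_channel_image(
            ss.ChannelImageSpec(hct_fraction=float(true_hct)), seed=true_hct
        )
        est = hct.quantify_hematocrit(hct.correct_background(img))
        assert est.hct_percent == pytest.approx(truth.hct_percent, abs=1.0)

    @pytest.mark.parametrize("true_hct", list(range(10, 100, 20)))
    def test_noisy_tilted_within_three_points(self, true_hct):
        img, truth = ss.make_channel_image(
            ss.ChannelImageSpec(
                hct_fraction=float(true_hct),
                noise_sd=0.05,
                illumination_gradient=0.2,
                stray_mark_density=5.0,
            ),
            seed=100 + true_hct,
        )
        est = hct.quantify_hematocrit(hct.correct_background(img))
        assert est.hct_percent == pytest.approx(truth.hct_percent, abs=3.0)


class TestDetectStabilization:
    def test_constant_series_stable_at_first_window(self):
        series = [(t, 40.0) for t in range(0, 200, 20)]
        r = hct.detect_stabilization(series)
        assert r.reached and r.stable_time == 20.0 and r.stable_value == 40.0

    def test_steep_linear_series_never_stable(self):
        series = [(t, 100.0 - 2.0 * t) for t in range(0, 200, 20)]
        r = hct.detect_stabilization(series, epsilon=1.0)
        assert not r.reached

    def test_exponential_series_settles_near_observed_plateau(self):
        # tau 50 s, 20 s sampling, eps 1% -> plateau declared within one
        # sampling interval of the observed 200 s stabilization
        times = np.arange(0.0, 400.0, 20.0)
        series = [(t, 40.0 + 60.0 * np.exp(-t / 50.0)) for t in times]
        r = hct.detect_stabilization(series, epsilon=1.0, k=3)
        assert r.reached
        assert abs(r.stable_time - 200.0) <= 20.0
        assert r.stable_value == pytest.approx(40.0, abs=2.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(eps=st.floats(0.2, 5.0))
    def test_time_monotone_in_epsilon(self, eps):
        times = np.arange(0.0, 400.0, 20.0)
        series = [(t, 40.0 + 60.0 * np.exp(-t / 50.0)) for t in times]
        loose = hct.detect_stabilization(series, epsilon=eps)
        tight = hct.detect_stabilization(series, epsilon=eps / 2)
        if tight.reached:
            assert loose.reached and loose.stable_time <= tight.stable_time

    def test_unsorted_times_rejected(self):
        with pytest.raises(InvalidArgument):
            hct.detect_stabilization([(0.0, 1.0), (0.0, 1.0), (1.0, 1.0), (2.0, 1.0)])
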