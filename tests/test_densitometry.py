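"""Band detection, ladder indexing and the intensity-weighted mean Lk."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoquant.densitometry import (
    BandTable,
    LaneProfile,
    Peak,
    assign_linking_numbers,
    detect_bands,
    extract_lane_profile,
    quantify_profile,
    subtract_background,
    weighted_mean_lk,
)
from topoquant.errors import (
    AmbiguousLadderError,
    BoundsError,
    InvalidBandError,
    InvalidParameterError,
    NoBandsError,
)
from topoquant.simulate import NoiseModel, make_topoisomer_distribution, render_lane

from conftest import QUANTIFY_KW


def _peaks(centers, intensities=None):
    intensities = intensities or [1.0] * len(centers)
    return [Peak(c, 1.0, 1.0, i) for c, i in zip(centers, intensities)]


class TestExtractLaneProfile:
    def test_constant_image_gives_flat_profile(self):
        img = np.full((40, 30), 7.5)
        prof = extract_lane_profile(img, (0, 40, 5, 15))
        assert np.all(prof.intensities == 7.5)
        assert prof.positions[0] == 0 and prof.positions[-1] == 39

    def test_matches_simulated_lane(self, geometry, seven_band_dist):
        from topoquant.simulate import render_gel_image

        lane = render_lane(seven_band_dist, geometry, NoiseModel(), 1e5)
        img = render_gel_image({"lane": lane}, lane_width_px=8, gap_px=4)
        prof = extract_lane_profile(img, (0, len(lane), 4, 12))
        # image is rescaled to uint16; compare shapes after renormalization
        scale = lane.intensities.max() / prof.intensities.max()
        np.testing.assert_allclose(
            prof.intensities * scale, lane.intensities, atol=lane.intensities.max() * 1e-4
        )

    def test_width_one_roi_is_single_column(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 10))
        prof = extract_lane_profile(img, (0, 20, 3, 4))
        np.testing.assert_array_equal(prof.intensities, img[:, 3])

    def test_roi_outside_image_is_bounds_error(self):
        with pytest.raises(BoundsError):
            extract_lane_profile(np.zeros((10, 10)), (0, 11, 0, 5))


class TestSubtractBackground:
    def test_linear_ramp_removed(self):
        n = 2000
        prof = LaneProfile(np.arange(n, dtype=float), 5.0 + 0.1 * np.arange(n))
        out = subtract_background(prof, 30)
        assert out.intensities.max() < 0.01 * np.ptp(prof.intensities)

    def test_gaussian_peak_height_preserved(self):
        x = np.arange(600, dtype=float)
        g = 100.0 * np.exp(-0.5 * ((x - 300) / 5) ** 2)
        out = subtract_background(LaneProfile(x, g), 60)
        assert out.intensities.max() == pytest.approx(100.0, rel=0.02)

    def test_zero_profile_stays_zero(self):
        prof = LaneProfile(np.arange(100, dtype=float), np.zeros(100))
        out = subtract_background(prof, 10)
        assert np.all(out.intensities == 0)

    def test_window_larger_than_profile_rejected(self):
        prof = LaneProfile(np.arange(50, dtype=float), np.zeros(50))
        with pytest.raises(InvalidParameterError):
            subtract_background(prof, 50)


class TestDetectBands:
    def test_seven_zero_noise_bands_centered_correctly(
        self, geometry, seven_band_dist
    ):
        lane = render_lane(seven_band_dist, geometry, NoiseModel(), 1e5)
        peaks = detect_bands(subtract_background(lane, 180), 0.05, 20)
        assert len(peaks) == 7
        true_centers = geometry.band_center(seven_band_dist.lk_values)
        for p, c in zip(peaks, true_centers):
            assert abs(p.center_px - c) <= 1.0

    def test_flat_profile_yields_empty_list(self):
        prof = LaneProfile(np.arange(100, dtype=float), np.full(100, 3.0))
        assert detect_bands(prof) == []

    def test_seeded_noisy_lane_keeps_exactly_seven_bands(
        self, geometry, seven_band_dist
    ):
        lane = render_lane(seven_band_dist, geometry, NoiseModel(0, 0, 0.01, 42), 1e5)
        corrected = subtract_background(lane, 180, presmooth_sigma_px=4)
        peaks = detect_bands(corrected, 0.05, 20, smoothing_sigma_px=4)
        assert len(peaks) == 7

    def test_band_areas_proportional_to_probabilities(self, geometry, seven_band_dist):
        lane = render_lane(seven_band_dist, geometry, NoiseModel(), 1e5)
        peaks = detect_bands(subtract_background(lane, 180), 0.05, 20)
        areas = np.array([p.integrated_intensity for p in peaks])
        ratio = areas / areas.sum() / seven_band_dist.probabilities
        assert np.max(np.abs(ratio - 1)) < 0.005

    @given(
        data=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=8, max_size=64
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_local_maxima(self, data):
        """Every detected band is a strict local maximum, and every strict
        local maximum clearing the prominence bar with no taller neighbour
        within the separation window is detected."""
        y = np.asarray(data)
        prof = LaneProfile(np.arange(y.size, dtype=float), y)
        peaks = detect_bands(prof, min_prominence_frac=0.05, min_separation_px=1.0)
        got = {int(p.center_px) for p in peaks}

        def is_local_max(i):
            # walk to the edges of a flat top; both flanks must fall away
            j = i
            while j > 0 and y[j - 1] == y[i]:
                j -= 1
            k = i
            while k < y.size - 1 and y[k + 1] == y[i]:
                k += 1
            return j > 0 and y[j - 1] < y[i] and k < y.size - 1 and y[k + 1] < y[i]

        assert all(is_local_max(i) for i in got)
        strict = {
            i
            for i in range(1, y.size - 1)
            if y[i] > y[i - 1] and y[i] > y[i + 1]
        }
        # the unique global maximum must be found whenever it clears the
        # prominence bar over both full-side minima (for that peak the
        # find_peaks prominence bases are exactly the side minima)
        if y.max() > 0:
            for i in sorted(strict):
                if not all(y[j] < y[i] for j in range(y.size) if j != i):
                    continue
                clearance = y[i] - max(y[:i].min(), y[i + 1 :].min())
                if clearance >= 0.05 * y.max():
                    assert i in got

    def test_rejects_narrow_spikes_when_width_filter_on(self):
        x = np.arange(400, dtype=float)
        wide = 50 * np.exp(-0.5 * ((x - 100) / 8) ** 2)
        spike = np.zeros_like(x)
        spike[300] = 60.0
        prof = LaneProfile(x, wide + spike)
        with_filter = detect_bands(prof, 0.05, 5, min_width_px=10)
        without = detect_bands(prof, 0.05, 5)
        assert [round(p.center_px) for p in with_filter] == [100]
        assert len(without) == 2


class TestAssignLinkingNumbers:
    def test_regular_ladder_indices(self):
        table = assign_linking_numbers(_peaks([100.0, 130.0, 160.0]))
        assert table.lk_indices.tolist() == [0, 1, 2]

    def test_missing_band_leaves_gap(self):
        table = assign_linking_numbers(_peaks([100.0, 130.0, 190.0]))
        assert table.lk_indices.tolist() == [0, 1, 3]

    def test_single_peak_is_index_zero(self):
        table = assign_linking_numbers(_peaks([250.0]))
        assert table.lk_indices.tolist() == [0]

    def test_colliding_indices_raise_with_positions(self):
        with pytest.raises(AmbiguousLadderError, match="105"):
            assign_linking_numbers(_peaks([100.0, 105.0, 160.0]), expected_spacing_px=60)

    def test_explicit_origin_anchors_ladder(self):
        table = assign_linking_numbers(
            _peaks([160.0, 190.0]), expected_spacing_px=30, origin_px=100.0
        )
        assert table.lk_indices.tolist() == [2, 3]


class TestWeightedMeanLk:
    def test_examples(self):
        one = BandTable("l", [100.0], [5.0], [2])
        assert weighted_mean_lk(one) == 2.0
        two = BandTable("l", [100.0, 130.0], [3.0, 3.0], [0, 1])
        assert weighted_mean_lk(two) == 0.5
        three = BandTable("l", [100.0, 130.0, 160.0], [1.0, 2.0, 3.0], [0, 1, 2])
        assert weighted_mean_lk(three) == pytest.approx(8.0 / 6.0)

    def test_empty_table_rejected(self):
        with pytest.raises(NoBandsError):
            weighted_mean_lk(BandTable("l", [], [], []))

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InvalidBandError):
            weighted_mean_lk(BandTable("l", [100.0, 130.0], [1.0, 0.0], [0, 1]))

    @given(scale=st.floats(min_value=1e-3, max_value=1e6), shift=st.integers(0, 7))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_translation_covariance(self, scale, shift):
        base = BandTable("l", [100.0, 130.0, 160.0], [1.0, 2.0, 3.0], [0, 1, 2])
        scaled = BandTable(
            "l", base.centers_px, base.integrated_intensities * scale, base.lk_indices
        )
        assert weighted_mean_lk(scaled) == pytest.approx(weighted_mean_lk(base))
        shifted = BandTable(
            "l", base.centers_px, base.integrated_intensities, base.lk_indices + shift
        )
        assert weighted_mean_lk(shifted) == pytest.approx(weighted_mean_lk(base) + shift)


class TestRoundTrip:
    @pytest.mark.parametrize("mean_lk", np.arange(0.5, 5.01, 0.5).tolist())
    def test_zero_noise_recovery_within_002(self, geometry, mean_lk):
        dist = make_topoisomer_distribution(mean_lk, 0.8, 4)
        lane = render_lane(dist, geometry, NoiseModel(), 1e5)
        bands, wlk = quantify_profile(lane, **QUANTIFY_KW)
        # per-lane indexing starts at the topmost detected band; add back its
        # true ladder index (known from the geometry) for an absolute check
        shift = round((bands.centers_px[0] - geometry.origin_px) / geometry.spacing_px)
        assert wlk + shift == pytest.approx(dist.mean_lk, abs=0.02)
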