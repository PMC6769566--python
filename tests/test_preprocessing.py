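"""Spectral operators against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msicyto import (
    EmptyPixelError,
    PeakList,
    PixelSpectrum,
    align_peaks,
    estimate_noise,
    filter_low_intensity,
    pick_peaks,
    process_spectrum,
    smooth,
    subtract_baseline,
    tic_normalize,
)
from msicyto.preprocessing import ProcessingParams, pick_peaks_vector


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, independent of the implementation)
# ---------------------------------------------------------------------------

def oracle_baseline(y, hw):
    out = np.empty_like(y)
    for i in range(len(y)):
        window = y[max(0, i - hw): i + hw + 1]
        out[i] = max(0.0, y[i] - np.median(window))
    return out


def oracle_smooth(y, hw):
    out = np.empty_like(y)
    for i in range(len(y)):
        window = y[max(0, i - hw): i + hw + 1]
        out[i] = sum(window) / len(window)
    return out


def oracle_local_maxima(y):
    """Indices strictly above neighboring distinct values; plateaus -> leftmost."""
    peaks = []
    i = 1
    n = len(y)
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[j]:
            j += 1
        if y[i] > y[i - 1] and j + 1 < n and y[i] > y[j + 1]:
            peaks.append(i)
        i = j + 1
    return peaks


def _spec(y, mz=None):
    y = np.asarray(y, dtype=np.float64)
    mz = np.linspace(3000, 20000, y.size) if mz is None else np.asarray(mz)
    return PixelSpectrum(x=1, y=1, mz=mz, intensity=y)


class TestBaseline:
    def test_constant_spectrum_goes_to_zero(self):
        out = subtract_baseline(_spec(np.full(200, 7.0)), 10)
        assert np.all(out.intensity == 0)

    def test_matches_brute_force_on_random_spectra(self, rng):
        for _ in range(5):
            y = rng.gamma(2.0, 5.0, size=500)
            hw = int(rng.integers(1, 60))
            out = subtract_baseline(_spec(y), hw)
            np.testing.assert_array_equal(out.intensity, oracle_baseline(y, hw))

    def test_narrow_peak_on_offset_height_preserved(self):
        n, c, h = 1001, 5.0, 40.0
        y = np.full(n, c)
        center = 500
        width = np.arange(-5, 6)
        y[center + width] += h * np.exp(-0.5 * (width / 2.0) ** 2)
        out = subtract_baseline(_spec(y), 100)
        assert abs(out.intensity[center] - h) / h < 0.01

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            subtract_baseline(_spec(np.ones(5)), 4)

    def test_mz_axis_unchanged(self, rng):
        s = _spec(rng.random(300))
        out = subtract_baseline(s, 20)
        np.testing.assert_array_equal(out.mz, s.mz)


class TestSmooth:
    def test_constant_unchanged(self):
        out = smooth(_spec(np.full(100, 3.5)), 2)
        np.testing.assert_allclose(out.intensity, 3.5)

    def test_unit_impulse_becomes_flat_top(self):
        y = np.zeros(101)
        y[50] = 1.0
        out = smooth(_spec(y), 2)
        np.testing.assert_allclose(out.intensity[48:53], 0.2)
        assert np.all(out.intensity[:48] == 0) and np.all(out.intensity[53:] == 0)

    def test_matches_brute_force_on_random_spectra(self, rng):
        for _ in range(5):
            y = rng.random(400)
            hw = int(rng.integers(1, 30))
            out = smooth(_spec(y), hw)
            np.testing.assert_allclose(out.intensity, oracle_smooth(y, hw), rtol=1e-12)

    def test_interior_mass_preserved(self, rng):
        y = rng.random(500)
        hw = 3
        out = smooth(_spec(y), hw)
        # away from the edges the window weights sum to one
        assert abs(out.intensity[hw:-hw].sum() - y[hw:-hw].sum()) < y.sum() * 0.05


class TestTicNormalize:
    def test_analytic_example(self):
        out = tic_normalize(_spec([2.0, 3.0, 5.0]))
        np.testing.assert_allclose(out.intensity, [0.2, 0.3, 0.5])

    def test_output_sums_to_one(self, rng):
        out = tic_normalize(_spec(rng.random(1000) * 50))
        assert abs(out.intensity.sum() - 1.0) < 1e-12

    def test_all_zero_pixel_signals_empty(self):
        with pytest.raises(EmptyPixelError):
            tic_normalize(_spec(np.zeros(10)))


class TestEstimateNoise:
    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0.0, 1.0, 4000)
        assert 0.9 <= estimate_noise(_spec(y)) <= 1.1

    def test_all_zero_gives_zero(self):
        assert estimate_noise(_spec(np.zeros(100))) == 0.0

    def test_robust_to_single_spike(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0.0, 1.0, 2000)
        base = estimate_noise(_spec(y))
        y_spiked = y.copy()
        y_spiked[1000] = 1e6
        assert abs(estimate_noise(_spec(y_spiked)) - base) / base < 0.05

    def test_matches_scaled_mad_definition(self, rng):
        y = rng.gamma(3.0, 2.0, 500)
        expected = 1.4826 * np.median(np.abs(y - np.median(y)))
        assert estimate_noise(_spec(y)) == pytest.approx(expected, rel=1e-12)


class TestPickPeaks:
    def test_zero_spectrum_gives_no_peaks(self):
        assert len(pick_peaks(_spec(np.zeros(50)))) == 0

    def test_five_planted_gaussians_found_exactly(self):
        mz = np.linspace(3000, 20000, 2000)
        centers = [4000, 6500, 9000, 12000, 16000]
        y = sum(np.exp(-0.5 * ((mz - c) / 30.0) ** 2) for c in centers)
        pl = pick_peaks(_spec(y, mz), snr_min=0)
        found = oracle_local_maxima(y)
        np.testing.assert_array_equal(np.sort(pl.mz), np.sort(mz[found]))
        assert len(pl) == 5
        assert np.allclose(sorted(pl.mz), centers, atol=10)

    def test_snr_boundary_is_inclusive(self):
        y = np.zeros(64)
        y[10], y[30] = 5.9, 6.0
        apex, snr = pick_peaks_vector(y, noise=1.0, snr_min=6.0)
        assert list(apex) == [30]
        assert snr[0] == pytest.approx(6.0)

    def test_plateau_resolved_to_leftmost(self):
        y = np.array([0.0, 1.0, 3.0, 3.0, 3.0, 1.0, 0.0])
        apex, _ = pick_peaks_vector(y, noise=0.0, snr_min=0.0)
        assert list(apex) == [2]

    def test_matches_brute_force_local_maxima(self, rng):
        for _ in range(20):
            y = np.round(rng.random(200) * 20) / 4  # coarse grid forces plateaus
            apex, _ = pick_peaks_vector(y, noise=0.0, snr_min=0.0)
            assert list(apex) == oracle_local_maxima(y)

    def test_noise_wiring_uses_scaled_mad(self, rng):
        y = np.abs(rng.normal(0.0, 1.0, 1000))
        y[500] = 50.0
        pl = pick_peaks(_spec(y), snr_min=6.0)
        noise = estimate_noise(_spec(y))
        assert np.all(pl.intensity / noise >= 6.0)


class TestFilterLowIntensity:
    def test_boundary_inclusive(self):
        pl = PeakList("o", mz=[4000.0, 5000.0, 6000.0],
                      intensity=[0.0001, 0.0003, 0.0005], snr=[9, 9, 9])
        out = filter_low_intensity(pl, 0.0003)
        np.testing.assert_array_equal(out.intensity, [0.0003, 0.0005])

    def test_empty_list_passes_through(self):
        pl = PeakList("o", mz=[], intensity=[], snr=[])
        assert len(filter_low_intensity(pl)) == 0

    def test_zero_threshold_is_identity(self):
        pl = PeakList("o", mz=[4000.0, 5000.0], intensity=[0.1, 0.2], snr=[9, 9])
        np.testing.assert_array_equal(filter_low_intensity(pl, 0.0).intensity, pl.intensity)

    def test_literal_reading_switch_inverts(self):
        pl = PeakList("o", mz=[4000.0, 5000.0], intensity=[0.0001, 0.0005], snr=[9, 9])
        out = filter_low_intensity(pl, 0.0003, keep_below=True)
        np.testing.assert_array_equal(out.intensity, [0.0001])


class TestAlignPeaks:
    def _pl(self, mzs, intens, name="o"):
        return PeakList(name, mz=mzs, intensity=intens, snr=np.full(len(mzs), 9.0))

    def test_wide_gap_splits_into_two_features(self):
        # 8000 vs 8008 Da: 1000 ppm gap > 500 ppm tolerance
        grid, fm = align_peaks(
            [self._pl([8000.0], [1.0]), self._pl([8008.0], [1.0], "p")], 500
        )
        assert len(grid) == 2

    def test_narrow_gap_merges_at_weighted_mean(self):
        grid, fm = align_peaks(
            [self._pl([8000.0], [3.0]), self._pl([8008.0], [1.0], "p")], 2000
        )
        assert len(grid) == 1
        assert grid.features[0] == pytest.approx((8000 * 3 + 8008 * 1) / 4)

    def test_single_list_is_identity(self):
        pl = self._pl([4000.0, 5000.0, 6000.0], [0.1, 0.2, 0.3])
        grid, fm = align_peaks([pl], 2000)
        np.testing.assert_allclose(grid.features, pl.mz)
        np.testing.assert_allclose(fm.intensities[0], pl.intensity)
        assert fm.detected.sum() == 3

    def test_all_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="no features|empty"):
            align_peaks([self._pl([], [])], 2000)

    def test_absent_feature_is_zero_with_detection_mask(self):
        grid, fm = align_peaks(
            [self._pl([4000.0, 9000.0], [0.5, 0.5]), self._pl([4000.0], [0.7], "p")],
            2000,
        )
        assert fm.intensities[1, 1] == 0.0
        assert fm.detected[1, 1] == 0 and fm.detected[1, 0] == 1

    def test_feature_count_non_increasing_in_tolerance(self, rng):
        lists = [
            self._pl(np.sort(rng.uniform(3000, 20000, 15)), rng.random(15), str(k))
            for k in range(4)
        ]
        counts = [len(align_peaks(lists, tol)[0]) for tol in (10, 100, 1000, 10000, 100000)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_gap_clustering(self, rng):
        mzs = np.sort(rng.uniform(3000, 20000, 40))
        tol = 3000.0
        # oracle: sequential scan cutting on relative gaps
        clusters, current = [], [mzs[0]]
        for a, b in zip(mzs[:-1], mzs[1:]):
            if (b - a) > a * tol * 1e-6:
                clusters.append(current)
                current = []
            current.append(b)
        clusters.append(current)
        grid, _ = align_peaks([self._pl(mzs, np.ones(40))], tol)
        assert len(grid) == len(clusters)
        np.testing.assert_allclose(grid.features, [np.mean(c) for c in clusters])


class TestProcessSpectrum:
    def test_planted_peaks_survive_full_chain(self):
        mz = np.linspace(3000, 20000, 4000)
        centers = [4000.0, 7000.0, 11000.0]
        y = 30.0 * np.exp(-(mz - 3000) / 3000)  # baseline
        for c in centers:
            y += 100.0 * np.exp(-0.5 * ((mz - c) / 17.0) ** 2)
        pl = process_spectrum(_spec(y, mz))
        for c in centers:
            assert np.min(np.abs(pl.mz - c)) < 20.0

    def test_all_zero_pixel_signals_empty(self):
        with pytest.raises(EmptyPixelError):
            process_spectrum(_spec(np.zeros(200)))

    def test_chain_output_is_tic_scale(self):
        mz = np.linspace(3000, 20000, 2000)
        y = 50.0 * np.exp(-0.5 * ((mz - 8000) / 20.0) ** 2) + 1.0
        pl = process_spectrum(_spec(y, mz))
        assert np.all(pl.intensity <= 1.0) and np.all(pl.intensity >= 0.0003)


class TestOperatorProperties:
    @settings(max_examples=30, deadline=None)
    @given(
        data=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=30, max_size=200),
        hw=st.integers(1, 10),
    )
    def test_baseline_and_smooth_match_oracles(self, data, hw):
        y = np.asarray(data)
        if y.size < 2 * hw + 1:
            return
        np.testing.assert_array_equal(
            subtract_baseline(_spec(y), hw).intensity, oracle_baseline(y, hw)
        )
        np.testing.assert_allclose(
            smooth(_spec(y), hw).intensity, oracle_smooth(y, hw), rtol=1e-9, atol=1e-12
        )

    @settings(max_examples=30, deadline=None)
    @given(data=st.lists(st.floats(0, 1e4), min_size=20, max_size=200))
    def test_chain_never_produces_negatives_or_nan(self, data):
        y = np.asarray(data)
        out = smooth(subtract_baseline(_spec(y), 5), 2)
        assert np.all(out.intensity >= 0) and np.all(np.isfinite(out.intensity))
        if out.intensity.sum() > 0:
            norm = tic_normalize(out)
            assert abs(norm.intensity.sum() - 1.0) < 1e-12
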