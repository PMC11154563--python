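import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppghb.dsp import Landmarks
from ppghb.errors import QualityError
from ppghb.features import (
    extract_ac,
    extract_dc,
    extract_features,
    quality_features,
    select_min_variance_mean,
    sliding_mean_variance,
)
from ppghb.synth import SimConfig, simulate


def brute_stats(x, dn):
    from numpy.lib.stride_tricks import sliding_window_view
    wins = sliding_window_view(np.asarray(x, dtype=float), dn)
    return wins.mean(axis=1), wins.var(axis=1)


class TestSlidingMeanVariance:
    def test_constant_sequence(self):
        stats = sliding_mean_variance([5, 5, 5, 5], 2)
        assert [s.mean for s in stats] == [5, 5, 5]
        assert [s.variance for s in stats] == [0, 0, 0]

    def test_hand_computed_example(self):
        stats = sliding_mean_variance([1, 2, 3, 4], 2)
        assert [s.mean for s in stats] == [1.5, 2.5, 3.5]
        assert [s.variance for s in stats] == [0.25, 0.25, 0.25]

    def test_recursion_matches_bruteforce_on_long_sequence(self, rng):
        x = rng.normal(size=1000)
        stats = sliding_mean_variance(x, 50)
        means, variances = brute_stats(x, 50)
        got_m = np.array([s.mean for s in stats])
        got_v = np.array([s.variance for s in stats])
        assert np.max(np.abs(got_m - means) / np.maximum(np.abs(means), 1e-30)) < 1e-9
        assert np.max(np.abs(got_v - variances) / np.maximum(variances, 1e-30)) < 1e-9

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_recursion_equals_direct_summation(self, data):
        x = data.draw(st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=60))
        dn = data.draw(st.integers(2, len(x)))
        stats = sliding_mean_variance(x, dn)
        means, variances = brute_stats(x, dn)
        np.testing.assert_allclose([s.mean for s in stats], means,
                                   rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose([s.variance for s in stats], variances,
                                   rtol=1e-7, atol=1e-7)

    def test_window_bounds(self):
        with pytest.raises(ValueError):
            sliding_mean_variance([1, 2, 3], 1)
        with pytest.raises(ValueError):
            sliding_mean_variance([1, 2, 3], 4)


class TestSelectMinVariance:
    def test_picks_flat_window(self):
        mean, var = select_min_variance_mean([10, 10, 10, 2])
        assert (mean, var) == (10.0, 0.0)

    def test_all_equal(self):
        mean, var = select_min_variance_mean([3.3] * 6)
        assert mean == pytest.approx(3.3, rel=1e-12)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_three_values_clamped_window(self):
        # window = max(2, 3 // 2) = 2; (8,7) var 0.25 beats (7,3) var 4
        mean, var = select_min_variance_mean([8, 7, 3])
        assert mean == 7.5
        assert var == 0.25

    def test_tie_goes_to_lowest_start(self):
        mean, _ = select_min_variance_mean([4, 4, 2, 2], window=2)
        assert mean == 4.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            select_min_variance_mean([1.0])


def make_beat_trace(amplitudes, baseline=0.0):
    """Trace with troughs at even indices (baseline) and peaks in between."""
    amplitudes = list(amplitudes)
    n = 2 * len(amplitudes) + 1
    x = np.full(n, baseline)
    peaks = np.arange(1, n, 2)
    troughs = np.arange(0, n, 2)
    x[peaks] = baseline + np.asarray(amplitudes)
    return x, Landmarks(peak_indices=peaks, trough_indices=troughs)


class TestExtractAC:
    def test_identical_amplitudes_recovered_exactly(self):
        x, lm = make_beat_trace([2.0] * 10)
        ac, min_var = extract_ac(x, lm)
        assert ac == pytest.approx(2.0, abs=1e-12)
        assert min_var == 0.0

    @pytest.mark.parametrize("outliers", [[0.2], [0.2, 0.1], [10.0], [9.0, 0.1]])
    def test_invariant_to_appended_corrupted_beats(self, outliers):
        clean, lm_clean = make_beat_trace([2.0] * 20)
        ac_clean, _ = extract_ac(clean, lm_clean)
        corrupted, lm_corr = make_beat_trace([2.0] * 20 + outliers)
        ac_corr, _ = extract_ac(corrupted, lm_corr)
        assert abs(ac_corr - ac_clean) < 1e-9

    def test_too_few_landmarks(self):
        x, _ = make_beat_trace([1.0])
        lm = Landmarks(peak_indices=np.array([1]), trough_indices=np.array([0]))
        with pytest.raises(QualityError):
            extract_ac(x, lm)


class TestExtractDC:
    def test_constant_baseline_exact(self):
        x, lm = make_beat_trace([1.0] * 8, baseline=130.0)
        assert extract_dc(x, lm) == pytest.approx(130.0, abs=1e-12)

    def test_drift_corrupted_trough_excluded(self):
        x, lm = make_beat_trace([1.0] * 5, baseline=100.0)
        x[lm.trough_indices[2]] = 80.0  # one trough dragged down by drift
        # sorted troughs: five at 100 then 80; window 3 picks a flat 100-window
        assert extract_dc(x, lm) == pytest.approx(100.0, abs=1e-12)

    def test_too_few_troughs(self):
        lm = Landmarks(peak_indices=np.array([1]), trough_indices=np.array([0]))
        with pytest.raises(QualityError):
            extract_dc(np.zeros(4), lm)


class TestExtractFeatures:
    def test_clean_record_recovers_ground_truth(self, clean_record):
        rec, truth = clean_record
        feats, vec = extract_features(rec)
        got = np.array([f.ratio for f in feats])
        np.testing.assert_allclose(got, truth.ratio, rtol=0.02)
        ac = np.array([f.ac for f in feats])
        dc = np.array([f.dc for f in feats])
        np.testing.assert_allclose(ac, truth.ac, rtol=0.02)
        np.testing.assert_allclose(dc, truth.dc, rtol=0.02)
        assert len(vec) == 9

    def test_channel_order_is_wavelength_then_broadband(self, clean_record):
        rec, _ = clean_record
        feats, _ = extract_features(rec)
        wl = [f.wavelength_nm for f in feats if not f.broadband]
        assert wl == sorted(wl)
        assert feats[-1].broadband

    def test_ratios_monotone_in_hemoglobin(self, ext_table):
        rec_lo, _ = simulate(SimConfig(hb_g_per_L=90, seed=4), ext_table)
        rec_hi, _ = simulate(SimConfig(hb_g_per_L=150, seed=4), ext_table)
        _, lo = extract_features(rec_lo)
        _, hi = extract_features(rec_hi)
        assert np.all(hi.ratios > lo.ratios)

    def test_constant_pressure_ninth_feature(self, clean_record):
        rec, _ = clean_record
        rec_p = type(rec)(
            time=rec.time, channels=rec.channels,
            wavelengths_nm=rec.wavelengths_nm, broadband=rec.broadband,
            pressure=np.full(rec.n_samples, 3.0),
            displacement=rec.displacement, fs_hz=rec.fs_hz)
        _, vec = extract_features(rec_p)
        assert vec.values[-1] == pytest.approx(3.0, abs=1e-12)

    def test_scale_equivariance(self, clean_record):
        rec, _ = clean_record
        k = 2.5
        scaled = type(rec)(
            time=rec.time, channels=k * rec.channels,
            wavelengths_nm=rec.wavelengths_nm, broadband=rec.broadband,
            pressure=rec.pressure, displacement=rec.displacement, fs_hz=rec.fs_hz)
        base, vec0 = extract_features(rec)
        feats, vec1 = extract_features(scaled)
        # equivariance holds to floating-point round-off (the FFT-based
        # filtering and the variance floor perturb the last few digits)
        for f0, f1 in zip(base, feats):
            assert f1.ac == pytest.approx(k * f0.ac, rel=1e-6)
            assert f1.dc == pytest.approx(k * f0.dc, rel=1e-6)
            assert f1.ratio == pytest.approx(f0.ratio, rel=1e-6)
        np.testing.assert_allclose(vec1.ratios, vec0.ratios, rtol=1e-6)

    def test_failed_channel_is_reported(self, clean_record):
        rec, _ = clean_record
        broken = rec.channels.copy()
        broken[:, 0] = 1.0  # flat channel: no landmarks
        bad = type(rec)(
            time=rec.time, channels=broken, wavelengths_nm=rec.wavelengths_nm,
            broadband=rec.broadband, pressure=rec.pressure,
            displacement=rec.displacement, fs_hz=rec.fs_hz)
        with pytest.raises(QualityError, match="660"):
            extract_features(bad)

    def test_quality_features_flag_broken_record(self, clean_record):
        rec, _ = clean_record
        good = quality_features(rec)
        broken = rec.channels.copy()
        broken[:, 3] = 1.0
        bad = type(rec)(
            time=rec.time, channels=broken, wavelengths_nm=rec.wavelengths_nm,
            broadband=rec.broadband, pressure=rec.pressure,
            displacement=rec.displacement, fs_hz=rec.fs_hz)
        worst = quality_features(bad)
        assert worst[0] > good[0]
        assert worst[1] == 0 and worst[2] == 0  # sentinel channel dominates
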