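import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressband import hrv, simulate
from stressband.hrv import (
    ArtifactRuleConfig,
    RRSegment,
    UnusableSeriesError,
    correct_rr,
    detect_rr_artifacts,
    hrv_freq_features,
    hrv_geometric_features,
    hrv_time_features,
    segment_beats,
)
from stressband.io_e4 import BeatSeries, ValidationError


def _series(ibis_ms):
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    return BeatSeries(0.0, np.cumsum(ibis_ms) / 1000.0, ibis_ms)


def _segment(ibis_ms):
    b = _series(ibis_ms)
    return RRSegment(0.0, b.beat_times[-1], b.beat_times, b.ibis)


def oracle_time_features(ibis):
    """Independent brute-force formulas over the interval list."""
    n = len(ibis)
    mean = sum(ibis) / n
    std = (sum((x - mean) ** 2 for x in ibis) / (n - 1)) ** 0.5
    d = [ibis[i + 1] - ibis[i] for i in range(n - 1)]
    rmssd = (sum(x * x for x in d) / len(d)) ** 0.5
    pnn50 = 100.0 * sum(1 for x in d if abs(x) > 50.0) / len(d)
    if len(d) > 1:
        dm = sum(d) / len(d)
        sdsd = (sum((x - dm) ** 2 for x in d) / (len(d) - 1)) ** 0.5
    else:
        sdsd = 0.0
    return mean, std, pnn50, rmssd, sdsd


class TestArtifactRule:
    def test_deviant_interval_flagged_against_local_median(self):
        beats = _series([800, 810, 790, 805, 1000, 800, 805, 795, 800])
        mask = detect_rr_artifacts(beats)
        # 1000 deviates ~25% from the local median of accepted neighbours
        assert mask[4]
        assert mask.sum() == 1

    def test_constant_series_has_no_artifacts(self):
        mask = detect_rr_artifacts(_series([800.0] * 50))
        assert not mask.any()

    def test_short_series_warns_and_returns_all_false(self):
        with pytest.warns(UserWarning, match="shorter than window"):
            mask = detect_rr_artifacts(_series([800, 810, 790]))
        assert not mask.any()

    def test_spike_run_does_not_drag_its_own_reference(self):
        # three consecutive 1.5x spikes: a causal accepted-only reference
        # flags them all, a naive running mean would not
        ibis = [800.0] * 10 + [1200.0] * 3 + [800.0] * 10
        mask = detect_rr_artifacts(_series(ibis))
        assert mask[10:13].all()
        assert mask.sum() == 3

    def test_injected_spike_recall(self):
        phys = simulate.easy_config().classes["mild"]
        rng = np.random.default_rng(7)
        beats = simulate.simulate_rr(phys, 600.0, rng)
        spike = rng.random(len(beats)) < 0.05
        ibis = beats.ibis.copy()
        ibis[spike] *= np.where(rng.random(spike.sum()) < 0.5, 1.5, 0.5)
        noisy = BeatSeries(0.0, beats.beat_times, ibis)
        mask = detect_rr_artifacts(noisy)
        recall = (mask & spike).sum() / spike.sum()
        assert recall >= 0.90


class TestCorrection:
    def test_all_false_mask_is_identity(self):
        beats = _series([800, 810, 790, 805, 795])
        out = correct_rr(beats, np.zeros(5, dtype=bool))
        np.testing.assert_array_equal(out.ibis, beats.ibis)
        np.testing.assert_array_equal(out.beat_times, beats.beat_times)

    def test_spline_restores_point_on_linear_ramp(self):
        ibis = np.linspace(700, 900, 11)
        beats = _series(ibis)
        mask = np.zeros(11, dtype=bool)
        mask[5] = True
        broken = BeatSeries(0.0, beats.beat_times, np.where(mask, 1200.0, ibis))
        out = correct_rr(broken, mask)
        # a cubic spline through collinear points is the line itself
        assert out.ibis[5] == pytest.approx(ibis[5], rel=1e-6)

    def test_unflagged_beats_unchanged(self, rng):
        ibis = 800 + 30 * rng.standard_normal(100)
        beats = _series(ibis)
        mask = rng.random(100) < 0.1
        out = correct_rr(beats, mask)
        np.testing.assert_array_equal(out.beat_times, beats.beat_times)
        np.testing.assert_array_equal(out.ibis[~mask], beats.ibis[~mask])

    def test_corrected_mean_close_to_clean_mean(self):
        phys = simulate.easy_config().classes["relax"]
        rng = np.random.default_rng(11)
        beats = simulate.simulate_rr(phys, 600.0, rng)
        clean_mean = beats.ibis.mean()
        spike = rng.random(len(beats)) < 0.05
        ibis = beats.ibis.copy()
        ibis[spike] *= 1.5
        noisy = BeatSeries(0.0, beats.beat_times, ibis)
        out = correct_rr(noisy, detect_rr_artifacts(noisy))
        assert abs(out.ibis.mean() - clean_mean) / clean_mean < 0.01

    def test_mostly_flagged_series_unusable(self):
        beats = _series([800.0] * 10)
        mask = np.ones(10, dtype=bool)
        mask[:4] = False
        with pytest.raises(UnusableSeriesError):
            correct_rr(beats, mask)


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration,expected", [(600.0, 9), (120.0, 1), (119.0, 0), (180.0, 2)]
    )
    def test_window_count_at_50_percent_overlap(self, duration, expected):
        ibis = [800.0] * int(duration / 0.8 + 5)
        beats = _series(ibis)
        segs = segment_beats(beats, 120.0, 0.5, duration=duration)
        assert len(segs) == expected
        if expected:
            assert [s.t_start for s in segs] == [60.0 * k for k in range(expected)]

    def test_low_quality_windows_dropped(self):
        beats = _series([800.0] * 200)
        interp = np.zeros(200, dtype=bool)
        interp[:100] = True  # first window mostly interpolated
        segs = segment_beats(beats, 60.0, 0.5, interpolated=interp, min_beats=10)
        assert all(s.t_start >= 60.0 for s in segs)


class TestTimeFeatures:
    def test_rmssd_hand_oracle(self):
        f = hrv_time_features(_segment([800, 810, 790, 805]))
        assert f.rmssd == pytest.approx((np.mean([100, 400, 225])) ** 0.5)

    def test_pnn50_counts_only_jumps_over_50ms(self):
        f = hrv_time_features(_segment([800, 860, 855, 900]))
        assert f.pnn50 == pytest.approx(100.0 / 3.0)

    def test_constant_series_has_zero_variability(self):
        f = hrv_time_features(_segment([800.0] * 20))
        assert f.std_rr == f.rmssd == f.sdsd == f.pnn50 == 0.0

    def test_matches_brute_force_oracle_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            ibis = rng.uniform(500, 1100, size=n)
            f = hrv_time_features(_segment(ibis))
            mean, std, pnn50, rmssd, sdsd = oracle_time_features(list(ibis))
            assert f.mean_rr == pytest.approx(mean, abs=1e-9)
            assert f.std_rr == pytest.approx(std, abs=1e-9)
            assert f.pnn50 == pytest.approx(pnn50, abs=1e-9)
            assert f.rmssd == pytest.approx(rmssd, abs=1e-9)
            assert f.sdsd == pytest.approx(sdsd, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=400.0, max_value=1500.0), min_size=3, max_size=60)
    )
    def test_oracle_equivalence_property(self, ibis):
        f = hrv_time_features(_segment(ibis))
        mean, std, pnn50, rmssd, sdsd = oracle_time_features(ibis)
        assert f.mean_rr == pytest.approx(mean, abs=1e-9)
        assert f.rmssd == pytest.approx(rmssd, abs=1e-9)
        assert f.pnn50 == pytest.approx(pnn50, abs=1e-9)

    def test_too_few_intervals_error(self):
        with pytest.raises(ValidationError):
            hrv_time_features(_segment([800.0]))


class TestGeometricFeatures:
    def test_single_bin_gives_unit_triangular_index(self):
        f = hrv_geometric_features(_segment([800.0] * 30))
        assert f.hrv_ti == pytest.approx(1.0)
        assert f.tinn == 0.0

    def test_two_bin_histogram_count_oracle(self):
        bw = hrv.HIST_BIN_MS
        # 6 intervals in one bin, 2 in the next
        ibis = [bw * 100 + 0.1 * bw] * 6 + [bw * 101 + 0.1 * bw] * 2
        f = hrv_geometric_features(_segment(ibis))
        assert f.hrv_ti == pytest.approx(8.0 / 6.0)

    def test_tinn_recovers_triangle_base(self):
        bw = hrv.HIST_BIN_MS
        # build a symmetric triangular histogram: counts 1,2,3,4,3,2,1
        counts = [1, 2, 3, 4, 3, 2, 1]
        ibis = []
        for j, c in enumerate(counts):
            ibis += [bw * (100 + j) + 0.5 * bw] * c
        f = hrv_geometric_features(_segment(ibis))
        # base runs from the empty bin left of the first to the right of the
        # last occupied one: 8 bin widths
        assert f.tinn == pytest.approx(8 * bw, abs=1e-9)


class TestFrequencyFeatures:
    def _tone(self, freq, duration=300.0, amp=40.0):
        times, ibis, t = [], [], 0.0
        while t < duration:
            rr = 800.0 + amp * np.sin(2 * np.pi * freq * t)
            t += rr / 1000.0
            times.append(t)
            ibis.append(rr)
        return RRSegment(0.0, duration, np.array(times), np.array(ibis))

    def test_constant_tachogram_has_no_power(self):
        seg = _segment([800.0] * 200)
        f = hrv_freq_features(seg)
        assert f.lf + f.hf + f.vlf < 1e-6

    def test_hf_tone_dominates_hf_band(self):
        f = hrv_freq_features(self._tone(0.25))
        assert f.hf / (f.lf + f.hf) > 0.9
        assert f.phf == pytest.approx(0.25, abs=1.0 / 300.0)

    def test_lf_tone_dominates_lf_band(self):
        f = hrv_freq_features(self._tone(0.10))
        assert f.lf_hf > 5
        assert f.plf == pytest.approx(0.10, abs=1.0 / 300.0)

    def test_parseval_total_power_matches_variance(self):
        seg = self._tone(0.25, duration=240.0)
        from scipy.interpolate import CubicSpline
        from scipy.signal import periodogram

        spline = CubicSpline(seg.beat_times, seg.ibis)
        grid = np.arange(seg.beat_times[0], seg.beat_times[-1], 0.25)
        y = spline(grid) - spline(grid).mean()
        f = hrv_freq_features(seg, window="boxcar", detrend="constant")
        total = f.lf + f.hf + f.vlf
        # add the residual band above HF for the full-spectrum comparison
        freqs, psd = periodogram(y, fs=4.0, window="boxcar", scaling="density")
        above = float(np.sum(psd[freqs >= 0.40]) * (freqs[1] - freqs[0]))
        assert total + above == pytest.approx(np.var(y), rel=0.05)

    def test_too_few_beats_error(self):
        with pytest.raises(ValidationError):
            hrv_freq_features(_segment([800.0, 810.0, 790.0]))


class TestConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ValidationError):
            ArtifactRuleConfig(threshold=1.5)

    def test_window_must_be_odd(self):
        with pytest.raises(ValidationError):
            ArtifactRuleConfig(window=4)
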