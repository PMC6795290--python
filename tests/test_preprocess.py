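"""Preprocessing chain: stitching, artifact removal, binning, smoothing, profiles."""

import numpy as np
import pandas as pd
import pytest

from circaphase.core import TimeSeries, ValidationError
from circaphase.preprocess import (aggregate_5min, average_24h_profile,
                                   lag_correlation, moving_average,
                                   remove_ingestion_artifacts, stitch_pills)


def series_from_hours(hours, values, subject="S1", unit="degC", channel="core_temp"):
    base = pd.Timestamp("2024-01-01 00:00")
    idx = pd.DatetimeIndex([base + pd.Timedelta(hours=h) for h in hours])
    return TimeSeries(idx, np.asarray(values, float), unit, subject, channel)


def minute_grid(start_h, end_h, fn, **kw):
    hours = np.arange(start_h, end_h, 1.0 / 60.0)
    return series_from_hours(hours, fn(hours), **kw)


class TestStitchPills:
    def test_empty_second_pill_identity(self):
        p1 = minute_grid(8, 32, lambda h: 37.0 + 0.0 * h)
        p2 = TimeSeries(pd.DatetimeIndex([]), [], "degC", "S1", "core_temp")
        out = stitch_pills(p1, p2)
        assert np.array_equal(out.values, p1.values)

    def test_counting_oracle(self):
        # pill1: hours 0..48; pill2: hours 24..72 -> output = pill1 + pill2 after 48
        p1 = minute_grid(0, 48, lambda h: 37.0 + 0.1 * np.cos(h))
        p2 = minute_grid(24, 72, lambda h: 37.0 + 0.1 * np.cos(h))
        out = stitch_pills(p1, p2)
        n_after = int(np.sum(p2.timestamps > p1.timestamps[-1]))
        assert len(out) == len(p1) + n_after

    def test_no_discontinuity_noiseless(self):
        fn = lambda h: 37.0 + 0.3 * np.cos(2 * np.pi * (h - 4) / 24.0)
        p1 = minute_grid(8, 40, fn)
        p2 = minute_grid(32, 70, fn)
        out = stitch_pills(p1, p2)
        jumps = np.abs(np.diff(out.values))
        assert jumps.max() < 0.01  # minute-to-minute slope of the cosine only

    def test_monotone_output(self):
        p1 = minute_grid(0, 30, lambda h: 37.0 + 0 * h)
        p2 = minute_grid(20, 50, lambda h: 37.0 + 0 * h)
        out = stitch_pills(p1, p2)
        assert (np.diff(out.timestamps.asi8) > 0).all()

    def test_gap_warns_but_stitches(self):
        p1 = minute_grid(0, 10, lambda h: 37.0 + 0 * h)
        p2 = minute_grid(40, 50, lambda h: 37.0 + 0 * h)
        with pytest.warns(UserWarning, match="gap"):
            out = stitch_pills(p1, p2)
        assert len(out) == len(p1) + len(p2)

    def test_identical_starts_rejected(self):
        p1 = minute_grid(0, 10, lambda h: 37.0 + 0 * h)
        p2 = minute_grid(0, 12, lambda h: 37.0 + 0 * h)
        with pytest.raises(ValidationError):
            stitch_pills(p1, p2)


class TestArtifacts:
    def test_clean_series_unchanged(self):
        s = minute_grid(0, 6, lambda h: 37.0 + 0 * h)
        assert len(remove_ingestion_artifacts(s)) == len(s)

    def test_spike_in_window_removed(self):
        vals = np.full(360, 37.0)
        vals[10] = 20.0
        s = series_from_hours(np.arange(360) / 60.0, vals)
        out = remove_ingestion_artifacts(s, window_h=3.0)
        assert len(out) == 359
        assert 20.0 not in out.values

    def test_spike_past_window_retained(self):
        hours = np.arange(0, 40, 1.0 / 60.0)
        vals = np.full(hours.size, 37.0)
        vals[30 * 60] = 41.0  # hour 30, far beyond the window
        s = series_from_hours(hours, vals)
        out = remove_ingestion_artifacts(s, window_h=3.0)
        assert 41.0 in out.values


class TestAggregate:
    def test_constant(self):
        s = minute_grid(0, 2, lambda h: np.full(h.size, 37.0))
        out = aggregate_5min(s)
        assert np.allclose(out.values, 37.0)

    def test_bin_mean(self):
        s = series_from_hours([0.0, 1 / 60, 2 / 60], [36.8, 37.0, 37.2])
        out = aggregate_5min(s)
        assert len(out) == 1
        assert out.values[0] == pytest.approx(37.0)

    def test_bin_count_oracle(self):
        hours = np.arange(0, 3.0, 1.0 / 60.0)  # 180 minutes -> 36 full bins
        s = series_from_hours(hours, np.ones(hours.size))
        assert len(aggregate_5min(s)) == 36

    def test_clock_alignment(self):
        s = series_from_hours([0.05, 0.1], [1.0, 2.0])  # 00:03 and 00:06
        out = aggregate_5min(s)
        assert out.timestamps[0].minute == 0 and out.timestamps[1].minute == 5


class TestMovingAverage:
    def test_constant_unchanged(self):
        s = minute_grid(0, 24, lambda h: np.full(h.size, 5.0))
        assert np.allclose(moving_average(aggregate_5min(s)).values, 5.0)

    def test_spike_attenuation_hand_value(self):
        # 5-min bins; +1.2 degC spike in one bin -> 1.2/12 = 0.1 at the center
        vals = np.full(48, 36.0)
        vals[24] = 37.2
        s = series_from_hours(np.arange(48) / 12.0, vals)  # already 5-min spacing
        out = moving_average(s, window_min=60.0)
        assert out.values[24] == pytest.approx(36.0 + 0.1)

    def test_linear_trend_slope_preserved(self):
        s = series_from_hours(np.arange(48) / 12.0, np.arange(48) * 0.5)
        out = moving_average(s)
        inner = out.values[8:-8]
        assert np.allclose(np.diff(inner), 0.5, atol=1e-9)

    def test_mean_preserved_and_constant_commutes(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(37.0, 0.2, 288)
        s = series_from_hours(np.arange(288) / 12.0, vals)
        sm = moving_average(s)
        # adding a constant commutes
        s2 = s.replace(values=vals + 1.5)
        assert np.allclose(moving_average(s2).values, sm.values + 1.5, atol=1e-12)


class TestDailyProfile:
    def test_two_identical_days(self):
        fn = lambda h: 37.0 + 0.3 * np.cos(2 * np.pi * h / 24.0)
        s = minute_grid(0, 48, lambda h: fn(np.mod(h, 24.0)))
        prof = average_24h_profile(aggregate_5min(s))
        one_day = aggregate_5min(minute_grid(0, 24, fn))
        assert np.allclose(prof.values, one_day.values, atol=1e-12)

    def test_bin_mean_across_days(self):
        s = series_from_hours([0.0, 0.5, 24.0, 48.0], [1.0, 0.0, 2.0, 3.0])
        prof = average_24h_profile(s)
        assert prof.values[0] == pytest.approx(2.0)  # mean of 1, 2, 3

    def test_short_series_rejected(self):
        s = minute_grid(0, 20, lambda h: 37.0 + 0 * h)
        with pytest.raises(ValidationError):
            average_24h_profile(s)

    def test_cosine_acrophase_preserved(self):
        peak = 17.0 + 40.0 / 60.0
        fn = lambda h: 36.8 + 0.3 * np.cos(2 * np.pi * (h - peak) / 24.0)
        s = minute_grid(0, 72, fn)
        prof = average_24h_profile(aggregate_5min(s))
        # grid-search oracle on the profile values
        best_bin = np.nanargmax(prof.values)
        assert abs(prof.bin_center_hours[best_bin] - peak) <= 5.0 / 60.0


class TestLagCorrelation:
    def _pair(self, shift_min=0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        hours = np.arange(0, 30, 1.0 / 60.0)
        sig = 0.5 * np.cos(2 * np.pi * hours / 24.0) + 0.2 * np.sin(2 * np.pi * hours / 6.0)
        a = series_from_hours(hours, sig + rng.normal(0, noise, hours.size))
        b = series_from_hours(hours + shift_min / 60.0,
                              sig + rng.normal(0, noise, hours.size))
        return a, b

    def test_identity(self):
        a, _ = self._pair()
        best, r = lag_correlation(a, a, max_lag_min=10)
        assert best == 0 and r[0] == pytest.approx(1.0)

    def test_shifted_copy_sign_convention(self):
        a, b = self._pair(shift_min=7)
        best, _ = lag_correlation(a, b, max_lag_min=15)
        assert best == -7

    def test_white_noise_low_correlation(self):
        rng = np.random.default_rng(1)
        hours = np.arange(0, 30, 1.0 / 60.0)
        a = series_from_hours(hours, rng.normal(size=hours.size))
        b = series_from_hours(hours, rng.normal(size=hours.size))
        _, r = lag_correlation(a, b, max_lag_min=10)
        assert np.nanmax(np.abs(r.to_numpy())) < 0.15

    def test_no_overlap_rejected(self):
        a = minute_grid(0, 25, lambda h: h)
        b = minute_grid(30, 55, lambda h: h)
        with pytest.raises(ValidationError):
            lag_correlation(a, b)
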