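"""Raw pill and chest series to clean, averaged 24-hour profiles.

The chain, applied identically to core and chest surface temperature:
drop ingestion artifacts from the start of each pill segment, stitch the
two pill segments into one series (first pill until its elimination, second
pill thereafter), aggregate to 5-minute means on clock-aligned bins, smooth
with a centred 1-hour moving average, then average over days into a single
24-hour profile on a 5-minute grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TimeSeries, ValidationError

__all__ = [
    "DailyProfile",
    "stitch_pills",
    "remove_ingestion_artifacts",
    "aggregate_5min",
    "moving_average",
    "average_24h_profile",
    "lag_correlation",
]

log = logging.getLogger("circaphase.preprocess")


@dataclass
class DailyProfile:
    """Averaged 24-hour profile on a 5-minute clock grid.

    ``minutes`` are the left edges of the bins (0, 5, ..., 1435); bins that
    received no data carry NaN values and a zero count, never a silent zero.
    """

    minutes: np.ndarray          # minute-of-day left edges, length 288
    values: np.ndarray           # mean per bin, NaN where empty
    counts: np.ndarray           # samples contributing to each bin
    channel: str = ""
    subject_id: str = ""
    bin_width_min: int = 5

    def __post_init__(self) -> None:
        if len(self.minutes) != len(self.values) or len(self.values) != len(self.counts):
            raise ValidationError("profile arrays differ in length")
        expected = np.arange(0, 1440, self.bin_width_min)
        if not np.array_equal(np.asarray(self.minutes), expected):
            raise ValidationError("profile grid must cover the full 24 h at the bin width")

    @property
    def bin_center_hours(self) -> np.ndarray:
        return (np.asarray(self.minutes, dtype=float) + self.bin_width_min / 2.0) / 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"minute_of_day": self.minutes, "value": self.values,
                             "count": self.counts})


def stitch_pills(pill1: TimeSeries, pill2: TimeSeries) -> TimeSeries:
    """Link the two pill segments into a single core temperature series.

    The first pill contributes every sample up to its last one (elimination);
    the second pill contributes only samples strictly after that instant, its
    overlap being discarded.  A gap of more than 24 h between the segments is
    reported with a warning but still stitched.
    """
    if len(pill2) == 0:
        return pill1.replace()
    if len(pill1) == 0:
        return pill2.replace()
    if pill1.subject_id != pill2.subject_id:
        raise ValidationError("pill segments belong to different subjects")
    if pill1.unit != pill2.unit:
        raise ValidationError("pill segments carry different units")
    if pill1.timestamps[0] == pill2.timestamps[0]:
        raise ValidationError("pill segments start at the identical instant")
    if pill1.timestamps[0] > pill2.timestamps[0]:
        raise ValidationError("pill1 must start no later than pill2")
    cut = pill1.timestamps[-1]
    keep = pill2.timestamps > cut
    gap_h = (pill2.timestamps[keep][0] - cut) / pd.Timedelta(hours=1) if keep.any() else 0.0
    if gap_h > 24.0:
        warnings.warn(f"gap of {gap_h:.1f} h between pill segments for "
                      f"{pill1.subject_id}; stitching anyway", stacklevel=2)
    ts = pill1.timestamps.append(pill2.timestamps[keep])
    vals = np.concatenate([pill1.values, pill2.values[keep]])
    return TimeSeries(ts, vals, pill1.unit, pill1.subject_id, "core_temp")


def remove_ingestion_artifacts(series: TimeSeries, window_h: float = 3.0,
                               plausible_range: tuple[float, float] = (35.0, 40.0)
                               ) -> TimeSeries:
    """Delete implausible temperatures from the start of a pill segment.

    Within the first ``window_h`` hours of the segment, samples outside
    ``plausible_range`` (food/drink ingestion transients) are removed; later
    samples are always retained.  Removing more than half of the windowed
    samples triggers a warning.
    """
    if len(series) == 0:
        return series.replace()
    lo, hi = plausible_range
    in_window = series.hours_since(series.timestamps[0]) < window_h
    bad = in_window & ((series.values < lo) | (series.values > hi))
    n_bad = int(bad.sum())
    if n_bad:
        log.info("removed %d ingestion artifact(s) from %s/%s", n_bad,
                 series.subject_id, series.channel)
    n_win = int(in_window.sum())
    if n_win and n_bad > 0.5 * n_win:
        warnings.warn(f"{n_bad}/{n_win} samples removed in the artifact window of "
                      f"{series.subject_id}/{series.channel}", stacklevel=2)
    return series.replace(timestamps=series.timestamps[~bad], values=series.values[~bad])


def aggregate_5min(series: TimeSeries, bin_minutes: int = 5) -> TimeSeries:
    """Aggregate a minute-level series to clock-aligned left-closed bin means.

    Bins start at 00:00, 00:05, ...; the bin value is the mean of the samples
    present in [edge, edge + bin); empty bins are absent from the output.
    Output timestamps are the bin left edges.
    """
    if len(series) == 0:
        return series.replace()
    frame = pd.Series(series.values,
                      index=series.timestamps.floor(f"{bin_minutes}min"))
    agg = frame.groupby(level=0).mean()
    return series.replace(timestamps=pd.DatetimeIndex(agg.index),
                          values=agg.to_numpy())


def moving_average(series: TimeSeries, window_min: float = 60.0) -> TimeSeries:
    """Centred moving mean over samples within [t - w/2, t + w/2).

    Edges average over whatever samples are available.  For 5-minute data and
    the default 1-hour window this is a 12-bin mean.
    """
    if len(series) == 0:
        return series.replace()
    t = series.timestamps.asi8 / 6e10  # minutes
    half = window_min / 2.0
    left = np.searchsorted(t, t - half, side="left")
    right = np.searchsorted(t, t + half, side="left")
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    means = (csum[right] - csum[left]) / np.maximum(1, right - left)
    return series.replace(values=means)


def average_24h_profile(series: TimeSeries, bin_minutes: int = 5) -> DailyProfile:
    """Collapse a multi-day series into one averaged 24-hour profile.

    Each clock bin is the mean across days of the available values; bins
    with no data stay NaN.  Requires at least 24 h of span.
    """
    if series.span_hours < 24.0 - 1e-9:
        raise ValidationError(
            f"need >= 24 h of data for a daily profile, got {series.span_hours:.1f} h")
    minute_of_day = (series.timestamps.hour * 60 + series.timestamps.minute
                     + series.timestamps.second / 60.0)
    bin_idx = (np.asarray(minute_of_day) // bin_minutes).astype(int)
    n_bins = 1440 // bin_minutes
    sums = np.bincount(bin_idx, weights=series.values, minlength=n_bins)
    counts = np.bincount(bin_idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DailyProfile(np.arange(0, 1440, bin_minutes), means, counts,
                        channel=series.channel, subject_id=series.subject_id,
                        bin_width_min=bin_minutes)


def lag_correlation(a: TimeSeries, b: TimeSeries, max_lag_min: int = 30
                    ) -> tuple[int, pd.Series]:
    """Pearson correlation between two series at integer-minute lags.

    The correlation at lag L pairs ``a(t)`` with ``b(t - L)``: a *negative*
    best lag means b is a delayed copy of a.  Requires at least 24 h of
    overlap; ties in the maximum are broken toward lag 0.
    Returns ``(best_lag, r_by_lag)``.
    """
    sa = pd.Series(a.values, index=a.timestamps)
    sb = pd.Series(b.values, index=b.timestamps)
    overlap = (max(a.timestamps[0], b.timestamps[0]),
               min(a.timestamps[-1], b.timestamps[-1]))
    if (overlap[1] - overlap[0]) < pd.Timedelta(hours=24):
        raise ValidationError("series overlap shorter than 24 h")
    lags = np.arange(-max_lag_min, max_lag_min + 1)
    rs = {}
    for L in lags:
        shifted = sb.copy()
        shifted.index = shifted.index + pd.Timedelta(minutes=int(L))
        joined = pd.concat([sa, shifted], axis=1, join="inner").dropna()
        if len(joined) < 3:
            rs[int(L)] = np.nan
            continue
        rs[int(L)] = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
    r_by_lag = pd.Series(rs).sort_index()
    finite = r_by_lag.dropna()
    if finite.empty:
        raise ValidationError("no overlapping samples at any lag")
    best_r = finite.max()
    best_candidates = finite.index[np.isclose(finite.to_numpy(), best_r)]
    best = int(min(best_candidates, key=lambda L: (abs(L), L)))
    return best, r_by_lag
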