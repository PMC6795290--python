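"""Dim light melatonin onset (DLMO) from evening salivary profiles.

DLMO is the evening clock time at which salivary melatonin concentration
first exceeds a baseline-derived threshold.  The threshold is either
*individual* — mean of 3 consecutive pre-rise values plus twice their
sample standard deviation — or, when a subject lacks an adequate baseline,
*pooled* — mean plus twice the SD of baseline values pooled across the
subjects that do have one.  A sample is invalid when the wrist light
record shows more than 50 lux within the 30 minutes preceding collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClockPhase, TimeSeries, ValidationError

__all__ = [
    "MelatoninProfile",
    "InsufficientBaselineError",
    "LUX_LIMIT",
    "validate_samples",
    "select_baseline",
    "individual_threshold",
    "pooled_threshold",
    "compute_dlmo",
    "estimate_dlmo",
]

LUX_LIMIT = 50.0
_LUX_WINDOW_MIN = 30.0

VALID, INVALID, INDETERMINATE = "valid", "invalid", "indeterminate"


class InsufficientBaselineError(ValidationError):
    """Fewer than 3 usable consecutive pre-rise baseline samples."""


@dataclass
class MelatoninProfile:
    """An evening salivary profile with validity flags and the DLMO estimate."""

    times: np.ndarray                 # evening clock hours
    concentrations: np.ndarray        # pg/mL
    validity: list[str]
    threshold: float | None = None
    threshold_kind: str | None = None     # "individual" | "pooled"
    dlmo: ClockPhase | None = None
    baseline_values: np.ndarray | None = None
    reason: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.dlmo is not None:
            lo, hi = self.times.min(), self.times.max()
            if not (lo - 1e-9 <= self.dlmo.clock_hours <= hi + 1e-9):
                raise ValidationError("DLMO outside the sampled span")
        if self.threshold is not None and self.threshold <= 0:
            raise ValidationError("melatonin threshold must be positive")


def validate_samples(sample_times_h, lux: TimeSeries) -> list[str]:
    """Flag each sample valid / invalid / indeterminate from the lux record.

    A sample collected at clock hour t is invalid iff any lux reading
    exceeds 50 in the half-open window (t-30 min, t].  If the lux record
    leaves more than 5 consecutive minutes of that window uncovered, the
    sample is flagged indeterminate instead.
    """
    if lux.unit != "lux":
        raise ValidationError(f"expected a lux series, got unit {lux.unit!r}")
    lux_h = lux.hours_since(lux.timestamps[0].normalize())
    flags = []
    for t in np.asarray(sample_times_h, dtype=float):
        in_win = (lux_h > t - _LUX_WINDOW_MIN / 60.0 + 1e-12) & (lux_h <= t + 1e-12)
        pts = np.sort(lux_h[in_win])
        if pts.size == 0:
            flags.append(INDETERMINATE)
            continue
        edges = np.concatenate([[t - _LUX_WINDOW_MIN / 60.0], pts, [t]])
        if np.max(np.diff(edges)) > 5.0 / 60.0 + 1e-9:
            flags.append(INDETERMINATE)
            continue
        flags.append(INVALID if np.any(lux.values[in_win] > LUX_LIMIT) else VALID)
    return flags


def select_baseline(times, concentrations, validity,
                    rise_factor: float = 1.5) -> np.ndarray:
    """Pick 3 consecutive valid pre-rise samples for the individual threshold.

    Only the *earliest* triple of consecutive all-valid samples is a
    candidate (scanning later would pick up flat stretches of the post-rise
    plateau).  The triple qualifies when it is flat: each value at most
    ``rise_factor`` times the running mean of its predecessors within the
    triple.  Anything else — an invalid sample breaking the earliest triple
    with no later one, or a rise already under way — raises
    :class:`InsufficientBaselineError` and the caller falls back to the
    pooled threshold.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    for i in range(len(t) - 2):
        if any(v != VALID for v in validity[i:i + 3]):
            continue
        window = c[i:i + 3]
        if window[1] <= rise_factor * window[0] and \
           window[2] <= rise_factor * np.mean(window[:2]):
            return window.copy()
        raise InsufficientBaselineError(
            "earliest 3 consecutive valid samples are not pre-rise (already rising)")
    raise InsufficientBaselineError("no 3 consecutive valid samples")


def individual_threshold(baseline_values) -> float:
    """Mean of 3 consecutive pre-rise values plus twice their sample SD."""
    b = np.asarray(baseline_values, dtype=float)
    if b.size != 3 or not np.all(np.isfinite(b)):
        raise InsufficientBaselineError(
            f"individual threshold needs exactly 3 baseline values, got {b.size}")
    return float(b.mean() + 2.0 * b.std(ddof=1))


def pooled_threshold(pooled_values) -> float:
    """Mean plus twice the sample SD of baselines pooled across subjects."""
    p = np.asarray(pooled_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 2:
        raise ValidationError("pooled threshold needs at least 2 baseline values")
    return float(p.mean() + 2.0 * p.std(ddof=1))


def compute_dlmo(times, concentrations, threshold: float,
                 validity=None) -> tuple[ClockPhase | None, str]:
    """First upward threshold crossing, linearly interpolated.

    Only valid samples contribute.  The crossing is strict (a sample exactly
    at the threshold has not yet exceeded it) and interpolated between the
    last valid sample at or below the threshold and the first valid sample
    above it.  Returns ``(phase, reason)``; the phase is None when the
    threshold is never exceeded or the first valid sample is already above.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if validity is None:
        validity = [VALID] * len(t)
    keep = np.array([v == VALID for v in validity])
    t, c = t[keep], c[keep]
    if t.size == 0:
        return None, "all samples invalid"
    if t.size < 2:
        return None, "fewer than 2 valid samples"
    above = c > threshold
    if above[0]:
        return None, "first valid sample already above threshold"
    if not above.any():
        return None, "threshold never exceeded"
    k = int(np.argmax(above))
    frac = (threshold - c[k - 1]) / (c[k] - c[k - 1])
    return ClockPhase(t[k - 1] + frac * (t[k] - t[k - 1])), ""


def estimate_dlmo(times, concentrations, lux: TimeSeries | None = None,
                  pooled_baseline=None, subject_id: str = "") -> MelatoninProfile:
    """Full per-subject DLMO estimate with threshold fallback.

    Uses the individual baseline threshold when 3 consecutive valid pre-rise
    samples exist, otherwise the pooled threshold (if a pool is supplied).
    """
    validity = (validate_samples(times, lux) if lux is not None
                else [VALID] * len(np.asarray(times)))
    baseline = None
    try:
        baseline = select_baseline(times, concentrations, validity)
        threshold = individual_threshold(baseline)
        kind = "individual"
    except InsufficientBaselineError:
        if pooled_baseline is None:
            return MelatoninProfile(times, concentrations, validity,
                                    reason="insufficient baseline and no pool",
                                    subject_id=subject_id)
        threshold = pooled_threshold(pooled_baseline)
        kind = "pooled"
    phase, reason = compute_dlmo(times, concentrations, threshold, validity)
    return MelatoninProfile(times, concentrations, validity,
                            threshold=threshold, threshold_kind=kind,
                            dlmo=phase, baseline_values=baseline,
                            reason=reason, subject_id=subject_id)
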