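"""Synthetic cohort generator with known ground-truth circadian parameters.

Emulates the statistical structure of a field study in which each subject
contributes (a) two ingestible-pill core body temperature segments started
24 h apart, (b) a ~7-day chest recording of surface temperature and activity
counts with device-removal gaps, and (c) an evening salivary melatonin
profile with a wrist lux record.  Ground truth (phases, harmonic
coefficients, rest span) is always emitted alongside the raw series so every
downstream stage can be tested by parameter recovery.

Defaults encode the cohort conditions the pipeline is designed for:
core bathyphase near 03:30 spread over ~7 h, center of rest near 03:05
spread over ~5 h, chest acrophase near 03:00 spread over ~9 h, evening
melatonin onset near 20:50, chronotype score anticorrelated with the
rest phases (Spearman r ≈ -0.7), and a core bathyphase that follows the
published four-covariate linear equation up to residual noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (ClockPhase, SubjectRecord, TimeSeries, ValidationError,
                   canonical_hours, categorize_chronotype)
from .intime import PUBLISHED_COEFFS

__all__ = [
    "GeneratorConfig",
    "SubjectTruth",
    "generate_cohort",
    "generate_core_temperature",
    "generate_chest_data",
    "generate_melatonin_profile",
    "truths_to_frame",
    "subject_record",
    "write_cohort",
]

_EPOCH = pd.Timestamp("2024-01-01 00:00:00")  # arbitrary fixed study start


@dataclass
class GeneratorConfig:
    """Generation parameters; defaults are the study conditions being emulated.

    Phases are decimal hours on the unwrapped [12, 36) axis (daytime values
    keep their clock value, nocturnal values are clock + 24).
    """

    # --- core body temperature rhythm (degC) ---
    core_mesor: float = 37.0
    core_amp24_mean: float = 0.35
    core_amp24_sd: float = 0.07
    core_amp12_mean: float = 0.12
    core_amp12_sd: float = 0.04
    core_noise_sd: float = 0.15
    # --- pill segments ---
    pill_duration_median_days: float = 1.6
    pill_duration_log_sd: float = 0.58
    pill_duration_range_days: tuple[float, float] = (0.2, 13.4)
    ingestion_artifact_window_h: float = 2.0
    ingestion_artifact_rate: float = 0.08     # per minute within the window
    plausible_range: tuple[float, float] = (35.0, 40.0)
    # --- chest surface temperature ---
    chest_mesor_mean: float = 34.5
    chest_mesor_sd: float = 0.9
    chest_amp24_by_class: dict = field(default_factory=lambda: {
        "24h": 0.8, "12h": 0.3, "none": 0.01})
    chest_amp12_by_class: dict = field(default_factory=lambda: {
        "24h": 0.4, "12h": 0.8, "none": 0.01})
    chest_noise_sd: float = 0.25
    dominant_class_probs: dict = field(default_factory=lambda: {
        "24h": 0.636, "12h": 0.273, "none": 0.091})
    # --- activity (counts/min) ---
    activity_state_means: tuple[float, float, float] = (2.0, 35.0, 180.0)
    activity_dispersion: float = 3.0          # negative-binomial shape
    activity_scale_log_sd: float = 0.5        # subject-level multiplier
    activity_persistence: float = 0.90
    rest_floor: float = 0.03                  # rest prob outside the span
    rest_edge_width_h: float = 1.0
    gap_fraction: float = 0.02                # device-removal missingness
    # --- phase structure across the cohort ---
    chronotype_mean: float = 57.0
    chronotype_sd: float = 10.0
    center_of_rest_mean: float = 27.083       # 03:05
    center_of_rest_sd: float = 1.3
    score_rest_correlation: float = -0.70
    chest_acro_mean: float = 27.0             # 03:00
    chest_acro_sd: float = 2.2
    rest_chest_correlation: float = 0.67
    dlmo_mean: float = 20.833                 # 20:50
    dlmo_sd: float = 1.1
    rest_dlmo_correlation: float = 0.40
    rest_duration_mean_h: float = 8.5
    rest_duration_sd_h: float = 0.75
    # --- published-equation structure of the core bathyphase ---
    intime_intercept: float = 18.95
    core_phase_noise_sd: float = 0.9          # residual SD around the equation
    # --- melatonin profile ---
    melatonin_baseline_range: tuple[float, float] = (1.0, 4.0)
    melatonin_amplitude_range: tuple[float, float] = (8.0, 25.0)
    melatonin_rise_scale_h: float = 0.5
    melatonin_noise_frac: float = 0.12
    lux_contamination_fraction: float = 0.04
    melatonin_missing_frac: float = 0.18
    # --- subject demographics ---
    age_range: tuple[float, float] = (21.0, 78.0)
    bmi_mean: float = 24.5
    bmi_sd: float = 3.5

    def validate(self) -> "GeneratorConfig":
        fracs = {
            "gap_fraction": self.gap_fraction,
            "lux_contamination_fraction": self.lux_contamination_fraction,
            "melatonin_missing_frac": self.melatonin_missing_frac,
            "ingestion_artifact_rate": self.ingestion_artifact_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("core_noise_sd", "chest_noise_sd", "core_phase_noise_sd",
                     "center_of_rest_sd", "chest_acro_sd", "dlmo_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if abs(sum(self.dominant_class_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("dominant_class_probs must sum to 1")
        lo, hi = self.pill_duration_range_days
        if not 0 < lo < hi:
            raise ValidationError("invalid pill_duration_range_days")
        return self


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject (bit-reproducible from seed+index)."""

    subject_id: str
    index: int
    sex: int
    age: float
    bmi: float
    chronotype_score: int
    chronotype_category: str
    # phases, unwrapped decimal hours on [12, 36)
    true_core_bathyphase: float
    true_core_acrophase: float
    true_chest_acrophase: float
    true_chest_bathyphase: float
    true_center_of_rest: float
    true_dlmo: float
    # harmonic truth (a1/b1 at 12 h, a2/b2 at 24 h)
    core_mesor: float
    core_a1: float
    core_b1: float
    core_a2: float
    core_b2: float
    chest_mesor: float
    chest_a1: float
    chest_b1: float
    chest_a2: float
    chest_b2: float
    dominant_class: str
    # noise / nuisance parameters
    core_noise_sd: float
    chest_noise_sd: float
    activity_scale: float
    rest_onset: float          # clock hours of rest-span start
    rest_duration: float       # hours
    melatonin_baseline: float
    melatonin_amplitude: float
    melatonin_available: bool


# ---------------------------------------------------------------------------
# Harmonic helpers
# ---------------------------------------------------------------------------

def harmonic_curve(t_hours: np.ndarray, mesor: float, a1: float, b1: float,
                   a2: float, b2: float) -> np.ndarray:
    """Two-harmonic cosinor curve: 12-h (a1, b1) and 24-h (a2, b2) components."""
    t = np.asarray(t_hours, dtype=float)
    w1, w2 = 2 * np.pi / 12.0, 2 * np.pi / 24.0
    return (mesor + a1 * np.cos(w1 * t) + b1 * np.sin(w1 * t)
            + a2 * np.cos(w2 * t) + b2 * np.sin(w2 * t))


def _amp_phase_to_ab(amplitude: float, peak_hours: float, period: float) -> tuple[float, float]:
    """Coefficients (a, b) of A*cos(2*pi*(t - peak)/T) on the cos/sin basis."""
    w = 2 * np.pi / period
    return amplitude * np.cos(w * peak_hours), amplitude * np.sin(w * peak_hours)


def _grid_extrema(mesor, a1, b1, a2, b2) -> tuple[float, float]:
    """(acrophase, bathyphase) of the noiseless curve on a 1-min grid,
    ties broken toward the earliest clock time."""
    t = np.arange(1440) / 60.0
    y = harmonic_curve(t, mesor, a1, b1, a2, b2)
    return float(t[int(np.argmax(y))]), float(t[int(np.argmin(y))])


# ---------------------------------------------------------------------------
# Cohort truth
# ---------------------------------------------------------------------------

def generate_cohort(n: int, seed: int, config: GeneratorConfig | None = None
                    ) -> list[SubjectTruth]:
    """Draw ``n`` subjects with correlated ground-truth circadian parameters.

    Sexes alternate (balanced within 1).  Chronotype score drives the rest
    phases negatively; the true core bathyphase is the published linear
    equation evaluated at (sex, score, center of rest, chest bathyphase)
    plus an intercept and Gaussian residual noise.  Fully deterministic
    given (seed, subject index).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    cfg = (config or GeneratorConfig()).validate()
    truths = []
    for i in range(n):
        rng = np.random.default_rng([int(seed) % (2**31), 1000 + i])
        sex = 1 if i % 2 == 0 else 0
        age = float(rng.uniform(*cfg.age_range))
        bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 16.5, 40.0))
        score = int(np.clip(round(rng.normal(cfg.chronotype_mean, cfg.chronotype_sd)), 16, 86))
        z = (score - cfg.chronotype_mean) / cfg.chronotype_sd

        r = cfg.score_rest_correlation
        cor = (cfg.center_of_rest_mean + r * cfg.center_of_rest_sd * z
               + np.sqrt(max(0.0, 1 - r**2)) * cfg.center_of_rest_sd * rng.standard_normal())
        z_cor = (cor - cfg.center_of_rest_mean) / cfg.center_of_rest_sd

        rc = cfg.rest_chest_correlation
        chest_acro = (cfg.chest_acro_mean + rc * cfg.chest_acro_sd * z_cor
                      + np.sqrt(max(0.0, 1 - rc**2)) * cfg.chest_acro_sd * rng.standard_normal())
        chest_acro = canonical_hours(chest_acro)

        rd = cfg.rest_dlmo_correlation
        dlmo = (cfg.dlmo_mean + rd * cfg.dlmo_sd * z_cor
                + np.sqrt(max(0.0, 1 - rd**2)) * cfg.dlmo_sd * rng.standard_normal())
        dlmo = float(np.clip(dlmo, 18.6, 22.8))  # keep onset inside the sampling evening

        dom_items = sorted(cfg.dominant_class_probs.items())
        dom = rng.choice([k for k, _ in dom_items], p=[v for _, v in dom_items])

        # chest curve: 24-h peak at the (nightly) acrophase, 12-h peak jittered
        chest_mesor = float(rng.normal(cfg.chest_mesor_mean, cfg.chest_mesor_sd))
        ca24 = max(0.01, rng.normal(cfg.chest_amp24_by_class[dom], 0.1 * cfg.chest_amp24_by_class[dom]))
        ca12 = max(0.01, rng.normal(cfg.chest_amp12_by_class[dom], 0.1 * cfg.chest_amp12_by_class[dom]))
        # positive 12-h phase offset so the global minimum follows the
        # nightly acrophase (daytime bathyphase), and no exact degeneracy
        delta12 = float(rng.uniform(0.1, 0.6))
        ch_a2, ch_b2 = _amp_phase_to_ab(ca24, chest_acro % 24.0, 24.0)
        ch_a1, ch_b1 = _amp_phase_to_ab(ca12, (chest_acro + delta12) % 12.0, 12.0)
        chest_acro_true, chest_bathy_true = _grid_extrema(chest_mesor, ch_a1, ch_b1, ch_a2, ch_b2)
        chest_acro_true = canonical_hours(chest_acro_true)
        # chest bathyphase is daytime (~11:00): coded on the clock axis [0, 24)
        chest_bathy_true = chest_bathy_true % 24.0

        # core bathyphase follows the published equation + residual noise
        eq = PUBLISHED_COEFFS
        core_bathy = (cfg.intime_intercept
                      + eq["sex"] * sex
                      + eq["chronotype_score"] * score
                      + eq["center_of_rest"] * cor
                      + eq["chest_bathyphase"] * chest_bathy_true
                      + rng.normal(0.0, cfg.core_phase_noise_sd))
        core_bathy = canonical_hours(core_bathy)

        amp24 = max(0.15, rng.normal(cfg.core_amp24_mean, cfg.core_amp24_sd))
        amp12 = max(0.0, rng.normal(cfg.core_amp12_mean, cfg.core_amp12_sd))
        # both harmonics reach their minimum at the bathyphase, so the truth
        # bathyphase of the summed curve is exact
        b = core_bathy % 24.0
        co_a2, co_b2 = _amp_phase_to_ab(amp24, (b - 12.0) % 24.0, 24.0)
        co_a1, co_b1 = _amp_phase_to_ab(amp12, (b - 6.0) % 12.0, 12.0)
        core_acro_true, core_bathy_true = _grid_extrema(cfg.core_mesor, co_a1, co_b1, co_a2, co_b2)

        dur = float(np.clip(rng.normal(cfg.rest_duration_mean_h, cfg.rest_duration_sd_h), 6.0, 11.0))
        onset = (cor - dur / 2.0) % 24.0

        truths.append(SubjectTruth(
            subject_id=f"S{i + 1:03d}", index=i, sex=sex, age=age, bmi=bmi,
            chronotype_score=score, chronotype_category=categorize_chronotype(score),
            true_core_bathyphase=canonical_hours(core_bathy_true),
            true_core_acrophase=canonical_hours(core_acro_true),
            true_chest_acrophase=chest_acro_true,
            true_chest_bathyphase=chest_bathy_true,   # clock axis, see above
            true_center_of_rest=canonical_hours(cor),
            true_dlmo=canonical_hours(dlmo),
            core_mesor=cfg.core_mesor, core_a1=co_a1, core_b1=co_b1,
            core_a2=co_a2, core_b2=co_b2,
            chest_mesor=chest_mesor, chest_a1=ch_a1, chest_b1=ch_b1,
            chest_a2=ch_a2, chest_b2=ch_b2,
            dominant_class=str(dom),
            core_noise_sd=cfg.core_noise_sd, chest_noise_sd=cfg.chest_noise_sd,
            activity_scale=float(np.exp(rng.normal(0.0, cfg.activity_scale_log_sd))),
            rest_onset=onset, rest_duration=dur,
            melatonin_baseline=float(rng.uniform(*cfg.melatonin_baseline_range)),
            melatonin_amplitude=float(rng.uniform(*cfg.melatonin_amplitude_range)),
            melatonin_available=bool(rng.random() >= cfg.melatonin_missing_frac),
        ))
    return truths


def truths_to_frame(truths: Sequence[SubjectTruth]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truths])


def subject_record(truth: SubjectTruth) -> SubjectRecord:
    return SubjectRecord(subject_id=truth.subject_id, sex=truth.sex,
                         age=truth.age, bmi=truth.bmi,
                         chronotype_score=truth.chronotype_score)


# ---------------------------------------------------------------------------
# Raw series
# ---------------------------------------------------------------------------

def _minute_index(start: pd.Timestamp, n_minutes: int) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_minutes, freq="min")


def generate_core_temperature(truth: SubjectTruth, days: float = 14.0,
                              seed: int = 0, config: GeneratorConfig | None = None
                              ) -> tuple[TimeSeries, TimeSeries]:
    """Two pill segments of minute-level core temperature, ingested 24 h apart.

    Per-segment durations are log-normal (median ~1.6 days) clipped to
    [0.2, 13.4] days and to the requested horizon, so the segments may or
    may not overlap.  The first ``ingestion_artifact_window_h`` hours of each
    segment are contaminated with spikes outside the plausible [35, 40] degC
    band, mimicking food and drink ingestion.
    """
    if days < 2:
        raise ValidationError("core recording horizon must be >= 2 days")
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng([int(seed) % (2**31), 2000 + truth.index])
    out = []
    for p in range(2):
        start = _EPOCH + pd.Timedelta(hours=8.0 + 24.0 * p)
        dur_days = float(np.exp(rng.normal(np.log(cfg.pill_duration_median_days),
                                           cfg.pill_duration_log_sd)))
        dur_days = float(np.clip(dur_days, *cfg.pill_duration_range_days))
        dur_days = min(dur_days, days - p)  # clip to the requested horizon
        n = max(2, int(round(dur_days * 1440)))
        idx = _minute_index(start, n)
        t = (idx.asi8 - _EPOCH.value) / 3.6e12  # hours since study midnight
        y = harmonic_curve(t, truth.core_mesor, truth.core_a1, truth.core_b1,
                           truth.core_a2, truth.core_b2)
        y = y + rng.normal(0.0, truth.core_noise_sd, size=n)
        # ingestion artifacts in the first window
        win = int(cfg.ingestion_artifact_window_h * 60)
        hit = rng.random(min(win, n)) < cfg.ingestion_artifact_rate
        kind_low = rng.random(hit.size) < 0.7
        art = np.where(kind_low, rng.uniform(20.0, 34.0, hit.size),
                       rng.uniform(40.3, 41.5, hit.size))
        y[:hit.size][hit] = art[hit]
        out.append(TimeSeries(idx, y, "degC", truth.subject_id, f"core_temp_pill{p + 1}"))
    return out[0], out[1]


def _rest_bump(clock_h: np.ndarray, onset: float, duration: float,
               edge_width: float) -> np.ndarray:
    """Smooth 0..1 indicator of the rest span with raised-cosine edges."""
    # signed hours since rest onset, wrapped to [0, 24)
    rel = np.mod(clock_h - onset, 24.0)
    w = max(edge_width, 1e-6)
    up = np.clip(rel / w, 0.0, 1.0)
    down = np.clip((duration - rel) / w, 0.0, 1.0)
    bump = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))
    bump[rel >= duration] = 0.0
    return bump


def _gap_mask(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean keep-mask with ~``fraction`` of minutes removed in contiguous
    device-removal episodes (5–90 min, log-normal around ~25 min)."""
    keep = np.ones(n, dtype=bool)
    target = int(round(fraction * n))
    if target <= 0:
        return keep
    removed = 0
    for _ in range(10 * max(1, target // 5)):
        if removed >= target:
            break
        dur = int(np.clip(round(np.exp(rng.normal(np.log(25.0), 0.5))), 5, 90))
        dur = min(dur, target - removed)
        start = int(rng.integers(0, max(1, n - dur)))
        seg = slice(start, start + dur)
        newly = int(np.count_nonzero(keep[seg]))
        keep[seg] = False
        removed += newly
    return keep


def generate_chest_data(truth: SubjectTruth, days: float = 7.0, seed: int = 0,
                        config: GeneratorConfig | None = None,
                        deterministic_states: bool = False,
                        return_states: bool = False):
    """Minute-level chest surface temperature and activity counts.

    Activity follows a sticky 3-regime (rest / moderate / high) Markov chain
    whose rest probability peaks inside the truth rest span; counts are
    negative-binomial per state.  With ``deterministic_states=True`` the
    state is rest exactly inside the span (no stochastic regime switching).
    Short device-removal gaps are cut from both channels together.
    """
    if days < 1:
        raise ValidationError("chest recording must span at least 1 day")
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng([int(seed) % (2**31), 3000 + truth.index])
    n = int(round(days * 1440))
    idx = _minute_index(_EPOCH, n)
    t = (idx.asi8 - _EPOCH.value) / 3.6e12
    clock = np.mod(t, 24.0)

    temp = harmonic_curve(t, truth.chest_mesor, truth.chest_a1, truth.chest_b1,
                          truth.chest_a2, truth.chest_b2)
    temp = temp + rng.normal(0.0, truth.chest_noise_sd, size=n)

    bump = _rest_bump(clock, truth.rest_onset, truth.rest_duration, cfg.rest_edge_width_h)
    p_rest = cfg.rest_floor + (1.0 - 2.0 * cfg.rest_floor) * bump
    if deterministic_states:
        states = np.where(bump >= 0.5, 0, 1).astype(np.int64)
        # occasional high-activity bouts outside rest, deterministic pattern
        states[(bump < 0.5) & (np.arange(n) % 7 == 0)] = 2
    else:
        pi = np.empty((n, 3))
        pi[:, 0] = p_rest
        pi[:, 1] = (1.0 - p_rest) * 0.75
        pi[:, 2] = (1.0 - p_rest) * 0.25
        stay = cfg.activity_persistence
        states = np.empty(n, dtype=np.int64)
        u_stay = rng.random(n)
        states[0] = rng.choice(3, p=pi[0] / pi[0].sum())
        for k in range(1, n):
            if u_stay[k] < stay:
                states[k] = states[k - 1]
            else:
                pk = pi[k] / pi[k].sum()
                states[k] = rng.choice(3, p=pk)
    mu = np.asarray(cfg.activity_state_means) * truth.activity_scale
    r = cfg.activity_dispersion
    p_nb = r / (r + mu[states])
    counts = rng.negative_binomial(r, p_nb).astype(float)

    keep = _gap_mask(n, cfg.gap_fraction, rng)
    temp_series = TimeSeries(idx[keep], temp[keep], "degC",
                             truth.subject_id, "chest_temp")
    act_series = TimeSeries(idx[keep], counts[keep], "counts_per_min",
                            truth.subject_id, "activity")
    if return_states:
        return temp_series, act_series, states[keep]
    return temp_series, act_series


def generate_melatonin_profile(truth: SubjectTruth,
                               sample_times: Sequence[float] = (18, 19, 20, 21, 22, 23),
                               seed: int = 0,
                               config: GeneratorConfig | None = None,
                               force_contaminated: Sequence[int] = (),
                               ) -> tuple[np.ndarray, np.ndarray, TimeSeries]:
    """Evening salivary melatonin samples plus the wrist lux record.

    Concentration is a flat baseline before the true onset and a logistic
    rise after it, so with zero noise the individual threshold (baseline
    mean + 2 SD) is crossed at the true onset exactly.  A configurable
    fraction of samples receives a >50 lux burst within the preceding
    30 minutes; ``force_contaminated`` marks specific sample indices.
    """
    cfg = (config or GeneratorConfig()).validate()
    times = np.asarray(sorted(float(x) for x in sample_times))
    if times.min() < 17.0 or times.max() > 24.0:
        raise ValidationError("melatonin sample times must lie in the 17:00-24:00 evening")
    rng = np.random.default_rng([int(seed) % (2**31), 4000 + truth.index])

    t_on = truth.true_dlmo % 24.0
    s = cfg.melatonin_rise_scale_h
    t50 = t_on + 2.4 * s
    q = 1.0 / (1.0 + np.exp((t50 - t_on) / s))
    rise = 1.0 / (1.0 + np.exp((t50 - times) / s))
    conc = truth.melatonin_baseline + truth.melatonin_amplitude * np.maximum(
        0.0, rise - q) / (1.0 - q)
    conc = conc * np.exp(rng.normal(0.0, cfg.melatonin_noise_frac, size=times.size))

    # minute-level lux from 17:00 to 24:00, dim throughout the evening
    start = _EPOCH + pd.Timedelta(hours=17)
    n_lux = 7 * 60
    lux_idx = _minute_index(start, n_lux)
    lux = np.exp(rng.normal(np.log(4.0), 0.6, size=n_lux))
    lux = np.clip(lux, 0.0, 45.0)
    contaminated = set(int(i) for i in force_contaminated)
    for i in range(times.size):
        if i not in contaminated and rng.random() < cfg.lux_contamination_fraction:
            contaminated.add(i)
    lux_hours = 17.0 + np.arange(n_lux) / 60.0
    for i in sorted(contaminated):
        burst_t = times[i] - rng.uniform(2.0, 28.0) / 60.0
        j = int(np.clip(round((burst_t - 17.0) * 60), 0, n_lux - 5))
        lux[j:j + 4] = rng.uniform(60.0, 300.0, size=min(4, n_lux - j))
    lux_series = TimeSeries(lux_idx, lux, "lux", truth.subject_id, "lux")
    return times, conc, lux_series


# ---------------------------------------------------------------------------
# Cohort dataset on disk
# ---------------------------------------------------------------------------

def write_cohort(truths: Sequence[SubjectTruth], outdir, seed: int,
                 config: GeneratorConfig | None = None,
                 chest_days: float = 7.0, core_days: float = 14.0) -> None:
    """Write per-subject raw CSVs plus ``truth.csv`` and the config used."""
    import pathlib

    import yaml

    from .core import write_timeseries
    cfg = (config or GeneratorConfig()).validate()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tr in truths:
        p1, p2 = generate_core_temperature(tr, days=core_days, seed=seed, config=cfg)
        ct, ac = generate_chest_data(tr, days=chest_days, seed=seed, config=cfg)
        write_timeseries(p1, outdir / f"{tr.subject_id}_core_pill1.csv")
        write_timeseries(p2, outdir / f"{tr.subject_id}_core_pill2.csv")
        write_timeseries(ct, outdir / f"{tr.subject_id}_chest_temp.csv")
        write_timeseries(ac, outdir / f"{tr.subject_id}_activity.csv")
        if tr.melatonin_available:
            times, conc, lux = generate_melatonin_profile(tr, seed=seed, config=cfg)
            pd.DataFrame({"time_hours": times, "concentration": conc,
                          "subject_id": tr.subject_id}).to_csv(
                outdir / f"{tr.subject_id}_melatonin.csv", index=False)
            write_timeseries(lux, outdir / f"{tr.subject_id}_lux.csv")
    truths_to_frame(truths).to_csv(outdir / "truth.csv", index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["seed"] = int(seed)
    cfg_dict["n"] = len(truths)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
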