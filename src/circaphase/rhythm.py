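"""Two-harmonic cosinor fitting, phase extraction, bootstrap CIs, and
dominant-period classification.

The model is the classical multi-harmonic cosinor with fixed periods
T1 = 12 h and T2 = 24 h:

    y(t) = M + a1*cos(2*pi*t/T1) + b1*sin(2*pi*t/T1)
             + a2*cos(2*pi*t/T2) + b2*sin(2*pi*t/T2) + e(t)

estimated by ordinary least squares.  The acrophase is the clock time of
the maximum of the fitted curve on a 1-minute grid and the bathyphase the
time of its minimum; 90% circular confidence intervals come from a
residual-resampling bootstrap.  A periodogram-style test against a
day-shuffling permutation null classifies each subject's dominant
periodic component as 24 h, 12 h, or none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClockPhase, TimeSeries, ValidationError, circular_signed_diff
from .preprocess import DailyProfile

__all__ = [
    "CosinorFit",
    "PhaseCI",
    "PeriodClassification",
    "fit_cosinor",
    "extract_phases",
    "bootstrap_phase_ci",
    "classify_dominant_period",
    "design_matrix",
]

_PERIODS = (12.0, 24.0)
_GRID_MIN = 1440
_T_GRID = np.arange(_GRID_MIN) / 60.0


def design_matrix(t_hours: np.ndarray, periods=_PERIODS) -> np.ndarray:
    """OLS design {1, cos/sin at each period} evaluated at ``t_hours``."""
    t = np.asarray(t_hours, dtype=float)
    cols = [np.ones_like(t)]
    for T in periods:
        w = 2 * np.pi / T
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


@dataclass
class PhaseCI:
    """Circular confidence interval (lo, hi arc containing the estimate)."""

    lo: float
    hi: float
    level: float

    @property
    def width_h(self) -> float:
        return float((self.hi - self.lo) % 24.0)

    def contains(self, phase: "float | ClockPhase") -> bool:
        ph = float(phase)
        arc = (self.hi - self.lo) % 24.0
        pos = (ph - self.lo) % 24.0
        if pos > 24.0 - 1e-9:    # equality up to float wrap
            pos = 0.0
        return pos <= arc + 1e-12


@dataclass
class CosinorFit:
    """Fitted 2-harmonic cosinor: coefficients, phases, and residuals."""

    mesor: float
    a1: float                    # 12-h harmonic
    b1: float
    a2: float                    # 24-h harmonic
    b2: float
    t_hours: np.ndarray          # sample times used (hours; mod 24 = clock)
    y: np.ndarray
    residuals: np.ndarray
    fitted_grid: np.ndarray      # fitted curve on the 1-min clock grid
    acrophase: ClockPhase | None
    bathyphase: ClockPhase | None
    subject_id: str = ""
    channel: str = ""
    ci_acro: PhaseCI | None = None
    ci_bathy: PhaseCI | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.mesor, self.a1, self.b1, self.a2, self.b2])

    @property
    def peak_trough_range(self) -> float:
        return float(self.fitted_grid.max() - self.fitted_grid.min())

    @property
    def phases_defined(self) -> bool:
        return self.acrophase is not None

    def curve(self, t_hours: np.ndarray) -> np.ndarray:
        return design_matrix(t_hours) @ self.coefficients

    def as_dict(self) -> dict:
        d = {"mesor": self.mesor, "a1": self.a1, "b1": self.b1,
             "a2": self.a2, "b2": self.b2,
             "peak_trough_range": self.peak_trough_range,
             "acrophase": None if self.acrophase is None else self.acrophase.hours,
             "bathyphase": None if self.bathyphase is None else self.bathyphase.hours,
             "subject_id": self.subject_id, "channel": self.channel}
        for name, ci in (("acro", self.ci_acro), ("bathy", self.ci_bathy)):
            if ci is not None:
                d[f"ci_{name}_lo"] = ci.lo
                d[f"ci_{name}_hi"] = ci.hi
                d[f"ci_{name}_level"] = ci.level
        return d


def _grid_phases(curve: np.ndarray, amp_tol: float = 1e-10
                 ) -> tuple[ClockPhase | None, ClockPhase | None]:
    if curve.max() - curve.min() <= amp_tol:
        return None, None
    acro = ClockPhase(_T_GRID[int(np.argmax(curve))])
    bathy = ClockPhase(_T_GRID[int(np.argmin(curve))])
    return acro, bathy


def _extract_ty(data) -> tuple[np.ndarray, np.ndarray, str, str]:
    if isinstance(data, DailyProfile):
        mask = np.isfinite(data.values)
        return (data.bin_center_hours[mask], data.values[mask],
                data.subject_id, data.channel)
    if isinstance(data, TimeSeries):
        midnight = data.timestamps[0].normalize()
        return (data.hours_since(midnight), data.values,
                data.subject_id, data.channel)
    raise TypeError(f"expected DailyProfile or TimeSeries, got {type(data)!r}")


def fit_cosinor(data: "DailyProfile | TimeSeries",
                periods: tuple[float, float] = _PERIODS) -> CosinorFit:
    """Least-squares 2-harmonic cosinor fit of a daily profile or series.

    Requires at least 8 distinct time points spanning >= 12 h.  A constant
    input fits with zero amplitudes and undefined phases; a rank-deficient
    design (e.g. all samples at the same clock time) raises.
    """
    t, y, subject_id, channel = _extract_ty(data)
    finite = np.isfinite(y)
    t, y = t[finite], y[finite]
    distinct = np.unique(np.round(t * 60))
    if distinct.size < 8:
        raise ValidationError(f"need >= 8 distinct time points, got {distinct.size}")
    if (t.max() - t.min()) < 12.0:
        raise ValidationError("samples must span at least 12 h")
    X = design_matrix(t, periods)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValidationError("rank-deficient cosinor design "
                              "(samples do not resolve both harmonics)")
    fitted = X @ coef
    grid = design_matrix(_T_GRID, periods) @ coef
    acro, bathy = _grid_phases(grid)
    return CosinorFit(mesor=float(coef[0]), a1=float(coef[1]), b1=float(coef[2]),
                      a2=float(coef[3]), b2=float(coef[4]),
                      t_hours=t, y=y, residuals=y - fitted, fitted_grid=grid,
                      acrophase=acro, bathyphase=bathy,
                      subject_id=subject_id, channel=channel)


def extract_phases(fit: CosinorFit) -> tuple[ClockPhase, ClockPhase]:
    """Acrophase and bathyphase: argmax/argmin of the fitted curve on a
    1-minute grid over [0, 24), ties broken toward the earliest clock time."""
    if not fit.phases_defined:
        raise ValidationError("phases undefined: fitted curve has zero amplitude")
    return fit.acrophase, fit.bathyphase


def bootstrap_phase_ci(fit: CosinorFit, n_boot: int = 1000, level: float = 0.90,
                       seed: int = 0) -> tuple[PhaseCI, PhaseCI]:
    """Residual-resampling bootstrap CIs for both phases.

    Each replicate refits the cosinor on fitted values plus i.i.d. resampled
    residuals; the CI is the shortest-arc interval spanned by the central
    ``level`` mass of bootstrap phase deviations re-centred on the point
    estimate, which avoids wrap artifacts near midnight.  The fit's
    ``ci_acro``/``ci_bathy`` fields are filled and the pair returned.
    """
    if not fit.phases_defined:
        raise ValidationError("cannot bootstrap an undefined phase")
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} is small; CIs will be unstable", stacklevel=2)
    rng = np.random.default_rng(int(seed) % (2**31))
    X = design_matrix(fit.t_hours)
    pinv = np.linalg.pinv(X)
    yhat = X @ fit.coefficients
    n = yhat.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_y = yhat[None, :] + fit.residuals[idx]
    coefs = pinv @ boot_y.T                       # (5, n_boot)
    grid = design_matrix(_T_GRID) @ coefs         # (1440, n_boot)
    acro_b = _T_GRID[np.argmax(grid, axis=0)]
    bathy_b = _T_GRID[np.argmin(grid, axis=0)]

    out = []
    for point, boots in ((fit.acrophase, acro_b), (fit.bathyphase, bathy_b)):
        dev = np.array([circular_signed_diff(b, point) for b in boots])
        a = (1.0 - level) / 2.0
        lo_d, hi_d = np.quantile(dev, [a, 1.0 - a])
        out.append(PhaseCI(lo=(point.hours + lo_d) % 24.0,
                           hi=(point.hours + hi_d) % 24.0, level=level))
    fit.ci_acro, fit.ci_bathy = out[0], out[1]
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Dominant-period classification
# ---------------------------------------------------------------------------

@dataclass
class PeriodClassification:
    dominant: str                 # "24h", "12h", or "none"
    power_24: float
    power_12: float
    null_band: dict               # period -> permutation threshold
    n_days: int


def _harmonic_powers(minutes: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Squared amplitudes at 24 h and 12 h from a joint 2-harmonic OLS fit."""
    X = design_matrix(minutes / 60.0)
    coef, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < X.shape[1]:
        return np.nan, np.nan
    p12 = coef[1] ** 2 + coef[2] ** 2
    p24 = coef[3] ** 2 + coef[4] ** 2
    return float(p24), float(p12)


def classify_dominant_period(series: TimeSeries, seed: int = 0,
                             n_perm: int = 200,
                             band_quantile: float = 0.975) -> PeriodClassification:
    """Classify the dominant periodic component (24 h, 12 h, or none).

    Spectral power (squared harmonic amplitude) at 24 h and 12 h is compared
    against a null built by circularly shifting each recorded day by an
    independent random offset, which destroys day-to-day phase coherence
    while preserving within-day structure.  A period is significant when its
    observed power exceeds the ``band_quantile`` permutation quantile (97.5%
    per period, a two-period multiplicity allowance); the dominant period is
    the significant one with greater power, or none.
    """
    days = series.timestamps.normalize()
    unique_days = days.unique()
    if len(unique_days) < 3:
        raise ValidationError("need >= 3 days of data to classify the dominant period")
    minute_of_day = (series.timestamps.hour * 60 + series.timestamps.minute).to_numpy()
    day_code = pd.factorize(days)[0]
    mat = np.full((len(unique_days), 1440), np.nan)
    mat[day_code, minute_of_day] = series.values

    flat_minutes = np.tile(np.arange(1440), len(unique_days)).astype(float)

    def powers(matrix):
        vals = matrix.ravel()
        ok = np.isfinite(vals)
        return _harmonic_powers(flat_minutes[ok], vals[ok])

    obs24, obs12 = powers(mat)
    rng = np.random.default_rng(int(seed) % (2**31))
    null24 = np.empty(n_perm)
    null12 = np.empty(n_perm)
    for b in range(n_perm):
        shifts = rng.integers(0, 1440, size=mat.shape[0])
        rolled = np.empty_like(mat)
        for d in range(mat.shape[0]):
            rolled[d] = np.roll(mat[d], shifts[d])
        null24[b], null12[b] = powers(rolled)
    band = {"24h": float(np.nanquantile(null24, band_quantile)),
            "12h": float(np.nanquantile(null12, band_quantile))}
    sig = {"24h": obs24 > band["24h"], "12h": obs12 > band["12h"]}
    if not (sig["24h"] or sig["12h"]):
        dominant = "none"
    elif sig["24h"] and (not sig["12h"] or obs24 >= obs12):
        dominant = "24h"
    else:
        dominant = "12h"
    return PeriodClassification(dominant=dominant, power_24=obs24, power_12=obs12,
                                null_band=band, n_days=len(unique_days))
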