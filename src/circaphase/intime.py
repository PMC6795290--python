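"""INTime: prediction of the core temperature bathyphase from noninvasive markers.

The predictor is an ordinary linear regression of the core body temperature
bathyphase (decimal hours, unwrapped so the nocturnal cluster is contiguous)
on per-subject covariates.  The published fixed-coefficient instance is

    core bathyphase = 1.33*sex - 0.058*chronotype score
                      + 0.472*center-of-rest time - 0.145*chest bathyphase

with sex coded 1 for male, 0 for female, and all phases in decimal hours.
Model building follows the study recipe: a pairwise Spearman / two-sample
t-test screen of candidate predictors, then bidirectional stepwise selection
by the small-sample corrected Akaike criterion (AICc) starting from the full
model.  A residual-bootstrap Monte Carlo assesses how large a cohort would
be needed to stabilise the adjusted R-squared of the fit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .core import ValidationError, circular_signed_diff

__all__ = [
    "PUBLISHED_COEFFS",
    "PublishedINTime",
    "INTimeModel",
    "correlation_screen",
    "ScreenReport",
    "fit_intime",
    "predict_bathyphase",
    "accuracy_summary",
    "AccuracyReport",
    "sample_size_stability",
    "StabilityResult",
    "aicc",
]

#: Printed coefficients of the published INTime equation (hours per unit).
PUBLISHED_COEFFS: Mapping[str, float] = {
    "sex": 1.33,
    "chronotype_score": -0.058,
    "center_of_rest": 0.472,
    "chest_bathyphase": -0.145,
}

#: Candidate covariates the full model starts from.
DEFAULT_CANDIDATES = ("sex", "age", "bmi", "chronotype_score", "dlmo",
                      "center_of_rest", "chest_acrophase", "chest_bathyphase")


@dataclass(frozen=True)
class PublishedINTime:
    """The fixed-coefficient published equation (intercept-free, immutable)."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_COEFFS))

    def predict(self, covariates: Mapping[str, float]) -> float:
        total = 0.0
        for name, coef in self.coefficients.items():
            if name not in covariates or pd.isna(covariates[name]):
                raise ValidationError(f"missing covariate {name!r} for INTime prediction")
            total += coef * float(covariates[name])
        return total


@dataclass
class INTimeModel:
    """A fitted bathyphase regression with its stepwise selection trace."""

    outcome: str
    covariates: list[str]
    params: pd.Series                     # includes 'const' when fitted with intercept
    adj_r2: float
    residuals: np.ndarray
    residual_sd: float
    nobs: int
    selection_trace: list[tuple[str, str, float]]   # (action, variable, AICc)
    prediction_level: float = 0.90
    _results: object = field(default=None, repr=False, compare=False)
    _exog: pd.DataFrame = field(default=None, repr=False, compare=False)

    def predict(self, covariates: Mapping[str, float] | pd.DataFrame,
                level: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Point prediction and (lo, hi) prediction band for new subjects."""
        level = self.prediction_level if level is None else level
        if isinstance(covariates, Mapping):
            covariates = pd.DataFrame([covariates])
        X = pd.DataFrame(index=covariates.index)
        for v in self.covariates:
            if v not in covariates.columns or covariates[v].isna().any():
                raise ValidationError(f"missing covariate {v!r} for INTime prediction")
            X[v] = covariates[v].astype(float)
        if "const" in self.params.index:
            X = sm.add_constant(X, has_constant="add")
        pred = self._results.get_prediction(X[self.params.index])
        frame = pred.summary_frame(alpha=1.0 - level)
        band = np.column_stack([frame["obs_ci_lower"], frame["obs_ci_upper"]])
        return frame["mean"].to_numpy(), band


# ---------------------------------------------------------------------------
# Covariate screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    spearman_r: pd.DataFrame
    spearman_p: pd.DataFrame
    ttests: pd.DataFrame          # rows: (binary var, numeric var) t / p
    flagged: list[tuple[str, str, float]]   # pairs with p < alpha
    alpha: float = 0.1


_BINARY_VARS = ("sex", "concurrent_treatment")


def correlation_screen(data: pd.DataFrame,
                       numeric_vars: Sequence[str] | None = None,
                       alpha: float = 0.1) -> ScreenReport:
    """Pairwise Spearman correlations among phase estimates and scores, plus
    two-sample t-tests of each numeric variable across binary covariates.

    ``data`` is one row per subject with phases and covariates merged.
    Cells with fewer than 3 complete pairs are reported missing (NaN).
    Pairs with two-tailed p < ``alpha`` (default 0.1) are flagged.
    """
    if numeric_vars is None:
        numeric_vars = [c for c in ("dlmo", "core_acrophase", "core_bathyphase",
                                    "chest_acrophase", "chest_bathyphase",
                                    "center_of_rest", "chronotype_score",
                                    "age", "bmi") if c in data.columns]
    if len(data.dropna(subset=[v for v in numeric_vars if v in data.columns],
                       how="all")) < 5:
        raise ValidationError("need at least 5 subjects for the covariate screen")
    k = len(numeric_vars)
    r = pd.DataFrame(np.full((k, k), np.nan), index=numeric_vars, columns=numeric_vars)
    p = r.copy()
    for i, a in enumerate(numeric_vars):
        for j, b in enumerate(numeric_vars):
            if j < i:
                continue
            pair = data[[a, b]].dropna()
            if len(pair) < 3:
                continue
            if a == b:
                rr, pp = 1.0, 0.0
            else:
                rr, pp = st.spearmanr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    rows = []
    for bv in _BINARY_VARS:
        if bv not in data.columns or data[bv].nunique() < 2:
            continue
        for nv in numeric_vars:
            sub = data[[bv, nv]].dropna()
            g0 = sub.loc[sub[bv].astype(float) == 0, nv]
            g1 = sub.loc[sub[bv].astype(float) == 1, nv]
            if len(g0) < 2 or len(g1) < 2:
                rows.append({"binary": bv, "variable": nv, "t": np.nan, "p": np.nan})
                continue
            t, pp = st.ttest_ind(g1, g0)
            rows.append({"binary": bv, "variable": nv, "t": float(t), "p": float(pp)})
    ttests = pd.DataFrame(rows, columns=["binary", "variable", "t", "p"])
    flagged = [(a, b, float(p.loc[a, b]))
               for i, a in enumerate(numeric_vars) for b in numeric_vars[i + 1:]
               if np.isfinite(p.loc[a, b]) and p.loc[a, b] < alpha]
    flagged += [(row["binary"], row["variable"], row["p"])
                for _, row in ttests.iterrows()
                if np.isfinite(row["p"]) and row["p"] < alpha]
    return ScreenReport(r, p, ttests, flagged, alpha)


# ---------------------------------------------------------------------------
# Stepwise AICc selection
# ---------------------------------------------------------------------------

def aicc(results) -> float:
    """Corrected Akaike criterion; k counts coefficients plus the error variance."""
    k = len(results.params) + 1
    n = results.nobs
    if n - k - 1 <= 0:
        return np.inf
    aic = -2.0 * results.llf + 2.0 * k
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


def _fit_ols(y: pd.Series, X: pd.DataFrame, variables: Sequence[str],
             include_intercept: bool):
    exog = X[list(variables)].astype(float)
    if include_intercept:
        exog = sm.add_constant(exog, has_constant="add")
    if exog.shape[1] == 0:
        exog = pd.DataFrame(np.zeros((len(y), 0)), index=y.index)
    return sm.OLS(y, exog).fit()


def fit_intime(data: pd.DataFrame,
               candidates: Sequence[str] = DEFAULT_CANDIDATES,
               outcome: str = "core_bathyphase",
               include_intercept: bool = True,
               refit_on_selected: bool = True,
               prediction_level: float = 0.90) -> INTimeModel:
    """Bidirectional stepwise AICc regression of the core bathyphase.

    ``data`` holds one row per subject with the outcome and candidate
    columns (phases in unwrapped decimal hours).  Selection runs on the
    subset of rows complete for *all* candidates, so AICc values are
    comparable across candidate models; the selected model is then refit on
    every row complete for the selected variables (``refit_on_selected``).
    """
    candidates = [c for c in candidates if c in data.columns]
    if not candidates:
        raise ValidationError("no candidate covariates present in data")
    common = data.dropna(subset=[outcome, *candidates])
    p_full = len(candidates) + (1 if include_intercept else 0)
    if len(common) <= p_full + 2:
        raise ValidationError(
            f"too few complete rows (n={len(common)}) for {p_full} parameters; "
            "AICc selection is unstable")
    y = common[outcome].astype(float)
    X = common

    current = list(candidates)
    res = _fit_ols(y, X, current, include_intercept)
    best = aicc(res)
    trace: list[tuple[str, str, float]] = [("start", "+".join(current), best)]
    while True:
        moves = [("drop", v) for v in current]
        moves += [("add", v) for v in candidates if v not in current]
        scored = []
        for action, v in moves:
            trial = ([c for c in current if c != v] if action == "drop"
                     else current + [v])
            if not trial and not include_intercept:
                continue
            scored.append((aicc(_fit_ols(y, X, trial, include_intercept)), action, v, trial))
        if not scored:
            break
        scored.sort(key=lambda s: s[0])
        cand_aicc, action, v, trial = scored[0]
        if cand_aicc < best - 1e-9:
            best, current = cand_aicc, trial
            trace.append((action, v, best))
        else:
            break

    if refit_on_selected:
        fit_rows = data.dropna(subset=[outcome, *current]) if current else data.dropna(subset=[outcome])
        y_fin = fit_rows[outcome].astype(float)
        results = _fit_ols(y_fin, fit_rows, current, include_intercept)
    else:
        fit_rows = common
        results = _fit_ols(y, X, current, include_intercept)
    resid = np.asarray(results.resid, dtype=float)
    k = len(results.params)
    dof = max(1, int(results.nobs) - k)
    model = INTimeModel(
        outcome=outcome, covariates=list(current),
        params=results.params, adj_r2=float(results.rsquared_adj),
        residuals=resid, residual_sd=float(np.sqrt(resid @ resid / dof)),
        nobs=int(results.nobs), selection_trace=trace,
        prediction_level=prediction_level,
        _results=results,
        _exog=results.model.exog.copy() if hasattr(results.model, "exog") else None,
    )
    return model


def predict_bathyphase(model: INTimeModel | PublishedINTime,
                       covariates: Mapping[str, float] | pd.DataFrame,
                       level: float = 0.90):
    """Predict the core bathyphase (decimal hours) with a prediction band.

    Fitted models return ``(point, (lo, hi))`` per subject; the published
    equation stores no residual variance, so its band is ``None``.
    """
    if isinstance(model, PublishedINTime):
        if isinstance(covariates, pd.DataFrame):
            return np.array([model.predict(row) for _, row in covariates.iterrows()]), None
        return model.predict(covariates), None
    return model.predict(covariates, level=level)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    n: int
    median_error_h: float
    iqr_h: tuple[float, float]
    min_error_h: float
    max_error_h: float
    frac_within_1h: float
    band_coverage: float | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iqr_h"] = list(self.iqr_h)
        return d


def accuracy_summary(predicted: Sequence[float], measured: Sequence[float],
                     bands: np.ndarray | None = None) -> AccuracyReport:
    """Signed prediction errors (predicted - measured, wrap-safe) in hours.

    Reports median, IQR, extremes, the fraction of subjects with absolute
    error under 1 h, and (when bands are given) the fraction of measured
    values inside their prediction band.
    """
    pred = np.asarray([float(p) for p in predicted])
    meas = np.asarray([float(m) for m in measured])
    if pred.shape != meas.shape:
        raise ValidationError("predicted and measured lengths differ")
    err = np.array([circular_signed_diff(p, m) for p, m in zip(pred, meas)])
    coverage = None
    if bands is not None:
        bands = np.asarray(bands, dtype=float)
        inside = (meas >= bands[:, 0]) & (meas <= bands[:, 1])
        coverage = float(np.mean(inside))
    return AccuracyReport(
        n=len(err),
        median_error_h=float(np.median(err)),
        iqr_h=(float(np.percentile(err, 25)), float(np.percentile(err, 75))),
        min_error_h=float(err.min()), max_error_h=float(err.max()),
        frac_within_1h=float(np.mean(np.abs(err) < 1.0)),
        band_coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Sample-size stability of the fit
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    reference_adj_r2: float
    widths: pd.DataFrame                  # index: n, columns: CI level -> width
    relative_widths: pd.DataFrame
    required_n: dict                      # level -> smallest n meeting the criterion


def sample_size_stability(model: INTimeModel, n_grid: Sequence[int],
                          trials: int = 1000,
                          ci_levels: Sequence[float] = (0.90, 0.95),
                          seed: int = 0,
                          criterion: float = 0.10) -> StabilityResult:
    """Residual-bootstrap Monte Carlo of the adjusted R-squared stability.

    For each candidate cohort size n, ``trials`` pseudo-datasets are built by
    resampling covariate rows of the fitted design and adding resampled
    residuals to the fitted values; the model is refit and the adjusted
    R-squared collected.  The result reports, per CI level, the width of the
    central interval of that distribution relative to the reference adjusted
    R-squared, and the smallest n whose relative width is below ``criterion``.
    """
    X = np.asarray(model._exog, dtype=float)
    if X is None:
        raise ValidationError("model carries no design matrix")
    beta = model.params.to_numpy(dtype=float)
    resid = model.residuals
    k = X.shape[1]
    n_grid = sorted(int(n) for n in n_grid)
    if n_grid[0] <= k + 2:
        raise ValidationError(f"smallest n in grid ({n_grid[0]}) too close to "
                              f"model dimension ({k})")
    rng = np.random.default_rng(int(seed) % (2**31))
    widths = {lev: [] for lev in ci_levels}
    for n in n_grid:
        adj = np.empty(trials)
        for b in range(trials):
            rows = rng.integers(0, X.shape[0], size=n)
            Xb = X[rows]
            yb = Xb @ beta + resid[rng.integers(0, resid.size, size=n)]
            coef, _, _, _ = np.linalg.lstsq(Xb, yb, rcond=None)
            fit = Xb @ coef
            rss = float(np.sum((yb - fit) ** 2))
            tss = float(np.sum((yb - yb.mean()) ** 2))
            if tss <= 0:
                adj[b] = np.nan
                continue
            adj[b] = 1.0 - (rss / max(1, n - k)) / (tss / (n - 1))
        for lev in ci_levels:
            a = (1.0 - lev) / 2.0
            lo, hi = np.nanpercentile(adj, [100 * a, 100 * (1 - a)])
            widths[lev].append(float(hi - lo))
    widths_df = pd.DataFrame(widths, index=pd.Index(n_grid, name="n"))
    rel = widths_df / abs(model.adj_r2)
    required = {}
    for lev in ci_levels:
        ok = rel.index[rel[lev] < criterion]
        required[lev] = int(ok[0]) if len(ok) else None
    return StabilityResult(model.adj_r2, widths_df, rel, required)
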