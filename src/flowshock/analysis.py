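"""Derived statistics from binned series and comparison against predictions.

Covers the quantities an operator would extract from the 1-min series:
baseline level and noise, earliest detectable deviation from baseline
(k-sigma rule), the linear decline rate during chlorination, the exponential
washout rate, simple derived ratios (percent reduction, fold increase,
volume changes), and residual/RMSE/lag comparison of a measured series
against the mixing-model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .gating import BinnedSeries
from .reactor import Trajectory

__all__ = [
    "BaselineStats",
    "LinearFit",
    "WashoutFit",
    "ComparisonReport",
    "baseline_stats",
    "detect_onset",
    "fit_linear_rate",
    "fit_washout",
    "percent_reduction",
    "fold_increase",
    "volume_changes",
    "derived_quantities",
    "compare_to_prediction",
]


@dataclass
class BaselineStats:
    mean: float
    sd: float
    n: int
    window: tuple[float, float]


@dataclass
class LinearFit:
    slope: float       # cells/ul/min
    intercept: float
    r_squared: float
    n: int


@dataclass
class WashoutFit:
    """Fit of ``c(t) = a + b * exp(-r * t)`` (t relative to window start)."""

    ok: bool
    rate: float | None = None       # 1/min
    asymptote: float | None = None
    amplitude: float | None = None
    message: str = ""


@dataclass
class ComparisonReport:
    time_min: np.ndarray
    measured: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray           # measured - predicted
    rmse: float
    max_abs_residual: float
    lag_min: float                  # >0: measured lags the prediction
    excluded_window: tuple[float, float] | None = None


def baseline_stats(series: BinnedSeries,
                   window: tuple[float, float] = (0.0, 15.0)) -> BaselineStats:
    """Mean and sample SD of bin concentrations inside a stable window."""
    sub = series.window(*window)
    vals = sub.concentration
    if len(vals) < 2:
        raise ValueError("baseline window must contain at least 2 bins")
    return BaselineStats(mean=float(np.mean(vals)),
                         sd=float(np.std(vals, ddof=1)),
                         n=len(vals), window=window)


def detect_onset(series: BinnedSeries, baseline: BaselineStats,
                 k_sigma: float = 3.0, min_consecutive: int = 2,
                 direction: str = "both") -> float | None:
    """Earliest bin start where the series leaves the baseline band.

    A deviation is ``min_consecutive`` consecutive bins beyond
    ``mean ± k_sigma * sd`` (one-sided for ``direction`` "up"/"down").
    Only bins after the baseline window are considered. With sd = 0 any
    departure from the mean triggers. Returns the first deviating bin's
    start time, or None.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    after = series.bin_start_min >= baseline.window[1] - 1e-9
    t = series.bin_start_min[after]
    c = series.concentration[after]
    hi = baseline.mean + k_sigma * baseline.sd
    lo = baseline.mean - k_sigma * baseline.sd
    if direction == "up":
        dev = c > hi
    elif direction == "down":
        dev = c < lo
    elif direction == "both":
        dev = (c > hi) | (c < lo)
    else:
        raise ValueError("direction must be 'up', 'down' or 'both'")
    run = 0
    for i, flag in enumerate(dev):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(t[i - min_consecutive + 1])
    return None


def fit_linear_rate(series: BinnedSeries,
                    window: tuple[float, float]) -> LinearFit:
    """Ordinary least-squares slope of concentration vs time (bin centers)."""
    sub = series.window(*window)
    if len(sub.concentration) < 3:
        raise ValueError("linear fit needs at least 3 bins")
    t = sub.bin_center_min
    if np.ptp(t) == 0:
        raise ValueError("degenerate window: all bins at one time")
    res = linregress(t, sub.concentration)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2), n=len(t))


def fit_washout(series: BinnedSeries, window: tuple[float, float],
                floor: float = 0.0) -> WashoutFit:
    """Nonlinear least-squares fit of exponential washout to an asymptote.

    Fits ``c(t) = a + b * exp(-r * t)`` with t counted from the window start.
    ``floor`` is the initial guess for the asymptote (e.g. the tap-water
    level); it is not a hard constraint. Non-convergence or an
    unidentifiable rate yields ``ok=False`` with a diagnostic message.
    """
    sub = series.window(*window)
    c = sub.concentration
    if len(c) < 4:
        return WashoutFit(ok=False, message="fewer than 4 bins in window")
    t = sub.bin_center_min - sub.bin_center_min[0]
    if np.std(c) < 1e-12 * max(1.0, abs(np.mean(c))):
        return WashoutFit(ok=False, message="constant series: rate unidentifiable")
    a0 = floor if floor > 0 else float(min(c))
    b0 = float(c[0] - a0)
    if abs(b0) < 1e-12:
        b0 = float(np.ptp(c)) or 1.0
    r0 = 2.0 / max(t[-1], 1e-6)
    try:
        popt, pcov = curve_fit(
            lambda tt, a, b, r: a + b * np.exp(-r * tt),
            t, c, p0=[a0, b0, r0], maxfev=10000,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]))
    except (RuntimeError, ValueError) as exc:
        return WashoutFit(ok=False, message=f"fit failed: {exc}")
    a, b, r = popt
    var_r = pcov[2, 2]
    if not np.isfinite(var_r) or (r > 0 and np.sqrt(var_r) > 10 * r):
        return WashoutFit(ok=False, rate=float(r), asymptote=float(a),
                          amplitude=float(b),
                          message="rate poorly identified (huge variance)")
    return WashoutFit(ok=True, rate=float(r), asymptote=float(a),
                      amplitude=float(b))


def percent_reduction(before: float, after: float) -> float:
    """``100 * (1 - after/before)``; requires a positive reference."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return 100.0 * (1.0 - after / before)


def fold_increase(peak: float, baseline: float) -> tuple[float, int]:
    """Peak over baseline; returns (exact fold, nearest integer fold)."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    f = peak / baseline
    return f, int(round(f))


def volume_changes(dilution_rate: float, elapsed: float) -> float:
    """Number of reactor volumes exchanged: ``D * t``."""
    if dilution_rate < 0 or elapsed < 0:
        raise ValueError("dilution_rate and elapsed must be >= 0")
    return dilution_rate * elapsed


def derived_quantities(before: float, after: float, peak: float,
                       baseline: float, dilution_rate: float,
                       elapsed: float) -> dict:
    """Bundle of the simple derived ratios for a report."""
    f, f_round = fold_increase(peak, baseline)
    return {
        "percent_reduction": percent_reduction(before, after),
        "fold_increase": f,
        "fold_increase_rounded": f_round,
        "volume_changes": volume_changes(dilution_rate, elapsed),
    }


def compare_to_prediction(measured: BinnedSeries, predicted: Trajectory,
                          column: str = "tcc", max_lag_bins: int = 5,
                          exclude_window: tuple[float, float] | None = None,
                          ) -> ComparisonReport:
    """Residuals, RMSE and best cross-correlation lag vs a predicted trajectory.

    The prediction is interpolated at (aligned) bin centers; only bins whose
    centers fall inside the prediction's span are compared. ``exclude_window``
    (reactor minutes) removes bins from the RMSE and max-residual summary
    (e.g. the chlorination window, where the no-chlorine-effect prediction is
    known not to apply) but not from the lag estimate. A positive lag means
    the measurement trails the prediction.
    """
    centers = measured.bin_center_min
    lo, hi = predicted.span
    m = (centers >= lo) & (centers <= hi)
    if not np.any(m):
        raise ValueError("no overlap between measured bins and prediction")
    t = centers[m]
    meas = measured.concentration[m]
    pred = predicted.at(t, column)
    residuals = meas - pred

    keep = np.ones(len(t), dtype=bool)
    if exclude_window is not None:
        keep = (t < exclude_window[0]) | (t > exclude_window[1])
        if not np.any(keep):
            raise ValueError("exclude_window removes every bin")
    rmse = float(np.sqrt(np.mean(residuals[keep] ** 2)))
    max_abs = float(np.max(np.abs(residuals[keep])))

    bin_min = measured.bin_width_s / 60.0
    best_lag, best_score = 0, -np.inf
    mm = meas - meas.mean()
    for lag in range(-max_lag_bins, max_lag_bins + 1):
        pp = predicted.at(t - lag * bin_min, column)
        pp = pp - pp.mean()
        denom = np.sqrt((mm ** 2).sum() * (pp ** 2).sum())
        score = float((mm * pp).sum() / denom) if denom > 0 else -np.inf
        if score > best_score:
            best_score, best_lag = score, lag
    return ComparisonReport(time_min=t, measured=meas, predicted=pred,
                            residuals=residuals, rmse=rmse,
                            max_abs_residual=max_abs,
                            lag_min=best_lag * bin_min,
                            excluded_window=exclude_window)
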