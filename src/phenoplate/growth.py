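"""Non-parametric growth-curve analysis.

The central quantity is the **maximum slope**: ordinary least squares is fit
in every sliding window of ``fitrange`` consecutive timepoints and the
largest fitted slope is reported, together with its timing, the lag phase,
initial/final population proxies and the goodness of fit of the winning
window.  This makes no assumption about the shape of the growth curve
(logistic, diauxic, ...), at the cost of a mild flattening bias that grows
with the window width.

The default ``fitrange`` is 12 points, suited to imaging every 20 minutes
(a 4-hour window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import CurveLengthError, SingularFitError
from .imaging import TimecourseTable

DEFAULT_FITRANGE = 12


@dataclass
class GrowthCurve:
    """Timestamped population-size proxy series for one plate position."""

    t: np.ndarray
    y: np.ndarray
    position: tuple[int, int] | None = None
    plate_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise CurveLengthError("growth curve needs at least 3 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("timestamps must be finite")


@dataclass
class GrowthParameters:
    """Result of a sliding-window maximum-slope fit.

    ``lag`` is where the winning window's regression line crosses the
    initial level ``y0`` (mean of the first ``fitrange`` points), clipped at
    0; it is NaN (undefined) when the winning slope is not positive or the
    crossing precedes the first timepoint by more than one sampling
    interval.
    """

    max_slope: float
    t_max: float
    lag: float
    y0: float
    y_end: float
    r2: float
    fitrange: int
    reason: str | None = None


def _window_ols(tw: np.ndarray, yw: np.ndarray):
    """Vectorised OLS per window; returns slope, intercept, r2 arrays."""
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    dt = tw - tm
    dy = yw - ym
    sxx = (dt * dt).sum(axis=1)
    if np.any(sxx <= 0):
        raise SingularFitError("constant time within a regression window")
    slope = (dt * dy).sum(axis=1) / sxx
    intercept = ym[:, 0] - slope * tm[:, 0]
    sst = (dy * dy).sum(axis=1)
    sse = sst - slope**2 * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.where(np.abs(sse) < 1e-12, 1.0, 0.0))
    return slope, intercept, np.clip(r2, 0.0, 1.0)


def fit_max_slope(curve: GrowthCurve, fitrange: int = DEFAULT_FITRANGE) -> GrowthParameters:
    """Maximum slope over all sliding OLS windows of ``fitrange`` points.

    Windows containing non-finite values are skipped, not imputed.  Raises
    :class:`CurveLengthError` when the curve is shorter than ``fitrange``
    and :class:`SingularFitError` when no window is usable.
    """
    if fitrange < 2:
        raise ValueError("fitrange must be >= 2")
    t, y = curve.t, curve.y
    if len(t) < fitrange:
        raise CurveLengthError(
            f"curve has {len(t)} points but fitrange is {fitrange}"
        )
    tw = sliding_window_view(t, fitrange)
    yw = sliding_window_view(y, fitrange)
    valid = np.all(np.isfinite(yw), axis=1)
    if not valid.any():
        raise SingularFitError("no window free of missing values")
    slope, intercept, r2 = _window_ols(tw[valid], yw[valid])

    finite_y = y[np.isfinite(y)]
    if finite_y.size and np.ptp(finite_y) == 0:
        return GrowthParameters(
            max_slope=np.nan, t_max=np.nan, lag=np.nan, y0=float(finite_y[0]),
            y_end=float(finite_y[-1]), r2=np.nan, fitrange=fitrange,
            reason="constant-series",
        )

    best = int(np.argmax(slope))
    best_slope = float(slope[best])
    t_max = float(tw[valid][best].mean())
    y0 = float(np.nanmean(y[:fitrange]))
    y_end = float(np.nanmean(y[-fitrange:]))

    lag = np.nan
    if best_slope > 0:
        crossing = (y0 - float(intercept[best])) / best_slope
        dt_med = float(np.median(np.diff(t)))
        if crossing >= t[0] - dt_med:
            lag = max(crossing, 0.0)
    return GrowthParameters(
        max_slope=best_slope,
        t_max=t_max,
        lag=lag,
        y0=y0,
        y_end=y_end,
        r2=float(r2[best]),
        fitrange=fitrange,
    )


def summarize_curves(
    table: TimecourseTable,
    fitrange: int = DEFAULT_FITRANGE,
    plots_dir: str | None = None,
) -> pd.DataFrame:
    """Fit every curve of a timecourse table; one parameter row per column.

    Per-curve failures are downgraded to missing values with a reason code
    so one bad position never aborts a plate.
    """
    if table.data.shape[1] == 0:
        raise ValueError("timecourse table has no curves")
    t = table.timepoints
    rows = []
    for name in table.data.columns:
        y = table.data[name].to_numpy(dtype=float)
        try:
            params = fit_max_slope(GrowthCurve(t, y), fitrange)
        except (CurveLengthError, SingularFitError, ValueError) as exc:
            params = GrowthParameters(
                max_slope=np.nan, t_max=np.nan, lag=np.nan, y0=np.nan,
                y_end=np.nan, r2=np.nan, fitrange=fitrange,
                reason=type(exc).__name__,
            )
        rows.append(
            {
                "position": name,
                "max_slope": params.max_slope,
                "t_max": params.t_max,
                "lag": params.lag,
                "y0": params.y0,
                "y_end": params.y_end,
                "r2": params.r2,
                "fitrange": fitrange,
                "reason": params.reason,
            }
        )
        if plots_dir is not None:
            _plot_curve(plots_dir, name, t, y, params)
    return pd.DataFrame(rows)


def mean_growth_rate(table: TimecourseTable) -> pd.Series:
    """Average growth rate per interval: mean over positions of the
    difference in intensity sums between consecutive timepoints, divided by
    the time step.  Indexed by the interval midpoint (hours)."""
    t = table.timepoints
    if len(t) < 2:
        raise CurveLengthError("need at least 2 timepoints for growth rates")
    vals = table.data.to_numpy(dtype=float)
    dt = np.diff(t)
    rates = np.nanmean(np.diff(vals, axis=0), axis=1) / dt
    mid = (t[:-1] + t[1:]) / 2
    return pd.Series(rates, index=mid, name="mean_growth_rate")


def _plot_curve(plots_dir: str, name: str, t: np.ndarray, y: np.ndarray, params) -> None:
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(plots_dir, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(t, y, ".-", ms=3)
    if np.isfinite(params.max_slope) and np.isfinite(params.t_max):
        ym = np.interp(params.t_max, t, y)
        half = (t[-1] - t[0]) / 10
        ax.plot(
            [params.t_max - half, params.t_max + half],
            [ym - half * params.max_slope, ym + half * params.max_slope],
            "r-", lw=2,
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("population proxy")
    ax.set_title(name, fontsize=9)
    fig.tight_layout()
    fig.savefig(os.path.join(plots_dir, f"curve_{name}.png"), dpi=100)
    plt.close(fig)
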