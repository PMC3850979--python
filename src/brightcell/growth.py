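"""Population growth analysis from per-frame cell counts.

With frames every few minutes, the population doubling time needs no model
fit: for each time point t, find the first later time t₂ at which the
(lightly smoothed) mean count reaches twice its value at t; the doubling
time is simply DT(t) = t₂ − t, linearly interpolated between the bracketing
samples. The estimate is invariant to shifting all timestamps and to
rescaling all counts, and is undefined once the series no longer doubles
before it ends.

A culture typically traverses three phases — sub-exponential early growth,
a clearly exponential phase, and a plateau once the well saturates. The
phase report formalizes what is usually read off a log-scale plot: a
two-breakpoint piecewise-linear fit to log counts, with each phase's slope
converted to a doubling time ln 2 / slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountSeries:
    """Per-timepoint mean ± sd of counts (and optionally densities)."""

    time_hours: np.ndarray
    mean_count: np.ndarray
    sd_count: np.ndarray
    mean_density: np.ndarray | None = None
    sd_density: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_hours = np.asarray(self.time_hours, dtype=float)
        self.mean_count = np.asarray(self.mean_count, dtype=float)
        self.sd_count = np.asarray(self.sd_count, dtype=float)
        if np.any(np.diff(self.time_hours) <= 0):
            raise ValueError("time_hours must be strictly increasing")
        if np.any(self.mean_count < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class DoublingSeries:
    """Pointwise doubling times; NaN where the series never doubles."""

    time_hours: np.ndarray
    doubling_time_hours: np.ndarray


def aggregate_counts(per_fov_counts: pd.DataFrame,
                     pixel_size_um: float | None = None,
                     image_shape: tuple[int, int] | None = None) -> CountSeries:
    """Aggregate a (fov, timepoint, time_hours, n_cells) table across FOVs.

    Mean and standard deviation are taken across fields of view at each
    timepoint. Timepoints missing some fields of view are kept (with a
    warning); duplicated (fov, timepoint) pairs are an error.
    """
    df = per_fov_counts
    required = {"fov", "timepoint", "time_hours", "n_cells"}
    if missing := required - set(df.columns):
        raise ValueError(f"counts table lacks columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("empty counts table")
    if df.duplicated(["fov", "timepoint"]).any():
        raise ValueError("duplicate (fov, timepoint) rows")
    n_fov = df["fov"].nunique()
    grouped = df.groupby("timepoint").agg(
        time_hours=("time_hours", "mean"),
        mean=("n_cells", "mean"),
        sd=("n_cells", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n=("n_cells", "size"),
    ).sort_values("time_hours")
    if (grouped["n"] < n_fov).any():
        warnings.warn("some timepoints are missing fields of view; "
                      "their statistics use the frames present")
    series = CountSeries(grouped["time_hours"].to_numpy(),
                         grouped["mean"].to_numpy(), grouped["sd"].to_numpy())
    if pixel_size_um is not None and image_shape is not None:
        area_mm2 = image_shape[0] * image_shape[1] * pixel_size_um ** 2 * 1e-6
        series.mean_density = series.mean_count / area_mm2
        series.sd_density = series.sd_count / area_mm2
    return series


def _smooth(counts: np.ndarray, time_hours: np.ndarray,
            window_hours: float) -> np.ndarray:
    """Centered moving average over a time window (assumes ~regular sampling)."""
    if window_hours <= 0 or len(counts) < 3:
        return counts.astype(float)
    dt = np.median(np.diff(time_hours))
    half = max(int(round(window_hours / (2 * dt))), 0)
    if half == 0:
        return counts.astype(float)
    kernel = np.ones(2 * half + 1)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / den


def doubling_time(series: CountSeries,
                  smooth_window_hours: float = 1.0) -> DoublingSeries:
    """Pointwise doubling time: lag until the smoothed count first doubles.

    The crossing time is linearly interpolated between the samples
    bracketing 2·N(t); non-monotone noise is handled by taking the first
    crossing. Time points whose doubled count is never reached get NaN.
    """
    t = series.time_hours
    if len(t) < 2:
        raise ValueError("need at least two timepoints")
    n = _smooth(series.mean_count, t, smooth_window_hours)
    dt_out = np.full(len(t), np.nan)
    for i in range(len(t)):
        target = 2.0 * n[i]
        if target <= 0:
            continue
        ahead = np.flatnonzero(n[i:] >= target)
        if ahead.size == 0:
            continue
        j = i + int(ahead[0])
        if j == i:
            dt_out[i] = 0.0
            continue
        n0, n1 = n[j - 1], n[j]
        frac = (target - n0) / (n1 - n0) if n1 > n0 else 1.0
        t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
        dt_out[i] = t_cross - t[i]
    return DoublingSeries(t.copy(), dt_out)


@dataclass
class PhaseReport:
    """Two-breakpoint piecewise log-linear description of the growth curve.

    ``breakpoints_hours`` are the two phase boundaries; per phase, the slope
    of log2 counts per hour and the implied doubling time 1/slope in hours
    (infinite for non-growing phases). This formalizes the phase structure a
    log-scale plot shows by eye.
    """

    breakpoints_hours: tuple[float, float]
    slopes_log2_per_hour: tuple[float, float, float]
    doubling_times_hours: tuple[float, float, float]
    sse: float


def phase_report(series: CountSeries, min_phase_points: int = 4,
                 n_candidates: int = 60) -> PhaseReport:
    """Fit three growth phases by grid search over breakpoint pairs.

    Log2 counts are fitted piecewise-linearly; the breakpoint pair
    minimizing the total squared error is selected from a grid of candidate
    sample indices (``n_candidates`` per axis, O(1) segment fits via prefix
    sums). Zero counts are excluded from the log fit.
    """
    t, n = series.time_hours, series.mean_count
    keep = n > 0
    t, n = t[keep], n[keep]
    if len(t) < 3 * min_phase_points:
        raise ValueError("too few positive timepoints for a 3-phase fit")
    y = np.log2(n)

    # prefix sums for O(1) least-squares over any contiguous segment
    one = np.ones_like(t)
    P = {k: np.concatenate(([0.0], np.cumsum(v)))
         for k, v in {"1": one, "t": t, "tt": t * t, "y": y,
                      "ty": t * y, "yy": y * y}.items()}

    def seg_fit(i: int, j: int) -> tuple[float, float]:
        """OLS slope and SSE of y~t over samples [i, j)."""
        m = j - i
        st = P["t"][j] - P["t"][i]
        stt = P["tt"][j] - P["tt"][i]
        sy = P["y"][j] - P["y"][i]
        sty = P["ty"][j] - P["ty"][i]
        syy = P["yy"][j] - P["yy"][i]
        det = m * stt - st * st
        if det <= 1e-12:
            return 0.0, syy - sy * sy / m
        slope = (m * sty - st * sy) / det
        intercept = (sy - slope * st) / m
        sse = syy - 2 * slope * sty - 2 * intercept * sy \
            + slope ** 2 * stt + 2 * slope * intercept * st + intercept ** 2 * m
        return slope, max(sse, 0.0)

    npts = len(t)
    cand = np.unique(np.linspace(min_phase_points,
                                 npts - min_phase_points, n_candidates,
                                 dtype=int))
    best = None
    for b1 in cand:
        s1, e1 = seg_fit(0, b1)
        for b2 in cand[cand >= b1 + min_phase_points]:
            s2, e2 = seg_fit(b1, b2)
            s3, e3 = seg_fit(b2, npts)
            sse = e1 + e2 + e3
            if best is None or sse < best[0]:
                best = (sse, b1, b2, (s1, s2, s3))
    sse, b1, b2, slopes = best
    dts = tuple(1.0 / s if s > 1e-12 else float("inf") for s in slopes)
    return PhaseReport(
        breakpoints_hours=(float(t[b1]), float(t[b2])),
        slopes_log2_per_hour=tuple(float(s) for s in slopes),
        doubling_times_hours=dts,
        sse=float(sse),
    )
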