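"""Growth descriptors from green-area time-series.

Rosette growth over the assay window is close to exponential, so the
central quantity is the classical relative growth rate

    RGR = (ln A2 - ln A1) / (t2 - t1)    [pixel pixel^-1 day^-1]

computed per sampling interval, together with log-linear exponential fits
(area ~ A0 * exp(r t), fitted by OLS on ln(area); the fit's Pearson r and
regression-F p-value summarise goodness and significance), group mean +/- SE
curves, short-interval percentage increases, survival rates (a plant whose
area falls to the death threshold is counted dead from then on) and
population quartile summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthSeries",
    "RGRSeries",
    "ExponentialFit",
    "QuartileSummary",
    "rgr",
    "fit_exponential",
    "group_curve",
    "interval_percent_increase",
    "survival_rate",
    "survival_curve",
    "quartile_summary",
]


@dataclass
class GrowthSeries:
    """One plant's (or group's) green area indexed by time in days."""

    plant_id: str
    treatment: str
    times: np.ndarray
    areas: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")


@dataclass
class RGRSeries:
    """Per-interval relative growth rates; NaN marks intervals with a dead or
    absent plant (zero area at either end)."""

    midpoints: np.ndarray
    values: np.ndarray


@dataclass
class ExponentialFit:
    """OLS fit of ln(area) on time: area = A0 * exp(rate * t)."""

    a0: float
    rate: float
    pearson_r: float
    p_value: float
    n_points: int


@dataclass
class QuartileSummary:
    """Population distribution summary at one time-point (quartiles by linear
    interpolation between order statistics; SE is the standard error of the
    mean, sd/sqrt(n))."""

    q1: float
    median: float
    q3: float
    minimum: float
    maximum: float
    se: float
    n: int


def rgr(series: GrowthSeries) -> RGRSeries:
    """Classical relative growth rate per sampling interval.

    Intervals bounded by a non-positive area yield NaN (a dead plant has no
    growth rate) rather than an exception.
    """
    t, a = series.times, series.areas
    mid = (t[:-1] + t[1:]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (np.log(a[1:]) - np.log(a[:-1])) / np.diff(t)
    vals = np.where((a[:-1] > 0) & (a[1:] > 0), vals, np.nan)
    return RGRSeries(midpoints=mid, values=vals)


def fit_exponential(series: GrowthSeries) -> ExponentialFit:
    """Exponential fit by ordinary least squares after log-linearization.

    Only strictly positive areas enter the fit; the Pearson correlation of
    (t, ln A) and the regression F-test p-value (equivalently the slope
    t-test in simple regression) quantify the fit, as is conventional for
    growth-curve reporting.
    """
    ok = series.areas > 0
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 positive-area points, got {int(ok.sum())}")
    t = series.times[ok]
    y = np.log(series.areas[ok])
    res = stats.linregress(t, y)
    return ExponentialFit(a0=float(np.exp(res.intercept)), rate=float(res.slope),
                          pearson_r=float(res.rvalue), p_value=float(res.pvalue),
                          n_points=int(ok.sum()))


def group_curve(series_list: list[GrowthSeries]) -> pd.DataFrame:
    """Mean +/- SE of area across plants at each shared time-point.

    All series must share one time grid (plants imaged together).  Returns a
    DataFrame with columns time, mean, se, n.
    """
    if not series_list:
        raise ValueError("empty group")
    t0 = series_list[0].times
    for s in series_list[1:]:
        if len(s.times) != len(t0) or not np.allclose(s.times, t0):
            raise ValueError("group_curve requires a shared time grid")
    mat = np.stack([s.areas for s in series_list])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return pd.DataFrame({"time": t0, "mean": mean, "se": se, "n": n})


def interval_percent_increase(series: GrowthSeries, window: float,
                              rtol: float = 1e-6) -> np.ndarray:
    """Percentage area increase over every available window of given length.

    For each sample with a partner exactly ``window`` days later,
    ``100 * (A(t+w) - A(t)) / A(t)``; zero-baseline intervals give NaN.
    Used to quantify short-interval sensitivity (e.g. the 2-hour increase of
    an exponentially growing rosette: 100*(exp(r*2/24)-1) percent).
    """
    t, a = series.times, series.areas
    if window > t[-1] - t[0]:
        raise ValueError("window longer than the observed span")
    out = []
    for i in range(len(t)):
        j = np.flatnonzero(np.isclose(t - t[i], window, rtol=0, atol=rtol * max(1.0, window)))
        if j.size:
            out.append(100.0 * (a[j[0]] - a[i]) / a[i] if a[i] > 0 else np.nan)
    return np.asarray(out)


def _alive_matrix(series_list: list[GrowthSeries], death_threshold: float) -> np.ndarray:
    """alive[i, j]: plant i alive at time index j, with death absorbing."""
    mat = np.stack([s.areas for s in series_list])
    dead = np.maximum.accumulate(mat <= death_threshold, axis=1)
    return ~dead


def survival_rate(series_list: list[GrowthSeries], day: float,
                  death_threshold: float = 0.0) -> float:
    """Percentage of plants alive at ``day``.

    A plant is dead once its area drops to ``death_threshold`` or below, and
    stays dead regardless of later values (death is absorbing).
    """
    if not series_list:
        raise ValueError("empty group")
    t0 = series_list[0].times
    if not (t0[0] <= day <= t0[-1]):
        raise ValueError(f"day {day} outside observed range [{t0[0]}, {t0[-1]}]")
    j = int(np.flatnonzero(t0 <= day)[-1])
    alive = _alive_matrix(series_list, death_threshold)
    return 100.0 * float(alive[:, j].mean())


def survival_curve(series_list: list[GrowthSeries],
                   death_threshold: float = 0.0) -> pd.DataFrame:
    """Survival (%) at every time-point of the shared grid."""
    if not series_list:
        raise ValueError("empty group")
    alive = _alive_matrix(series_list, death_threshold)
    return pd.DataFrame({"time": series_list[0].times,
                         "survival": 100.0 * alive.mean(axis=0)})


def quartile_summary(areas) -> QuartileSummary:
    """Distribution summary of one day's areas (Q1/median/Q3 by linear
    interpolation, plus extremes and the SE of the mean)."""
    a = np.asarray(areas, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one observation")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    se = float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0
    return QuartileSummary(q1=float(q1), median=float(med), q3=float(q3),
                           minimum=float(a.min()), maximum=float(a.max()),
                           se=se, n=int(a.size))
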