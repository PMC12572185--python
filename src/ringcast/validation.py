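"""Comparing simulated intra-annual growth with dendrometer and NDVI data.

Dendrometer stem-size traces mix irreversible radial growth with
reversible water-related oscillations; the zero-growth approach treats
only increases above the running stem-size maximum as growth. NDVI
phenology proxies are the first/last crossings of half the annual
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import correlation_significance
from .solar import DAYS_IN_MONTH

__all__ = [
    "SeasonalComparison",
    "NDVISeason",
    "zero_growth_extract",
    "monthly_growth_totals",
    "monthly_standardize_and_compare",
    "ndvi_crossing_dates",
]


@dataclass(frozen=True)
class SeasonalComparison:
    r: float
    ci95: tuple[float, float]
    rmse: float
    peak_offset: int  # simulated peak month - observed peak month


@dataclass(frozen=True)
class NDVISeason:
    onset_doy: float | None
    cessation_doy: float | None
    degenerate: bool


def zero_growth_extract(trace: pd.Series | pd.DataFrame) -> pd.Series:
    """Cumulative irreversible growth from a stem-size trace.

    ``growth(t) = running_max(x, up to t) - x(0)``; only excursions above
    the previous running maximum count as growth, so the output is
    non-decreasing and invariant to reversible shrink-swell cycles below
    the running maximum. Accepts a Series indexed by time or the
    (day, stem_um) frame the synthetic generator writes.
    """
    if isinstance(trace, pd.DataFrame):
        trace = pd.Series(trace["stem_um"].to_numpy(), index=trace["day"].to_numpy())
    t = np.asarray(trace.index, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace timestamps must be strictly increasing")
    x = trace.to_numpy(dtype=float)
    cum = np.maximum.accumulate(x) - x[0]
    return pd.Series(cum, index=trace.index, name="growth")


def monthly_growth_totals(growth: pd.Series) -> np.ndarray:
    """Aggregate a cumulative daily growth series (index = day-of-year)
    into 12 monthly growth totals."""
    edges = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])
    days = np.asarray(growth.index, dtype=float)
    cum = growth.to_numpy(dtype=float)
    month_end = np.interp(edges[1:], days, cum)
    month_start = np.interp(edges[:-1], days, cum)
    return month_end - month_start


def monthly_standardize_and_compare(obs_monthly, sim_monthly) -> SeasonalComparison:
    """Standardize both 12-month vectors by their annual sums and compare.

    Returns Pearson r with Fisher 95% CI, RMSE of the standardized
    vectors and the signed month offset of the growth peaks
    (simulated - observed).
    """
    obs = np.asarray(obs_monthly, dtype=float)
    sim = np.asarray(sim_monthly, dtype=float)
    if obs.size != 12 or sim.size != 12:
        raise ValueError("both inputs must have 12 monthly values")
    if obs.sum() == 0.0 or sim.sum() == 0.0:
        raise ValueError("annual growth sum is zero; cannot standardize")
    obs = obs / obs.sum()
    sim = sim / sim.sum()
    sig = correlation_significance(sim, obs)
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    offset = int(np.argmax(sim)) - int(np.argmax(obs))
    return SeasonalComparison(r=sig.r, ci95=sig.ci95, rmse=rmse, peak_offset=offset)


def ndvi_crossing_dates(ndvi: pd.DataFrame | pd.Series, min_amplitude: float = 1e-9) -> NDVISeason:
    """First upward and last downward crossings of half the annual NDVI
    amplitude, as day-of-year.

    Crossings between 16-day composites are linearly interpolated; a
    sample lying exactly on the threshold counts as a crossing at that
    sample's date. A flat series (amplitude below ``min_amplitude``) or a
    series that never crosses flags no growing season.
    """
    if isinstance(ndvi, pd.DataFrame):
        ndvi = pd.Series(ndvi["ndvi"].to_numpy(), index=ndvi["day"].to_numpy())
    days = np.asarray(ndvi.index, dtype=float)
    v = ndvi.to_numpy(dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 samples per year; got {v.size}")
    amplitude = float(v.max() - v.min())
    if amplitude < min_amplitude:
        return NDVISeason(onset_doy=None, cessation_doy=None, degenerate=True)
    thr = float(v.min()) + 0.5 * amplitude

    def _interp(i):  # crossing between samples i and i+1
        return days[i] + (thr - v[i]) / (v[i + 1] - v[i]) * (days[i + 1] - days[i])

    onset = None
    for i in range(v.size - 1):
        if v[i] == thr:
            onset = float(days[i])
            break
        if v[i] < thr <= v[i + 1]:
            onset = float(days[i + 1]) if v[i + 1] == thr else float(_interp(i))
            break
    cessation = None
    for i in range(v.size - 2, -1, -1):
        if v[i + 1] == thr:
            cessation = float(days[i + 1])
            break
        if v[i] >= thr > v[i + 1]:
            cessation = float(days[i]) if v[i] == thr else float(_interp(i))
            break
    if onset is None or cessation is None:
        return NDVISeason(onset_doy=None, cessation_doy=None, degenerate=True)
    return NDVISeason(onset_doy=onset, cessation_doy=cessation, degenerate=False)
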