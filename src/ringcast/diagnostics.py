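"""Derived growth statistics: deficits, cessation, phenology, peak counts,
relative ring widths and tests against the baseline period.

The growth deficit of a month is the gap between photoperiod-potential
growth (GrE, the growth that would occur under optimal temperature and
moisture) and realized growth (GrINT), attributed to cold or drought by
the month's limiting factor; high-temperature and low-moisture limitation
are both drought stress. Deficits are standardized by the annual sum of
GrE, so realized growth plus deficits account for the full photoperiod
potential exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GrowthSimulation, LIMITING_LABELS

__all__ = [
    "DeficitRecord",
    "PhenologyRecord",
    "WelchResult",
    "growth_deficit",
    "cessation_months",
    "growing_season",
    "count_growth_peaks",
    "relative_trw",
    "welch_one_sample",
    "phenology_shift_rate",
]

_COLD_CODES = (1,)  # low_temperature
_DROUGHT_CODES = (2, 3)  # high_temperature, low_moisture


@dataclass(frozen=True)
class DeficitRecord:
    year: int
    cold_deficit: float
    drought_deficit: float
    total_deficit: float


@dataclass(frozen=True)
class PhenologyRecord:
    year: int
    start_month: int | None
    end_month: int | None
    duration: int | None
    degenerate: bool


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: int
    p_value: float
    difference: float
    ci95: tuple[float, float]


def growth_deficit(sim: GrowthSimulation, year: int) -> DeficitRecord:
    """Cold and drought growth deficits as fractions of the annual
    photoperiod-potential growth sum(GrE)."""
    iy = sim.year_index(year)
    gd = sim.grE - sim.grINT[iy]  # >= 0 since grINT <= grE
    limiting = sim.limiting[iy]
    total_potential = float(sim.grE.sum())  # > 0: daylength is never zero all year
    cold = float(gd[np.isin(limiting, _COLD_CODES)].sum()) / total_potential
    drought = float(gd[np.isin(limiting, _DROUGHT_CODES)].sum()) / total_potential
    return DeficitRecord(
        year=int(year),
        cold_deficit=cold,
        drought_deficit=drought,
        total_deficit=cold + drought,
    )


def cessation_months(sim: GrowthSimulation, year: int) -> dict[int, str]:
    """Months (1..12) with zero integral growth rate, labelled "cold" or
    "drought" by the month's limiting factor."""
    iy = sim.year_index(year)
    out = {}
    for m in range(12):
        if sim.grINT[iy, m] == 0.0:
            code = int(sim.limiting[iy, m])
            out[m + 1] = "cold" if code in _COLD_CODES else "drought"
    return out


def growing_season(sim: GrowthSimulation, year: int) -> PhenologyRecord:
    """Growing-season start/end from cumulative integral growth rates.

    Start is the first month where the cumulative GrINT reaches 2.5% of
    the annual total; end the first month reaching 97.5%. Assigned at
    month granularity (the model is monthly). A zero-growth year is
    degenerate.
    """
    iy = sim.year_index(year)
    cum = np.cumsum(sim.grINT[iy])
    total = cum[-1]
    if total <= 0.0:
        return PhenologyRecord(year=int(year), start_month=None, end_month=None,
                               duration=None, degenerate=True)
    start = int(np.argmax(cum >= 0.025 * total)) + 1
    end = int(np.argmax(cum >= 0.975 * total)) + 1
    return PhenologyRecord(
        year=int(year), start_month=start, end_month=end,
        duration=end - start + 1, degenerate=False,
    )


def count_growth_peaks(rates) -> int:
    """Strict local maxima in a 12-month rate vector.

    Interior months must strictly exceed both neighbours; January and
    December are compared against their single neighbour. Plateaus are
    not peaks.
    """
    r = np.asarray(rates, dtype=float)
    if r.size != 12:
        raise ValueError(f"expected 12 monthly rates; got {r.size}")
    count = 0
    if r[0] > r[1]:
        count += 1
    if r[-1] > r[-2]:
        count += 1
    interior = (r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])
    return count + int(interior.sum())


def relative_trw(forecast_trw: float, baseline_trws) -> tuple[float, float]:
    """Forecast ring width relative to the baseline mean.

    Returns ``(ratio, percent_change)``; a ratio of 1.48 is +48%.
    """
    baseline = np.asarray(baseline_trws, dtype=float)
    mean = float(baseline.mean())
    if mean == 0.0:
        raise ValueError("baseline mean ring width is zero (degenerate site)")
    ratio = float(forecast_trw) / mean
    return ratio, 100.0 * (ratio - 1.0)


def welch_one_sample(forecast: float, baseline) -> WelchResult:
    """One-sample two-sided t test of a forecast value against the
    baseline sample of annual values.

    ``t = (mean(baseline) - forecast) / (s / sqrt(n))`` with df = n - 1;
    the reported difference is forecast - baseline mean, with its 95% CI.
    """
    baseline = np.asarray(baseline, dtype=float)
    n = baseline.size
    if n < 2:
        raise ValueError(f"baseline needs >= 2 values; got {n}")
    s = float(baseline.std(ddof=1))
    if s == 0.0:
        raise ValueError("baseline has zero variance")
    se = s / np.sqrt(n)
    mean = float(baseline.mean())
    t_stat = (mean - float(forecast)) / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    diff = float(forecast) - mean
    half = stats.t.ppf(0.975, df) * se
    return WelchResult(
        t_stat=float(t_stat), df=df, p_value=float(p),
        difference=diff, ci95=(diff - half, diff + half),
    )


def phenology_shift_rate(months: float, years: float, days_per_month: float = 30.0) -> float:
    """Convert a growing-season shift in months over a span of years to
    days per year (30-day months by convention)."""
    if years <= 0:
        raise ValueError("years must be positive")
    return months * days_per_month / years
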