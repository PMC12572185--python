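"""Synthetic inputs for every pipeline stage.

Generates seasonal monthly climate with interannual noise, pseudo-observed
multi-tree ring-width series from known ("truth") model parameters,
scenario anomaly tables, dendrometer stem-size traces with reversible
water-related oscillations, and 16-day NDVI curves. All generators are
deterministic under a fixed seed.

Temperature seasonality peaks in July (all emulated sites are mid-latitude
Northern Hemisphere). Monthly precipitation is gamma-distributed — strictly
positive and right-skewed like real monthly totals — with the shape chosen
so the coefficient of variation equals the requested interannual fraction.
The ontogenetic trend on ring widths is A*exp(-t/tau)+c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GrowthSimulation, MonthlyClimateSeries, TreeRingSeries, VSLiteParameters
from .model import simulate
from .solar import DAYS_IN_MONTH

__all__ = [
    "SyntheticSiteSpec",
    "generate_climate",
    "generate_pseudo_observed_rings",
    "generate_anomaly_table",
    "generate_dendrometer_trace",
    "generate_ndvi_curve",
    "DEFAULT_SCENARIOS",
    "DEFAULT_PERIODS",
]

DEFAULT_SCENARIOS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5")
DEFAULT_PERIODS = ("2020-2039", "2040-2059", "2060-2079", "2080-2099")

# per-scenario warming multiplier (low- to high-emission ordering)
_SCENARIO_WEIGHTS = {0: 0.4, 1: 0.6, 2: 0.85, 3: 1.0}


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Recipe for one synthetic site's monthly climate."""

    site_id: str = "synthetic-site"
    latitude: float = 49.0
    mean_annual_temp: float = 8.0
    temp_seasonal_amplitude: float = 9.5
    annual_precip: float = 650.0
    precip_seasonality: float = 0.35
    interannual_sd_temp: float = 2.0
    interannual_sd_precip_frac: float = 0.5
    years: tuple[int, int] = (1960, 2020)
    seed: int = 0

    def __post_init__(self):
        if not 40.0 <= self.latitude <= 55.0:
            raise ValueError(f"latitude must lie in [40, 55] degN; got {self.latitude}")
        if self.annual_precip <= 0:
            raise ValueError(f"annual_precip must be positive; got {self.annual_precip}")
        if not 0.0 <= self.precip_seasonality <= 1.0:
            raise ValueError(f"precip_seasonality must lie in [0, 1]; got {self.precip_seasonality}")
        if self.interannual_sd_temp < 0 or self.interannual_sd_precip_frac < 0:
            raise ValueError("interannual_sd_temp and interannual_sd_precip_frac must be >= 0")
        if self.years[1] - self.years[0] + 1 < 2:
            raise ValueError(f"years must span >= 2 calendar years; got {self.years}")


def _seasonal_cycle(spec: SyntheticSiteSpec):
    """July-peaking 12-month temperature cycle and precip monthly means."""
    month = np.arange(12)
    phase = np.cos(2.0 * np.pi * (month - 6) / 12.0)  # 1 in July, -1 in January
    temp = spec.mean_annual_temp + spec.temp_seasonal_amplitude * phase
    precip = (spec.annual_precip / 12.0) * (1.0 + spec.precip_seasonality * phase)
    return temp, precip


def generate_climate(spec: SyntheticSiteSpec) -> MonthlyClimateSeries:
    """Seasonal monthly climate with Gaussian temperature noise and gamma
    precipitation noise; bit-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.years[1] - spec.years[0] + 1
    temp_cycle, precip_means = _seasonal_cycle(spec)
    temp = np.tile(temp_cycle, (n, 1))
    if spec.interannual_sd_temp > 0:
        temp = temp + rng.normal(0.0, spec.interannual_sd_temp, size=(n, 12))
    cv = spec.interannual_sd_precip_frac
    if cv > 0:
        shape = 1.0 / cv**2
        precip = rng.gamma(shape, precip_means / shape, size=(n, 12))
    else:
        precip = np.tile(precip_means, (n, 1))
    precip = np.maximum(precip, 0.0)
    return MonthlyClimateSeries(
        site_id=spec.site_id,
        latitude=spec.latitude,
        years=np.arange(spec.years[0], spec.years[1] + 1),
        temp=temp,
        precip=precip,
    )


def generate_pseudo_observed_rings(
    climate: MonthlyClimateSeries,
    truth: VSLiteParameters,
    n_trees: int = 12,
    noise_sd: float = 0.05,
    seed: int = 0,
    trend_amplitude: float = 2.0,
    trend_tau: float = 50.0,
    trend_offset: float = 0.5,
) -> list[TreeRingSeries]:
    """Pseudo-observed ring widths (mm) from a truth-parameterized model run.

    The annual ring-width proxy from ``simulate(climate, truth)`` is scaled
    by a negative-exponential ontogenetic trend ``A*exp(-t/tau)+c`` (mm per
    unit proxy) and per-tree, per-year lognormal noise of log-sd
    ``noise_sd``. Rings start in the second climate year (the first year's
    proxy lacks its previous-year term).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if climate.n_years < 2:
        raise ValueError("climate must span >= 2 years (ring proxy needs a previous year)")
    rng = np.random.default_rng(seed)
    sim = simulate(climate, truth)
    years = sim.years[1:]
    proxy = sim.trw_proxy[1:]
    age = np.arange(years.size, dtype=float)
    trend = trend_amplitude * np.exp(-age / trend_tau) + trend_offset
    trees = []
    for i in range(n_trees):
        noise = rng.lognormal(0.0, noise_sd, size=years.size) if noise_sd > 0 else 1.0
        width = trend * (proxy + _ZERO_WIDTH_FLOOR) * noise
        # Tucson series ids are at most 8 characters
        trees.append(TreeRingSeries(tree_id=f"{climate.site_id[:5]}{i + 1:03d}", years=years, width=width))
    return trees


# rings cannot be exactly zero-width in rwl data; a tiny floor keeps widths
# positive in years the truth model simulates no growth at all
_ZERO_WIDTH_FLOOR = 1e-3


def generate_anomaly_table(
    scenarios=DEFAULT_SCENARIOS,
    periods=DEFAULT_PERIODS,
    warming_per_period: float = 1.0,
    precip_shift: float = -2.0,
) -> pd.DataFrame:
    """Bi-decadal anomaly table: one (dT degC, dP mm) per scenario x period x month.

    Warming grows linearly with the period index and is scaled down for
    lower-emission scenarios, so temperature anomalies are monotone
    non-decreasing across periods within every scenario. Anomalies are
    additive and month-uniform.
    """
    scenarios = list(scenarios)
    periods = list(periods)
    if not scenarios or not periods:
        raise ValueError("scenarios and periods must be non-empty")
    rows = []
    for s_idx, scen in enumerate(scenarios):
        weight = _SCENARIO_WEIGHTS.get(s_idx, 1.0)
        for p_idx, period in enumerate(periods):
            dtemp = warming_per_period * (p_idx + 1) * weight
            dprec = precip_shift * (p_idx + 1) * weight
            for month in range(1, 13):
                rows.append(
                    {"scenario": scen, "period": period, "month": month,
                     "dtemp_c": dtemp, "dprecip_mm": dprec}
                )
    return pd.DataFrame(rows)


def generate_dendrometer_trace(
    sim: GrowthSimulation,
    year: int,
    osc_amplitude: float = 50.0,
    seed: int = 0,
    growth_scale: float = 1000.0,
) -> pd.DataFrame:
    """Daily stem-size trace (micrometres) for one simulated year.

    Irreversible growth accumulates at the simulation's monthly integral
    growth rates, linearly interpolated between month midpoints and scaled
    to ``growth_scale`` um per unit annual GrINT sum; a zero-mean
    reversible oscillation (stem water flux) of amplitude
    ``osc_amplitude`` um rides on top. The series starts at 0.
    Columns: day (1..365), stem_um.
    """
    iy = sim.year_index(year)
    rates = sim.grINT[iy]  # per-month growth rate
    month_edges = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])
    mid = 0.5 * (month_edges[:-1] + month_edges[1:])
    days = np.arange(1, 366, dtype=float)
    daily_rate = np.interp(days - 0.5, mid, rates / DAYS_IN_MONTH)
    growth = np.cumsum(daily_rate) * growth_scale
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    period = rng.uniform(4.0, 9.0)  # days, synoptic-scale water cycling
    osc = osc_amplitude * np.sin(2.0 * np.pi * days / period + phase)
    stem = growth + osc
    stem -= stem[0]
    return pd.DataFrame({"day": days.astype(int), "stem_um": stem})


def generate_ndvi_curve(
    start_month: int,
    end_month: int,
    base: float = 0.35,
    amplitude: float = 0.4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """16-day NDVI series for one year (23 samples, MODIS cadence).

    Double-sigmoid seasonal curve: green-up centred mid ``start_month``,
    senescence centred mid ``end_month``; values clipped to [-1, 1].
    Columns: day (day-of-year of each composite), ndvi.
    """
    if start_month >= end_month:
        raise ValueError(f"start_month ({start_month}) must precede end_month ({end_month})")
    month_edges = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])
    mid = 0.5 * (month_edges[:-1] + month_edges[1:])
    c_up, c_down = mid[start_month - 1], mid[end_month - 1]
    doy = 8.0 + 16.0 * np.arange(23)
    tau = 10.0  # days, green-up steepness
    curve = base + amplitude / (1.0 + np.exp(-(doy - c_up) / tau)) / (1.0 + np.exp((doy - c_down) / tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve = curve + rng.normal(0.0, noise_sd, size=doy.size)
    return pd.DataFrame({"day": doy.astype(int), "ndvi": np.clip(curve, -1.0, 1.0)})
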