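"""Forecast climatologies and burn-in growth forecasts.

For each SSP scenario and bi-decadal period, three 12-month climatologies
are built from the normal period 1995-2014: the mean, a cool-wet extreme
(0.15 temperature / 0.75 precipitation quantiles) and a warm-dry extreme
(0.85 / 0.25), each plus the scenario x period monthly anomalies.
Forecasts replicate one climatology for a burn-in of consecutive
identical years and keep only the last, so the bucket state and the
previous-year ring carry-over are equilibrated. Nothing in this module is
stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import GrowthSimulation, MonthlyClimateSeries, VSLiteParameters, BucketConstants
from .model import simulate

__all__ = [
    "Climatology",
    "NormalPeriodStats",
    "normal_period_stats",
    "build_mean_climatology",
    "build_extreme_climatology",
    "build_all_climatologies",
    "burn_in_forecast",
    "CLIMATOLOGY_KINDS",
]

CLIMATOLOGY_KINDS = ("mean", "cool_wet", "warm_dry")

#: quantile levels (temperature, precipitation) defining the extremes
EXTREME_QUANTILES = {"cool_wet": (0.15, 0.75), "warm_dry": (0.85, 0.25)}


@dataclass(frozen=True)
class Climatology:
    """A 12-month temperature/precipitation vector tagged with scenario,
    bi-decadal period and kind (mean | cool_wet | warm_dry)."""

    site_id: str
    scenario: str
    period: str
    kind: str
    temp: np.ndarray
    precip: np.ndarray
    latitude: float

    def __post_init__(self):
        if np.any(np.asarray(self.precip) < 0):
            raise ValueError("climatology precipitation must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "scenario": self.scenario,
                "period": self.period,
                "kind": self.kind,
                "month": np.arange(1, 13),
                "temp_c": self.temp,
                "precip_mm": self.precip,
            }
        )


@dataclass(frozen=True)
class NormalPeriodStats:
    """Per-calendar-month normal-period climate: means and the raw window
    samples (n_window_years x 12) for empirical quantiles."""

    site_id: str
    latitude: float
    window: tuple[int, int]
    temp_samples: np.ndarray
    precip_samples: np.ndarray

    @property
    def temp_mean(self) -> np.ndarray:
        return self.temp_samples.mean(axis=0)

    @property
    def precip_mean(self) -> np.ndarray:
        return self.precip_samples.mean(axis=0)

    def temp_quantile(self, q: float) -> np.ndarray:
        """Per-month empirical temperature quantile (linear interpolation,
        the type-7 rule)."""
        return np.quantile(self.temp_samples, q, axis=0)

    def precip_quantile(self, q: float) -> np.ndarray:
        return np.quantile(self.precip_samples, q, axis=0)


def normal_period_stats(
    series: MonthlyClimateSeries, window: tuple[int, int] = (1995, 2014)
) -> NormalPeriodStats:
    """Extract the normal-period window; errors if not fully covered."""
    sub = series.subset(window[0], window[1])
    return NormalPeriodStats(
        site_id=series.site_id,
        latitude=series.latitude,
        window=window,
        temp_samples=sub.temp.copy(),
        precip_samples=sub.precip.copy(),
    )


def _anomaly_vectors(anomalies: pd.DataFrame, scenario: str, period: str):
    rows = anomalies[(anomalies["scenario"] == scenario) & (anomalies["period"] == period)]
    rows = rows.sort_values("month")
    if len(rows) != 12 or set(rows["month"]) != set(range(1, 13)):
        missing = sorted(set(range(1, 13)) - set(rows["month"]))
        raise ValueError(
            f"missing anomaly cell for (scenario={scenario}, period={period}, months={missing})"
        )
    return rows["dtemp_c"].to_numpy(dtype=float), rows["dprecip_mm"].to_numpy(dtype=float)


def _assemble(stats, base_temp, base_precip, anomalies, scenario, period, kind) -> Climatology:
    dt, dp = _anomaly_vectors(anomalies, scenario, period)
    precip = base_precip + dp
    if np.any(precip < 0):
        warnings.warn(
            f"negative forecast precipitation floored at 0 for (scenario={scenario}, "
            f"period={period}, kind={kind})",
            stacklevel=3,
        )
        precip = np.maximum(precip, 0.0)
    return Climatology(
        site_id=stats.site_id,
        scenario=scenario,
        period=period,
        kind=kind,
        temp=base_temp + dt,
        precip=precip,
        latitude=stats.latitude,
    )


def build_mean_climatology(
    stats: NormalPeriodStats, anomalies: pd.DataFrame, scenario: str, period: str
) -> Climatology:
    """Normal-period monthly means plus the scenario x period anomalies."""
    return _assemble(stats, stats.temp_mean, stats.precip_mean, anomalies, scenario, period, "mean")


def build_extreme_climatology(
    stats: NormalPeriodStats, anomalies: pd.DataFrame, scenario: str, period: str, kind: str
) -> Climatology:
    """Extreme-year climatology: historical quantile base plus anomalies."""
    if kind not in EXTREME_QUANTILES:
        raise ValueError(f"kind must be one of {sorted(EXTREME_QUANTILES)}; got {kind!r}")
    q_t, q_p = EXTREME_QUANTILES[kind]
    return _assemble(
        stats, stats.temp_quantile(q_t), stats.precip_quantile(q_p), anomalies, scenario, period, kind
    )


def build_all_climatologies(
    stats: NormalPeriodStats, anomalies: pd.DataFrame, scenarios=None, periods=None
) -> list[Climatology]:
    """The full grid: every scenario x period x (mean, cool_wet, warm_dry)."""
    scenarios = list(scenarios) if scenarios is not None else sorted(anomalies["scenario"].unique())
    periods = list(periods) if periods is not None else sorted(anomalies["period"].unique())
    out = []
    for scen in scenarios:
        for period in periods:
            out.append(build_mean_climatology(stats, anomalies, scen, period))
            for kind in ("cool_wet", "warm_dry"):
                out.append(build_extreme_climatology(stats, anomalies, scen, period, kind))
    return out


def burn_in_forecast(
    climatology: Climatology,
    p: VSLiteParameters,
    n_burn: int = 10,
    bucket_constants: BucketConstants | None = None,
) -> GrowthSimulation:
    """Run ``n_burn`` consecutive identical years and keep the last.

    Returns a single-year GrowthSimulation whose bucket state and
    previous-year ring carry-over are equilibrated under the constant
    forcing.
    """
    if n_burn < 2:
        raise ValueError("n_burn must be >= 2 (the proxy needs a previous year)")
    climate = MonthlyClimateSeries(
        site_id=climatology.site_id,
        latitude=climatology.latitude,
        years=np.arange(1, n_burn + 1),
        temp=np.tile(climatology.temp, (n_burn, 1)),
        precip=np.tile(climatology.precip, (n_burn, 1)),
    )
    sim = simulate(climate, p, bucket_constants=bucket_constants)
    last = slice(n_burn - 1, n_burn)
    moisture = sim.moisture
    return GrowthSimulation(
        site_id=sim.site_id,
        years=sim.years[last],
        grT=sim.grT[last],
        grM=sim.grM[last],
        grE=sim.grE,
        grINT=sim.grINT[last],
        limiting=sim.limiting[last],
        trw_proxy=sim.trw_proxy[last],
        moisture=replace(
            moisture,
            moisture=moisture.moisture[last],
            evapo=moisture.evapo[last],
            runoff=moisture.runoff[last],
            drainage=moisture.drainage[last],
            overflow=moisture.overflow[last],
            end_state=moisture.end_state[last],
        ),
        params=p,
        first_year_partial=False,
    )
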