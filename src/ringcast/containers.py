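"""Core data containers shared across the pipeline.

Monthly climate forcing, model parameters, soil-moisture state and
simulation output are plain dataclasses wrapping numpy arrays with a
(year, month) layout: arrays are shaped ``(n_years, 12)`` with month
index 0 = January internally; all I/O uses 1-based months (Jan = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimateSeries",
    "BucketConstants",
    "SoilMoistureSeries",
    "VSLiteParameters",
    "GrowthSimulation",
    "TreeRingSeries",
    "SiteChronology",
    "LIMITING_LABELS",
]

#: integer codes used in :attr:`GrowthSimulation.limiting`
LIMITING_LABELS = {0: "none", 1: "low_temperature", 2: "high_temperature", 3: "low_moisture"}


@dataclass(frozen=True)
class MonthlyClimateSeries:
    """Monthly mean temperature (degC) and precipitation totals (mm) for one site.

    ``temp`` and ``precip`` are ``(n_years, 12)`` arrays over the contiguous
    calendar years in ``years``.
    """

    site_id: str
    latitude: float
    years: np.ndarray
    temp: np.ndarray
    precip: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        temp = np.asarray(self.temp, dtype=float)
        precip = np.asarray(self.precip, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "temp", temp)
        object.__setattr__(self, "precip", precip)
        n = years.size
        if temp.shape != (n, 12) or precip.shape != (n, 12):
            raise ValueError(
                f"temp/precip must be (n_years, 12); got {temp.shape} and "
                f"{precip.shape} for {n} years"
            )
        if n > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be contiguous calendar years")
        if np.any(precip < 0):
            raise ValueError("precip must be non-negative")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def subset(self, first: int, last: int) -> "MonthlyClimateSeries":
        """Return the sub-series covering calendar years ``first..last`` inclusive."""
        mask = (self.years >= first) & (self.years <= last)
        if not mask.any() or mask.sum() != last - first + 1:
            raise ValueError(f"years {first}-{last} not fully covered by series")
        return replace(self, years=self.years[mask], temp=self.temp[mask], precip=self.precip[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns site_id, year, month, temp_c, precip_mm."""
        n = self.n_years
        return pd.DataFrame(
            {
                "site_id": np.repeat(self.site_id, n * 12),
                "year": np.repeat(self.years, 12),
                "month": np.tile(np.arange(1, 13), n),
                "temp_c": self.temp.ravel(),
                "precip_mm": self.precip.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, latitude: float, site_id: str | None = None) -> "MonthlyClimateSeries":
        """Build from a long-format frame (columns year, month, temp_c, precip_mm)."""
        if site_id is not None:
            frame = frame[frame["site_id"] == site_id]
        elif "site_id" in frame.columns:
            ids = frame["site_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"frame holds {len(ids)} sites; pass site_id")
            site_id = str(ids[0])
        else:
            site_id = "site"
        frame = frame.sort_values(["year", "month"])
        years = np.unique(frame["year"].to_numpy())
        n = years.size
        if len(frame) != n * 12:
            raise ValueError("every year must have exactly 12 months")
        temp = frame["temp_c"].to_numpy(dtype=float).reshape(n, 12)
        precip = frame["precip_mm"].to_numpy(dtype=float).reshape(n, 12)
        return cls(site_id=site_id, latitude=latitude, years=years, temp=temp, precip=precip)


@dataclass(frozen=True)
class BucketConstants:
    """Leaky-bucket water-balance constants (CPC-style defaults of the
    original VS-Lite distribution).

    ``mmax``/``mmin`` bound relative volumetric soil moisture (v/v);
    ``alpha``, ``mu_th`` and ``m_th`` shape drainage and runoff;
    ``rootd`` (mm) converts mm of water to v/v over the rooting depth;
    ``m0`` is the initial moisture; the month is integrated in
    ``n_substeps`` equal sub-steps.
    """

    mmax: float = 0.76
    mmin: float = 0.01
    alpha: float = 0.093
    m_th: float = 4.886
    mu_th: float = 5.8
    rootd: float = 1000.0
    m0: float = 0.2
    n_substeps: int = 4

    def __post_init__(self):
        if self.mmax <= self.mmin:
            raise ValueError(f"mmax ({self.mmax}) must exceed mmin ({self.mmin})")
        if self.rootd <= 0 or self.n_substeps < 1:
            raise ValueError("rootd must be positive and n_substeps >= 1")


@dataclass(frozen=True)
class SoilMoistureSeries:
    """Monthly relative volumetric soil moisture plus water-balance diagnostics.

    All arrays are ``(n_years, 12)``. ``moisture`` is the within-month mean
    state; ``evapo``, ``runoff``, ``drainage`` are monthly losses in mm;
    ``overflow`` is the mm-equivalent removed (or added) by clipping the
    state into ``[mmin, mmax]``, so the balance
    ``dM*rootd + E + R + D - P + overflow = 0`` closes exactly.
    """

    moisture: np.ndarray
    constants: BucketConstants
    evapo: np.ndarray
    runoff: np.ndarray
    drainage: np.ndarray
    overflow: np.ndarray
    end_state: np.ndarray  # end-of-month state, (n_years, 12)


@dataclass(frozen=True)
class VSLiteParameters:
    """The eight site-calibrated parameters of the modified growth model.

    Temperature response is a trapezoid: no growth below ``t1`` or above
    ``t4`` (heat decline), optimal on ``[t2, t3]``. Moisture response is a
    ramp from ``m1`` to ``m2``. ``w`` weights the previous year's growth in
    the ring-width proxy; ``mcap`` is the calibrated bucket capacity (v/v).
    """

    t1: float = 4.0
    t2: float = 12.0
    t3: float = 22.0
    t4: float = 32.0
    m1: float = 0.02
    m2: float = 0.25
    w: float = 0.3
    mcap: float = 0.76

    def __post_init__(self):
        if not (self.t1 < self.t2 <= self.t3 < self.t4):
            raise ValueError(
                f"temperature thresholds must satisfy t1 < t2 <= t3 < t4; got "
                f"({self.t1}, {self.t2}, {self.t3}, {self.t4})"
            )
        if not self.m1 < self.m2:
            raise ValueError(f"moisture thresholds must satisfy m1 < m2; got ({self.m1}, {self.m2})")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"previous-year weight w must lie in [0, 1]; got {self.w}")
        if self.mcap <= 0:
            raise ValueError(f"bucket capacity mcap must be positive; got {self.mcap}")

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3, self.t4, self.m1, self.m2, self.w, self.mcap])

    @classmethod
    def from_array(cls, a) -> "VSLiteParameters":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class GrowthSimulation:
    """Output of one model run: monthly partial/integral growth rates,
    limiting-factor codes, soil moisture, and the annual ring-width proxy.

    ``grT``, ``grM``, ``grINT`` are ``(n_years, 12)``; ``grE`` is the
    12-month photoperiod response (latitude-only, year-invariant);
    ``limiting`` holds integer codes per :data:`LIMITING_LABELS`;
    ``trw_proxy`` is annual. The first year's proxy lacks a previous year
    (``first_year_partial``) and is the plain current-year sum.
    """

    site_id: str
    years: np.ndarray
    grT: np.ndarray
    grM: np.ndarray
    grE: np.ndarray
    grINT: np.ndarray
    limiting: np.ndarray
    trw_proxy: np.ndarray
    moisture: SoilMoistureSeries
    params: VSLiteParameters
    first_year_partial: bool = True

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in simulation ({self.years[0]}-{self.years[-1]})")
        return int(idx[0])

    def monthly_frame(self) -> pd.DataFrame:
        n = self.n_years
        return pd.DataFrame(
            {
                "site_id": np.repeat(self.site_id, n * 12),
                "year": np.repeat(self.years, 12),
                "month": np.tile(np.arange(1, 13), n),
                "grT": self.grT.ravel(),
                "grM": self.grM.ravel(),
                "grE": np.tile(self.grE, n),
                "grINT": self.grINT.ravel(),
                "m_rel": self.moisture.moisture.ravel(),
                "limiting": [LIMITING_LABELS[c] for c in self.limiting.ravel()],
            }
        )

    def annual_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_id, "year": self.years, "trw_proxy": self.trw_proxy}
        )


@dataclass(frozen=True)
class TreeRingSeries:
    """Ring widths (mm) of one tree; missing rings are NaN."""

    tree_id: str
    years: np.ndarray
    width: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        width = np.asarray(self.width, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "width", width)
        if years.shape != width.shape:
            raise ValueError("years and width must align")
        present = np.isfinite(width)
        if np.any(width[present] <= 0):
            raise ValueError(f"tree {self.tree_id}: ring widths must be positive where present")

    def to_series(self) -> pd.Series:
        return pd.Series(self.width, index=self.years, name=self.tree_id)


@dataclass(frozen=True)
class SiteChronology:
    """Detrended, biweight-averaged site index chronology (dimensionless, mean ~ 1)."""

    site_id: str
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "year": self.years,
                "index": self.index,
                "depth": self.sample_depth,
            }
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name=self.site_id)
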