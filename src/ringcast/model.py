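"""The modified VS-Lite growth model.

Monthly partial growth rates for temperature (trapezoid with a
heat-decline limb), soil moisture (ramp) and photoperiod (normalized
daylength) combine by Liebig's minimum rule into an integral growth rate
GrINT = min(GrT, GrM) * GrE, with a per-month limiting-factor label. The
annual tree-ring-width proxy sums GrINT over the year with a weighted
contribution from the previous year:

    TRW_y = (sum_m GrINT_{y,m} + w * sum_m GrINT_{y-1,m}) / (1 + w)

The (1+w) normalization keeps the proxy on a common [0, 12] scale across
values of w; it is correlation-invariant and therefore does not affect
calibration.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    BucketConstants,
    GrowthSimulation,
    MonthlyClimateSeries,
    VSLiteParameters,
)
from .hydro import leaky_bucket, thornthwaite_pet
from .solar import monthly_daylength

__all__ = [
    "partial_growth_temperature",
    "partial_growth_moisture",
    "partial_growth_photoperiod",
    "integral_growth_rate",
    "limiting_factor",
    "tree_ring_width_proxy",
    "annual_trw_proxy",
    "simulate",
]

# limiting-factor codes (see containers.LIMITING_LABELS)
_NONE, _LOW_T, _HIGH_T, _LOW_M = 0, 1, 2, 3


def partial_growth_temperature(temp, p: VSLiteParameters, t_params=None):
    """Trapezoidal temperature response GrT in [0, 1].

    Zero at/below ``t1`` and at/above ``t4``, linear ramps to the optimum
    plateau ``[t2, t3]``; continuous everywhere. ``t_params`` may supply a
    broadcastable ``(t1, t2, t3, t4)`` tuple of arrays for batched
    evaluation (calibration hot path); ``p`` is then ignored.
    """
    t1, t2, t3, t4 = t_params if t_params is not None else (p.t1, p.t2, p.t3, p.t4)
    temp = np.asarray(temp, dtype=float)
    rising = (temp - t1) / (t2 - t1)
    falling = (t4 - temp) / (t4 - t3)
    return np.clip(np.minimum(rising, falling), 0.0, 1.0)


def partial_growth_moisture(moisture, p: VSLiteParameters, m_params=None):
    """Moisture ramp GrM in [0, 1]: zero at/below ``m1``, one at/above ``m2``."""
    m1, m2 = m_params if m_params is not None else (p.m1, p.m2)
    moisture = np.asarray(moisture, dtype=float)
    return np.clip((moisture - m1) / (m2 - m1), 0.0, 1.0)


def partial_growth_photoperiod(latitude: float) -> np.ndarray:
    """Photoperiod response GrE: mean monthly daylength normalized by the
    site's longest-month daylength; equals 1 in the longest-day month."""
    daylength = monthly_daylength(latitude)
    peak = daylength.max()
    if peak <= 0.0:  # permanent polar night: no photoperiod signal
        return np.ones(12)
    return daylength / peak


def limiting_factor(grT, grM, temp, p: VSLiteParameters, t_params=None):
    """Per-month limiting-factor code.

    ``none`` where both partial rates are 1; ``low_moisture`` where
    moisture is the (strictly or tied) lower rate below 1;
    ``low_temperature``/``high_temperature`` where temperature is
    strictly lower, split by which side of the optimum plateau the
    month's temperature lies on. Exact ties below 1 go to moisture
    (deterministic; ties have measure zero on real forcing).
    """
    t1, t2, t3, t4 = t_params if t_params is not None else (p.t1, p.t2, p.t3, p.t4)
    grT, grM, temp = np.broadcast_arrays(grT, grM, np.asarray(temp, dtype=float))
    code = np.full(grT.shape, _NONE, dtype=np.int8)
    both_optimal = (grT >= 1.0) & (grM >= 1.0)
    moisture_limited = ~both_optimal & (grM <= grT)
    temp_limited = ~both_optimal & (grT < grM)
    code[moisture_limited] = _LOW_M
    mid_plateau = 0.5 * (np.asarray(t2) + np.asarray(t3)) * np.ones_like(temp)
    code[temp_limited & (temp <= mid_plateau)] = _LOW_T
    code[temp_limited & (temp > mid_plateau)] = _HIGH_T
    return code


def integral_growth_rate(grT, grM, grE):
    """GrINT = min(GrT, GrM) * GrE (Liebig's minimum rule times photoperiod)."""
    return np.minimum(grT, grM) * grE


def tree_ring_width_proxy(grint_current, grint_previous, w: float):
    """Annual ring-width proxy from two consecutive years of monthly GrINT.

    Returns ``(sum(current) + w * sum(previous)) / (1 + w)``. With no
    previous year (``grint_previous is None``) the plain current-year sum
    is returned (callers flag such years).
    """
    cur = float(np.sum(grint_current))
    if grint_previous is None:
        return cur
    return (cur + w * float(np.sum(grint_previous))) / (1.0 + w)


def annual_trw_proxy(grint: np.ndarray, w) -> np.ndarray:
    """Vectorized proxy over a ``(..., n_years, 12)`` GrINT array.

    The first year gets the plain annual sum (no previous year).
    ``w`` may be scalar or broadcastable over leading axes.
    """
    sums = grint.sum(axis=-1)
    w = np.asarray(w, dtype=float)[..., np.newaxis] if np.ndim(w) else w
    trw = np.empty_like(sums)
    trw[..., 0] = sums[..., 0]
    trw[..., 1:] = (sums[..., 1:] + w * sums[..., :-1]) / (1.0 + w)
    return trw


def simulate(
    climate: MonthlyClimateSeries,
    p: VSLiteParameters,
    bucket_constants: BucketConstants | None = None,
    per_year_heat_index: bool = True,
) -> GrowthSimulation:
    """Run the full model chain on monthly climate.

    PET (Thornthwaite) -> leaky bucket with capacity ``p.mcap`` ->
    response functions -> GrINT and limiting factors -> annual ring-width
    proxy. Requires at least two years of climate; the first simulated
    year's proxy has no previous-year term and is flagged.
    """
    if climate.n_years < 2:
        raise ValueError("simulation needs >= 2 years of climate (previous-year proxy term)")
    constants = bucket_constants or BucketConstants()
    if p.mcap <= constants.mmin:
        raise ValueError(f"mcap ({p.mcap}) must exceed bucket mmin ({constants.mmin})")
    constants = BucketConstants(
        mmax=p.mcap,
        mmin=constants.mmin,
        alpha=constants.alpha,
        m_th=constants.m_th,
        mu_th=constants.mu_th,
        rootd=constants.rootd,
        m0=constants.m0,
        n_substeps=constants.n_substeps,
    )
    pet = thornthwaite_pet(climate, per_year_heat_index=per_year_heat_index)
    moisture = leaky_bucket(climate.precip, pet, constants)
    grT = partial_growth_temperature(climate.temp, p)
    grM = partial_growth_moisture(moisture.moisture, p)
    grE = partial_growth_photoperiod(climate.latitude)
    grINT = integral_growth_rate(grT, grM, grE)
    limiting = limiting_factor(grT, grM, climate.temp, p)
    trw = annual_trw_proxy(grINT, p.w)
    return GrowthSimulation(
        site_id=climate.site_id,
        years=climate.years,
        grT=grT,
        grM=grM,
        grE=grE,
        grINT=grINT,
        limiting=limiting,
        trw_proxy=trw,
        moisture=moisture,
        params=p,
    )
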