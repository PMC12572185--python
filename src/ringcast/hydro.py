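"""Climate forcing: Thornthwaite PET, leaky-bucket soil moisture, and the
annual climatic water balance.

The potential-evapotranspiration model is Thornthwaite's monthly formula
with daylength correction; the heat-load index can be computed per
calendar year (the default used throughout this package) or from the
series-mean monthly temperatures. Soil moisture is a single leaky bucket
losing moisture-scaled evapotranspiration, saturation-dependent fast
runoff and slow drainage, integrated in sub-monthly steps.
"""

from __future__ import annotations

import numpy as np

from .containers import BucketConstants, MonthlyClimateSeries, SoilMoistureSeries
from .solar import DAYS_IN_MONTH, monthly_daylength

__all__ = [
    "thornthwaite_pet",
    "leaky_bucket",
    "bucket_moisture",
    "climatic_water_balance",
    "classify_cwb",
    "CWB_CLASS_BINS",
]

#: climatic-water-balance site classes, mm/yr upper edges
CWB_CLASS_BINS = {"dry": 200.0, "moderate": 700.0, "humid": float("inf")}


def thornthwaite_pet(series: MonthlyClimateSeries, per_year_heat_index: bool = True) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), shape ``(n_years, 12)``.

    PET_m = 16 * (L_m/12) * (N_m/30) * (10*max(T_m,0)/I)^a with the heat
    index I = sum((max(T,0)/5)^1.514) over the 12 months — per calendar
    year when ``per_year_heat_index`` is set, else from series-mean
    monthly temperatures — and the cubic exponent a(I). Months with
    T <= 0 degC have PET = 0; an all-subzero year (I = 0) yields zero PET
    without division.
    """
    t = np.maximum(series.temp, 0.0)
    if per_year_heat_index:
        heat_index = np.sum((t / 5.0) ** 1.514, axis=1, keepdims=True)  # (n_years, 1)
    else:
        t_clim = np.maximum(series.temp.mean(axis=0), 0.0)
        heat_index = np.full((series.n_years, 1), np.sum((t_clim / 5.0) ** 1.514))
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    daylength = monthly_daylength(series.latitude)
    corr = (daylength / 12.0) * (DAYS_IN_MONTH / 30.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * corr * (10.0 * t / heat_index) ** a
    pet = np.where((t <= 0.0) | (heat_index <= 0.0), 0.0, pet)
    return pet


def bucket_moisture(
    precip: np.ndarray,
    pet: np.ndarray,
    constants: BucketConstants,
    mmax=None,
):
    """Run the leaky bucket over a flat month sequence; supports batches.

    ``precip`` and ``pet`` are ``(n_months,)``. ``mmax`` overrides the
    capacity and may be a scalar or a ``(k,)`` batch of capacities, in
    which case all outputs gain a leading batch axis. Returns a dict of
    arrays: within-month mean state ``m``, end-of-month state ``m_end``
    and monthly totals ``evapo``, ``runoff``, ``drainage``, ``overflow``
    (mm; overflow is the clip correction, signed).
    """
    c = constants
    mmax = c.mmax if mmax is None else np.asarray(mmax, dtype=float)
    batch = np.ndim(mmax) == 1
    k = mmax.shape[0] if batch else 1
    n_months = precip.shape[-1]
    shape = (k, n_months) if batch else (n_months,)

    m = np.minimum(c.m0, mmax) * np.ones((k,) if batch else ())
    out = {name: np.zeros(shape) for name in ("m", "m_end", "evapo", "runoff", "drainage", "overflow")}
    dt = 1.0 / c.n_substeps
    slow = c.alpha * c.mu_th / (1.0 + c.mu_th)  # slow drainage coefficient
    fast = c.alpha / (1.0 + c.mu_th)  # linear part of fast runoff

    for t in range(n_months):
        p_s = precip[t] * dt
        ep_s = pet[t] * dt
        m_accum = 0.0
        for _ in range(c.n_substeps):
            evapo = ep_s * m / mmax
            runoff = p_s * (m / mmax) ** c.m_th + fast * m * c.rootd * dt
            drain = slow * m * c.rootd * dt
            m_raw = m + (p_s - evapo - runoff - drain) / c.rootd
            m_new = np.clip(m_raw, c.mmin, mmax)
            over = (m_raw - m_new) * c.rootd
            out["evapo"][..., t] += evapo
            out["runoff"][..., t] += runoff
            out["drainage"][..., t] += drain
            out["overflow"][..., t] += over
            m = m_new
            m_accum = m_accum + m
        out["m"][..., t] = m_accum / c.n_substeps
        out["m_end"][..., t] = m
    return out


def leaky_bucket(
    precip: np.ndarray,
    pet: np.ndarray,
    constants: BucketConstants | None = None,
) -> SoilMoistureSeries:
    """Leaky-bucket soil moisture for ``(n_years, 12)`` precip/PET arrays.

    Months are chained across years. Every monthly loss term and the clip
    overflow are reported so water conservation is checkable:
    ``dM*rootd + E + R + D - P + overflow == 0`` to float precision.
    """
    constants = constants or BucketConstants()
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if precip.shape != pet.shape:
        raise ValueError(f"precip {precip.shape} and pet {pet.shape} must have equal shape")
    shape = precip.shape
    res = bucket_moisture(precip.ravel(), pet.ravel(), constants)
    return SoilMoistureSeries(
        moisture=res["m"].reshape(shape),
        constants=constants,
        evapo=res["evapo"].reshape(shape),
        runoff=res["runoff"].reshape(shape),
        drainage=res["drainage"].reshape(shape),
        overflow=res["overflow"].reshape(shape),
        end_state=res["m_end"].reshape(shape),
    )


def climatic_water_balance(series: MonthlyClimateSeries, per_year_heat_index: bool = True):
    """Annual climatic water balance (mm) and its period mean.

    CWB_y = annual precipitation - annual PET. Returns ``(cwb, mean)``
    with ``cwb`` per year.
    """
    pet = thornthwaite_pet(series, per_year_heat_index=per_year_heat_index)
    cwb = series.precip.sum(axis=1) - pet.sum(axis=1)
    return cwb, float(cwb.mean())


def classify_cwb(mean_cwb: float) -> str:
    """Site humidity class from period-mean CWB: dry (<=200 mm), moderate
    (200-700 mm], humid (>700 mm)."""
    for label, upper in CWB_CLASS_BINS.items():
        if mean_cwb <= upper:
            return label
    return "humid"
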