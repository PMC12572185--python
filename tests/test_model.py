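"""Growth-response functions, the minimum rule, the ring-width proxy and
the full simulation chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringcast.containers import BucketConstants, VSLiteParameters
from ringcast.hydro import leaky_bucket, thornthwaite_pet
from ringcast.model import (
    annual_trw_proxy,
    integral_growth_rate,
    limiting_factor,
    partial_growth_moisture,
    partial_growth_photoperiod,
    partial_growth_temperature,
    simulate,
    tree_ring_width_proxy,
)

from conftest import constant_climate


@pytest.fixture(scope="module")
def p():
    return VSLiteParameters(t1=4.0, t2=12.0, t3=22.0, t4=32.0, m1=0.02, m2=0.25, w=0.3, mcap=0.76)


class TestTemperatureResponse:
    def test_vertices_and_midpoints(self, p):
        assert partial_growth_temperature(p.t1, p) == 0.0
        assert partial_growth_temperature((p.t1 + p.t2) / 2, p) == pytest.approx(0.5)
        assert partial_growth_temperature(p.t2, p) == 1.0
        assert partial_growth_temperature(p.t3, p) == 1.0
        assert partial_growth_temperature((p.t3 + p.t4) / 2, p) == pytest.approx(0.5)
        assert partial_growth_temperature(p.t4, p) == 0.0
        assert partial_growth_temperature(-40.0, p) == 0.0
        assert partial_growth_temperature(60.0, p) == 0.0

    def test_continuity_on_dense_grid(self, p):
        """Max jump between adjacent grid points shrinks with the grid step."""
        for step, bound in [(1e-3, 2e-4), (1e-5, 2e-6)]:
            grid = np.arange(-5.0, 40.0, step)
            vals = partial_growth_temperature(grid, p)
            assert np.max(np.abs(np.diff(vals))) < bound

    def test_degenerate_plateau_allowed(self):
        q = VSLiteParameters(t2=15.0, t3=15.0)
        assert partial_growth_temperature(15.0, q) == 1.0

    def test_ordering_violations_rejected(self):
        with pytest.raises(ValueError, match="t1 < t2"):
            VSLiteParameters(t1=13.0, t2=12.0)
        with pytest.raises(ValueError, match="m1 < m2"):
            VSLiteParameters(m1=0.3, m2=0.2)
        with pytest.raises(ValueError, match="w"):
            VSLiteParameters(w=1.5)


class TestMoistureResponse:
    def test_endpoints(self, p):
        assert partial_growth_moisture(p.m1, p) == 0.0
        assert partial_growth_moisture(p.m2, p) == 1.0
        assert partial_growth_moisture(0.0, p) == 0.0
        assert partial_growth_moisture(0.7, p) == 1.0

    def test_monotone_on_grid(self, p):
        grid = np.linspace(0.0, 0.8, 500)
        vals = partial_growth_moisture(grid, p)
        assert np.all(np.diff(vals) >= 0.0)


class TestPhotoperiodResponse:
    def test_equator_flat(self):
        assert np.allclose(partial_growth_photoperiod(0.0), 1.0)

    def test_midlatitude_peaks_in_june(self):
        grE = partial_growth_photoperiod(50.0)
        assert grE[5] == 1.0  # June holds the solstice
        assert grE[11] < grE[5]
        assert np.all(grE > 0.0) and np.all(grE <= 1.0)


class TestIntegralGrowthRate:
    def test_minimum_rule_arithmetic(self, p):
        assert integral_growth_rate(0.4, 0.9, 0.5) == pytest.approx(0.2)
        assert integral_growth_rate(1.0, 1.0, 0.8) == pytest.approx(0.8)

    @given(
        grT=st.floats(0, 1), grM=st.floats(0, 1), grE=st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_liebig_consistency(self, grT, grM, grE):
        grint = integral_growth_rate(grT, grM, grE)
        assert grint <= min(grT, grM) + 1e-15
        assert grint <= grE + 1e-15
        assert grint >= 0.0

    def test_limiting_labels(self, p):
        # rising limb, temperature strictly lower -> low_temperature
        t = 8.0
        grT = partial_growth_temperature(t, p)
        assert limiting_factor(grT, 0.9, t, p) == 1
        # falling limb -> high_temperature
        t = 29.0
        grT = partial_growth_temperature(t, p)
        assert limiting_factor(grT, 0.9, t, p) == 2
        # moisture strictly lower -> low_moisture
        assert limiting_factor(1.0, 0.5, 17.0, p) == 3
        # both optimal -> none
        assert limiting_factor(1.0, 1.0, 17.0, p) == 0
        # exact tie below 1 -> moisture wins
        assert limiting_factor(0.5, 0.5, 8.0, p) == 3


class TestRingWidthProxy:
    def test_no_memory_limit(self):
        cur = np.full(12, 0.5)
        assert tree_ring_width_proxy(cur, None, 0.3) == pytest.approx(6.0)
        prev = np.full(12, 0.25)
        assert tree_ring_width_proxy(cur, prev, 0.0) == pytest.approx(6.0)

    def test_identical_years_symmetric_under_w(self):
        year = np.full(12, 0.4)
        for w in (0.0, 0.5, 1.0):
            assert tree_ring_width_proxy(year, year, w) == pytest.approx(4.8)

    def test_autocorrelation_increases_with_w(self):
        """On white-noise annual sums the proxy is an MA(1) filter; its
        lag-1 autocorrelation w/(1+w^2) grows monotonically with w."""
        rng = np.random.default_rng(5)
        grint = rng.uniform(0.0, 1.0, size=(1000, 12))
        acs = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            trw = annual_trw_proxy(grint, w)[1:]
            ac = np.corrcoef(trw[:-1], trw[1:])[0, 1]
            acs.append(ac)
        assert np.all(np.diff(acs) > 0.0)


class TestSimulate:
    def test_cold_bounds_shut_down_growth(self, default_climate):
        frozen = VSLiteParameters(t1=38.0, t2=39.0, t3=39.5, t4=40.0)
        sim = simulate(default_climate, frozen)
        assert np.all(sim.grINT == 0.0)
        assert np.all(sim.trw_proxy == 0.0)

    def test_deterministic_repeat(self, default_climate, truth_params):
        a = simulate(default_climate, truth_params)
        b = simulate(default_climate, truth_params)
        assert np.array_equal(a.grINT, b.grINT)
        assert np.array_equal(a.trw_proxy, b.trw_proxy)

    def test_two_year_constant_climate_matches_hand_chain(self, p):
        """Independent scalar re-computation of the whole 24-month chain."""
        clim = constant_climate(14.0, 70.0, n_years=2, latitude=49.0)
        sim = simulate(clim, p)

        # --- independent oracle: plain python loops ---
        import math

        # heat index & PET (same every year: constant temperature)
        heat = 12 * (14.0 / 5.0) ** 1.514
        a_exp = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
        days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        mid = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
        daylength = []
        for doy in mid:
            decl = math.radians(23.44) * math.sin(2 * math.pi * (doy - 81) / 365.0)
            x = max(-1.0, min(1.0, -math.tan(math.radians(49.0)) * math.tan(decl)))
            daylength.append(24.0 * math.acos(x) / math.pi)
        pet = [16.0 * (dl / 12.0) * (nd / 30.0) * (10.0 * 14.0 / heat) ** a_exp
               for dl, nd in zip(daylength, days)]
        # bucket: 4 sub-steps, capacity p.mcap
        c = BucketConstants(mmax=p.mcap)
        m = min(c.m0, c.mmax)
        m_monthly = []
        for t in range(24):
            acc = 0.0
            for _ in range(c.n_substeps):
                dt = 1.0 / c.n_substeps
                ev = pet[t % 12] * dt * m / c.mmax
                ro = 70.0 * dt * (m / c.mmax) ** c.m_th + (c.alpha / (1 + c.mu_th)) * m * c.rootd * dt
                dr = (c.alpha * c.mu_th / (1 + c.mu_th)) * m * c.rootd * dt
                m = m + (70.0 * dt - ev - ro - dr) / c.rootd
                m = min(max(m, c.mmin), c.mmax)
                acc += m
            m_monthly.append(acc / c.n_substeps)
        grE_peak = max(daylength)
        trw = []
        grint_years = []
        for y in range(2):
            grint = []
            for mth in range(12):
                grT = min(max((14.0 - p.t1) / (p.t2 - p.t1), 0.0), 1.0)
                mm = m_monthly[12 * y + mth]
                grM = min(max((mm - p.m1) / (p.m2 - p.m1), 0.0), 1.0)
                grE = daylength[mth] / grE_peak
                grint.append(min(grT, grM) * grE)
            grint_years.append(grint)
        trw.append(sum(grint_years[0]))
        trw.append((sum(grint_years[1]) + p.w * sum(grint_years[0])) / (1 + p.w))

        assert np.allclose(sim.grINT, np.array(grint_years), atol=1e-12)
        assert np.allclose(sim.trw_proxy, np.array(trw), atol=1e-12)

    def test_uniform_cooling_never_raises_growth_on_rising_limb(self, p, noise_free_climate):
        """Cool every month by 1 degC; months that stay on the rising limb
        (T and T-1 both < t2) cannot gain temperature-response growth."""
        from dataclasses import replace

        cooled = replace(noise_free_climate, temp=noise_free_climate.temp - 1.0)
        base = simulate(noise_free_climate, p)
        cool = simulate(cooled, p)
        mask = noise_free_climate.temp < p.t2
        assert np.all(cool.grT[mask] <= base.grT[mask] + 1e-15)

    def test_reduces_to_classic_ramp_without_heat_decline(self, default_climate):
        """With the heat limb pushed past any observed temperature and
        w = 0, the trapezoid degenerates to the classic two-parameter
        rising ramp and the proxy to the plain annual sum."""
        mod = VSLiteParameters(t1=4.0, t2=12.0, t3=900.0, t4=1000.0, w=0.0)
        sim = simulate(default_climate, mod)
        ramp = np.clip((default_climate.temp - 4.0) / 8.0, 0.0, 1.0)
        assert np.allclose(sim.grT, ramp)
        assert np.allclose(sim.trw_proxy[1:], sim.grINT.sum(axis=1)[1:])

    def test_rates_bounded_and_proxy_in_range(self, default_climate, truth_params):
        sim = simulate(default_climate, truth_params)
        for arr in (sim.grT, sim.grM, sim.grINT):
            assert np.all((arr >= 0.0) & (arr <= 1.0))
        assert np.all((sim.trw_proxy >= 0.0) & (sim.trw_proxy <= 12.0))
        # Liebig consistency on real forcing
        assert np.all(sim.grINT <= np.minimum(sim.grT, sim.grM) + 1e-15)

    def test_single_year_rejected(self, p):
        with pytest.raises(ValueError, match=">= 2 years"):
            simulate(constant_climate(10.0, 50.0, n_years=1), p)
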