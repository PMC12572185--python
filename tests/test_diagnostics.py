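"""Growth deficits, cessation, phenology, peak counting, relative ring
widths and the one-sample Welch test."""

import numpy as np
import pytest
from scipy import stats as sps

from ringcast.containers import GrowthSimulation, SoilMoistureSeries, BucketConstants, VSLiteParameters
from ringcast.diagnostics import (
    cessation_months,
    count_growth_peaks,
    growing_season,
    growth_deficit,
    phenology_shift_rate,
    relative_trw,
    welch_one_sample,
)
from ringcast.model import simulate


def _toy_sim(grint, limiting, grE=None):
    """Assemble a one-year GrowthSimulation from raw monthly arrays."""
    grint = np.asarray(grint, dtype=float).reshape(1, 12)
    grE = np.ones(12) if grE is None else np.asarray(grE, dtype=float)
    zeros = np.zeros((1, 12))
    moisture = SoilMoistureSeries(
        moisture=zeros, constants=BucketConstants(), evapo=zeros, runoff=zeros,
        drainage=zeros, overflow=zeros, end_state=zeros,
    )
    return GrowthSimulation(
        site_id="toy", years=np.array([2000]), grT=grint, grM=grint, grE=grE,
        grINT=grint * grE, limiting=np.asarray(limiting, dtype=np.int8).reshape(1, 12),
        trw_proxy=np.array([float((grint * grE).sum())]), moisture=moisture,
        params=VSLiteParameters(), first_year_partial=False,
    )


class TestGrowthDeficit:
    def test_optimal_growth_has_no_deficit(self):
        sim = _toy_sim(np.ones(12), np.zeros(12))
        rec = growth_deficit(sim, 2000)
        assert rec.cold_deficit == rec.drought_deficit == rec.total_deficit == 0.0

    def test_total_cold_shutdown(self):
        sim = _toy_sim(np.zeros(12), np.ones(12))  # all cold-limited
        rec = growth_deficit(sim, 2000)
        assert rec.cold_deficit == pytest.approx(1.0)
        assert rec.drought_deficit == 0.0

    def test_hand_built_split_attribution(self):
        """First half cold-limited at GrINT 0.25, second half moisture-
        limited at 0.5, flat GrE = 1: deficits 6*0.75/12 and 6*0.5/12."""
        grint = np.array([0.25] * 6 + [0.5] * 6)
        limiting = np.array([1] * 6 + [3] * 6)
        rec = growth_deficit(_toy_sim(grint, limiting), 2000)
        assert rec.cold_deficit == pytest.approx(6 * 0.75 / 12)
        assert rec.drought_deficit == pytest.approx(6 * 0.5 / 12)
        assert rec.total_deficit == pytest.approx(rec.cold_deficit + rec.drought_deficit)

    def test_conservation_on_real_simulation(self, default_climate, truth_params):
        """(sum GrINT + sum GD) / sum GrE = 1 for every simulated year."""
        sim = simulate(default_climate, truth_params)
        for year in sim.years:
            rec = growth_deficit(sim, int(year))
            realized = sim.grINT[sim.year_index(int(year))].sum() / sim.grE.sum()
            assert realized + rec.total_deficit == pytest.approx(1.0, abs=1e-12)


class TestCessation:
    def test_causes_follow_limiting_labels(self):
        grint = np.array([0.0, 0.0, 0.2, 0.5, 1.0, 1.0, 0.0, 1.0, 0.6, 0.3, 0.0, 0.0])
        limiting = np.array([1, 1, 1, 1, 0, 0, 3, 0, 2, 1, 1, 2])
        months = cessation_months(_toy_sim(grint, limiting), 2000)
        assert months == {1: "cold", 2: "cold", 7: "drought", 11: "cold", 12: "drought"}

    def test_no_zero_months_empty(self):
        months = cessation_months(_toy_sim(np.full(12, 0.3), np.ones(12)), 2000)
        assert months == {}


class TestGrowingSeason:
    def test_single_burst_month(self):
        grint = np.zeros(12)
        grint[5] = 0.8  # all growth in June
        rec = growing_season(_toy_sim(grint, np.zeros(12)), 2000)
        assert rec.start_month == rec.end_month == 6
        assert rec.duration == 1

    def test_uniform_april_to_september(self):
        grint = np.zeros(12)
        grint[3:9] = 0.5
        rec = growing_season(_toy_sim(grint, np.zeros(12)), 2000)
        assert rec.start_month == 4  # cumulative 1/6 >= 2.5 %
        assert rec.end_month == 9  # first month reaching 97.5 % is the last
        assert rec.duration == 6

    def test_zero_growth_year_degenerate(self):
        rec = growing_season(_toy_sim(np.zeros(12), np.ones(12)), 2000)
        assert rec.degenerate and rec.start_month is None

    def test_march_growth_cannot_delay_start(self, default_climate, truth_params):
        sim = simulate(default_climate, truth_params)
        year = int(sim.years[10])
        before = growing_season(sim, year)
        boosted = sim.grINT.copy()
        boosted[sim.year_index(year), 2] += 0.5  # add March growth
        sim2 = _toy_sim(boosted[sim.year_index(year)], sim.limiting[sim.year_index(year)])
        after = growing_season(sim2, 2000)
        assert after.start_month <= before.start_month


class TestPeakCount:
    @pytest.mark.parametrize(
        "rates,expected",
        [
            (np.exp(-0.5 * ((np.arange(12) - 6) / 2.0) ** 2), 1),  # unimodal bell
            ([0, 0, 0.2, 0.6, 0.9, 0.5, 0.3, 0.5, 0.8, 0.4, 0.1, 0], 2),  # May + Sep bumps
            (np.full(12, 0.4), 0),  # plateau: strictness
            ([0.9, 0.1] * 6, 6),  # alternating attains the maximum
        ],
    )
    def test_counts(self, rates, expected):
        assert count_growth_peaks(rates) == expected

    def test_boundary_months_one_sided(self):
        rates = np.zeros(12)
        rates[0] = 1.0
        assert count_growth_peaks(rates) == 1
        rates = np.zeros(12)
        rates[11] = 1.0
        assert count_growth_peaks(rates) == 1


class TestRelativeTrw:
    def test_identity_and_percent_convention(self):
        baseline = np.full(60, 2.0)
        ratio, pct = relative_trw(2.0, baseline)
        assert ratio == 1.0 and pct == 0.0
        ratio, pct = relative_trw(2.0 * 1.48, baseline)
        assert ratio == pytest.approx(1.48)
        assert pct == pytest.approx(48.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            relative_trw(1.0, np.zeros(60))


class TestWelch:
    def test_forecast_at_baseline_mean(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=60)
        res = welch_one_sample(base.mean(), base)
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 59

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        base = rng.normal(2.0, 0.5, size=60)
        res = welch_one_sample(1.7, base)
        ref = sps.ttest_1samp(base, popmean=1.7)
        assert res.t_stat == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        lo, hi = ref.confidence_interval(0.95)
        # scipy brackets the baseline mean; ours brackets the difference
        assert res.ci95[0] == pytest.approx(1.7 - hi, abs=1e-10)
        assert res.ci95[1] == pytest.approx(1.7 - lo, abs=1e-10)

    def test_type_one_error_near_nominal(self):
        """10,000 null replicates (n = 60): rejection rate 5% +/- 1%."""
        rng = np.random.default_rng(42)
        data = rng.normal(size=(10_000, 60))
        means = data.mean(axis=1)
        sds = data.std(axis=1, ddof=1)
        t = means / (sds / np.sqrt(60))
        p = 2.0 * sps.t.sf(np.abs(t), 59)
        rate = float(np.mean(p < 0.05))
        # spot-check the vectorized nulls against the package implementation
        res = welch_one_sample(0.0, data[0])
        assert res.t_stat == pytest.approx(t[0]) and res.p_value == pytest.approx(p[0])
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_degenerate_baselines_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            welch_one_sample(0.0, [1.0])
        with pytest.raises(ValueError, match="variance"):
            welch_one_sample(0.0, np.ones(10))


class TestPhenologyShiftRate:
    def test_months_over_years_to_days_per_year(self):
        assert phenology_shift_rate(1.44, 110.0) == pytest.approx(0.39, abs=0.005)
        assert phenology_shift_rate(12.0, 360.0) == pytest.approx(1.0)

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ValueError):
            phenology_shift_rate(1.0, 0.0)
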