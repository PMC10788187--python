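import numpy as np
import pytest

from tempmort.attribution import (
    TemperatureLevels,
    aggregate_cities,
    attribute_city,
    attribute_daily,
    decompose,
    find_mmt,
    monte_carlo_eci,
)
from tempmort.cityfit import PERCENTILE_GRID
from tempmort.splines import BasisSpec, evaluate_basis

from oracles import attribution_loop_oracle

SPEC = BasisSpec("bspline_quadratic", (8.0, 15.0, 22.0), (0.0, 30.0))


def coef_for(f, spec=SPEC):
    """Coefficients reproducing a function in the quadratic-spline space.

    The no-intercept basis spans exactly the splines vanishing at the lower
    boundary, so the target is anchored there (the additive constant is
    irrelevant: attribution and MMT use only curve differences). Quadratics
    lie in the space, so the least-squares fit is exact.
    """
    lo, hi = spec.boundary_knots
    x = np.linspace(lo, hi, 2000)
    B = evaluate_basis(x, spec).values
    y = f(x) - f(np.array([lo]))[0]
    c, *_ = np.linalg.lstsq(B, y, rcond=None)
    assert np.max(np.abs(B @ c - y)) < 1e-8
    return c


def pct_table(lo=0.0, hi=30.0):
    """Linear temperature-percentile table: percentile p -> lo + p/100*(hi-lo)."""
    return lo + (hi - lo) * PERCENTILE_GRID / 100.0


class TestFindMMT:
    def test_symmetric_parabola_minimum_at_p60(self):
        table = pct_table()
        t60 = table[PERCENTILE_GRID == 60.0][0]
        coef = coef_for(lambda x: (np.asarray(x, float) - t60) ** 2)
        res = find_mmt(coef, SPEC, table)
        assert res.mmp == pytest.approx(60.0)
        assert res.mmt == pytest.approx(t60)

    def test_monotone_decreasing_clamps_at_99(self):
        coef = coef_for(lambda x: -x)
        res = find_mmt(coef, SPEC, pct_table())
        assert res.mmp == pytest.approx(99.0)

    def test_flat_curve_ties_break_to_50(self):
        res = find_mmt(np.zeros(5), SPEC, pct_table())
        assert res.mmp == pytest.approx(50.0)

    def test_nonfinite_curve_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            find_mmt(np.array([np.nan] * 5), SPEC, pct_table())

    def test_wrong_table_resolution_errors(self):
        with pytest.raises(ValueError, match="0-100 by 0.1"):
            find_mmt(np.zeros(5), SPEC, np.linspace(0, 30, 101))


class TestAttributeDaily:
    def test_flat_curve_zero_an(self):
        temps = np.random.default_rng(0).uniform(0, 30, 100)
        an = attribute_daily(np.zeros(5), SPEC, temps, np.full(100, 10.0), mmt=15.0)
        assert np.allclose(an, 0.0)

    def test_constant_series_closed_form(self):
        coef = coef_for(lambda x: 0.01 * (x - 15.0) ** 2)
        x0, d = 25.0, 12.0
        temps = np.full(80, x0)
        temps[0] = 15.0  # keep the MMT inside the observed range
        r = 0.01 * (x0 - 15.0) ** 2
        an = attribute_daily(coef, SPEC, temps, np.full(80, d), mmt=15.0)
        assert np.allclose(an[1:], d * (1.0 - np.exp(-r)), atol=1e-10)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        temps = rng.uniform(0, 30, 60)
        deaths = rng.integers(5, 30, 60).astype(float)
        f = lambda x: 0.004 * (np.asarray(x, float) - 12.0) ** 2
        coef = coef_for(f)
        mask = np.ones(60, bool)
        mask[:25] = False
        an = attribute_daily(coef, SPEC, temps, deaths, mmt=12.0, attributable_mask=mask)
        oracle = attribution_loop_oracle(lambda t: float(f(t)), temps, deaths, 12.0, 25)
        assert np.allclose(an[25:], oracle[25:], atol=1e-10)
        assert np.isnan(an[:25]).all()

    def test_mmt_outside_range_errors(self):
        with pytest.raises(ValueError, match="outside observed"):
            attribute_daily(np.zeros(5), SPEC, np.full(10, 20.0), np.full(10, 5.0), mmt=5.0)

    def test_nonnegative_for_rr_above_one(self):
        coef = coef_for(lambda x: 0.02 * (x - 18.0) ** 2)
        rng = np.random.default_rng(2)
        temps = rng.uniform(0, 30, 200)
        an = attribute_daily(coef, SPEC, temps, np.full(200, 10.0), mmt=18.0)
        assert np.all(an >= -1e-12)


class TestDecompose:
    def test_partition_sums(self):
        rng = np.random.default_rng(3)
        temps = rng.uniform(0, 30, 150)
        deaths = rng.integers(1, 20, 150).astype(float)
        coef = coef_for(lambda x: 0.01 * (x - 14.0) ** 2)
        an = attribute_daily(coef, SPEC, temps, deaths, mmt=14.0)
        levels = TemperatureLevels(p1=2.0, mmt=14.0, p99=28.0)
        an_by, af_by, total = decompose(an, temps, deaths, levels)
        assert an_by["cold"] + an_by["heat"] == pytest.approx(an_by["total"], abs=1e-12)
        assert an_by["extreme_cold"] + an_by["moderate_cold"] == pytest.approx(an_by["cold"], abs=1e-12)
        assert an_by["moderate_heat"] + an_by["extreme_heat"] == pytest.approx(an_by["heat"], abs=1e-12)
        assert af_by["total"] == pytest.approx(100.0 * an_by["total"] / total)

    def test_all_days_moderate_heat(self):
        temps = np.linspace(15.0, 27.0, 50)
        deaths = np.full(50, 10.0)
        coef = coef_for(lambda x: 0.01 * (x - 14.0) ** 2)
        an = attribute_daily(coef, SPEC, temps, deaths, mmt=15.0)
        levels = TemperatureLevels(p1=2.0, mmt=15.0, p99=28.0)
        an_by, _, _ = decompose(an, temps, deaths, levels)
        assert an_by["cold"] == 0.0
        assert an_by["extreme_heat"] == 0.0
        assert an_by["moderate_heat"] == pytest.approx(an_by["total"])

    def test_toy_hand_enumeration(self):
        # 30 days: 5 extreme cold (T=1), 10 moderate cold (T=8),
        # 10 moderate heat (T=20), 5 extreme heat (T=29); 10 deaths/day
        temps = np.array([1.0] * 5 + [8.0] * 10 + [20.0] * 10 + [29.0] * 5)
        deaths = np.full(30, 10.0)
        f = lambda x: 0.005 * (np.asarray(x, float) - 15.0) ** 2
        coef = coef_for(f)
        an = attribute_daily(coef, SPEC, temps, deaths, mmt=15.0)
        levels = TemperatureLevels(p1=2.0, mmt=15.0, p99=28.0)
        an_by, _, _ = decompose(an, temps, deaths, levels)
        expect = lambda T, n: n * 10.0 * (1.0 - np.exp(-float(f(T))))
        assert an_by["extreme_cold"] == pytest.approx(expect(1.0, 5), abs=1e-9)
        assert an_by["moderate_cold"] == pytest.approx(expect(8.0, 10), abs=1e-9)
        assert an_by["moderate_heat"] == pytest.approx(expect(20.0, 10), abs=1e-9)
        assert an_by["extreme_heat"] == pytest.approx(expect(29.0, 5), abs=1e-9)


class TestMonteCarlo:
    temps = np.random.default_rng(4).uniform(0, 30, 400)
    deaths = np.full(400, 20.0)
    levels = TemperatureLevels(p1=1.5, mmt=16.0, p99=28.5)

    def test_zero_vcov_collapses_to_point(self):
        coef = coef_for(lambda x: 0.01 * (x - 16.0) ** 2)
        an = attribute_daily(coef, SPEC, self.temps, self.deaths, mmt=16.0)
        an_by, _, _ = decompose(an, self.temps, self.deaths, self.levels)
        draws = monte_carlo_eci(coef, np.zeros((5, 5)), SPEC, self.temps, self.deaths,
                                16.0, self.levels, n_sim=200, rng=0)
        for comp, vals in draws.items():
            assert np.allclose(vals, an_by[comp], atol=1e-9)

    def test_deterministic_given_seed(self):
        coef = coef_for(lambda x: 0.01 * (x - 16.0) ** 2)
        a = monte_carlo_eci(coef, 1e-4 * np.eye(5), SPEC, self.temps, self.deaths,
                            16.0, self.levels, n_sim=200, rng=7)
        b = monte_carlo_eci(coef, 1e-4 * np.eye(5), SPEC, self.temps, self.deaths,
                            16.0, self.levels, n_sim=200, rng=7)
        assert all(np.array_equal(a[c], b[c]) for c in a)

    def test_conservation_per_draw(self):
        coef = coef_for(lambda x: 0.01 * (x - 16.0) ** 2)
        d = monte_carlo_eci(coef, 1e-4 * np.eye(5), SPEC, self.temps, self.deaths,
                            16.0, self.levels, n_sim=300, rng=1)
        assert np.allclose(d["cold"] + d["heat"], d["total"], atol=1e-10)
        assert np.allclose(d["extreme_cold"] + d["moderate_cold"], d["cold"], atol=1e-10)
        assert np.allclose(d["moderate_heat"] + d["extreme_heat"], d["heat"], atol=1e-10)

    def test_doubling_nsim_stable(self):
        coef = coef_for(lambda x: 0.008 * (x - 16.0) ** 2)
        v = 2e-5 * np.eye(5)
        tot_deaths = self.deaths.sum()
        e1 = monte_carlo_eci(coef, v, SPEC, self.temps, self.deaths, 16.0, self.levels,
                             n_sim=1000, rng=3)
        e2 = monte_carlo_eci(coef, v, SPEC, self.temps, self.deaths, 16.0, self.levels,
                             n_sim=2000, rng=3)
        for comp in ("total", "cold", "heat"):
            q1 = np.percentile(e1[comp], [2.5, 97.5]) / tot_deaths * 100
            q2 = np.percentile(e2[comp], [2.5, 97.5]) / tot_deaths * 100
            assert np.max(np.abs(q1 - q2)) < 0.5

    def test_small_nsim_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            monte_carlo_eci(np.zeros(5), np.eye(5), SPEC, self.temps, self.deaths,
                            16.0, self.levels, n_sim=50)

    def test_asymmetric_vcov_rejected(self):
        v = np.eye(5)
        v[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            monte_carlo_eci(np.zeros(5), v, SPEC, self.temps, self.deaths,
                            16.0, self.levels, n_sim=200)


class TestAttributeCity:
    def test_full_result_consistency(self):
        rng = np.random.default_rng(5)
        temps = rng.uniform(0, 30, 600)
        deaths = rng.integers(10, 40, 600).astype(np.int64)
        coef = coef_for(lambda x: 0.006 * (x - 17.0) ** 2)
        table = np.percentile(temps, PERCENTILE_GRID)
        res = attribute_city(coef, 1e-5 * np.eye(5), SPEC, temps, deaths, table,
                             n_sim=300, rng=0, city_id="t")
        assert res.an["cold"] + res.an["heat"] == pytest.approx(res.an["total"], abs=1e-10)
        for comp in res.af:
            lo, hi = res.af_ci[comp]
            assert lo <= hi
        # RR at the reported MMT equals 1 after centering, by construction
        b = attribute_daily(coef, SPEC, np.array([res.mmt.mmt]), np.array([1.0]), res.mmt.mmt,
                            None)
        assert b[0] == pytest.approx(0.0, abs=1e-12)


class TestAggregate:
    def _toy_result(self, city, an_total, deaths, n_sim=100, seed=0):
        from tempmort.attribution import AttributionResult, COMPONENTS

        rng = np.random.default_rng(seed)
        an = {c: 0.0 for c in COMPONENTS}
        an["moderate_cold"] = an["cold"] = an["total"] = an_total
        af = {c: 100.0 * v / deaths for c, v in an.items()}
        draws = {c: np.full(n_sim, an[c]) + rng.normal(0, 1e-6, n_sim) for c in COMPONENTS}
        return AttributionResult(city_id=city, stratum="total", total_deaths=deaths,
                                 an=an, af=af, draws=draws,
                                 an_ci={c: (0, 0) for c in COMPONENTS},
                                 af_ci={c: (0, 0) for c in COMPONENTS})

    def test_single_city_identity(self):
        r = self._toy_result("a", 50.0, 1000)
        assert aggregate_cities([r]) is r

    def test_two_identical_cities_same_af(self):
        a = self._toy_result("a", 50.0, 1000)
        b = self._toy_result("b", 50.0, 1000, seed=1)
        agg = aggregate_cities([a, b])
        assert agg.af["total"] == pytest.approx(a.af["total"])
        assert agg.an["total"] == pytest.approx(100.0)

    def test_three_city_hand_arithmetic(self):
        rs = [self._toy_result(c, an, d) for c, an, d in
              [("a", 10.0, 100), ("b", 30.0, 300), ("c", 20.0, 100)]]
        agg = aggregate_cities(rs)
        assert agg.an["total"] == pytest.approx(60.0)
        assert agg.total_deaths == 500
        assert agg.af["total"] == pytest.approx(100.0 * 60.0 / 500.0)

    def test_mismatched_nsim_rejected(self):
        a = self._toy_result("a", 10.0, 100, n_sim=100)
        b = self._toy_result("b", 10.0, 100, n_sim=200)
        with pytest.raises(ValueError, match="n_sim"):
            aggregate_cities([a, b])
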