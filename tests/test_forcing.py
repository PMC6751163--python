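import numpy as np
import pytest

from ecosink.forcing import (
    LaiSeries,
    ScenarioSpec,
    composite_to_daily,
    gen_drivers,
    gen_lai,
    gen_met,
    lai_climatology,
    make_baseline,
)
from ecosink.grid import gen_grid
from ecosink.trends import linear_trend


@pytest.fixture(scope="module")
def grid9():
    return gen_grid(3, 3, (-50.0, 70.0), seed=1)


class TestGenMet:
    def test_zero_noise_years_identical(self, grid9):
        grid, _ = grid9
        met = gen_met(grid, (2000, 2004), seed=0, noise_scale=0.0)
        for var in ("tmax", "tmin", "srad", "rh", "precip"):
            arr = getattr(met, var)
            for y in range(1, arr.shape[0]):
                np.testing.assert_array_equal(arr[y], arr[0])

    def test_temperature_trend_recovered_by_ols(self, grid9):
        # Monte Carlo over seeds: mean recovered slope within 2 SE of 0.3
        grid, _ = grid9
        slopes = []
        for seed in range(40):
            met = gen_met(grid, (1981, 2010),
                          trend={"tmax": 0.3, "tmin": 0.3}, seed=seed)
            tmean = 0.5 * (met.tmax + met.tmin)
            annual = tmean.mean(axis=(1, 2))
            s, _ = linear_trend(annual)
            slopes.append(s * 10.0)  # per decade
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.3) < 2 * se + 1e-3

    def test_determinism_and_invariants(self, grid9):
        grid, _ = grid9
        a = gen_met(grid, (1990, 1994), seed=5)
        b = gen_met(grid, (1990, 1994), seed=5)
        np.testing.assert_array_equal(a.tmax, b.tmax)
        np.testing.assert_array_equal(a.precip, b.precip)
        a.validate()  # tmax>=tmin, rh in [0,100], srad/precip >= 0

    def test_invariants_over_many_seeds(self, grid9):
        grid, _ = grid9
        for seed in range(30):
            gen_met(grid, (2000, 2001), seed=seed).validate()


class TestGenLai:
    def test_no_trend_no_noise_identical_years(self, grid9):
        grid, _ = grid9
        lai = gen_lai(grid, (1990, 1995), trend=0.0, noise_sd=0.0, seed=0)
        for y in range(1, lai.values.shape[0]):
            np.testing.assert_array_equal(lai.values[y], lai.values[0])

    def test_global_mean_rises_point_one_over_36yr(self, grid9):
        # trend calibrated so an area-weighted 1.6 mean gains 0.1 in 36 years
        grid, _ = grid9
        lai = gen_lai(grid, (1981, 2016), trend=0.1 / 3.5, noise_sd=0.05,
                      base=1.6, seed=2)
        w = grid.pixel_area / grid.pixel_area.sum()
        annual = (lai.values.mean(axis=1) * w[None, :]).sum(axis=1)
        assert annual[-1] - annual[0] == pytest.approx(0.1, abs=0.03)

    def test_per_pixel_trend_field_recovered(self):
        grid, _ = gen_grid(10, 20, (-50, 70), seed=3)  # 200 pixels
        rng = np.random.default_rng(4)
        true_trend = rng.uniform(-0.05, 0.1, grid.n_pix)
        lai = gen_lai(grid, (1981, 2016), trend=true_trend, noise_sd=0.1,
                      seed=5)
        annual = lai.values.mean(axis=1)  # (n_yr, n_pix)
        slope, _ = linear_trend(annual)
        r = np.corrcoef(slope * 10.0, true_trend)[0, 1]
        assert r > 0.9

    def test_negative_base_rejected(self, grid9):
        grid, _ = grid9
        with pytest.raises(ValueError):
            gen_lai(grid, (1990, 1991), base=-1.0)

    def test_composite_length_validated(self, grid9):
        grid, _ = grid9
        with pytest.raises(ValueError):
            gen_lai(grid, (1990, 1991), composite_length=10)


class TestGenDrivers:
    def test_co2_endpoints_exact(self, grid9):
        grid, _ = grid9
        drv = gen_drivers((1981, 2016), (340.13, 404.20), (42.3, 58.9), grid)
        assert drv.co2[0] == pytest.approx(340.13)
        assert drv.co2[-1] == pytest.approx(404.20)

    def test_cumulative_excess_nitrogen(self, grid9):
        # linear 42.3 -> 58.9 Tg N/yr over 1981-2016: 0.30 Pg N above 1981
        grid, _ = grid9
        drv = gen_drivers((1981, 2016), (340.13, 404.20), (42.3, 58.9), grid)
        total_g = (drv.ndep * grid.pixel_area[None, :]).sum(axis=1)
        excess_pg = (total_g - total_g[0]).sum() / 1e15
        assert excess_pg == pytest.approx(0.30, abs=0.005)

    def test_disaggregation_conserves_global_total(self, grid9):
        grid, _ = grid9
        drv = gen_drivers((1981, 2016), (340.0, 404.0), (42.3, 58.9), grid,
                          seed=9)
        total_g = (drv.ndep * grid.pixel_area[None, :]).sum(axis=1)
        frac = np.linspace(0, 1, 36)
        expected = (42.3 + (58.9 - 42.3) * frac) * 1e12
        np.testing.assert_allclose(total_g, expected, rtol=1e-6)

    def test_anchor_curve_pins_observed_1981_level(self, grid9):
        # piecewise-linear historical curve: 296 p.p.m. in 1901 rising to
        # the observed 340.13 in 1981 and 404.20 in 2016
        grid, _ = grid9
        drv = gen_drivers((1901, 2016), (296.0, 404.2), (12.0, 58.9), grid,
                          co2_anchors=[[1901, 296.0], [1981, 340.13],
                                       [2016, 404.20]],
                          ndep_anchors_tg=[[1901, 12.0], [1981, 42.3],
                                           [2016, 58.9]])
        assert drv.co2[80] == pytest.approx(340.13)
        assert drv.co2[-1] == pytest.approx(404.20)
        total_g = (drv.ndep[80] * grid.pixel_area).sum()
        assert total_g == pytest.approx(42.3e12, rel=1e-6)

    def test_bad_endpoints_rejected(self, grid9):
        grid, _ = grid9
        with pytest.raises(ValueError):
            gen_drivers((1981, 1990), (-1.0, 400.0), (42.3, 58.9), grid)


class TestCompositeToDaily:
    def _series(self, values, doys, length=16):
        return LaiSeries(values=np.asarray(values, dtype=np.float32),
                         composite_doys=np.asarray(doys),
                         composite_length=length)

    def test_constant_composites_constant_daily(self):
        lai = self._series(np.full((2, 4, 3), 1.5), [1, 100, 200, 300])
        daily = composite_to_daily(lai)
        np.testing.assert_allclose(daily, 1.5, rtol=1e-6)

    def test_linear_midpoint(self):
        vals = np.zeros((1, 2, 1), dtype=np.float32)
        vals[0, 0, 0], vals[0, 1, 0] = 1.0, 2.0
        daily = composite_to_daily(self._series(vals, [1, 17]))
        assert daily[0, 8, 0] == pytest.approx(1.5)  # day 9, 1-based

    def test_interpolation_passes_through_knots(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 4, (2, 5, 4)).astype(np.float32)
        doys = np.array([10, 80, 150, 250, 340])
        daily = composite_to_daily(self._series(vals, doys))
        for y in range(2):
            for i, d in enumerate(doys):
                np.testing.assert_allclose(daily[y, d - 1], vals[y, i],
                                           rtol=1e-6)


class TestMakeBaseline:
    def _spec(self, modes, seed=0):
        return ScenarioSpec(modes=modes, baseline_lai_window=(1982, 1986),
                            climate_resample_window=(1971, 1979),
                            period=(1981, 2016), seed=seed)

    def test_all_transient_is_identity(self, small_forcing):
        spec = self._spec({d: "transient" for d in
                           ("lai", "co2", "ndep", "climate")})
        assert make_baseline(small_forcing, spec) is small_forcing

    def test_frozen_drivers_have_zero_trend(self, small_forcing):
        spec = self._spec({d: "baseline" for d in
                           ("lai", "co2", "ndep", "climate")})
        out = make_baseline(small_forcing, spec)
        sim = out.years >= 1981
        assert np.ptp(out.drivers.co2[sim]) == 0.0
        assert np.ptp(out.drivers.ndep[sim], axis=0).max() == 0.0
        # LAI identical across years -> exactly zero trend
        clim = lai_climatology(small_forcing.lai, small_forcing.years,
                               (1982, 1986))
        np.testing.assert_allclose(out.lai.values,
                                   np.broadcast_to(clim[None],
                                                   out.lai.values.shape),
                                   rtol=1e-6)

    def test_resampled_climate_trend_near_zero_in_expectation(
            self, small_forcing):
        spec_modes = {"lai": "transient", "co2": "transient",
                      "ndep": "transient", "climate": "baseline"}
        slopes = []
        for seed in range(60):
            out = make_baseline(small_forcing, self._spec(spec_modes, seed))
            sim = out.years >= 1981
            tmean = 0.5 * (out.met.tmax[sim] + out.met.tmin[sim])
            annual = tmean.mean(axis=(1, 2))
            s, _ = linear_trend(annual)
            slopes.append(s)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se + 1e-4

    def test_same_seed_same_resampling(self, small_forcing):
        spec = self._spec({"lai": "baseline", "co2": "baseline",
                           "ndep": "baseline", "climate": "baseline"}, seed=4)
        a = make_baseline(small_forcing, spec)
        b = make_baseline(small_forcing, spec)
        np.testing.assert_array_equal(a.met.tmax, b.met.tmax)

    def test_idempotent(self, small_forcing):
        spec = self._spec({"lai": "baseline", "co2": "baseline",
                           "ndep": "baseline", "climate": "baseline"}, seed=4)
        once = make_baseline(small_forcing, spec)
        twice = make_baseline(once, spec)
        np.testing.assert_array_equal(once.met.tmax, twice.met.tmax)
        np.testing.assert_array_equal(once.lai.values, twice.lai.values)
        np.testing.assert_array_equal(once.drivers.co2, twice.drivers.co2)

    def test_uncovered_window_rejected(self, small_forcing):
        spec = ScenarioSpec(modes={"lai": "baseline", "co2": "baseline",
                                   "ndep": "baseline", "climate": "baseline"},
                            climate_resample_window=(1950, 1960),
                            period=(1981, 2016))
        with pytest.raises(ValueError):
            make_baseline(small_forcing, spec)

    def test_missing_mode_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(modes={"lai": "transient"})
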