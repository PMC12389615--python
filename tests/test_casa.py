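import numpy as np
import pytest

from nppkit import casa
from nppkit.casa import FPAR_MAX, FPAR_MIN, VegClassParams
from nppkit.raster import Grid, GridError, RasterCube

from conftest import make_grid


@pytest.fixture
def one_class_params():
    return {1: VegClassParams(1, "grass", 0.542, 0.1, 0.7)}


@pytest.fixture
def vegtype():
    return make_grid(np.ones((3, 3), dtype=np.int16))


class TestSrIndex:
    @pytest.mark.parametrize("ndvi,expected", [
        (0.0, 1.0),
        (0.5, 3.0),
        (-0.1, 0.9 / 1.1),
    ])
    def test_values(self, ndvi, expected):
        grid = make_grid(np.full((2, 2), ndvi, dtype=np.float32))
        np.testing.assert_allclose(casa.sr_index(grid).values, expected, rtol=1e-6)

    def test_clipping_prevents_blowup(self):
        grid = make_grid(np.full((2, 2), 0.9999, dtype=np.float32))
        assert np.isfinite(casa.sr_index(grid).values).all()


class TestFpar:
    def test_endpoints(self, one_class_params, vegtype):
        p = one_class_params[1]
        hi = casa.fpar_from_ndvi(make_grid(np.full((3, 3), p.ndvi_max, dtype=np.float32)),
                                 vegtype, one_class_params)
        lo = casa.fpar_from_ndvi(make_grid(np.full((3, 3), p.ndvi_min, dtype=np.float32)),
                                 vegtype, one_class_params)
        np.testing.assert_allclose(hi.values, FPAR_MAX, atol=1e-6)
        np.testing.assert_allclose(lo.values, FPAR_MIN, atol=1e-6)

    def test_midpoint_linear(self, one_class_params, vegtype):
        p = one_class_params[1]
        mid = (p.ndvi_min + p.ndvi_max) / 2
        out = casa.fpar_from_ndvi(make_grid(np.full((3, 3), mid, dtype=np.float32)),
                                  vegtype, one_class_params)
        np.testing.assert_allclose(out.values, (FPAR_MAX + FPAR_MIN) / 2, atol=1e-6)

    def test_sr_endpoints(self, one_class_params, vegtype):
        p = one_class_params[1]
        hi = casa.fpar_from_sr(make_grid(np.full((3, 3), p.sr_max, dtype=np.float32)),
                               vegtype, one_class_params)
        lo = casa.fpar_from_sr(make_grid(np.full((3, 3), p.sr_min, dtype=np.float32)),
                               vegtype, one_class_params)
        np.testing.assert_allclose(hi.values, FPAR_MAX, atol=1e-5)
        np.testing.assert_allclose(lo.values, FPAR_MIN, atol=1e-5)

    def test_clipped_into_bounds_for_any_ndvi(self, one_class_params, vegtype):
        rng = np.random.default_rng(0)
        ndvi = make_grid(rng.uniform(-1, 1, (3, 3)).astype(np.float32))
        out = casa.fpar_from_ndvi(ndvi, vegtype, one_class_params)
        assert (out.values >= FPAR_MIN - 1e-9).all()
        assert (out.values <= FPAR_MAX + 1e-9).all()

    def test_missing_class_listed(self, one_class_params):
        veg = make_grid(np.full((3, 3), 9, dtype=np.int16))
        with pytest.raises(GridError, match=r"\[9\]"):
            casa.fpar_from_ndvi(make_grid(np.zeros((3, 3), dtype=np.float32)),
                                veg, one_class_params)

    def test_combined_is_mean(self):
        a = make_grid(np.full((2, 2), FPAR_MIN, dtype=np.float32))
        b = make_grid(np.full((2, 2), FPAR_MAX, dtype=np.float32))
        out = casa.fpar_combined(a, b)
        np.testing.assert_allclose(out.values, (FPAR_MAX + FPAR_MIN) / 2, atol=1e-7)
        same = casa.fpar_combined(a, a)
        np.testing.assert_allclose(same.values, a.values)


class TestApar:
    def test_zero_sol(self):
        fpar = make_grid(np.full((2, 2), 0.5, dtype=np.float32))
        sol = make_grid(np.zeros((2, 2), dtype=np.float32))
        np.testing.assert_allclose(casa.apar(fpar, sol).values, 0.0)

    def test_arithmetic(self):
        fpar = make_grid(np.full((2, 2), 0.5, dtype=np.float32))
        sol = make_grid(np.full((2, 2), 100.0, dtype=np.float32))
        np.testing.assert_allclose(casa.apar(fpar, sol).values, 25.0)

    def test_linear_in_sol(self):
        fpar = make_grid(np.full((2, 2), 0.3, dtype=np.float32))
        one = casa.apar(fpar, make_grid(np.full((2, 2), 50.0, dtype=np.float32)))
        two = casa.apar(fpar, make_grid(np.full((2, 2), 100.0, dtype=np.float32)))
        np.testing.assert_allclose(two.values, 2 * one.values)

    def test_negative_sol_rejected(self):
        fpar = make_grid(np.full((2, 2), 0.5, dtype=np.float32))
        with pytest.raises(GridError):
            casa.apar(fpar, make_grid(np.full((2, 2), -1.0, dtype=np.float32)))


class TestOptimalTemperature:
    def _cubes(self, ndvi_by_month, temp_by_month, years=(2001, 2002)):
        layers_n, layers_t, times = [], [], []
        for year in years:
            for m, (nv, tv) in enumerate(zip(ndvi_by_month, temp_by_month), start=1):
                layers_n.append(make_grid(np.full((2, 2), nv, dtype=np.float32)))
                layers_t.append(make_grid(np.full((2, 2), tv, dtype=np.float32)))
                times.append((year, m))
        return RasterCube(layers_n, times), RasterCube(layers_t, times)

    def test_peak_month_temperature(self):
        ndvi = [0.1, 0.2, 0.8, 0.3]
        temp = [0.0, 5.0, 20.0, 10.0]
        cube_n, cube_t = self._cubes(ndvi, temp)
        out = casa.optimal_temperature(cube_n, cube_t)
        np.testing.assert_allclose(out.values, 20.0)

    def test_tie_breaks_earliest(self):
        cube_n, cube_t = self._cubes([0.5, 0.5, 0.5], [3.0, 8.0, 12.0])
        out = casa.optimal_temperature(cube_n, cube_t)
        np.testing.assert_allclose(out.values, 3.0)

    def test_single_month(self):
        cube_n, cube_t = self._cubes([0.4], [17.0])
        np.testing.assert_allclose(casa.optimal_temperature(cube_n, cube_t).values, 17.0)


class TestStress:
    def test_t1_at_topt_20(self):
        topt = make_grid(np.full((2, 2), 20.0, dtype=np.float32))
        temp = make_grid(np.full((2, 2), 15.0, dtype=np.float32))
        t1, _ = casa.temperature_stress(topt, temp)
        np.testing.assert_allclose(t1.values, 1.0, atol=1e-6)

    def test_t2_at_topt(self):
        topt = make_grid(np.full((2, 2), 18.0, dtype=np.float32))
        t1, t2 = casa.temperature_stress(topt, topt)
        expected = 1.1814 / ((1 + np.exp(-2.0)) * (1 + np.exp(-3.0)))
        np.testing.assert_allclose(t2.values, expected, rtol=1e-5)

    def test_t1_zero_below_minus_10(self):
        topt = make_grid(np.full((2, 2), 20.0, dtype=np.float32))
        temp = make_grid(np.full((2, 2), -30.0, dtype=np.float32))
        t1, _ = casa.temperature_stress(topt, temp)
        np.testing.assert_allclose(t1.values, 0.0)

    @pytest.mark.parametrize("ratio,expected", [(1.0, 1.0), (0.0, 0.5), (0.5, 0.75)])
    def test_water_stress_ratio(self, ratio, expected):
        assert casa.water_stress_ratio(np.array([ratio]), np.array([1.0]))[0] == pytest.approx(expected)

    def test_water_stress_zero_potential(self):
        assert casa.water_stress_ratio(np.array([0.0]), np.array([0.0]))[0] == pytest.approx(0.5)

    def test_water_stress_cube_bounds(self, tiny_cfg):
        from nppkit import synth
        precip, temp, sol = synth.generate_climate_cubes(tiny_cfg)
        w = casa.water_stress(precip, temp, sol)
        for g in w.layers:
            assert (g.values >= 0.5 - 1e-6).all() and (g.values <= 1.0 + 1e-6).all()


class TestNpp:
    def _ones(self, value):
        return make_grid(np.full((3, 3), value, dtype=np.float32))

    def test_direct_evaluation(self, one_class_params, vegtype):
        out = casa.monthly_npp(self._ones(0.95), self._ones(100.0), self._ones(1.0),
                               self._ones(1.0), self._ones(1.0), vegtype, one_class_params)
        np.testing.assert_allclose(out.values, 25.745, rtol=1e-6)

    def test_zero_sol_gives_zero(self, one_class_params, vegtype):
        out = casa.monthly_npp(self._ones(0.95), self._ones(0.0), self._ones(1.0),
                               self._ones(1.0), self._ones(1.0), vegtype, one_class_params)
        np.testing.assert_allclose(out.values, 0.0)

    def test_linear_in_eps_max(self, vegtype):
        full = {1: VegClassParams(1, "a", 0.542, 0.1, 0.7)}
        half = {1: VegClassParams(1, "a", 0.271, 0.1, 0.7)}
        args = (self._ones(0.95), self._ones(100.0), self._ones(1.0),
                self._ones(1.0), self._ones(1.0), vegtype)
        np.testing.assert_allclose(casa.monthly_npp(*args, half).values,
                                   casa.monthly_npp(*args, full).values / 2, rtol=1e-6)

    def test_annual_sum(self):
        layers = [make_grid(np.full((2, 2), 10.0, dtype=np.float32)) for _ in range(12)]
        cube = RasterCube(layers, [(2001, m) for m in range(1, 13)])
        np.testing.assert_allclose(casa.annual_npp(cube).values, 120.0)

    def test_annual_requires_12_months(self):
        layers = [make_grid(np.zeros((2, 2), dtype=np.float32)) for _ in range(11)]
        cube = RasterCube(layers, [(2001, m) for m in range(1, 12)])
        with pytest.raises(GridError, match="12"):
            casa.annual_npp(cube)

    def test_total_tgc_hand_summed(self):
        # 3x3 grid of 500 m pixels, each 200 gC m-2: 9 * 200 * 250000 m2 * 1e-12
        grid = make_grid(np.full((3, 3), 200.0, dtype=np.float32))
        assert casa.total_npp_tgc(grid) == pytest.approx(9 * 200 * 2.5e5 * 1e-12)


class TestParams:
    def test_defaults_loadable(self):
        params = casa.default_params()
        assert set(params) == {1, 2, 3, 4, 5, 6}
        for p in params.values():
            assert p.sr_min < p.sr_max

    def test_invalid_eps_max(self):
        with pytest.raises(ValueError):
            VegClassParams(1, "x", 3.0, 0.1, 0.7)

    def test_bounds_ordering_enforced(self):
        with pytest.raises(ValueError):
            VegClassParams(1, "x", 0.5, 0.7, 0.1)

    def test_load_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("class_id,name\n1,x\n")
        with pytest.raises(ValueError, match="missing columns"):
            casa.load_params(path)
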