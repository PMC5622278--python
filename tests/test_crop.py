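"""LUE crop model: development, growth, water stress, roots, nutrition
indices, senescence, cutting/grazing and harvest."""

import math
from datetime import date as Date

import pytest

from landsim.crop import (CropState, cut_or_graze, daily_growth, develop,
                          grazing_returns, harvest, n_max_prop_leaf,
                          nutrient_demand, nutrition_indices,
                          p_max_prop_leaf, root_distribution,
                          senesce_and_return, sow, update_lai, water_stress,
                          water_stress_factor)
from landsim.params import CropParams, GrazingParams, Params, grass_params

from conftest import make_layer


def day(tmin=10.0, tmax=20.0, rad=15.0, month=6):
    from landsim.weather import WeatherDay

    return WeatherDay(Date(2001, month, 15), tmin, tmax, 0.0, rad, 1.0, 2.0)


def emerged_wheat(cp=None, leaf=100.0, stem=100.0, root=50.0,
                  storage=0.0, dvs=0.5):
    cp = cp or CropParams()
    state = sow("wheat")
    state.emerged = True
    state.dvs = dvs
    state.mass.update(leaf=leaf, stem=stem, root=root, storage=storage)
    state.root_depth = 400.0
    update_lai(state, cp)
    return state


class TestDevelop:
    def test_sub_base_temperature_day_gives_no_progress(self):
        cp = CropParams(vern_days=0.0, photo_base=0.0, photo_sat=0.1)
        state = emerged_wheat(cp)
        dvs0 = state.dvs
        develop(state, day(tmin=-5.0, tmax=-1.0), 51.8, cp)
        assert state.dvs == dvs0

    def test_thermal_time_reaches_anthesis_on_schedule(self):
        cp = CropParams(vern_days=0.0, photo_base=0.0, photo_sat=0.1,
                        tsum1=1000.0)
        state = emerged_wheat(cp, dvs=0.0)
        days = 0
        while state.dvs < 1.0 and days < 200:
            develop(state, day(tmin=20.0, tmax=20.0), 51.8, cp)
            days += 1
        assert days == math.ceil(1000.0 / 20.0)

    def test_grass_never_reaches_flowering(self):
        cp = grass_params()
        state = sow("grass")
        state.emerged = True
        state.dvs = 0.998
        for _ in range(100):
            develop(state, day(tmin=20.0, tmax=25.0), 51.8, cp)
        assert state.dvs < 1.0

    def test_root_depth_grows_12_mm_per_day_to_maximum(self):
        cp = CropParams(vern_days=0.0, photo_base=0.0, photo_sat=0.1)
        state = emerged_wheat(cp)
        state.root_depth = 600.0
        develop(state, day(), 51.8, cp)
        assert state.root_depth == 612.0
        for _ in range(20):
            develop(state, day(), 51.8, cp)
        assert state.root_depth == cp.max_root_depth


class TestDailyGrowth:
    def test_any_zero_factor_stops_growth(self):
        cp = CropParams()
        for w, n, p in ((0, 1, 1), (1, 0, 1), (1, 1, 0)):
            state = emerged_wheat(cp)
            assert daily_growth(state, day(), w, n, p, cp) == 0.0

    def test_closed_canopy_growth_is_q_times_lue(self):
        # Q = 0.5 * 20 MJ * ~1.0 interception = 10 MJ PAR; dB = 10 * 3 = 30
        cp = CropParams()
        state = emerged_wheat(cp, leaf=2000.0)   # LAI 44 -> full cover
        db = daily_growth(state, day(rad=20.0), 1.0, 1.0, 1.0, cp)
        assert db == pytest.approx(30.0, rel=1e-9)

    def test_grass_lue_reduced_at_high_radiation(self):
        cp = grass_params()
        state = sow("grass")
        state.emerged = True
        state.mass["leaf"] = 2000.0
        update_lai(state, cp)
        db_hi = daily_growth(state, day(rad=40.0, tmin=12, tmax=18), 1.0,
                             1.0, 1.0, cp)
        state2 = sow("grass")
        state2.emerged = True
        state2.mass["leaf"] = 2000.0
        update_lai(state2, cp)
        db_lo = daily_growth(state2, day(rad=10.0, tmin=12, tmax=18), 1.0,
                             1.0, 1.0, cp)
        assert db_hi == pytest.approx(db_lo * 4.0 * 0.33, rel=1e-9)

    def test_partition_fractions_route_mass_to_storage_after_anthesis(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=1.2, leaf=500.0)
        daily_growth(state, day(rad=20.0), 1.0, 1.0, 1.0, cp)
        assert state.mass["storage"] > 0.0
        assert state.mass["root"] == 50.0    # nothing routed to roots


class TestWaterStress:
    def test_plateau_between_minus5_and_minus40_kpa(self):
        cp = CropParams()
        layer = make_layer()
        layer.water = 0.5 * (layer.anchors.theta_a
                             + layer.anchors.theta_d) * layer.thickness
        assert water_stress_factor(layer, cp) == 1.0

    def test_midway_to_wilting_gives_half(self):
        cp = CropParams()
        layer = make_layer()
        a = layer.anchors
        layer.water = 0.5 * (a.theta_d + a.theta_wp) * layer.thickness
        assert water_stress_factor(layer, cp) == pytest.approx(0.5,
                                                               rel=1e-9)

    def test_grass_floor_at_wilting_point(self):
        cp = grass_params()
        layer = make_layer()
        layer.water = layer.anchors.theta_wp * layer.thickness
        assert water_stress_factor(layer, cp) == pytest.approx(0.4,
                                                               rel=1e-9)

    def test_grass_unstressed_at_saturation(self):
        cp = grass_params()
        layer = make_layer()
        layer.water = layer.sat_mm
        assert water_stress_factor(layer, cp) == 1.0

    def test_no_demand_gives_unit_reduction_factor(self, profile):
        w_rf, atran = water_stress(profile, 0.0, [1.0, 0.0, 0.0],
                                   CropParams())
        assert w_rf == 1.0 and sum(atran) == 0.0

    def test_unstressed_profile_meets_demand(self, profile):
        cp = CropParams()
        for layer in profile:
            a = layer.anchors
            layer.water = 0.5 * (a.theta_a + a.theta_d) * layer.thickness
        w_rf, atran = water_stress(profile, 3.0, [0.6, 0.3, 0.1], cp)
        assert w_rf == pytest.approx(1.0, rel=1e-9)
        assert sum(atran) == pytest.approx(3.0, rel=1e-9)

    def test_actual_transpiration_never_exceeds_potential(self, profile):
        cp = CropParams()
        for layer in profile:
            a = layer.anchors
            layer.water = 0.7 * (a.theta_d + a.theta_wp) / 2 \
                * layer.thickness
        w_rf, atran = water_stress(profile, 5.0, [0.5, 0.3, 0.2], cp)
        assert sum(atran) <= 5.0 + 1e-12
        assert 0.0 <= w_rf <= 1.0


class TestRootDistribution:
    def test_shallow_roots_confined_to_layer_one(self, profile):
        assert root_distribution(100.0, profile) == [1.0, 0.0, 0.0]

    def test_full_depth_exponential_profile(self, profile):
        # a = -ln(0.02)/690; independent evaluation of the layer integrals
        a = -math.log(0.02) / 690.0
        masses = [math.exp(-a * 0.0) - math.exp(-a * 230.0),
                  math.exp(-a * 230.0) - math.exp(-a * 460.0),
                  math.exp(-a * 460.0) - math.exp(-a * 690.0)]
        expected = [m / sum(masses) for m in masses]
        got = root_distribution(690.0, profile)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx([0.743, 0.202, 0.055], abs=1.5e-3)

    def test_fractions_sum_to_one_and_decrease_with_depth(self, profile):
        for depth in (150.0, 300.0, 500.0, 690.0):
            f = root_distribution(depth, profile)
            assert sum(f) == pytest.approx(1.0, abs=1e-12)
            assert f[0] >= f[1] >= f[2]


class TestNutritionIndices:
    def test_unstressed_at_organ_maxima(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=0.0)
        nmax = n_max_prop_leaf(0.0, cp)
        state.n["leaf"] = state.mass["leaf"] * nmax
        state.n["stem"] = state.mass["stem"] * 0.5 * nmax
        pmax = p_max_prop_leaf(0.0, cp)
        state.p["leaf"] = state.mass["leaf"] * pmax
        state.p["stem"] = state.mass["stem"] * 0.5 * pmax
        n_ni, p_ni = nutrition_indices(state, cp)
        assert n_ni == 1.0 and p_ni == 1.0

    def test_wheat_leaf_n_maximum_at_emergence(self):
        # 0.046 * e^0 + 0.014 = 0.060
        assert n_max_prop_leaf(0.0, CropParams()) == pytest.approx(0.060,
                                                                   rel=1e-9)

    def test_half_headroom_gives_index_half(self):
        cp = CropParams()
        state = emerged_wheat(cp, leaf=100.0, stem=100.0, dvs=0.0)
        nmax_leaf = n_max_prop_leaf(0.0, cp)
        max_conc = (100.0 * nmax_leaf + 100.0 * 0.5 * nmax_leaf) / 200.0
        target = cp.n_res + 0.5 * (max_conc - cp.n_res)
        state.n["leaf"] = target * 200.0   # all in leaf; index uses the sum
        n_ni, _ = nutrition_indices(state, cp)
        assert n_ni == pytest.approx(0.5, rel=1e-9)

    def test_no_stress_before_emergence(self):
        cp = CropParams()
        state = sow("wheat")
        assert nutrition_indices(state, cp) == (1.0, 1.0)

    def test_wheat_p_max_interpolates_between_knots(self):
        cp = CropParams()
        assert p_max_prop_leaf(0.0, cp) == 0.0066
        assert p_max_prop_leaf(0.35, cp) == pytest.approx(
            0.0066 + (0.0036 - 0.0066) * 0.5, rel=1e-9)
        assert p_max_prop_leaf(1.5, cp) == 0.0009


class TestDemandAndSenescence:
    def test_post_anthesis_demand_is_zero(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=1.1)
        assert nutrient_demand(state, cp) == (0.0, 0.0)

    def test_demand_zero_at_organ_maxima(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=0.3)
        nmax = n_max_prop_leaf(0.3, cp)
        pmax = p_max_prop_leaf(0.3, cp)
        state.n.update(leaf=state.mass["leaf"] * nmax,
                       stem=state.mass["stem"] * 0.5 * nmax,
                       root=state.mass["root"] * cp.n_max_root)
        state.p.update(leaf=state.mass["leaf"] * pmax,
                       stem=state.mass["stem"] * 0.5 * pmax,
                       root=state.mass["root"] * cp.p_max_root)
        assert nutrient_demand(state, cp) == (0.0, 0.0)

    def test_no_root_death_before_threshold_stage(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=1.0, root=100.0)
        ret = senesce_and_return(state, day(), 1.0, cp)
        assert state.mass["root"] == 100.0

    def test_late_season_root_death_rate(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=1.6, root=100.0)
        senesce_and_return(state, day(), 1.0, cp)
        assert state.mass["root"] == pytest.approx(98.0, rel=1e-12)

    def test_mass_conservation_of_senescence(self):
        cp = CropParams()
        state = emerged_wheat(cp, dvs=1.6)
        state.n.update(leaf=2.0, stem=1.0, root=0.5)
        state.dead_leaf, state.dead_leaf_n = 20.0, 0.4
        n0 = state.total_n
        ret = senesce_and_return(state, day(tmax=35.0), 0.5, cp)
        assert state.total_n + ret.n / 10.0 == pytest.approx(n0, rel=1e-9)


class TestCutGrazeHarvest:
    def test_cut_respects_biomass_floor(self):
        cp = grass_params()
        state = sow("grass")
        state.emerged = True
        state.mass.update(leaf=200.0, stem=100.0)
        rem = cut_or_graze(state, None, cp)
        assert rem.dry_matter == pytest.approx(250.0, rel=1e-12)
        assert state.above_ground == pytest.approx(50.0, rel=1e-12)

    def test_cut_below_floor_removes_nothing(self):
        cp = grass_params()
        state = sow("grass")
        state.emerged = True
        state.mass["leaf"] = 40.0
        rem = cut_or_graze(state, None, cp)
        assert rem.dry_matter == 0.0

    def test_cut_on_wheat_rejected(self):
        with pytest.raises(ValueError):
            cut_or_graze(emerged_wheat(), None, CropParams())

    def test_beef_grazing_manure_rates(self):
        gp = GrazingParams()
        c, n = grazing_returns("beef", 2.0, gp)
        assert c == pytest.approx(8.06, rel=1e-12)
        assert n == pytest.approx(0.44, rel=1e-12)

    def test_harvest_yield_at_85_percent_dry_matter(self):
        cp = CropParams()
        state = emerged_wheat(cp, storage=510.0, dvs=2.0)
        state.n["storage"] = 10.0
        result = harvest(state, cp)
        assert result.yield_t_ha == pytest.approx(6.0, rel=1e-9)
        assert result.grain_n == pytest.approx(100.0, rel=1e-12)

    def test_harvest_without_storage_yields_zero(self):
        cp = CropParams()
        state = emerged_wheat(cp, storage=0.0, dvs=2.0)
        assert harvest(state, cp).yield_t_ha == 0.0

    def test_harvest_returns_roots_to_soil(self):
        cp = CropParams()
        state = emerged_wheat(cp, storage=500.0, root=80.0, dvs=2.0)
        state.n["root"] = 1.0
        result = harvest(state, cp)
        assert result.residue.c == pytest.approx(80.0 * 0.45 * 10.0,
                                                 rel=1e-12)
        assert result.residue.n == pytest.approx(10.0, rel=1e-12)


class TestYieldMonotoneInLUE:
    def test_more_efficient_crop_yields_no_less(self):
        import warnings

        from landsim.fixtures import build_fixture_farm
        from landsim.grid import run
        from landsim.weather import synth_weather

        warnings.filterwarnings("ignore")
        weather = synth_weather(3, 51.8, 4, start_year=2001)
        yields = []
        for lue in (2.0, 3.0, 3.5):
            params = Params()
            params.wheat.lue = lue
            grid, events = build_fixture_farm(
                "broadbalk_like_plot", n_dose=192.0, years=2,
                start_year=2001, params=params)
            _, harvests, _ = run(grid, weather, events)
            yields.append(sum(h.yield_t_ha for h in harvests))
        assert yields == sorted(yields)
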