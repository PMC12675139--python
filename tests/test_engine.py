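import numpy as np
import pandas as pd
import pytest

from maizegap.engine import (
    CO2_REFERENCE,
    MGMT_YA,
    MGMT_YP,
    MGMT_YW,
    FertilityFactors,
    ManagementConfig,
    SoilProfile,
    calibrate_fertility,
    f_co2,
    simulate_season,
)

from conftest import constant_season


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"theta_wp": 0.4},  # wp above fc
            {"theta_sat": 0.2},  # sat below fc
            {"max_root_depth": -1.0},
        ],
    )
    def test_soil_invariants(self, kw):
        with pytest.raises(ValueError):
            SoilProfile(**kw)

    def test_management_invariants(self):
        with pytest.raises(ValueError):
            ManagementConfig(fertility_stress=120.0)
        with pytest.raises(ValueError):
            ManagementConfig(irrigation="sprinkler")
        with pytest.raises(ValueError):
            ManagementConfig(irrigation_trigger_fraction=0.0)
        assert ManagementConfig(fertility_stress=30.0).brel == 70.0


class TestFertilityCalibration:
    def test_no_stress_is_identity(self, crop, soil):
        assert calibrate_fertility(crop, soil, 100.0) == FertilityFactors()

    @pytest.mark.parametrize("brel", [70.0, 50.0])
    def test_reference_biomass_ratio_recovered(self, crop, soil, brel, sowing):
        factors = calibrate_fertility(crop, soil, brel)
        season = constant_season()
        stressed = simulate_season(season, crop, soil, MGMT_YW, sowing, fertility=factors)
        free = simulate_season(season, crop, soil, MGMT_YW, sowing)
        assert stressed.biomass / free.biomass == pytest.approx(brel / 100.0, abs=0.005)

    def test_stress_factors_decrease_with_target(self, crop, soil):
        f70 = calibrate_fertility(crop, soil, 70.0)
        f50 = calibrate_fertility(crop, soil, 50.0)
        assert f50.f_ccx < f70.f_ccx < 1.0
        assert f50.f_wp < f70.f_wp < 1.0

    def test_out_of_range_target_rejected(self, crop, soil):
        with pytest.raises(ValueError):
            calibrate_fertility(crop, soil, 0.0)

    def test_unattainable_target_reports_bracket(self, crop, soil):
        with pytest.raises(ValueError, match=r"bracket \[0, 1\]"):
            calibrate_fertility(crop, soil, 5.0)


class TestCo2Response:
    def test_normalised_at_reference(self):
        assert f_co2(CO2_REFERENCE) == pytest.approx(1.0)

    def test_muted_c4_gain_at_550ppm(self):
        assert 1.0 < f_co2(550.0) <= 1.10

    def test_monotone_over_plausible_range(self):
        co2 = np.linspace(300.0, 1000.0, 200)
        vals = [f_co2(c) for c in co2]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            f_co2(0.0)


class TestSeasonSimulation:
    def test_brel_design_feature_under_non_limiting_water(self, crop, soil, benign_season, sowing):
        ya = simulate_season(benign_season, crop, soil, MGMT_YA, sowing)
        yw = simulate_season(benign_season, crop, soil, MGMT_YW, sowing)
        assert ya.yield_dry / yw.yield_dry == pytest.approx(0.700, abs=0.005)

    def test_net_irrigation_keeps_depletion_at_trigger(self, crop, soil, drought_season, sowing):
        yp = simulate_season(drought_season, crop, soil, MGMT_YP, sowing)
        assert yp.irrigation_sum > 0.0
        assert yp.max_raw_depletion_fraction <= 0.5 + 1e-9

    def test_no_water_no_transpiration_no_yield(self, crop, drought_season, sowing):
        dry = SoilProfile(initial_fraction_fc=SoilProfile().theta_wp / SoilProfile().theta_fc)
        res = simulate_season(drought_season, crop, dry, MGMT_YA, sowing)
        assert res.transpiration_sum == 0.0
        assert res.yield_dry == 0.0

    def test_elevated_co2_increases_biomass(self, crop, soil, benign_season, sowing):
        lo = benign_season.copy()
        lo["co2"] = 360.0
        hi = benign_season.copy()
        hi["co2"] = 700.0
        b_lo = simulate_season(lo, crop, soil, MGMT_YW, sowing).biomass
        b_hi = simulate_season(hi, crop, soil, MGMT_YW, sowing).biomass
        assert b_hi >= b_lo

    def test_water_balance_closes(self, crop, soil, shallow_soil, benign_season, drought_season, sowing):
        cases = [
            (benign_season, soil, MGMT_YA),
            (benign_season, soil, MGMT_YP),
            (drought_season, shallow_soil, MGMT_YA),
            (drought_season, shallow_soil, MGMT_YP),
        ]
        for season, sp, mgmt in cases:
            res = simulate_season(season, crop, sp, mgmt, sowing)
            assert abs(res.water_balance_residual) < 0.01

    def test_adding_water_never_decreases_yield(self, crop, shallow_soil, drought_season, sowing):
        yields = []
        for extra in (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0):
            season = drought_season.copy()
            season["precip"] = extra
            yields.append(
                simulate_season(season, crop, shallow_soil, MGMT_YA, sowing).yield_dry
            )
        assert all(b >= a - 1e-9 for a, b in zip(yields, yields[1:]))

    def test_irrigation_never_decreases_yield(self, crop, shallow_soil, drought_season, sowing):
        rainfed = simulate_season(drought_season, crop, shallow_soil, MGMT_YW, sowing)
        irrigated = simulate_season(drought_season, crop, shallow_soil, MGMT_YP, sowing)
        assert irrigated.yield_dry >= rainfed.yield_dry

    def test_potential_regime_dominates(self, crop, shallow_soil, drought_season, sowing):
        ya = simulate_season(drought_season, crop, shallow_soil, MGMT_YA, sowing)
        yw = simulate_season(drought_season, crop, shallow_soil, MGMT_YW, sowing)
        yp = simulate_season(drought_season, crop, shallow_soil, MGMT_YP, sowing)
        assert yp.yield_dry >= yw.yield_dry
        assert yp.yield_dry >= ya.yield_dry

    def test_terminal_drought_reverses_fertility_advantage(
        self, crop, shallow_soil, drought_season, sowing
    ):
        """The unstressed crop's larger canopy exhausts the store before
        flowering, collapsing grain set; the fertility-stressed crop conserves
        water and ends above it (the negative water-limited gap case)."""
        ya = simulate_season(drought_season, crop, shallow_soil, MGMT_YA, sowing)
        yw = simulate_season(drought_season, crop, shallow_soil, MGMT_YW, sowing)
        assert yw.yield_dry < ya.yield_dry

    def test_engine_is_deterministic(self, crop, soil, benign_season, sowing):
        a = simulate_season(benign_season, crop, soil, MGMT_YA, sowing)
        b = simulate_season(benign_season, crop, soil, MGMT_YA, sowing)
        assert a.yield_dry == b.yield_dry
        assert a.etc_sum == b.etc_sum

    def test_incomplete_season_reports_zero_yield(self, crop, soil):
        cold = constant_season(tav=10.0)  # 2 GDD/day: cannot reach 1122
        res = simulate_season(cold, crop, soil, MGMT_YA, pd.Timestamp("2001-05-01"))
        assert not res.complete
        assert res.yield_dry == 0.0
        assert res.cycle_length is None and res.maturity_date is None

    def test_yield_never_exceeds_biomass(self, crop, soil, benign_season, sowing):
        res = simulate_season(benign_season, crop, soil, MGMT_YA, sowing)
        assert 0.0 < res.yield_dry <= res.biomass

    def test_daily_diagnostics_states_bounded(self, crop, soil, benign_season, sowing):
        res = simulate_season(benign_season, crop, soil, MGMT_YA, sowing, diagnostics=True)
        d = res.daily
        factors = calibrate_fertility(crop, soil, 70.0)
        assert d["cc"].between(0.0, crop.ccx * factors.f_ccx + 1e-12).all()
        assert d["ks_sto"].between(0.0, 1.0).all()
        assert d["ks_exp"].between(0.0, 1.0).all()
        assert d["hi"].between(0.0, crop.hi0).all()
        assert d["cum_gdd"].is_monotonic_increasing

    def test_missing_eto_rejected(self, crop, soil, sowing):
        season = constant_season().drop(columns=["eto"])
        with pytest.raises(ValueError, match="eto"):
            simulate_season(season, crop, soil, MGMT_YA, sowing)

    def test_sowing_outside_series_rejected(self, crop, soil, benign_season):
        with pytest.raises(ValueError):
            simulate_season(benign_season, crop, soil, MGMT_YA, pd.Timestamp("1999-05-01"))
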