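import numpy as np
import pandas as pd
import pytest

from maizegap.phenology import (
    STAGES,
    CropParameters,
    SowingRule,
    cycle_complete,
    find_sowing_date,
    stage_schedule,
)

from conftest import weather_frame


def year_tmin(tmin_by_day, year=2001):
    """Whole-year frame with a prescribed tmin series (degC, padded)."""
    df = weather_frame([15.0], year=year)
    df["tmin"] = float(tmin_by_day) if np.isscalar(tmin_by_day) else np.resize(
        np.asarray(tmin_by_day, dtype=float), len(df)
    )
    return df


class TestCropParameterInvariants:
    def test_defaults_are_valid(self):
        crop = CropParameters()
        assert crop.gdd_maturity == 1122.0
        assert crop.tbase == 8.0 and crop.tupper == 30.0

    @pytest.mark.parametrize(
        "kw",
        [
            {"gdd_emergence": 700.0},  # emergence after max canopy
            {"gdd_senescence": 1200.0},  # senescence after maturity
            {"gdd_flowering": 1000.0},  # flowering after senescence
            {"tbase": 31.0},
            {"ccx": 1.4},
            {"hi0": 0.0},
            {"cgc": -0.01},
        ],
    )
    def test_violations_rejected(self, kw):
        with pytest.raises(ValueError):
            CropParameters(**kw)


class TestSowingDate:
    def test_warm_since_january_sows_on_window_opening(self):
        # tmin above threshold all year: the 4-day run ending 1 March is
        # satisfied by late-February days, so sowing is the first window day
        df = year_tmin(9.0)
        assert find_sowing_date(df) == pd.Timestamp("2001-03-01")

    def test_cold_spring_falls_back_to_window_end(self):
        df = year_tmin(5.0)
        assert find_sowing_date(df) == pd.Timestamp("2001-04-29")

    def test_three_day_warm_spell_is_not_enough(self):
        tmin = np.full(365, 5.0)
        # 10-12 March warm only: persistence of 4 never reached
        doy = pd.date_range("2001-01-01", "2001-12-31").dayofyear
        warm = (doy >= pd.Timestamp("2001-03-10").dayofyear) & (
            doy <= pd.Timestamp("2001-03-12").dayofyear
        )
        tmin[warm] = 9.0
        assert find_sowing_date(year_tmin(tmin)) == pd.Timestamp("2001-04-29")

    def test_first_qualifying_run_inside_window(self):
        # cold until 20 March, then warm: sowing on the 4th warm day
        tmin = np.full(365, 5.0)
        start = pd.Timestamp("2001-03-20").dayofyear - 1
        tmin[start:] = 9.0
        assert find_sowing_date(year_tmin(tmin)) == pd.Timestamp("2001-03-23")

    def test_threshold_is_strict(self):
        # tmin exactly at the threshold never qualifies
        assert find_sowing_date(year_tmin(8.0)) == pd.Timestamp("2001-04-29")

    def test_sowing_always_inside_window(self):
        rng = np.random.default_rng(0)
        start = pd.Timestamp("2001-03-01")
        end = pd.Timestamp("2001-04-29")
        for _ in range(20):
            tmin = rng.normal(7.0, 4.0, 365)
            d = find_sowing_date(year_tmin(tmin))
            assert start <= d <= end

    def test_missing_window_days_rejected(self):
        df = year_tmin(9.0).iloc[:60]  # ends in February
        with pytest.raises(ValueError, match="window"):
            find_sowing_date(df)

    def test_rule_invariants(self):
        with pytest.raises(ValueError):
            SowingRule(persistence=0)
        with pytest.raises(ValueError):
            SowingRule(window_start=(5, 1), window_end=(4, 29))


class TestStageSchedule:
    def test_constant_rate_maturity_day(self, crop):
        # 11 GDD/day: maturity on day ceil(1122/11) = 102 after sowing
        df = weather_frame([19.0])
        sowing = pd.Timestamp("2001-05-01")
        sched = stage_schedule(df, sowing, crop)
        mat = sched.index[sched["cum_gdd"] >= crop.gdd_maturity][0]
        assert (mat - sowing).days == 102
        assert sched.loc[mat, "stage"] == "mature"

    def test_no_accumulation_below_base(self, crop):
        df = weather_frame([7.0])
        sched = stage_schedule(df, pd.Timestamp("2001-05-01"), crop)
        assert (sched["cum_gdd"] == 0).all()
        assert (sched["stage"] == "pre-emergence").all()

    def test_stage_labels_are_monotone(self, crop):
        df = weather_frame(15.0 + 8.0 * np.sin(np.linspace(0, 3, 365)))
        sched = stage_schedule(df, pd.Timestamp("2001-04-15"), crop)
        order = {s: i for i, s in enumerate(STAGES)}
        ranks = sched["stage"].map(order).to_numpy()
        assert (np.diff(ranks) >= 0).all()

    def test_uniform_warming_matures_strictly_earlier(self, crop):
        base = weather_frame([19.0])
        warm = weather_frame([21.0])
        sowing = pd.Timestamp("2001-05-01")
        m0 = stage_schedule(base, sowing, crop)
        m1 = stage_schedule(warm, sowing, crop)
        d0 = m0.index[m0["cum_gdd"] >= crop.gdd_maturity][0]
        d1 = m1.index[m1["cum_gdd"] >= crop.gdd_maturity][0]
        assert d1 < d0

    def test_sowing_outside_series_rejected(self, crop):
        with pytest.raises(ValueError):
            stage_schedule(weather_frame([19.0]), pd.Timestamp("2005-05-01"), crop)


class TestCycleComplete:
    def _craft(self, total_gdd, days=64):
        """Season accumulating exactly total_gdd from sowing, then cold.

        64 equal daily increments keep the partial sums exact in binary
        floating point when total_gdd/64 is a dyadic rational (1122/64 is),
        so the inclusive completion boundary can be probed reliably.
        """
        tav = np.zeros(365)
        # sowing at index 120; accumulation starts the day after
        tav[121: 121 + days] = 8.0 + total_gdd / days
        return weather_frame(tav)

    def test_just_below_threshold_is_incomplete(self, crop):
        df = self._craft(1121.9)
        sowing = df.index[120]
        complete, length = cycle_complete(df, sowing, crop)
        assert not complete and length is None

    def test_exact_threshold_is_complete(self, crop):
        df = self._craft(1122.0)
        sowing = df.index[120]
        complete, length = cycle_complete(df, sowing, crop)
        assert complete
        assert length is not None and length > 0

    def test_cycle_length_is_emergence_to_maturity(self, crop):
        df = weather_frame([19.0])  # 11 GDD/day
        sowing = pd.Timestamp("2001-05-01")
        complete, length = cycle_complete(df, sowing, crop)
        assert complete
        # emergence at ceil(78.5/11)=8 days, maturity at 102 days after sowing
        assert length == 102 - 8

    def test_warming_never_lengthens_the_cycle(self, crop):
        rng = np.random.default_rng(1)
        for _ in range(10):
            tav = np.clip(rng.normal(17.0, 3.0, 365), 9.0, 26.0)
            base = weather_frame(tav)
            warm = weather_frame(tav + 2.0)  # still below tupper
            sowing = pd.Timestamp("2001-05-01")
            cb, lb = cycle_complete(base, sowing, crop)
            cw, lw = cycle_complete(warm, sowing, crop)
            if cb:
                assert cw
                assert lw <= lb

    def test_requires_coverage_to_year_end(self, crop):
        df = weather_frame([19.0]).iloc[:200]
        with pytest.raises(ValueError):
            cycle_complete(df, pd.Timestamp("2001-05-01"), crop)
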