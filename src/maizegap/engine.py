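"""Daily water-driven crop growth for one cell-year under a management regime.

A deliberately minimal water-driven core in the AquaCrop tradition, not a port
of it: a single-layer root-zone bucket with overflow drainage, logistic canopy
cover driven by growing degree days, transpiration/evaporation partitioning by
canopy cover, linear root-zone depletion stress coefficients, biomass from
normalised water productivity times relative transpiration with a muted C4
CO2 response, and a harvest index that builds through grain filling and is
penalised by stomatal water stress during the flowering window.

Management regimes differ only in the fertility-stress level and the
irrigation mode: actual yield (Ya) carries the default 30% fertility stress,
water-limited yield (Yw) removes it, and potential yield (Yp) additionally
triggers net irrigation whenever root-zone depletion would exceed half of the
readily available water.

The soil store is simulated over the full effective rooting depth from day
one, while depletion, total and readily available water for the stress
coefficients are evaluated over the current (GDD-deepening) root depth; root
deepening therefore accesses water already in the budget.  The seasonal water
balance closes exactly: precip + irrigation + storage drawdown =
transpiration + evaporation + drainage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .phenology import CropParameters

__all__ = [
    "SoilProfile",
    "ManagementConfig",
    "SeasonResult",
    "FertilityFactors",
    "f_co2",
    "calibrate_fertility",
    "simulate_season",
    "CO2_REFERENCE",
]

CO2_REFERENCE = 369.41  # ppm, Mauna-Loa-era normalisation point
ZR_MIN = 0.30  # m, root depth at sowing

# Fertility-stress decomposition: one intensity x in [0, 1] maps to joint
# reductions of the canopy ceiling, the canopy growth rate and the water
# productivity.  The canopy share is deliberately large so that a
# fertility-stressed crop builds a smaller canopy and conserves soil water --
# the mechanism that makes Yw < Ya reachable in dry years.
_CCX_SHARE = 0.50
_CGC_SHARE = 0.30
_WP_SHARE = 0.35


@dataclass(frozen=True)
class SoilProfile:
    """Single-layer soil hydraulics [m3/m3] and rooting geometry.

    ``initial_fraction_fc`` sets the start-of-season moisture as a fraction of
    field capacity (clamped to the wilting-point..saturation band); the
    default 1.0 starts the profile at field capacity, the usual state of
    European soils at the end of winter.  ``rew`` is the readily evaporable
    water of the soil surface layer [mm].
    """

    theta_sat: float = 0.46
    theta_fc: float = 0.33
    theta_wp: float = 0.15
    max_root_depth: float = 1.0
    initial_fraction_fc: float = 1.0
    rew: float = 9.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wp < self.theta_fc < self.theta_sat < 1.0:
            raise ValueError("require 0 < theta_wp < theta_fc < theta_sat < 1")
        if self.max_root_depth <= 0.0:
            raise ValueError("max_root_depth must be positive")
        if self.initial_fraction_fc <= 0.0:
            raise ValueError("initial_fraction_fc must be positive")
        if self.rew <= 0.0:
            raise ValueError("rew must be positive")


@dataclass(frozen=True)
class ManagementConfig:
    """Fertility-stress level [%] and irrigation mode defining a regime."""

    fertility_stress: float = 30.0
    irrigation: str = "off"  # "off" | "net-requirement"
    irrigation_trigger_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fertility_stress <= 100.0:
            raise ValueError("fertility_stress must be in [0, 100]")
        if self.irrigation not in ("off", "net-requirement"):
            raise ValueError("irrigation must be 'off' or 'net-requirement'")
        if not 0.0 < self.irrigation_trigger_fraction <= 1.0:
            raise ValueError("irrigation_trigger_fraction must be in (0, 1]")

    @property
    def brel(self) -> float:
        """Relative biomass production [%] implied by the fertility stress."""
        return 100.0 - self.fertility_stress


# Regime presets
MGMT_YA = ManagementConfig(fertility_stress=30.0, irrigation="off")
MGMT_YW = ManagementConfig(fertility_stress=0.0, irrigation="off")
MGMT_YP = ManagementConfig(fertility_stress=0.0, irrigation="net-requirement")


@dataclass(frozen=True)
class FertilityFactors:
    """Joint canopy/productivity reductions representing soil-fertility stress."""

    f_ccx: float = 1.0
    f_cgc: float = 1.0
    f_wp: float = 1.0
    intensity: float = 0.0

    @classmethod
    def from_intensity(cls, x: float) -> "FertilityFactors":
        if not 0.0 <= x <= 1.0:
            raise ValueError("stress intensity must be in [0, 1]")
        return cls(
            f_ccx=1.0 - _CCX_SHARE * x,
            f_cgc=1.0 - _CGC_SHARE * x,
            f_wp=1.0 - _WP_SHARE * x,
            intensity=x,
        )


@dataclass
class SeasonResult:
    """Outcome of one simulated cell-year season."""

    sowing_date: pd.Timestamp
    maturity_date: pd.Timestamp | None
    complete: bool
    cycle_length: int | None
    yield_dry: float  # ton/ha
    biomass: float  # ton/ha
    etc_sum: float  # mm, germination -> maturity
    transpiration_sum: float  # mm, whole simulated season
    evaporation_sum: float  # mm
    irrigation_sum: float  # mm
    precip_sum: float  # mm over simulated days
    drainage_sum: float  # mm
    storage_change: float  # mm, end minus start
    max_raw_depletion_fraction: float
    harvest_index: float
    daily: pd.DataFrame | None = None

    @property
    def water_balance_residual(self) -> float:
        """precip + irrigation - Tr - E - drainage - storage change [mm]."""
        return (
            self.precip_sum
            + self.irrigation_sum
            - self.transpiration_sum
            - self.evaporation_sum
            - self.drainage_sum
            - self.storage_change
        )


def f_co2(co2: float, beta: float = 0.08, scale: float = 350.0) -> float:
    """Biomass multiplier for atmospheric CO2, normalised to 1 at 369.41 ppm.

    Saturating exponential form with a muted asymptote appropriate for a C4
    crop (maize gains little from CO2 fertilisation compared with C3 crops):
    ``1 + beta * (1 - exp(-(co2 - ref)/scale))``, continuous and
    non-decreasing in co2.
    """
    if co2 <= 0.0:
        raise ValueError("co2 must be positive")
    return 1.0 + beta * (1.0 - math.exp(-(co2 - CO2_REFERENCE) / scale))


def _canopy_adjusted(cc: float) -> float:
    """Effective transpiring cover with micro-advective enhancement."""
    ccs = 1.72 * cc - cc * cc + 0.30 * cc**3
    return min(max(ccs, 0.0), 1.0)


def simulate_season(
    weather: pd.DataFrame,
    crop: CropParameters,
    soil: SoilProfile,
    mgmt: ManagementConfig,
    sowing: pd.Timestamp,
    eto: pd.Series | None = None,
    fertility: FertilityFactors | None = None,
    diagnostics: bool = False,
) -> SeasonResult:
    """Run the daily loop from sowing until maturity or 31 December.

    ``weather`` must carry columns ``tav``, ``precip`` and ``co2``; reference
    evapotranspiration comes from ``eto`` (or a pre-computed ``eto`` column).
    ``fertility`` overrides the factors otherwise calibrated from
    ``mgmt.fertility_stress`` (used internally by the calibration itself).
    """
    if eto is None:
        if "eto" not in weather.columns:
            raise ValueError("provide eto or a weather frame with an 'eto' column")
        eto = weather["eto"]
    idx = pd.DatetimeIndex(weather.index)
    if sowing not in idx:
        raise ValueError("sowing date not inside the weather series")
    year_end = pd.Timestamp(sowing.year, 12, 31)
    season_end = min(year_end, idx[-1])

    if fertility is None:
        fertility = calibrate_fertility(crop, soil, mgmt.brel)

    season = weather.loc[sowing:season_end]
    dates = season.index
    tav = season["tav"].to_numpy(dtype=float).tolist()
    precip = season["precip"].to_numpy(dtype=float).tolist()
    co2 = season["co2"].to_numpy(dtype=float).tolist()
    eto_l = eto.loc[sowing:season_end].to_numpy(dtype=float).tolist()
    n = len(dates)

    zmax = min(soil.max_root_depth, crop.max_root_depth)
    zr_min = min(ZR_MIN, zmax)
    theta_fc, theta_wp, theta_sat = soil.theta_fc, soil.theta_wp, soil.theta_sat
    theta0 = min(max(soil.initial_fraction_fc * theta_fc, theta_wp), theta_sat)
    w = theta0 * zmax * 1000.0  # mm stored over the full column
    w0 = w
    w_sat = theta_sat * zmax * 1000.0
    w_wp_col = theta_wp * zmax * 1000.0

    ccx_eff = crop.ccx * fertility.f_ccx
    cgc_eff = crop.cgc * fertility.f_cgc
    irrigate = mgmt.irrigation == "net-requirement"
    trig = mgmt.irrigation_trigger_fraction
    flow_lo = crop.gdd_flowering
    flow_hi = crop.gdd_flowering + crop.gdd_flowering_span
    hi_span = crop.gdd_maturity - crop.gdd_flowering

    cum_gdd = 0.0
    cc = 0.0
    emerged = False
    biomass = 0.0  # g/m2
    hi = 0.0
    wsurf = soil.rew  # surface evaporable store starts wet
    ks_flow_sum = 0.0
    n_flow = 0
    tr_sum = e_sum = irr_sum = p_sum = drain_sum = etc_season = 0.0
    max_frac = 0.0
    mat_i: int | None = None
    emerge_i: int | None = None
    rows = [] if diagnostics else None

    for i in range(n):
        g = 0.0 if i == 0 else max(0.0, min(tav[i], crop.tupper) - crop.tbase)
        cum_gdd += g
        p = precip[i]
        p_sum += p
        w += p
        if w > w_sat:
            drain_sum += w - w_sat
            w = w_sat
        wsurf = min(soil.rew, wsurf + p)

        zr = zr_min + (zmax - zr_min) * min(1.0, cum_gdd / crop.gdd_max_canopy)
        theta = w / (zmax * 1000.0)
        taw = (theta_fc - theta_wp) * zr * 1000.0
        raw_sto = crop.p_upper * taw
        raw_exp = crop.p_lower * taw
        dr = max(0.0, (theta_fc - theta) * zr * 1000.0)
        ks_sto = 1.0 if dr <= raw_sto else max(0.0, (taw - dr) / (taw - raw_sto))
        ks_exp = 1.0 if dr <= raw_exp else max(0.0, (taw - dr) / (taw - raw_exp))

        if not emerged and cum_gdd >= crop.gdd_emergence:
            emerged = True
            emerge_i = i
            cc = crop.cc0
        if emerged:
            if cum_gdd < crop.gdd_senescence:
                if ccx_eff > 0.0 and cc < ccx_eff:
                    cc += cgc_eff * ks_exp * g * cc * (1.0 - cc / ccx_eff)
            else:
                cc *= max(0.0, 1.0 - crop.cdc * g)
            cc = min(max(cc, 0.0), ccx_eff)
        ccs = _canopy_adjusted(cc)

        et0 = eto_l[i]
        tr_pot = crop.kc_tr_x * ccs * et0 * ks_sto
        avail_rz = max(0.0, (theta - theta_wp)) * zr * 1000.0
        tr = min(tr_pot, avail_rz)
        w -= tr
        tr_sum += tr

        e_pot = crop.ke_x * (1.0 - ccs) * et0
        f_dry = 1.0 if wsurf >= 0.5 * soil.rew else wsurf / (0.5 * soil.rew)
        e = min(e_pot * f_dry, wsurf, max(0.0, w - w_wp_col))
        w -= e
        wsurf = max(0.0, wsurf - e)
        e_sum += e

        if et0 > 0.0:
            biomass += crop.wp_star * f_co2(co2[i]) * fertility.f_wp * (tr / et0)

        if flow_lo <= cum_gdd <= flow_hi:
            ks_flow_sum += ks_sto
            n_flow += 1
        if cum_gdd >= crop.gdd_flowering:
            hi = crop.hi0 * min(1.0, (cum_gdd - crop.gdd_flowering) / hi_span)

        irr_today = 0.0
        theta = w / (zmax * 1000.0)
        dr = max(0.0, (theta_fc - theta) * zr * 1000.0)
        if irrigate and dr > trig * raw_sto:
            irr_today = dr - trig * raw_sto
            w += irr_today
            irr_sum += irr_today
            wsurf = min(soil.rew, wsurf + irr_today)
            dr = trig * raw_sto
        if raw_sto > 0.0:
            max_frac = max(max_frac, dr / raw_sto)

        if emerged and (mat_i is None):
            etc_season += tr + e

        if rows is not None:
            rows.append(
                (dates[i], cum_gdd, zr, w / (zmax * 1000.0), dr, ks_sto, ks_exp,
                 cc, tr, e, irr_today, biomass, hi)
            )

        if cum_gdd >= crop.gdd_maturity:
            mat_i = i
            break

    complete = mat_i is not None
    if not complete and dates[-1] < year_end:
        raise ValueError(
            "weather series ends before both maturity and 31 December; "
            "completion cannot be decided"
        )
    hi_mult = (ks_flow_sum / n_flow) if n_flow > 0 else 1.0
    hi_final = hi * hi_mult if complete else 0.0
    yield_dry = biomass * hi_final / 100.0 if complete else 0.0  # g/m2 -> ton/ha
    cycle_length = None
    maturity = None
    if complete:
        maturity = dates[mat_i]
        if emerge_i is not None:
            cycle_length = int((dates[mat_i] - dates[emerge_i]) / pd.Timedelta(days=1))

    daily = None
    if rows is not None:
        daily = pd.DataFrame(
            rows,
            columns=["date", "cum_gdd", "root_depth", "theta", "depletion",
                     "ks_sto", "ks_exp", "cc", "tr", "e", "irrigation",
                     "biomass", "hi"],
        ).set_index("date")

    return SeasonResult(
        sowing_date=sowing,
        maturity_date=maturity,
        complete=complete,
        cycle_length=cycle_length,
        yield_dry=yield_dry,
        biomass=biomass / 100.0,
        etc_sum=etc_season,
        transpiration_sum=tr_sum,
        evaporation_sum=e_sum,
        irrigation_sum=irr_sum,
        precip_sum=p_sum,
        drainage_sum=drain_sum,
        storage_change=w - w0,
        max_raw_depletion_fraction=max_frac,
        harvest_index=hi_final,
        daily=daily,
    )


def _reference_season() -> tuple[pd.DataFrame, pd.Timestamp]:
    """Benign fixed season used as the fertility-calibration reference.

    Constant mild weather (tav 19 degC -> 11 GDD/day, ETo 4 mm/day) with
    rainfall at more than twice ETo, so water never limits growth and the
    biomass ratio isolates the fertility factors.
    """
    dates = pd.date_range("2001-05-01", periods=160, freq="D")
    return (
        pd.DataFrame(
            {
                "tav": 19.0,
                "precip": 10.0,
                "co2": CO2_REFERENCE,
                "eto": 4.0,
            },
            index=dates,
        ),
        dates[0],
    )


def _reference_biomass(crop: CropParameters, soil: SoilProfile, x: float) -> float:
    ref, sowing = _reference_season()
    res = simulate_season(
        ref, crop, soil, MGMT_YW, sowing, fertility=FertilityFactors.from_intensity(x)
    )
    return res.biomass


@lru_cache(maxsize=64)
def _calibrate_cached(crop: CropParameters, soil: SoilProfile, brel: float) -> FertilityFactors:
    unstressed = _reference_biomass(crop, soil, 0.0)
    if unstressed <= 0.0:
        raise RuntimeError("reference season produced no biomass; cannot calibrate")

    def ratio_error(x: float) -> float:
        return _reference_biomass(crop, soil, x) / unstressed - brel / 100.0

    lo, hi = 0.0, 1.0
    f_hi = ratio_error(hi)
    if f_hi > 0.0:
        raise ValueError(
            f"fertility target Brel={brel}% unattainable: biomass ratio at full "
            f"stress intensity is {f_hi + brel / 100.0:.3f} (bracket [0, 1])"
        )
    x = brentq(ratio_error, lo, hi, xtol=1e-6)
    return FertilityFactors.from_intensity(float(x))


def calibrate_fertility(
    crop: CropParameters, soil: SoilProfile, target_brel: float
) -> FertilityFactors:
    """Find fertility factors reproducing a relative biomass Brel on a
    no-water-stress reference season.

    A one-dimensional root search over the shared stress intensity; the
    returned factors give a stressed/unstressed end-of-season biomass ratio of
    ``target_brel``/100 within 0.5 percentage points.  Deterministic given the
    crop and soil; results are cached.
    """
    if not 0.0 < target_brel <= 100.0:
        raise ValueError("target_brel must be in (0, 100]")
    if target_brel == 100.0:
        return FertilityFactors()
    return _calibrate_cached(crop, soil, round(float(target_brel), 9))
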