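"""Adaptive growing season: sowing-date search, GDD-driven stages, cycle completion.

The crop calendar is thermal, not fixed: sowing is triggered by a persistence
criterion on minimum temperature inside a spring window, and every subsequent
stage boundary is defined in cumulative growing degree days (GDD) from sowing.
A cycle "completes" in a given year if the crop accumulates the full maturity
requirement before the end of the calendar year; in cold cells/years it does
not, and such seasons carry no harvest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import growing_degree_days

__all__ = ["CropParameters", "SowingRule", "find_sowing_date", "stage_schedule", "cycle_complete"]

STAGES = ["pre-emergence", "vegetative", "flowering", "senescence", "mature"]


@dataclass(frozen=True)
class CropParameters:
    """Generic grain-maize cultivar: thermal phenology plus growth/stress coefficients.

    Stage thresholds are cumulative GDD from sowing.  The total cycle
    requirement (``gdd_maturity``) is 1122 degC day; the sub-stage thresholds
    default to typical maize fractions of the total (emergence 7%, maximum
    canopy 60%, flowering 55%, senescence 80%) and are plain configuration.
    Growth coefficients follow water-driven crop-model conventions: ``cgc`` /
    ``cdc`` are canopy growth/decline rates per GDD, ``wp_star`` the
    CO2-normalised water productivity [g biomass per m2 per unit Tr/ETo],
    ``kc_tr_x`` the transpiration coefficient at full canopy, ``ke_x`` the
    maximum soil-evaporation coefficient, ``hi0`` the reference harvest index.
    ``p_upper``/``p_lower`` are the root-zone depletion fractions at which
    stomatal and canopy-expansion stress begin.
    """

    tbase: float = 8.0
    tupper: float = 30.0
    gdd_emergence: float = 78.5
    gdd_max_canopy: float = 673.0
    gdd_flowering: float = 617.0
    gdd_senescence: float = 898.0
    gdd_maturity: float = 1122.0
    gdd_flowering_span: float = 180.0
    kc_tr_x: float = 1.05
    ke_x: float = 1.10
    ccx: float = 0.96
    cc0: float = 0.05
    cgc: float = 0.012
    cdc: float = 0.010
    wp_star: float = 33.7
    hi0: float = 0.48
    p_upper: float = 0.55
    p_lower: float = 0.25
    max_root_depth: float = 1.5

    def __post_init__(self) -> None:
        if not self.tbase < self.tupper:
            raise ValueError("tbase must be below tupper")
        if not 0.0 < self.gdd_emergence < self.gdd_max_canopy <= self.gdd_senescence < self.gdd_maturity:
            raise ValueError(
                "stage thresholds must satisfy 0 < emergence < max_canopy <= senescence < maturity"
            )
        if not self.gdd_emergence <= self.gdd_flowering <= self.gdd_senescence:
            raise ValueError("gdd_flowering must lie between emergence and senescence")
        for name in ("gdd_flowering_span", "kc_tr_x", "ke_x", "cgc", "cdc",
                     "wp_star", "max_root_depth", "cc0"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        for name in ("ccx", "hi0", "p_upper", "p_lower"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class SowingRule:
    """Temperature-triggered sowing inside a spring window.

    Sowing happens on the first window day for which tmin exceeded the
    threshold on ``persistence`` consecutive days ending at (and including)
    that day; warm days immediately before the window count toward the run.
    If no day qualifies, sowing falls back to the last day of the window.
    """

    window_start: tuple[int, int] = (3, 1)  # (month, day): 1 March
    window_end: tuple[int, int] = (4, 29)  # 29 April
    tmin_threshold: float = 8.0
    persistence: int = 4

    def __post_init__(self) -> None:
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")


def find_sowing_date(year_weather: pd.DataFrame, rule: SowingRule = SowingRule()) -> pd.Timestamp:
    """Sowing date for one calendar year of daily weather (needs a ``tmin`` column)."""
    idx = pd.DatetimeIndex(year_weather.index)
    year = int(idx[0].year)
    start = pd.Timestamp(year, *rule.window_start)
    end = pd.Timestamp(year, *rule.window_end)
    needed = pd.date_range(start - pd.Timedelta(days=rule.persistence - 1), end, freq="D")
    if not needed.isin(idx).all():
        raise ValueError("weather series does not cover the sowing window")
    tmin = year_weather["tmin"]
    for day in pd.date_range(start, end, freq="D"):
        run = tmin.loc[day - pd.Timedelta(days=rule.persistence - 1): day]
        if (run > rule.tmin_threshold).all():
            return day
    return end


def stage_schedule(
    weather: pd.DataFrame, sowing: pd.Timestamp, crop: CropParameters = CropParameters()
) -> pd.DataFrame:
    """Cumulative GDD and stage label per day from sowing to the series end.

    Heat units accumulate from the day after sowing (the sowing day itself is
    day 0 with zero accumulation).  Returns a frame indexed by date with
    columns ``cum_gdd`` and ``stage``; labels step monotonically through
    pre-emergence, vegetative, flowering, senescence and mature.
    """
    idx = pd.DatetimeIndex(weather.index)
    if sowing not in idx:
        raise ValueError("sowing date not inside the weather series")
    sub = weather.loc[sowing:]
    gdd = growing_degree_days(sub["tav"], crop.tbase, crop.tupper).to_numpy()
    gdd[0] = 0.0  # accumulation starts the day after sowing
    cum = np.cumsum(gdd)
    bins = [crop.gdd_emergence, crop.gdd_flowering, crop.gdd_senescence, crop.gdd_maturity]
    labels = np.array(STAGES)[np.searchsorted(bins, cum, side="right")]
    return pd.DataFrame({"cum_gdd": cum, "stage": labels}, index=sub.index)


def maturity_date(schedule: pd.DataFrame, crop: CropParameters) -> pd.Timestamp | None:
    """First day on which cumulative GDD reaches the maturity requirement, or None."""
    hit = schedule.index[schedule["cum_gdd"].to_numpy() >= crop.gdd_maturity]
    return hit[0] if len(hit) else None


def cycle_complete(
    weather: pd.DataFrame, sowing: pd.Timestamp, crop: CropParameters = CropParameters()
) -> tuple[bool, int | None]:
    """Whether the cycle completes by 31 December, and its length in days.

    Completion is attained when cumulative GDD from sowing to the end of the
    calendar year reaches the maturity requirement (boundary inclusive).  The
    cycle length counts days from emergence (cumulative GDD reaching the
    emergence threshold) to maturity; incomplete cycles report no length.
    """
    year_end = pd.Timestamp(sowing.year, 12, 31)
    idx = pd.DatetimeIndex(weather.index)
    if idx[-1] < year_end:
        raise ValueError("weather series must cover sowing through 31 December")
    sched = stage_schedule(weather.loc[:year_end], sowing, crop)
    mat = maturity_date(sched, crop)
    if mat is None:
        return False, None
    cum = sched["cum_gdd"].to_numpy()
    emerge = sched.index[cum >= crop.gdd_emergence][0]
    return True, int((mat - emerge) / pd.Timedelta(days=1))


def mean_day_of_year(dates) -> float:
    """Mean day-of-year of a collection of dates (plain circularity-free mean)."""
    return float(np.mean([pd.Timestamp(d).dayofyear for d in dates]))


def ceil_days(total_gdd: float, per_day: float) -> int:
    """Days needed to accumulate ``total_gdd`` at a constant daily rate."""
    return math.ceil(total_gdd / per_day)
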