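"""Yield gaps, water productivity, multi-year cell statistics and skill metrics.

The three management regimes share the weather and sowing date of a cell-year
and differ only in management: actual yield Ya carries the default fertility
stress rainfed, water-limited yield Yw removes the fertility stress, and
potential yield Yp additionally activates net irrigation.  Yield gaps follow
YGw = (1 - Ya/Yw)*100 and YGp = (1 - Ya/Yp)*100, computed on multi-year mean
yields; YGw may be negative in dry cells where the unstressed crop exhausts
soil water.  Water productivity is yield per unit seasonal crop
evapotranspiration in kg/m3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    MGMT_YA,
    MGMT_YP,
    MGMT_YW,
    ManagementConfig,
    SeasonResult,
    SoilProfile,
    simulate_season,
)
from .phenology import CropParameters

__all__ = [
    "RegimeTriplet",
    "CellStatistics",
    "run_regimes",
    "yield_gaps",
    "water_productivity",
    "skill_metrics",
    "cell_statistics",
]


@dataclass(frozen=True)
class RegimeTriplet:
    """Ya/Yw/Yp season results for one cell-year (same weather, same sowing)."""

    ya: SeasonResult
    yw: SeasonResult
    yp: SeasonResult

    @property
    def yields(self) -> tuple[float, float, float]:
        return self.ya.yield_dry, self.yw.yield_dry, self.yp.yield_dry

    @property
    def etc(self) -> tuple[float, float, float]:
        return self.ya.etc_sum, self.yw.etc_sum, self.yp.etc_sum


def run_regimes(
    weather: pd.DataFrame,
    crop: CropParameters,
    soil: SoilProfile,
    sowing: pd.Timestamp,
    eto: pd.Series | None = None,
    mgmt_ya: ManagementConfig = MGMT_YA,
    mgmt_yw: ManagementConfig = MGMT_YW,
    mgmt_yp: ManagementConfig = MGMT_YP,
) -> RegimeTriplet:
    """Simulate the Ya, Yw and Yp regimes on identical weather and sowing date."""
    return RegimeTriplet(
        ya=simulate_season(weather, crop, soil, mgmt_ya, sowing, eto=eto),
        yw=simulate_season(weather, crop, soil, mgmt_yw, sowing, eto=eto),
        yp=simulate_season(weather, crop, soil, mgmt_yp, sowing, eto=eto),
    )


def yield_gaps(mean_ya: float, mean_yw: float, mean_yp: float) -> tuple[float, float]:
    """Water-limited and potential yield gaps [%] from mean yields.

    YGw = (1 - Ya/Yw)*100 and YGp = (1 - Ya/Yp)*100.  A non-positive
    denominator leaves the corresponding gap undefined (NaN), never silently
    zero; YGw may legitimately be negative.
    """
    ygw = (1.0 - mean_ya / mean_yw) * 100.0 if mean_yw > 0.0 else math.nan
    ygp = (1.0 - mean_ya / mean_yp) * 100.0 if mean_yp > 0.0 else math.nan
    return ygw, ygp


def water_productivity(yield_dry: float, etc_sum: float) -> float:
    """Water productivity [kg grain per m3 evapotranspired water].

    1 ton/ha = 0.1 kg/m2 and 1 mm = 1e-3 m3/m2, hence
    WP = 100 * yield[ton/ha] / ETc[mm].  Zero yield gives 0; a non-positive
    ETc with non-zero yield is undefined (NaN).
    """
    if yield_dry == 0.0:
        return 0.0
    if etc_sum <= 0.0:
        return math.nan
    return 100.0 * yield_dry / etc_sum


def skill_metrics(reference, simulated) -> tuple[float, float, float]:
    """Pearson R, bias and RMSD between paired reference and simulated yields.

    Bias is reference minus simulated (positive = model underestimates),
    matching the convention of comparing simulated yields against an external
    yield atlas.
    """
    ref = np.asarray(reference, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if ref.shape != sim.shape:
        raise ValueError("reference and simulated series differ in length")
    if ref.size < 2:
        raise ValueError("need at least 2 paired values")
    diff = ref - sim
    if np.std(ref) > 0.0 and np.std(sim) > 0.0:
        r = float(stats.pearsonr(ref, sim)[0])
    else:
        r = math.nan  # correlation undefined for a constant series
    bias = float(np.mean(diff))
    rmsd = float(np.sqrt(np.mean(diff**2)))
    return r, bias, rmsd


@dataclass
class CellStatistics:
    """Multi-year (nominally 30-year) per-cell summary across the three regimes.

    Means and interannual standard deviations are computed over complete-cycle
    years only; the yield gaps are computed on the multi-year mean yields.
    ``wp_*`` defaults to the mean over years of per-season water productivity
    (each season's yield over its seasonal ETc).
    """

    mean_ya: float
    mean_yw: float
    mean_yp: float
    sd_ya: float
    sd_yw: float
    sd_yp: float
    ygw: float
    ygp: float
    wpa: float
    wpw: float
    wpp: float
    mean_sowing_doy: float
    mean_cycle_length: float
    n_years: int
    n_complete_years: int
    n_failures: int


def _wp_aggregate(yields, etcs, how: str) -> float:
    yields = np.asarray(yields, dtype=float)
    etcs = np.asarray(etcs, dtype=float)
    if yields.size == 0:
        return math.nan
    if how == "ratio_of_means":
        return water_productivity(float(np.mean(yields)), float(np.mean(etcs)))
    per = [water_productivity(y, e) for y, e in zip(yields, etcs)]
    per = [p for p in per if not math.isnan(p)]
    return float(np.mean(per)) if per else math.nan


def cell_statistics(
    triplets: list[RegimeTriplet],
    failure_threshold: float = 4.0,
    wp_aggregate: str = "mean_of_ratios",
    count_incomplete_as_failure: bool = True,
) -> CellStatistics:
    """Summarise a cell's yearly regime triplets into multi-year statistics.

    Incomplete years (cycle not finished by 31 December) are excluded from
    yield/WP/cycle means but, by default, counted as crop failures; a failure
    year is one whose actual yield falls below ``failure_threshold`` ton/ha.
    """
    if not triplets:
        raise ValueError("no seasons supplied")
    complete = [t for t in triplets if t.ya.complete]
    ya = np.array([t.ya.yield_dry for t in complete])
    yw = np.array([t.yw.yield_dry for t in complete])
    yp = np.array([t.yp.yield_dry for t in complete])
    sow_doy = [t.ya.sowing_date.dayofyear for t in complete]
    cycles = [t.ya.cycle_length for t in complete if t.ya.cycle_length is not None]

    n_fail = sum(1 for t in complete if t.ya.yield_dry < failure_threshold)
    if count_incomplete_as_failure:
        n_fail += len(triplets) - len(complete)

    def _mean(a):
        return float(np.mean(a)) if len(a) else math.nan

    def _sd(a):
        return float(np.std(a, ddof=1)) if len(a) > 1 else math.nan

    mean_ya, mean_yw, mean_yp = _mean(ya), _mean(yw), _mean(yp)
    ygw, ygp = (
        yield_gaps(mean_ya, mean_yw, mean_yp)
        if complete
        else (math.nan, math.nan)
    )
    return CellStatistics(
        mean_ya=mean_ya,
        mean_yw=mean_yw,
        mean_yp=mean_yp,
        sd_ya=_sd(ya),
        sd_yw=_sd(yw),
        sd_yp=_sd(yp),
        ygw=ygw,
        ygp=ygp,
        wpa=_wp_aggregate([t.ya.yield_dry for t in complete], [t.ya.etc_sum for t in complete], wp_aggregate),
        wpw=_wp_aggregate([t.yw.yield_dry for t in complete], [t.yw.etc_sum for t in complete], wp_aggregate),
        wpp=_wp_aggregate([t.yp.yield_dry for t in complete], [t.yp.etc_sum for t in complete], wp_aggregate),
        mean_sowing_doy=_mean(sow_doy),
        mean_cycle_length=_mean(cycles),
        n_years=len(triplets),
        n_complete_years=len(complete),
        n_failures=n_fail,
    )
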