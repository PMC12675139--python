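"""Derived climate drivers: FAO-56 reference evapotranspiration and growing degree days.

The reference evapotranspiration (ETo) follows the FAO Irrigation and Drainage
Paper 56 daily Penman-Monteith combination equation for a clipped-grass
reference surface (albedo 0.23, surface resistance 70 s/m).  Growing degree
days (GDD) use the mean-temperature form with a base temperature below which
no development occurs and an upper temperature cap above which additional heat
does not contribute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "extraterrestrial_radiation",
    "reference_eto",
    "growing_degree_days",
    "derive_climate",
    "annual_aggregates",
    "relative_change",
]

# Physical constants (FAO-56 conventions)
SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
ALBEDO = 0.23
WIND_10M_TO_2M = 4.87 / np.log(67.8 * 10.0 - 5.42)  # FAO-56 log profile, ~0.748


def extraterrestrial_radiation(latitude: float, doy) -> np.ndarray:
    """Daily extraterrestrial radiation Ra [MJ m-2 day-1] for a latitude and day of year."""
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * doy)
    delta = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def _svp(t: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure [kPa] at air temperature t [degC]."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def reference_eto(weather: pd.DataFrame, latitude: float, elevation: float = 0.0) -> pd.Series:
    """FAO-56 Penman-Monteith daily reference evapotranspiration [mm/day].

    Parameters
    ----------
    weather
        Daily frame with columns ``tmin``, ``tmax``, ``tav``, ``rh`` (mean
        relative humidity, %), ``wind10`` (10-m wind speed, m/s) and ``srad``
        (shortwave downwelling radiation, MJ m-2 day-1), indexed by date.
    latitude
        Degrees north, used for clear-sky radiation.
    elevation
        Station elevation [m] for the psychrometric constant; default sea level.

    Notes
    -----
    Actual vapour pressure is derived from mean relative humidity applied to
    the mean of the saturation pressures at tmin and tmax (one of the
    FAO-56-sanctioned variants; the forcing provides daily-mean RH only).
    The 10-m wind is converted to the 2-m reference height with the FAO-56
    logarithmic profile factor.  Soil heat flux is zero at the daily scale and
    the result is floored at zero.
    """
    for col in ("tmin", "tmax", "tav", "rh", "wind10", "srad"):
        if col not in weather.columns:
            raise ValueError(f"weather frame is missing column {col!r}")
        vals = weather[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in column {col!r}")
    rh = weather["rh"].to_numpy(dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError("rh outside [0, 100]")

    tmin = weather["tmin"].to_numpy(dtype=float)
    tmax = weather["tmax"].to_numpy(dtype=float)
    tav = weather["tav"].to_numpy(dtype=float)
    u10 = weather["wind10"].to_numpy(dtype=float)
    rs = weather["srad"].to_numpy(dtype=float)
    doy = weather.index.dayofyear.to_numpy()

    es = (_svp(tmin) + _svp(tmax)) / 2.0
    ea = rh / 100.0 * es
    delta = 4098.0 * _svp(tav) / (tav + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    u2 = u10 * WIND_10M_TO_2M

    ra = extraterrestrial_radiation(latitude, doy)
    rso = (0.75 + 2e-5 * elevation) * ra
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_sun = np.where(rso > 0.0, rs / rso, 0.5)
    rel_sun = np.clip(rel_sun, 0.05, 1.0)
    rns = (1.0 - ALBEDO) * rs
    tmink, tmaxk = tmin + 273.16, tmax + 273.16
    rnl = (
        STEFAN_BOLTZMANN
        * (tmaxk**4 + tmink**4)
        / 2.0
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel_sun - 0.35)
    )
    # net longwave is a loss term; under heavy overcast the cloudiness factor
    # can go negative, which is floored rather than credited as a gain
    rn = rns - np.maximum(rnl, 0.0)

    num = 0.408 * delta * rn + gamma * 900.0 / (tav + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    eto = np.maximum(num / den, 0.0)
    return pd.Series(eto, index=weather.index, name="eto")


def growing_degree_days(tav, tbase: float = 8.0, tupper: float = 30.0):
    """Daily growing degree days: max(0, min(tav, tupper) - tbase).

    Temperatures above ``tupper`` are capped (they add no further heat units);
    temperatures at or below ``tbase`` contribute nothing.  Accepts scalars or
    array-likes and vectorises.
    """
    if not tbase < tupper:
        raise ValueError(f"tbase ({tbase}) must be below tupper ({tupper})")
    arr = np.asarray(tav, dtype=float)
    gdd = np.maximum(0.0, np.minimum(arr, tupper) - tbase)
    if np.isscalar(tav) or arr.ndim == 0:
        return float(gdd)
    if isinstance(tav, pd.Series):
        return pd.Series(gdd, index=tav.index, name="gdd")
    return gdd


def derive_climate(
    weather: pd.DataFrame,
    latitude: float,
    elevation: float = 0.0,
    tbase: float = 8.0,
    tupper: float = 30.0,
) -> pd.DataFrame:
    """Return a copy of the weather frame with ``eto`` and ``gdd`` columns appended."""
    out = weather.copy()
    out["eto"] = reference_eto(weather, latitude, elevation)
    out["gdd"] = growing_degree_days(weather["tav"], tbase, tupper)
    return out


def _check_whole_years(index: pd.DatetimeIndex) -> None:
    if len(index) == 0:
        raise ValueError("empty series")
    expected = pd.date_range(
        start=pd.Timestamp(index[0].year, 1, 1),
        end=pd.Timestamp(index[-1].year, 12, 31),
        freq="D",
    )
    if len(index) != len(expected) or not (index == expected).all():
        raise ValueError("series must cover contiguous whole calendar years")


def annual_aggregates(derived: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-year sums of precipitation, GDD and ETo.

    Requires a frame covering contiguous whole calendar years with columns
    ``precip``, ``gdd`` and ``eto``; returns one row per year with columns
    ``annual_precip`` [mm], ``annual_gdd`` [degC day], ``annual_eto`` [mm].
    """
    _check_whole_years(pd.DatetimeIndex(derived.index))
    for col in ("precip", "gdd", "eto"):
        if col not in derived.columns:
            raise ValueError(f"derived frame is missing column {col!r}")
    years = sorted(set(derived.index.year))
    rows = []
    for year in years:
        sub = derived.loc[str(year)]
        # plain Series.sum per year so the annual value equals the daily sum
        # bit-for-bit (no cross-year accumulation order effects)
        rows.append(
            {
                "annual_precip": sub["precip"].sum(),
                "annual_gdd": sub["gdd"].sum(),
                "annual_eto": sub["eto"].sum(),
            }
        )
    out = pd.DataFrame(rows, index=pd.Index(years, name="year"))
    return out


def relative_change(baseline, future):
    """(future - baseline) / baseline * 100, element-wise; NaN where baseline is 0."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(future, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b != 0.0, (f - b) / b * 100.0, np.nan)
    if np.isscalar(baseline) or out.ndim == 0:
        return float(out)
    return out
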