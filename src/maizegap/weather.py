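"""Synthetic daily weather for a single grid cell, plus small "GCM" ensembles.

The generator emulates the statistical structure of gridded daily reanalysis
forcing without reproducing any particular dataset: a sinusoidal annual
temperature cycle with first-order autoregressive (AR(1)) day-to-day
anomalies, precipitation occurrence from a two-state wet/dry Markov chain with
gamma-distributed wet-day amounts, latitude- and season-dependent shortwave
radiation (extraterrestrial radiation times a cloudiness factor tied to wet
days), and annual-resolution CO2.  Scenario modifications are applied as a
uniform warming offset, a multiplicative precipitation scaling and a linear
CO2 trend.

Each stochastic component draws from its own seeded substream, so changing
``delta_T`` shifts every temperature by exactly that offset and changing
``precip_factor`` rescales every wet-day amount exactly, without disturbing
any other draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import extraterrestrial_radiation

__all__ = [
    "ClimateSpec",
    "generate_weather",
    "generate_ensemble",
    "write_weather_csv",
    "read_weather_csv",
]

WEATHER_COLUMNS = ["tmin", "tmax", "tav", "precip", "rh", "wind10", "srad", "co2"]

# substream identifiers
_STREAM_TEMP = 0
_STREAM_OCCURRENCE = 1
_STREAM_AMOUNT = 2
_STREAM_RH = 3
_STREAM_WIND = 4
_STREAM_CLOUD = 5


@dataclass(frozen=True)
class ClimateSpec:
    """Cell climatology, scenario deltas and the seed for one weather series.

    Temperatures in degC, precipitation in mm/day, humidity in %, wind at 10 m
    in m/s, CO2 in ppm.  ``wet_day_prob`` is the stationary wet-day frequency
    of the occurrence chain and ``wet_persistence`` the wet-after-wet
    transition probability.
    """

    latitude: float = 48.0
    annual_mean_temp: float = 10.5
    seasonal_amplitude: float = 9.0
    diurnal_range: float = 9.0
    anomaly_sd: float = 2.5
    anomaly_autocorr: float = 0.7
    wet_day_prob: float = 0.35
    wet_persistence: float = 0.6
    mean_wet_amount: float = 5.0
    rh_mean: float = 75.0
    wind10_mean: float = 3.5
    co2_start: float = 369.41
    delta_T: float = 0.0
    precip_factor: float = 1.0
    co2_trend: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "latitude", "annual_mean_temp", "seasonal_amplitude", "diurnal_range",
            "anomaly_sd", "anomaly_autocorr", "wet_day_prob", "wet_persistence",
            "mean_wet_amount", "rh_mean", "wind10_mean", "co2_start", "delta_T",
            "precip_factor", "co2_trend",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite value for field {name!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("field 'latitude' must be in [-90, 90]")
        for name in ("wet_day_prob", "wet_persistence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"field {name!r} must be in [0, 1]")
        if not 0.0 <= self.anomaly_autocorr < 1.0:
            raise ValueError("field 'anomaly_autocorr' must be in [0, 1)")
        for name in ("seasonal_amplitude", "diurnal_range", "anomaly_sd",
                     "mean_wet_amount", "wind10_mean"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"field {name!r} must be non-negative")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError("field 'rh_mean' must be in [0, 100]")
        if self.co2_start <= 0.0:
            raise ValueError("field 'co2_start' must be positive")
        if self.precip_factor <= 0.0:
            raise ValueError("field 'precip_factor' must be positive")
        if self.wet_day_prob < 1.0:
            p01 = self.wet_day_prob * (1.0 - self.wet_persistence) / (1.0 - self.wet_day_prob)
            if p01 > 1.0:
                raise ValueError(
                    "field 'wet_day_prob' incompatible with 'wet_persistence': "
                    "implied dry-to-wet probability exceeds 1"
                )

    def wet_transition_matrix(self) -> np.ndarray:
        """2x2 occurrence transition matrix [[p_dd, p_dw], [p_wd, p_ww]].

        Built so the chain's stationary wet probability equals ``wet_day_prob``.
        """
        pi, pww = self.wet_day_prob, self.wet_persistence
        if pi >= 1.0:
            pdw = 1.0
        elif pi <= 0.0:
            pdw = 0.0
        else:
            pdw = pi * (1.0 - pww) / (1.0 - pi)
        return np.array([[1.0 - pdw, pdw], [1.0 - pww, pww]])


def _rng(spec: ClimateSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def generate_weather(spec: ClimateSpec, n_years: int, start_year: int = 1985) -> pd.DataFrame:
    """Generate ``n_years`` whole calendar years of daily weather for one cell.

    Returns a frame indexed by date with columns tmin, tmax, tav [degC],
    precip [mm/day], rh [%], wind10 [m/s], srad [MJ m-2 day-1], co2 [ppm].
    Identical (spec, seed) pairs reproduce the series bit-for-bit.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    dates = pd.date_range(
        start=pd.Timestamp(start_year, 1, 1),
        end=pd.Timestamp(start_year + n_years - 1, 12, 31),
        freq="D",
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)

    # --- temperature: annual sinusoid peaking mid-summer + AR(1) anomalies
    peak_doy = 197.0 if spec.latitude >= 0.0 else 15.0
    clim = spec.annual_mean_temp + spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - peak_doy) / 365.25
    )
    rng_t = _rng(spec, _STREAM_TEMP)
    z = rng_t.standard_normal(n)
    phi = spec.anomaly_autocorr
    innov_sd = spec.anomaly_sd * np.sqrt(1.0 - phi**2)
    anom = np.empty(n)
    prev = spec.anomaly_sd * z[0]
    anom[0] = prev
    for i in range(1, n):
        prev = phi * prev + innov_sd * z[i]
        anom[i] = prev
    tav = clim + anom + spec.delta_T
    tmin = tav - spec.diurnal_range / 2.0
    tmax = tav + spec.diurnal_range / 2.0

    # --- precipitation: two-state occurrence chain, gamma wet-day amounts
    rng_o = _rng(spec, _STREAM_OCCURRENCE)
    u = rng_o.random(n)
    tm = spec.wet_transition_matrix()
    wet = np.zeros(n, dtype=bool)
    wet[0] = u[0] < spec.wet_day_prob
    for i in range(1, n):
        wet[i] = u[i] < tm[1 if wet[i - 1] else 0, 1]
    rng_a = _rng(spec, _STREAM_AMOUNT)
    shape = 0.8
    amounts = rng_a.gamma(shape, spec.mean_wet_amount / shape, size=n)
    precip = np.where(wet, amounts * spec.precip_factor, 0.0)

    # --- shortwave radiation: Ra times a cloudiness factor tied to wet days
    ra = extraterrestrial_radiation(spec.latitude, doy)
    rng_c = _rng(spec, _STREAM_CLOUD)
    tau = np.where(wet, 0.40, 0.70) * np.clip(rng_c.normal(1.0, 0.08, size=n), 0.7, 1.1)
    srad = np.clip(tau, 0.10, 0.78) * ra

    # --- humidity and wind
    rng_h = _rng(spec, _STREAM_RH)
    rh = np.clip(
        spec.rh_mean + np.where(wet, 8.0, -3.0) + rng_h.normal(0.0, 6.0, size=n),
        10.0, 100.0,
    )
    rng_w = _rng(spec, _STREAM_WIND)
    sigma_w = 0.4
    wind10 = spec.wind10_mean * rng_w.lognormal(-0.5 * sigma_w**2, sigma_w, size=n)

    # --- CO2: annual value repeated daily
    year_index = dates.year.to_numpy() - start_year
    co2 = spec.co2_start + year_index * spec.co2_trend

    return pd.DataFrame(
        {
            "tmin": tmin,
            "tmax": tmax,
            "tav": tav,
            "precip": precip,
            "rh": rh,
            "wind10": wind10,
            "srad": srad,
            "co2": co2,
        },
        index=dates,
    )


def _member_spec(spec: ClimateSpec, member: int) -> ClimateSpec:
    """Perturbed spec for one ensemble member; member 0 is the spec itself."""
    if member == 0:
        return spec
    level = (member + 1) // 2
    sign = 1.0 if member % 2 == 1 else -1.0
    sd = spec.anomaly_sd * (1.0 + sign * 0.10 * level)
    wet = float(np.clip(spec.wet_day_prob + sign * 0.02 * level, 0.02, 0.95))
    # keep the occurrence chain valid under the perturbed stationary frequency
    if wet < 1.0:
        p01 = wet * (1.0 - spec.wet_persistence) / (1.0 - wet)
        if p01 > 1.0:
            wet = spec.wet_day_prob
    return dataclasses.replace(
        spec,
        anomaly_sd=max(sd, 0.0),
        wet_day_prob=wet,
        seed=int(spec.seed) + 1009 * member,
    )


def generate_ensemble(
    spec: ClimateSpec, n_members: int, n_years: int, start_year: int = 1985
) -> list[pd.DataFrame]:
    """A small climate-model-like ensemble: distinct seeds plus mild perturbations.

    Member 0 reproduces ``generate_weather(spec, ...)`` exactly; members differ
    in seed and in small documented perturbations of the anomaly standard
    deviation (±10% per level) and wet-day frequency (±0.02 per level), so the
    spread carries both noise and climatology differences.  Member order is
    stable and the whole ensemble is reproducible from ``spec.seed``.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    return [
        generate_weather(_member_spec(spec, m), n_years, start_year)
        for m in range(n_members)
    ]


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    """Write a daily weather frame as CSV with a leading ``date`` column."""
    out = weather.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.6f")


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {missing}")
    return df


def ensemble_to_dataset(members: list[pd.DataFrame], latitude: float, longitude: float):
    """Pack an ensemble of daily weather frames into a (member, time) Dataset.

    Coordinates carry CF-style latitude/longitude of the cell; write with
    ``ds.to_netcdf(path, engine="scipy")``.
    """
    import xarray as xr

    if not members:
        raise ValueError("empty ensemble")
    time = members[0].index
    data = {
        col: (
            ("member", "time"),
            np.stack([m[col].to_numpy(dtype=float) for m in members]),
        )
        for col in WEATHER_COLUMNS
    }
    return xr.Dataset(
        data,
        coords={
            "member": np.arange(len(members)),
            "time": time,
            "lat": ((), float(latitude), {"units": "degrees_north"}),
            "lon": ((), float(longitude), {"units": "degrees_east"}),
        },
    )
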