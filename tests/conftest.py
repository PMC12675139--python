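import numpy as np
import pandas as pd
import pytest

from maizegap.engine import CO2_REFERENCE, SoilProfile
from maizegap.phenology import CropParameters


@pytest.fixture(scope="session")
def crop() -> CropParameters:
    return CropParameters()


@pytest.fixture(scope="session")
def soil() -> SoilProfile:
    return SoilProfile()


def constant_season(
    tav: float = 19.0,
    eto: float = 4.0,
    precip: float = 10.0,
    co2: float = CO2_REFERENCE,
    year: int = 2001,
) -> pd.DataFrame:
    """One whole calendar year of constant daily forcing for the crop engine."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    df = pd.DataFrame(
        {"tav": float(tav), "precip": float(precip), "co2": float(co2)}, index=dates
    )
    df["eto"] = float(eto)
    return df


@pytest.fixture(scope="session")
def benign_season() -> pd.DataFrame:
    """Warm season with rainfall always well above evaporative demand."""
    return constant_season()


@pytest.fixture(scope="session")
def drought_season() -> pd.DataFrame:
    """Hot rainless season with high atmospheric demand."""
    return constant_season(tav=22.0, eto=6.0, precip=0.0)


@pytest.fixture(scope="session")
def shallow_soil() -> SoilProfile:
    """Small water store: terminal drought arrives before maturity."""
    return SoilProfile(max_root_depth=0.6)


@pytest.fixture(scope="session")
def sowing() -> pd.Timestamp:
    return pd.Timestamp("2001-05-01")


def weather_frame(tav, year: int = 2001, precip: float = 0.0) -> pd.DataFrame:
    """Whole-year frame with a prescribed daily tav sequence (tail padded)."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    arr = np.full(len(dates), np.nan)
    tav = np.asarray(tav, dtype=float)
    arr[: len(tav)] = tav
    arr[len(tav):] = tav[-1] if len(tav) else 0.0
    df = pd.DataFrame({"tav": arr, "precip": float(precip), "co2": CO2_REFERENCE}, index=dates)
    df["tmin"] = df["tav"] - 4.5
    df["tmax"] = df["tav"] + 4.5
    df["eto"] = 4.0
    return df
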