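"""Daily weather records: CSV input, a synthetic generator, and Penman ET.

The simulator is driven by an ordered, gap-free daily series of
:class:`WeatherDay` records.  ``synth_weather`` produces a statistically
plausible stand-in for south-east England conditions (sinusoidal temperature
and radiation climatology with autocorrelated anomalies; two-state Markov
rainfall occurrence with exponential amounts) so every scenario in the test
suite is generated at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

WEATHER_COLUMNS = ["date", "tmin", "tmax", "rain", "rad", "vp", "wind"]


class WeatherError(ValueError):
    """Malformed weather input (missing column, gap, invariant breach)."""


@dataclass(frozen=True)
class WeatherDay:
    date: Date
    tmin: float      # degC
    tmax: float      # degC
    rain: float      # mm d-1
    radiation: float  # MJ m-2 d-1, global
    vapour_pressure: float  # kPa
    windspeed: float  # m s-1

    @property
    def tavg(self) -> float:
        return 0.5 * (self.tmin + self.tmax)

    def validate(self) -> None:
        if self.tmax < self.tmin:
            raise WeatherError(f"{self.date}: tmax < tmin")
        if self.rain < 0:
            raise WeatherError(f"{self.date}: negative rain")
        if self.radiation < 0:
            raise WeatherError(f"{self.date}: negative radiation")


def read_weather(path) -> list[WeatherDay]:
    """Read a daily weather CSV (columns date,tmin,tmax,rain,rad,vp,wind).

    The series must be contiguous daily with ISO dates; any invariant breach
    is reported with the offending date.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherError(f"missing column(s): {', '.join(missing)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise WeatherError(f"unparseable date: {exc}") from exc
    days: list[WeatherDay] = []
    prev: Date | None = None
    for i, d in enumerate(dates):
        if prev is not None and d != prev + timedelta(days=1):
            raise WeatherError(f"gap in dates between {prev} and {d}")
        prev = d
        row = df.iloc[i]
        try:
            day = WeatherDay(d, float(row["tmin"]), float(row["tmax"]),
                             float(row["rain"]), float(row["rad"]),
                             float(row["vp"]), float(row["wind"]))
        except (ValueError, TypeError) as exc:
            raise WeatherError(f"unparseable value on {d}: {exc}") from exc
        day.validate()
        days.append(day)
    return days


def write_weather(days: list[WeatherDay], path) -> None:
    pd.DataFrame(
        {"date": [d.date.isoformat() for d in days],
         "tmin": [d.tmin for d in days], "tmax": [d.tmax for d in days],
         "rain": [d.rain for d in days], "rad": [d.radiation for d in days],
         "vp": [d.vapour_pressure for d in days],
         "wind": [d.windspeed for d in days]},
    ).to_csv(path, index=False)


def synth_weather(years: int, latitude: float = 51.8, seed: int = 0,
                  start_year: int = 2000, annual_rain: float = 700.0,
                  t_mean: float = 10.0, t_amp: float = 6.5) -> list[WeatherDay]:
    """Generate a synthetic daily weather series.

    Temperature and radiation follow sinusoidal annual cycles (peak late July
    / midsummer) with AR(1) daily anomalies; rainfall occurrence is a
    two-state Markov chain (p(wet|dry)=0.3, p(wet|wet)=0.6) with
    exponentially distributed wet-day amounts scaled to the requested mean
    annual total.  Reproducible for a given seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    days: list[WeatherDay] = []
    d = Date(start_year, 1, 1)
    end = Date(start_year + years, 1, 1)
    p_wd, p_ww = 0.3, 0.6
    wet_frac = p_wd / (p_wd + (1.0 - p_ww))     # stationary wet-day fraction
    mean_wet_amount = annual_rain / (365.25 * wet_frac)
    t_anom = 0.0
    wet = False
    while d < end:
        doy = d.timetuple().tm_yday
        phase = 2.0 * math.pi * (doy - 196) / 365.25    # peak mid/late July
        t_anom = 0.7 * t_anom + rng.normal(0.0, 2.0)
        tavg = t_mean + t_amp * math.cos(phase) + t_anom
        trange = max(2.0, 8.0 + 2.0 * math.cos(phase) + rng.normal(0.0, 1.5))
        rad_clear = max(1.0, 13.0 + 9.5 * math.cos(phase))
        cloud = rng.uniform(0.35, 1.0)
        wet = rng.random() < (p_ww if wet else p_wd)
        rain = float(rng.exponential(mean_wet_amount)) if wet else 0.0
        if wet:
            cloud *= 0.7
        rad = rad_clear * cloud
        es = saturation_vp(tavg)
        vp = max(0.1, es * rng.uniform(0.6, 0.95))
        wind = float(rng.gamma(2.0, 1.8))
        days.append(WeatherDay(d, tavg - trange / 2.0, tavg + trange / 2.0,
                               rain, rad, vp, wind))
        d += timedelta(days=1)
    return days


# --- radiation geometry and Penman potential evapotranspiration -------------

def saturation_vp(t: float) -> float:
    """Saturation vapour pressure (kPa) at temperature t (degC)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def solar_geometry(doy: int, latitude: float) -> tuple[float, float]:
    """Return (daylength h, extraterrestrial radiation MJ m-2 d-1)."""
    lat = math.radians(latitude)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(lat) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    daylength = 24.0 / math.pi * ws
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    ra = (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(lat) * math.sin(decl)
        + math.cos(lat) * math.cos(decl) * math.sin(ws))
    return daylength, max(ra, 0.1)


def penman_pet(day: WeatherDay, latitude: float, albedo: float = 0.23,
               gamma: float = 0.0665, lam: float = 2.45) -> float:
    """Penman potential evapotranspiration (mm d-1).

    Radiation term from net short- and long-wave balance, aerodynamic term
    from the classical wind function; split between soil evaporation and
    crop transpiration happens in the callers via canopy cover.
    """
    t = day.tavg
    es = 0.5 * (saturation_vp(day.tmin) + saturation_vp(day.tmax))
    ea = min(day.vapour_pressure, es)
    delta = 4098.0 * saturation_vp(t) / (t + 237.3) ** 2
    _, ra = solar_geometry(day.date.timetuple().tm_yday, latitude)
    rso = 0.75 * ra
    rns = (1.0 - albedo) * day.radiation
    sigma = 4.903e-9
    tk4 = 0.5 * ((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4)
    rel = min(1.0, day.radiation / rso)
    rnl = sigma * tk4 * (0.34 - 0.14 * math.sqrt(max(ea, 0.0))) \
        * (1.35 * rel - 0.35)
    rn = max(0.0, rns - max(0.0, rnl))
    ea_term = 2.6 * (1.0 + 0.536 * day.windspeed) * max(0.0, es - ea)
    pet = (delta * rn / lam + gamma * ea_term) / (delta + gamma)
    return max(0.0, pet)
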