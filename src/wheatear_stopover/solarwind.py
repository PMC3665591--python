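"""Solar geometry and wind support.

Sun position (elevation with atmospheric refraction), sunset/sunrise times and
night length are computed with the NOAA solar-position equations (low-accuracy
Meeus ephemeris, good to a few hundredths of a degree for 1950-2050), using
the civil convention that sunset/sunrise occur when the refracted solar
elevation crosses -0.833 deg.

Wind support is the tailwind component: the projection of the wind vector onto
the migratory goal direction, with wind direction given in the "blowing
toward" convention (degrees clockwise from geographic north).  When winds are
available at several pressure levels the level with the best support is taken,
since nocturnal migrants select their flight altitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SolarEvent",
    "WindObservation",
    "PolarDayNightError",
    "sun_elevation",
    "sun_events",
    "tailwind_component",
    "max_tailwind",
    "WALES",
    "read_covariates",
]

#: Study-site coordinates (Wales, Alaska): 65deg37'N, 168deg05'W.
WALES = (65.0 + 37.0 / 60.0, -(168.0 + 5.0 / 60.0))

SUNSET_ELEVATION = -0.833  # deg, horizon depression incl. standard refraction

WIND_LEVELS = ("surface", "1000", "925", "850", "700")


class PolarDayNightError(ValueError):
    """No sunset/sunrise exists at this latitude and date."""


@dataclass
class SolarEvent:
    date: date
    sunset_utc: datetime
    sunrise_next_utc: datetime

    @property
    def night_length(self) -> float:
        """Minutes from sunset to the following sunrise."""
        return (self.sunrise_next_utc - self.sunset_utc).total_seconds() / 60.0


@dataclass
class WindObservation:
    date: date
    level: str  # one of WIND_LEVELS
    speed: float  # m/s, >= 0
    direction_to: float  # deg clockwise from north, direction of air movement

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("wind speed must be non-negative")
        self.direction_to = self.direction_to % 360.0


# ---------------------------------------------------------------------------
# NOAA solar-position equations


def _julian_day(dt: datetime) -> float:
    if dt.tzinfo is not None:
        dt = dt.astimezone(timezone.utc).replace(tzinfo=None)
    y, m = dt.year, dt.month
    frac = (dt.hour + dt.minute / 60.0 + dt.second / 3600.0 + dt.microsecond / 3.6e9) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + dt.day + b - 1524.5 + frac


def _solar_coords(jc: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at Julian century jc."""
    gml = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m = math.radians(gma)
    eq_center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = gml + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    decl = math.degrees(math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0 = math.radians(gml)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y * var_y * math.sin(4 * l0)
        - 1.25 * ecc * ecc * math.sin(2 * m)
    )
    return decl, eq_time


def _refraction(elev: float) -> float:
    """NOAA atmospheric refraction correction (deg) for true elevation (deg)."""
    if elev > 85.0:
        return 0.0
    te = math.tan(math.radians(elev))
    if elev > 5.0:
        corr = 58.1 / te - 0.07 / te**3 + 0.000086 / te**5
    elif elev > -0.575:
        corr = 1735.0 + elev * (-518.2 + elev * (103.4 + elev * (-12.79 + elev * 0.711)))
    else:
        corr = -20.774 / te
    return corr / 3600.0


def sun_elevation(
    lat: float, lon: float, timestamp_utc: datetime, refraction: bool = True
) -> float:
    """Solar elevation (deg) at a UTC instant.

    ``lat``/``lon`` in degrees, longitude east-positive.  With
    ``refraction=True`` (default) the standard atmospheric refraction
    correction is applied, matching the NOAA calculator's corrected
    elevation; with ``refraction=False`` the geometric elevation is returned,
    which equals -0.833 deg exactly at the computed sunset/sunrise instants.
    Accuracy is within about 0.1 deg for 1950-2050.
    """
    if abs(lat) > 90:
        raise ValueError("latitude must be within [-90, 90]")
    ts = pd.Timestamp(timestamp_utc)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    dt = ts.to_pydatetime(warn=False)
    jd = _julian_day(dt)
    jc = (jd - 2451545.0) / 36525.0
    decl, eq_time = _solar_coords(jc)
    minutes = dt.hour * 60.0 + dt.minute + dt.second / 60.0 + dt.microsecond / 6e7
    tst = (minutes + eq_time + 4.0 * lon) % 1440.0
    ha = tst / 4.0 - 180.0 if tst / 4.0 >= 0 else tst / 4.0 + 180.0
    phi, d, h = map(math.radians, (lat, decl, ha))
    cos_zen = math.sin(phi) * math.sin(d) + math.cos(phi) * math.cos(d) * math.cos(h)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    elev = 90.0 - math.degrees(math.acos(cos_zen))
    return elev + _refraction(elev) if refraction else elev


def _event_minutes(lat: float, lon: float, day: date, rising: bool) -> float:
    """Sunrise/sunset time as minutes past UTC midnight of ``day``."""
    # iterate: declination/eq-time evaluated at successively better event times
    minutes = 720.0 - 4.0 * lon
    for _ in range(3):
        jd = _julian_day(datetime(day.year, day.month, day.day)) + minutes / 1440.0
        jc = (jd - 2451545.0) / 36525.0
        decl, eq_time = _solar_coords(jc)
        phi, d = math.radians(lat), math.radians(decl)
        cos_ha = (
            math.cos(math.radians(90.0 - SUNSET_ELEVATION)) / (math.cos(phi) * math.cos(d))
            - math.tan(phi) * math.tan(d)
        )
        if cos_ha > 1.0:
            raise PolarDayNightError(f"polar night at lat {lat} on {day}")
        if cos_ha < -1.0:
            raise PolarDayNightError(f"polar day (midnight sun) at lat {lat} on {day}")
        ha = math.degrees(math.acos(cos_ha))
        noon = 720.0 - 4.0 * lon - eq_time
        minutes = noon - 4.0 * ha if rising else noon + 4.0 * ha
    return minutes


def sun_events(lat: float, lon: float, day: date) -> SolarEvent:
    """Sunset on ``day`` and the next sunrise, both UTC; -0.833 deg convention.

    Raises :class:`PolarDayNightError` under midnight sun or polar night.
    """
    day = pd.Timestamp(day).date()
    sunset_min = _event_minutes(lat, lon, day, rising=False)
    midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    sunset = midnight + timedelta(minutes=sunset_min)
    nxt = day + timedelta(days=1)
    sunrise_min = _event_minutes(lat, lon, nxt, rising=True)
    midnight2 = datetime(nxt.year, nxt.month, nxt.day, tzinfo=timezone.utc)
    sunrise = midnight2 + timedelta(minutes=sunrise_min)
    if sunrise <= sunset:
        sunrise += timedelta(days=1)
    return SolarEvent(date=day, sunset_utc=sunset, sunrise_next_utc=sunrise)


# ---------------------------------------------------------------------------
# Wind support


def tailwind_component(wind_speed: float, wind_direction_to: float, goal_direction: float) -> float:
    """Signed wind support: ``cos(direction_to - goal) * speed``.

    Positive for wind blowing toward the goal, negative for headwind; the
    magnitude never exceeds the wind speed.
    """
    if wind_speed < 0:
        raise ValueError("wind speed must be non-negative")
    return math.cos(math.radians(wind_direction_to - goal_direction)) * wind_speed


def max_tailwind(observations: Sequence[WindObservation] | Iterable, goal_direction: float) -> float:
    """Best tailwind component over the available pressure levels."""
    comps = [tailwind_component(o.speed, o.direction_to, goal_direction) for o in observations]
    if not comps:
        raise ValueError("need at least one wind observation")
    return max(comps)


def read_covariates(path, goal_direction: float = 233.0) -> pd.DataFrame:
    """Read the daily-covariate table and derive the midnight tailwind column.

    Expected columns: ``date, temp_surface_C, wind_surface_ms,
    wind_surface_dir_to``, optional per-level ``wind_<lvl>_ms`` /
    ``wind_<lvl>_dir_to`` for levels 1000/925/850/700 mbar, optional
    precomputed ``twc_midnight_ms``.  When ``twc_midnight_ms`` is absent it is
    derived as the level-maximum tailwind toward ``goal_direction``.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    if "twc_midnight_ms" not in df.columns:
        twc = []
        for row in df.itertuples(index=False):
            obs = [
                WindObservation(
                    row.date.date(), "surface", row.wind_surface_ms, row.wind_surface_dir_to
                )
            ]
            for lvl in ("1000", "925", "850", "700"):
                s, d = f"wind_{lvl}_ms", f"wind_{lvl}_dir_to"
                if s in df.columns and d in df.columns:
                    obs.append(WindObservation(row.date.date(), lvl, getattr(row, s), getattr(row, d)))
            twc.append(max_tailwind(obs, goal_direction))
        df["twc_midnight_ms"] = twc
    return df
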