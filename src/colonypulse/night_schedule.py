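"""Solar and lunar timing for nocturnal colony monitoring.

Every sensor in the pipeline (acoustic recorder, IR camera, marine radar)
samples from local sunset to sunrise, so the night — labelled by the
evening's calendar date — is the common temporal frame.  This module
computes, per site and date, geometric sunset and sunrise and a
minute-resolution track of lunar illuminated fraction and whether the moon
is above the horizon.  Moonlight matters because storm-petrels avoid the
colony on bright nights, and the moon covariates feed both the synthetic
generator and the exported model-ready tables.

Timestamps are stored in UTC; the site's fixed UTC offset is carried
alongside so local-clock windows (e.g., camera bursts at 01:00–03:00) can
be resolved explicitly.  Positions use compact low-precision series: a
NOAA-style solar position and a truncated lunar theory.  Rise/set is the
geometric crossing of altitude 0° (no refraction) found on a 1-minute
grid, which is the resolution at which all downstream covariates are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta, timezone
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MoonSample",
    "NightSchedule",
    "RateWindow",
    "NoNightError",
    "WindowError",
    "compute_night",
    "resolve_window",
    "schedule_to_csv",
    "sun_altitude_deg",
    "moon_position",
]

_J2000 = 2451545.0


class NoNightError(ValueError):
    """Raised when the sun does not set (or rise) at the site/date (polar day/night)."""


class WindowError(ValueError):
    """Raised when a rate window resolves to an empty or inverted interval."""


def _julian_day(t: datetime) -> float:
    """Julian day (UT) of an aware or naive-UTC datetime."""
    if t.tzinfo is not None:
        t = t.astimezone(timezone.utc).replace(tzinfo=None)
    epoch = datetime(2000, 1, 1, 12, 0, 0)
    return _J2000 + (t - epoch).total_seconds() / 86400.0


def _sun_ecliptic_longitude(jd):
    """Geometric ecliptic longitude of the sun, degrees."""
    d = np.asarray(jd, dtype=float) - _J2000
    g = np.radians((357.529 + 0.98560028 * d) % 360.0)  # mean anomaly
    q = (280.459 + 0.98564736 * d) % 360.0              # mean longitude
    lam = q + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g)
    return lam % 360.0


def _obliquity_deg(jd):
    d = np.asarray(jd, dtype=float) - _J2000
    return 23.439 - 0.00000036 * d


def _gmst_deg(jd):
    d = np.asarray(jd, dtype=float) - _J2000
    return (280.46061837 + 360.98564736629 * d) % 360.0


def _equatorial(lam_deg, beta_deg, jd):
    """Ecliptic (lon, lat) -> (RA, Dec), all degrees."""
    eps = np.radians(_obliquity_deg(jd))
    lam = np.radians(lam_deg)
    beta = np.radians(beta_deg)
    sin_dec = np.sin(beta) * np.cos(eps) + np.cos(beta) * np.sin(eps) * np.sin(lam)
    dec = np.arcsin(np.clip(sin_dec, -1.0, 1.0))
    y = np.sin(lam) * np.cos(eps) - np.tan(beta) * np.sin(eps)
    ra = np.arctan2(y, np.cos(lam))
    return np.degrees(ra) % 360.0, np.degrees(dec)


def _altitude_deg(ra_deg, dec_deg, jd, lat_deg, lon_deg):
    """Geocentric geometric altitude of a body, degrees (no refraction/parallax)."""
    lst = _gmst_deg(jd) + lon_deg
    ha = np.radians((lst - ra_deg) % 360.0)
    lat = math.radians(lat_deg)
    dec = np.radians(dec_deg)
    sin_alt = math.sin(lat) * np.sin(dec) + math.cos(lat) * np.cos(dec) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))


def sun_altitude_deg(t, lat_deg: float, lon_deg: float):
    """Geometric solar altitude (degrees) at datetime(s) ``t`` (UTC)."""
    if isinstance(t, datetime):
        jd = _julian_day(t)
    else:
        jd = np.array([_julian_day(x) for x in t])
    lam = _sun_ecliptic_longitude(jd)
    ra, dec = _equatorial(lam, 0.0, jd)
    return _altitude_deg(ra, dec, jd, lat_deg, lon_deg)


def moon_position(jd):
    """Truncated lunar theory: ecliptic lon/lat (deg) and illuminated fraction.

    Keeps the largest periodic terms only; illumination is accurate to a few
    hundredths, which is ample for a behavioural covariate sampled nightly.
    """
    d = np.asarray(jd, dtype=float) - _J2000
    T = d / 36525.0
    # fundamental arguments, degrees
    Lp = (218.3164477 + 481267.88123421 * T) % 360.0   # mean longitude
    D = np.radians((297.8501921 + 445267.1114034 * T) % 360.0)   # elongation
    M = np.radians((357.5291092 + 35999.0502909 * T) % 360.0)    # sun anomaly
    Mp = np.radians((134.9633964 + 477198.8675055 * T) % 360.0)  # moon anomaly
    F = np.radians((93.2720950 + 483202.0175233 * T) % 360.0)    # arg latitude

    lon = (
        Lp
        + 6.288774 * np.sin(Mp)
        + 1.274027 * np.sin(2 * D - Mp)
        + 0.658314 * np.sin(2 * D)
        + 0.213618 * np.sin(2 * Mp)
        - 0.185116 * np.sin(M)
        - 0.114332 * np.sin(2 * F)
    ) % 360.0
    lat = (
        5.128122 * np.sin(F)
        + 0.280602 * np.sin(Mp + F)
        + 0.277693 * np.sin(Mp - F)
        + 0.173237 * np.sin(2 * D - F)
    )
    sun_lon = _sun_ecliptic_longitude(np.asarray(jd, dtype=float))
    # geocentric elongation -> illuminated fraction; sun-moon distance ratio
    # correction is < 0.3% and ignored
    cos_psi = np.cos(np.radians(lat)) * np.cos(np.radians(lon - sun_lon))
    illum = (1.0 - cos_psi) / 2.0
    return lon, lat, np.clip(illum, 0.0, 1.0)


def moon_altitude_deg(jd, lat_deg: float, lon_deg: float):
    lon, lat, _ = moon_position(jd)
    ra, dec = _equatorial(lon, lat, jd)
    return _altitude_deg(ra, dec, jd, lat_deg, lon_deg)


@dataclass(frozen=True)
class MoonSample:
    time: datetime
    illumination: float
    above_horizon: bool


@dataclass
class NightSchedule:
    """Per-night solar/lunar frame. ``date`` labels the evening; minutes after
    midnight belong to the same (previous evening's) night."""

    site_lat: float
    site_lon: float
    date: _date
    sunset: datetime            # UTC
    sunrise: datetime           # UTC, next morning
    local_utc_offset: float     # hours
    moon_times: np.ndarray = field(repr=False)      # datetime64[s], 1-min grid
    moon_illumination: np.ndarray = field(repr=False)
    moon_above: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.sunset >= self.sunrise:
            raise ValueError("sunset must precede sunrise")

    @property
    def night_length(self) -> timedelta:
        return self.sunrise - self.sunset

    def moon_track(self) -> list[MoonSample]:
        times = pd.to_datetime(self.moon_times).to_pydatetime()
        return [
            MoonSample(t.replace(tzinfo=timezone.utc), float(i), bool(a))
            for t, i, a in zip(times, self.moon_illumination, self.moon_above)
        ]

    def moon_factor_at(self, t: datetime) -> tuple[float, bool]:
        """(illumination, above_horizon) at the nearest minute of the track."""
        t = _naive_utc(t)
        idx = int(round((t - _naive_utc(self.sunset)).total_seconds() / 60.0))
        idx = min(max(idx, 0), len(self.moon_illumination) - 1)
        return float(self.moon_illumination[idx]), bool(self.moon_above[idx])

    @property
    def mean_illumination(self) -> float:
        return float(np.mean(self.moon_illumination))

    @property
    def fraction_of_night_moon_up(self) -> float:
        return float(np.mean(self.moon_above))


@dataclass(frozen=True)
class RateWindow:
    """A summary window anchored at sunset or sunrise, in signed minutes.

    The paper-standard comparison windows are ``RateWindow("sunset", 120, 240)``
    and ``RateWindow("sunrise", -120, -60)`` for aerial calls and
    ``RateWindow("sunrise", -440, -120)`` for ground calls.
    """

    anchor: Literal["sunset", "sunrise"]
    start_offset_min: float
    end_offset_min: float

    def __post_init__(self):
        if self.anchor not in ("sunset", "sunrise"):
            raise ValueError(f"anchor must be 'sunset' or 'sunrise', got {self.anchor!r}")


def _naive_utc(t: datetime) -> datetime:
    if t.tzinfo is not None:
        return t.astimezone(timezone.utc).replace(tzinfo=None)
    return t


def _find_crossing(times_jd, alts, direction: str) -> float | None:
    """First jd where alts crosses zero in the given direction; linear interp."""
    a0, a1 = alts[:-1], alts[1:]
    if direction == "down":
        hits = np.nonzero((a0 >= 0) & (a1 < 0))[0]
    else:
        hits = np.nonzero((a0 < 0) & (a1 >= 0))[0]
    if len(hits) == 0:
        return None
    i = hits[0]
    frac = a0[i] / (a0[i] - a1[i])
    return float(times_jd[i] + frac * (times_jd[i + 1] - times_jd[i]))


def compute_night(lat: float, lon: float, date: _date, utc_offset: float) -> NightSchedule:
    """Compute the NightSchedule for the night beginning on ``date``'s evening.

    Sunset is the geometric altitude-0 down-crossing after local noon on
    ``date``; sunrise is the subsequent up-crossing.  Raises
    :class:`NoNightError` when either event is missing within 24 h (polar
    day/night).
    """
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ValueError("latitude/longitude out of range")
    local_noon = datetime(date.year, date.month, date.day, 12) - timedelta(hours=utc_offset)
    jd0 = _julian_day(local_noon)
    # minute grid from local noon over 24 h
    grid = jd0 + np.arange(0, 24 * 60 + 1) / 1440.0
    lam = _sun_ecliptic_longitude(grid)
    ra, dec = _equatorial(lam, 0.0, grid)
    alts = _altitude_deg(ra, dec, grid, lat, lon)
    jd_set = _find_crossing(grid, alts, "down")
    if jd_set is None:
        raise NoNightError(f"no sunset at ({lat}, {lon}) on {date}")
    after = grid > jd_set
    jd_rise = _find_crossing(grid[after], alts[after], "up")
    if jd_rise is None:
        raise NoNightError(f"no sunrise following sunset at ({lat}, {lon}) on {date}")

    def _to_dt(jd: float) -> datetime:
        return datetime(2000, 1, 1, 12) + timedelta(days=jd - _J2000)

    sunset = _to_dt(jd_set).replace(microsecond=0)
    sunrise = _to_dt(jd_rise).replace(microsecond=0)

    n_min = int(math.ceil((sunrise - sunset).total_seconds() / 60.0)) + 1
    track_jd = _julian_day(sunset) + np.arange(n_min) / 1440.0
    _, _, illum = moon_position(track_jd)
    alt_moon = moon_altitude_deg(track_jd, lat, lon)
    times = np.array(
        [np.datetime64(sunset + timedelta(minutes=int(k)), "s") for k in range(n_min)]
    )
    return NightSchedule(
        site_lat=lat,
        site_lon=lon,
        date=date,
        sunset=sunset,
        sunrise=sunrise,
        local_utc_offset=utc_offset,
        moon_times=times,
        moon_illumination=illum,
        moon_above=alt_moon > 0.0,
    )


def resolve_window(schedule: NightSchedule, window: RateWindow) -> tuple[datetime, datetime]:
    """Resolve a RateWindow to an absolute half-open UTC interval [start, end)."""
    anchor = schedule.sunset if window.anchor == "sunset" else schedule.sunrise
    start = anchor + timedelta(minutes=window.start_offset_min)
    end = anchor + timedelta(minutes=window.end_offset_min)
    if end <= start:
        raise WindowError(f"window resolves to empty/inverted interval [{start}, {end})")
    lo = schedule.sunset - timedelta(hours=12)
    hi = schedule.sunrise + timedelta(hours=12)
    if start < lo or end > hi:
        raise WindowError("window offsets resolve outside [sunset-12h, sunrise+12h]")
    return start, end


def schedule_to_csv(schedules: Sequence[NightSchedule], path) -> pd.DataFrame:
    """Export nightly schedule summaries; returns the frame written."""
    rows = [
        {
            "night_date": s.date.isoformat(),
            "sunset_utc": s.sunset.isoformat(),
            "sunrise_utc": s.sunrise.isoformat(),
            "mean_illumination": s.mean_illumination,
            "fraction_of_night_moon_up": s.fraction_of_night_moon_up,
        }
        for s in schedules
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
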