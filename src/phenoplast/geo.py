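"""Spatial and temporal utilities for the farm network.

Julian-day calendar conventions, great-circle distances between farms and
weather stations, nearest-station assignment, and astronomical day length
(the photoperiod cue that varies with latitude across the study area).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: Solar altitude (degrees) defining sunrise/sunset: -50 arc-minutes accounts
#: for atmospheric refraction (~34') plus the solar semidiameter (~16').
SUNRISE_ALTITUDE_DEG = -0.833
#: Highest absolute latitude supported by :func:`day_length_minutes`; beyond
#: this, polar day/night can occur and the hour-angle equation has no solution.
MAX_DAYLENGTH_LATITUDE = 66.5


@dataclass(frozen=True)
class GeoPoint:
    """A point on the Earth's surface in decimal degrees (elevation in m)."""

    latitude: float
    longitude: float
    elevation: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


def _as_date(date: dt.date | str) -> dt.date:
    if isinstance(date, dt.datetime):
        return date.date()
    if isinstance(date, dt.date):
        return date
    if isinstance(date, str):
        return dt.date.fromisoformat(date)
    raise TypeError(f"not a calendar date: {date!r}")


def julian_day(date: dt.date | str) -> int:
    """Ordinal day of the year (January 1 = 1; Feb 29 = 60 in leap years)."""
    return _as_date(date).timetuple().tm_yday


def date_from_julian(year: int, day: int) -> dt.date:
    """Inverse of :func:`julian_day` for a given calendar year."""
    n_days = 366 if _is_leap(year) else 365
    if not 1 <= day <= n_days:
        raise ValueError(f"Julian day {day} outside [1, {n_days}] for {year}")
    return dt.date(year, 1, 1) + dt.timedelta(days=day - 1)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1 = math.radians(a.latitude), math.radians(a.longitude)
    lat2, lon2 = math.radians(b.latitude), math.radians(b.longitude)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def nearest_stations(
    farm: GeoPoint, stations: Mapping[str, GeoPoint], k: int = 1
) -> list[str]:
    """The ``k`` station ids closest to ``farm``, nearest first.

    Ties in distance are broken by lexicographic station id so that the
    assignment is deterministic.
    """
    if not stations:
        raise ValueError("empty station list")
    if k > len(stations):
        raise ValueError(f"k={k} exceeds number of stations ({len(stations)})")
    ranked = sorted(stations, key=lambda sid: (haversine_km(farm, stations[sid]), str(sid)))
    return ranked[:k]


def solar_declination_rad(day_of_year: int) -> float:
    """Solar declination (radians) from the NOAA low-accuracy Fourier fit."""
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1)
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def day_length_minutes(latitude: float, date: dt.date | str) -> float:
    """Sunrise-to-sunset duration in decimal minutes.

    Uses the standard solar-position equations (declination from the
    fractional year; sunrise hour angle at solar altitude -0.833 degrees to
    include refraction and the solar semidiameter). Valid only where the sun
    rises and sets every day, i.e. |latitude| < 66.5.
    """
    if abs(latitude) >= MAX_DAYLENGTH_LATITUDE:
        raise ValueError(
            f"latitude {latitude} outside supported range "
            f"(|lat| < {MAX_DAYLENGTH_LATITUDE}; polar day/night not handled)"
        )
    doy = julian_day(date)
    decl = solar_declination_rad(doy)
    lat = math.radians(latitude)
    zenith = math.radians(90.0 - SUNRISE_ALTITUDE_DEG)
    cos_ha = (math.cos(zenith) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha_deg = math.degrees(math.acos(cos_ha))
    # 1 degree of hour angle = 4 minutes; daylight spans 2*ha.
    return 8.0 * ha_deg


@dataclass
class DailyWeatherSeries:
    """Per-station daily weather (mean temperature degC, rainfall mm).

    Backed by a DataFrame with columns ``date`` (datetime64), ``tmean`` and
    ``rain``; either value column may contain NaN for missing days. Dates must
    be strictly increasing with no duplicates, and rainfall non-negative where
    present.
    """

    station_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"date", "tmean", "rain"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"weather series missing columns: {sorted(missing)}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if df["date"].duplicated().any():
            raise ValueError(f"duplicate dates in series {self.station_id!r}")
        if not df["date"].is_monotonic_increasing:
            df = df.sort_values("date")
        rain = df["rain"].to_numpy(dtype=float)
        if np.nanmin(rain, initial=0.0) < 0:
            raise ValueError(f"negative rainfall in series {self.station_id!r}")
        df["year"] = df["date"].dt.year.to_numpy()
        df["doy"] = df["date"].dt.dayofyear.to_numpy()
        self.data = df.reset_index(drop=True)

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def value_matrix(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """(years, matrix) with one row per year and one column per Julian day.

        Column ``j`` holds day ``j + 1``; days absent from the record are NaN.
        The matrix has 366 columns so leap years index naturally.
        """
        if variable not in ("tmean", "rain"):
            raise ValueError(f"unknown weather variable {variable!r}")
        years = np.asarray(self.years)
        mat = np.full((len(years), 366), np.nan)
        yindex = {y: i for i, y in enumerate(years)}
        rows = self.data["year"].map(yindex).to_numpy()
        cols = self.data["doy"].to_numpy() - 1
        mat[rows, cols] = self.data[variable].to_numpy(dtype=float)
        return years, mat


def average_stations(
    series: Sequence[DailyWeatherSeries], station_id: str = "station-mean"
) -> DailyWeatherSeries:
    """Average several stations into one series, day by day.

    Each day's value is the mean over stations reporting that day (the study
    averaged its three stations nearest the network centroid into a single
    climate series before the window scan).
    """
    if not series:
        raise ValueError("no series to average")
    frames = []
    for s in series:
        frames.append(s.data[["date", "tmean", "rain"]])
    merged = (
        pd.concat(frames, ignore_index=True)
        .groupby("date", as_index=False)
        .mean(numeric_only=True)
        .sort_values("date")
    )
    return DailyWeatherSeries(station_id=station_id, data=merged)


def assign_station_series(
    farms: Mapping[str, GeoPoint],
    stations: Mapping[str, GeoPoint],
    weather: Mapping[str, DailyWeatherSeries],
    k: int = 1,
) -> dict[str, DailyWeatherSeries]:
    """Per-farm weather series from each farm's ``k`` nearest stations.

    With ``k=1`` (default) every farm simply uses its nearest station's
    record; with ``k>1`` the nearest stations are averaged day by day.
    """
    out: dict[str, DailyWeatherSeries] = {}
    for farm_id, point in farms.items():
        ids = nearest_stations(point, stations, k=k)
        missing = [sid for sid in ids if sid not in weather]
        if missing:
            raise KeyError(f"no weather record for station(s) {missing} (farm {farm_id!r})")
        if k == 1:
            out[farm_id] = weather[ids[0]]
        else:
            out[farm_id] = average_stations(
                [weather[sid] for sid in ids], station_id="+".join(map(str, ids))
            )
    return out
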