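"""Readers, writers and pipeline configuration.

All interchange files are comma-separated UTF-8 text with a mandatory header
row and "." as the decimal mark; missing values are empty fields or ``NA``.
Dates are ISO-8601; laying dates may be given either as ISO dates or as
Julian-day integers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geo import DailyWeatherSeries, GeoPoint, julian_day

logger = logging.getLogger(__name__)

_NA = ["", "NA"]


class RecordValidationError(ValueError):
    """Raised when an input file contains malformed rows."""


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing required column(s) {missing}")


def read_sites(path: str | Path) -> tuple[pd.DataFrame, dict[str, GeoPoint]]:
    """Read a farms or stations table (id, lat, lon, elev[, n_boxes]).

    The id column may be named ``farm_id`` or ``station_id``. Returns the raw
    table plus a mapping from id to :class:`GeoPoint`.
    """
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    id_col = next((c for c in ("farm_id", "station_id", "id") if c in df.columns), None)
    if id_col is None:
        raise RecordValidationError(f"{path}: no farm_id/station_id/id column")
    _require_columns(df, ["latitude", "longitude"], path)
    df[id_col] = df[id_col].astype(str)
    points = {}
    for i, row in df.iterrows():
        try:
            points[row[id_col]] = GeoPoint(
                float(row["latitude"]),
                float(row["longitude"]),
                float(row["elevation"]) if "elevation" in df.columns and pd.notna(row["elevation"]) else None,
            )
        except (TypeError, ValueError) as exc:
            raise RecordValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return df, points


def read_weather(path: str | Path) -> dict[str, DailyWeatherSeries]:
    """Read daily station weather (station_id, date, tmean_c, rain_mm)."""
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(df, ["station_id", "date", "tmean_c", "rain_mm"], path)
    df = df.rename(columns={"tmean_c": "tmean", "rain_mm": "rain"})
    df["station_id"] = df["station_id"].astype(str)
    for col in ("tmean", "rain"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    out = {}
    for sid, grp in df.groupby("station_id"):
        out[sid] = DailyWeatherSeries(sid, grp[["date", "tmean", "rain"]])
    return out


def write_weather(weather: Mapping[str, DailyWeatherSeries], path: str | Path) -> None:
    frames = []
    for sid, series in weather.items():
        d = series.data[["date", "tmean", "rain"]].copy()
        d.insert(0, "station_id", sid)
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"tmean": "tmean_c", "rain": "rain_mm"})
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def read_breeding_records(path: str | Path) -> pd.DataFrame:
    """Read and validate breeding records.

    Columns: farm_id, nestbox_id, year, female_id (may be empty), age_class
    (SY/ASY/unknown), lay_date (Julian integer or ISO date), clutch_order.
    Malformed rows are rejected together, with their line numbers.
    """
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False, dtype=str)
    _require_columns(
        df,
        ["farm_id", "nestbox_id", "year", "female_id", "age_class", "lay_date", "clutch_order"],
        path,
    )
    errors: list[str] = []
    lay = np.empty(len(df))
    for i, raw in enumerate(df["lay_date"]):
        line = i + 2
        try:
            if "-" in str(raw):
                lay[i] = julian_day(str(raw))
            else:
                lay[i] = int(raw)
        except (ValueError, TypeError):
            errors.append(f"line {line}: unparseable lay_date {raw!r}")
            lay[i] = np.nan
            continue
        if not 1 <= lay[i] <= 366:
            errors.append(f"line {line}: lay_date {lay[i]:.0f} outside [1, 366]")
    year = pd.to_numeric(df["year"], errors="coerce")
    for i in np.flatnonzero(year.isna()):
        errors.append(f"line {i + 2}: unparseable year {df['year'].iloc[i]!r}")
    order = pd.to_numeric(df["clutch_order"], errors="coerce")
    for i in np.flatnonzero(~(order >= 1)):
        errors.append(f"line {i + 2}: clutch_order must be >= 1")
    bad_age = ~df["age_class"].isin(["SY", "ASY", "unknown"])
    for i in np.flatnonzero(bad_age.to_numpy()):
        errors.append(f"line {i + 2}: age_class {df['age_class'].iloc[i]!r} not SY/ASY/unknown")
    if errors:
        raise RecordValidationError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    out = pd.DataFrame(
        {
            "farm_id": df["farm_id"].astype(str),
            "nestbox_id": df["nestbox_id"].astype(str),
            "year": year.astype(int),
            "female_id": df["female_id"].where(df["female_id"].notna() & (df["female_id"] != "")),
            "age_class": df["age_class"],
            "lay_date": lay.astype(int),
            "clutch_order": order.astype(int),
        }
    )
    logger.info("read %d breeding records from %s", len(out), path)
    return out


def write_breeding_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Paths, scan settings and analysis options for a full pipeline run."""

    records: str
    farms: str
    stations: str
    weather: str
    out_dir: str = "pheno-results"
    frame: tuple[int, int] = (60, 151)
    span: tuple[int, int] = (5, 91)
    temp_stat: str = "mean"
    rain_stat: str = "sum"
    rain_window_stat: str = "mean"
    alpha: float = 0.05
    station_k: int = 1
    scan_station_k: int = 3
    density_split: str = "subject"
    exclude_first_year: bool = True
    farm_random_in_determinants: bool = False
    seed: int = 20230401

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        f0, f1 = self.frame
        s0, s1 = self.span
        if not (f0 < f1 and 1 <= s0 <= s1 <= f1 - f0):
            raise ValueError("frame/span do not define a valid window scan")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("frame", "span"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        data["frame"] = list(self.frame)
        data["span"] = list(self.span)
        return yaml.safe_dump(data, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
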