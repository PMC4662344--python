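"""Synthetic datasets with the statistical structure the analyses assume.

The full generator emulates a 10-year nest-box study: 40 farms of 10 boxes
spread over an ~80-km latitudinal span, ~10 weather stations, farm occupancy
declining on the logit scale, philopatric females returning across years and
ageing from second-year (SY) to after-second-year (ASY), and laying dates
produced by a linear mixed model on standardized covariates with year, farm,
farm-year and female random effects (optionally a female random slope on
within-female density). Every generative parameter is recorded in a
:class:`SyntheticTruth` so recovery tests can compare estimates to truth.

Smaller targeted simulators (farm-year summaries, consecutive-year deltas,
female-year tables, window-scan series) generate data directly at the level
each analysis consumes; they are the workhorses of the calibration and
recovery test suites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo import (
    DailyWeatherSeries,
    GeoPoint,
    date_from_julian,
    haversine_km,
    nearest_stations,
)
from .lmm import standardize
from .windows import WindowSpec

KM_PER_DEG_LAT = 2.0 * np.pi * 6371.0 / 360.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameter set for one simulated study.

    Fixed effects are on the scale of standardized covariates (days per SD);
    the intercept and age effect are in days. Variance components are
    standard deviations in days. Trend slopes give the deterministic
    interannual drift of each driver. Defaults reproduce the study
    conditions: headline coefficient estimates for the fixed effects, an
    occupancy level giving ~2,270 first clutches over 40 farms x 10 years,
    ~92% farm philopatry and a ~40% annual return rate.
    """

    intercept: float = 141.415
    beta_latitude: float = 0.479
    beta_density: float = -1.469  # between-female (habitat) component
    beta_density_within: float = 0.0  # within-female response to density change
    beta_temperature: float = -0.929
    beta_temp_x_density: float = -0.450
    beta_age_asy: float = -5.683

    sd_year: float = 2.0
    sd_farm: float = 1.0
    sd_farmyear: float = 3.2
    sd_female: float = 3.5
    sd_resid: float = 5.5
    sd_female_slope_density: float = 0.8
    cor_female_slope: float = 0.0

    trend_temp_per_year: float = 0.183
    trend_density_logit_per_year: float = -0.093
    lay_trend_direct_per_year: float = -0.45

    window_temp: WindowSpec = field(default_factory=lambda: WindowSpec(96, 129))
    window_rain: WindowSpec = field(default_factory=lambda: WindowSpec(128, 133))
    sd_window_anomaly: float = 0.9
    sd_year_anomaly: float = 0.4
    ar1_rho: float = 0.6
    ar1_innovation_sd: float = 2.2
    station_offset_sd: float = 0.3

    occupancy_logit: float = 0.32
    sd_farm_quality: float = 0.8
    philopatry: float = 0.92
    return_rate: float = 0.40
    sy_fraction_recruits: float = 0.65
    second_clutch_fraction: float = 0.127

    def replace(self, **kwargs) -> "SyntheticTruth":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    farms: pd.DataFrame
    stations: pd.DataFrame
    weather: dict[str, DailyWeatherSeries]
    records: pd.DataFrame
    truth: SyntheticTruth
    seed: int


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def generate_landscape(
    n_farms: int = 40,
    centroid: GeoPoint = GeoPoint(45.57, -72.64),
    lat_span_km: float = 80.0,
    lon_span_km: float = 127.0,
    n_stations: int = 10,
    n_boxes: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter farms and stations around the study centroid.

    Farms are uniform over the latitude/longitude spans (defaults give the
    ~10,200 km^2 study area with its 80-km latitudinal extent); elevations are
    drawn strongly correlated with longitude, mimicking the real terrain
    gradient that makes elevation and longitude collinear (r > 0.9). Stations
    are placed near a spread-out subset of farms; extra stations are added if
    any farm would otherwise be more than 20 km from its nearest station.
    """
    if n_farms < 2:
        raise ValueError("need at least 2 farms")
    rng = np.random.default_rng() if rng is None else rng
    half_lat = 0.5 * lat_span_km / KM_PER_DEG_LAT
    km_per_deg_lon = KM_PER_DEG_LAT * np.cos(np.radians(centroid.latitude))
    half_lon = 0.5 * lon_span_km / km_per_deg_lon

    lats = centroid.latitude + rng.uniform(-half_lat, half_lat, n_farms)
    # pin the extremes so the latitudinal span is the stated one
    lats[np.argmin(lats)] = centroid.latitude - half_lat
    lats[np.argmax(lats)] = centroid.latitude + half_lat
    lons = centroid.longitude + rng.uniform(-half_lon, half_lon, n_farms)
    lon_rel = (lons - centroid.longitude) / half_lon
    elev = 150.0 - 90.0 * lon_rel + rng.normal(0.0, 12.0, n_farms)
    farms = pd.DataFrame(
        {
            "farm_id": [f"F{i:02d}" for i in range(n_farms)],
            "latitude": lats,
            "longitude": lons,
            "elevation": elev,
            "n_boxes": n_boxes,
        }
    )

    order = np.argsort(lats + 0.3 * lon_rel)
    anchors = order[np.linspace(0, n_farms - 1, min(n_stations, n_farms)).astype(int)]
    st_lat = lats[anchors] + rng.normal(0, 3.0 / KM_PER_DEG_LAT, len(anchors))
    st_lon = lons[anchors] + rng.normal(0, 3.0 / km_per_deg_lon, len(anchors))
    st_points = [GeoPoint(la, lo) for la, lo in zip(st_lat, st_lon)]
    # coverage guarantee: every farm within 20 km of some station
    for i in range(n_farms):
        fp = GeoPoint(lats[i], lons[i])
        if min(haversine_km(fp, sp) for sp in st_points) > 20.0:
            st_points.append(
                GeoPoint(
                    lats[i] + rng.normal(0, 2.0 / KM_PER_DEG_LAT),
                    lons[i] + rng.normal(0, 2.0 / km_per_deg_lon),
                )
            )
    stations = pd.DataFrame(
        {
            "station_id": [f"S{i:02d}" for i in range(len(st_points))],
            "latitude": [p.latitude for p in st_points],
            "longitude": [p.longitude for p in st_points],
            "elevation": rng.normal(120.0, 30.0, len(st_points)),
        }
    )
    return farms, stations


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------


def generate_weather(
    stations: pd.DataFrame,
    years: Sequence[int],
    truth: SyntheticTruth = SyntheticTruth(),
    rng: np.random.Generator | None = None,
    first_day: int = 32,
    last_day: int = 181,
) -> dict[str, DailyWeatherSeries]:
    """Daily spring temperature and rainfall per station.

    Temperature = seasonal ramp + shared year anomaly + warming trend +
    window-specific year anomaly (the signal later tied to laying dates,
    confined to the truth temperature window) + station offset + AR(1)
    daily noise. Rainfall: Gamma daily draws with a lognormal year factor.
    """
    years = sorted(int(y) for y in years)
    if len(years) < 3:
        raise ValueError("need at least 3 years of weather")
    rng = np.random.default_rng() if rng is None else rng
    mid = float(np.mean(years))
    days = np.arange(first_day, last_day + 1)
    in_window = np.isin(days, np.asarray(list(truth.window_temp.days)))

    year_anom = rng.normal(0.0, truth.sd_year_anomaly, len(years))
    window_anom = rng.normal(0.0, truth.sd_window_anomaly, len(years))
    rain_factor = np.exp(rng.normal(0.0, 0.3, len(years)))

    out: dict[str, DailyWeatherSeries] = {}
    for sid in stations["station_id"]:
        offset = rng.normal(0.0, truth.station_offset_sd)
        frames = []
        for iy, year in enumerate(years):
            ramp = -3.0 + 0.17 * (days - 60)
            mean = (
                ramp
                + offset
                + year_anom[iy]
                + truth.trend_temp_per_year * (year - mid)
                + np.where(in_window, window_anom[iy], 0.0)
            )
            noise = np.empty(len(days))
            eps = rng.normal(0.0, truth.ar1_innovation_sd, len(days))
            noise[0] = eps[0] / np.sqrt(1.0 - truth.ar1_rho**2)
            for i in range(1, len(days)):
                noise[i] = truth.ar1_rho * noise[i - 1] + eps[i]
            rain = rng.gamma(0.25, 12.0 * rain_factor[iy], len(days))
            frames.append(
                pd.DataFrame(
                    {
                        "date": [date_from_julian(year, int(d)) for d in days],
                        "tmean": mean + noise,
                        "rain": rain,
                    }
                )
            )
        out[str(sid)] = DailyWeatherSeries(str(sid), pd.concat(frames, ignore_index=True))
    return out


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def generate_population(
    farms: pd.DataFrame,
    stations: pd.DataFrame,
    weather: Mapping[str, DailyWeatherSeries],
    years: Sequence[int],
    truth: SyntheticTruth = SyntheticTruth(),
    rng: np.random.Generator | None = None,
    station_k: int = 1,
) -> pd.DataFrame:
    """Breeding records for the whole study.

    Farm-year occupancy is binomial on the logit scale with a declining year
    trend and farm quality effects; boxes are filled by returning females
    (philopatric with probability ``truth.philopatry``, ASY from their second
    season) topped up with new recruits (SY with probability
    ``truth.sy_fraction_recruits``). Laying dates follow the linear mixed
    model of the truth on covariates standardized across the realized
    farm-year table, and ~12.7% of clutches are second clutches appended only
    to exercise the first-clutch filter (they carry no analysis signal).
    """
    years = sorted(int(y) for y in years)
    rng = np.random.default_rng() if rng is None else rng
    mid = float(np.mean(years))
    farm_ids = farms["farm_id"].astype(str).tolist()
    n_boxes = dict(zip(farm_ids, farms["n_boxes"]))
    farm_points = {
        str(r.farm_id): GeoPoint(r.latitude, r.longitude, r.elevation)
        for r in farms.itertuples()
    }
    station_points = {
        str(r.station_id): GeoPoint(r.latitude, r.longitude) for r in stations.itertuples()
    }
    farm_station = {
        fid: nearest_stations(p, station_points, k=station_k) for fid, p in farm_points.items()
    }

    # farm-year covariates (temperature from the farm's nearest station(s))
    from .windows import aggregate_window  # local import to avoid cycle

    temp_cache: dict[tuple[str, int], float] = {}
    for fid in farm_ids:
        sids = farm_station[fid]
        for year in years:
            vals = [
                aggregate_window(weather[s], truth.window_temp, year, "mean")
                for s in sids
            ]
            temp_cache[(fid, year)] = float(np.nanmean(vals))

    quality = dict(zip(farm_ids, rng.normal(0.0, truth.sd_farm_quality, len(farm_ids))))
    occupancy: dict[tuple[str, int], int] = {}
    for fid in farm_ids:
        for year in years:
            p = expit(
                truth.occupancy_logit
                + truth.trend_density_logit_per_year * (year - mid)
                + quality[fid]
            )
            occupancy[(fid, year)] = int(rng.binomial(n_boxes[fid], p))

    # standardization of covariates over occupied farm-years
    fy = pd.DataFrame(
        [
            {
                "farm_id": fid,
                "year": year,
                "temp": temp_cache[(fid, year)],
                "dens": occupancy[(fid, year)] / n_boxes[fid],
                "lat": farm_points[fid].latitude,
            }
            for fid in farm_ids
            for year in years
            if occupancy[(fid, year)] > 0
        ]
    )
    for col in ("temp", "dens", "lat"):
        mu, sd = fy[col].mean(), fy[col].std(ddof=1)
        fy[col + "_z"] = (fy[col] - mu) / sd
    fyz = fy.set_index(["farm_id", "year"])

    u_year = {
        y: truth.lay_trend_direct_per_year * (y - mid) + rng.normal(0, truth.sd_year)
        for y in years
    }
    u_farm = dict(zip(farm_ids, rng.normal(0.0, truth.sd_farm, len(farm_ids))))

    # female assignment across years
    next_id = [0]

    def new_female(age: str) -> dict:
        fid = f"B{next_id[0]:05d}"
        next_id[0] += 1
        return {
            "female_id": fid,
            "age_class": age,
            "intercept": rng.normal(0.0, truth.sd_female),
            "slope": rng.normal(0.0, truth.sd_female_slope_density),
        }

    alive: list[dict] = []  # females present last season, with last farm
    assignments: list[dict] = []
    for year in years:
        slots = {fid: occupancy[(fid, year)] for fid in farm_ids}
        returning = [f for f in alive if rng.random() < truth.return_rate]
        rng.shuffle(returning)
        placed = []
        for fem in returning:
            fid = fem["farm"]
            if rng.random() > truth.philopatry:
                others = [f for f in farm_ids if f != fid and slots[f] > 0]
                if others:
                    fid = others[rng.integers(len(others))]
            if slots.get(fid, 0) > 0:
                slots[fid] -= 1
                fem = dict(fem, farm=fid, age_class="ASY")
                placed.append(fem)
        for fid in farm_ids:
            while slots[fid] > 0:
                age = "SY" if rng.random() < truth.sy_fraction_recruits else "ASY"
                fem = dict(new_female(age), farm=fid)
                slots[fid] -= 1
                placed.append(fem)
        per_farm_count: dict[str, int] = {fid: 0 for fid in farm_ids}
        for fem in placed:
            fid = fem["farm"]
            assignments.append(
                {
                    "female_id": fem["female_id"],
                    "farm_id": fid,
                    "year": year,
                    "nestbox_id": f"{fid}-B{per_farm_count[fid]}",
                    "age_class": fem["age_class"],
                    "intercept": fem["intercept"],
                    "slope": fem["slope"],
                }
            )
            per_farm_count[fid] += 1
        alive = placed

    obs = pd.DataFrame(assignments)
    obs = obs.join(fyz[["temp_z", "dens_z", "lat_z"]], on=["farm_id", "year"])
    # within-female density deviation drives the individual slope
    obs["dens_W"] = obs["dens_z"] - obs.groupby("female_id")["dens_z"].transform("mean")
    u_fy = {
        (fid, y): rng.normal(0.0, truth.sd_farmyear) for fid in farm_ids for y in years
    }
    dens_B = obs["dens_z"] - obs["dens_W"]  # female mean experienced density
    eta = (
        truth.intercept
        + truth.beta_latitude * obs["lat_z"]
        + truth.beta_density * dens_B
        + truth.beta_density_within * obs["dens_W"]
        + truth.beta_temperature * obs["temp_z"]
        + truth.beta_temp_x_density * obs["temp_z"] * obs["dens_z"]
        + truth.beta_age_asy * (obs["age_class"] == "ASY").astype(float)
        + obs["year"].map(u_year)
        + obs["farm_id"].map(u_farm)
        + pd.Series([u_fy[(f, y)] for f, y in zip(obs["farm_id"], obs["year"])])
        + obs["intercept"]
        + obs["slope"] * obs["dens_W"]
        + rng.normal(0.0, truth.sd_resid, len(obs))
    )
    obs["lay_date"] = np.clip(np.round(eta), 61, 249).astype(int)
    obs["clutch_order"] = 1
    records = obs[
        ["farm_id", "nestbox_id", "year", "female_id", "age_class", "lay_date", "clutch_order"]
    ].copy()

    frac = truth.second_clutch_fraction
    if frac > 0:
        p_second = frac / (1.0 - frac)  # so seconds are `frac` of all clutches
        mask = rng.random(len(records)) < p_second
        seconds = records.loc[mask].copy()
        seconds["lay_date"] = np.clip(
            seconds["lay_date"] + rng.integers(28, 45, len(seconds)), 61, 249
        )
        seconds["clutch_order"] = 2
        records = pd.concat([records, seconds], ignore_index=True)
    return records.sort_values(["year", "farm_id", "nestbox_id", "clutch_order"]).reset_index(
        drop=True
    )


def generate_dataset(
    seed: int,
    n_farms: int = 40,
    years: Sequence[int] = tuple(range(2004, 2014)),
    truth: SyntheticTruth = SyntheticTruth(),
    n_stations: int = 10,
    station_k: int = 1,
) -> SyntheticDataset:
    """Full study dataset (landscape + weather + breeding records)."""
    rng = np.random.default_rng(seed)
    farms, stations = generate_landscape(
        n_farms=n_farms, n_stations=n_stations, rng=rng
    )
    weather = generate_weather(stations, years, truth, rng)
    records = generate_population(
        farms, stations, weather, years, truth, rng, station_k=station_k
    )
    return SyntheticDataset(farms, stations, weather, records, truth, seed)


# ---------------------------------------------------------------------------
# Targeted simulators for calibration and recovery tests
# ---------------------------------------------------------------------------


def simulate_farm_year_summaries(
    rng: np.random.Generator,
    truth: SyntheticTruth = SyntheticTruth(),
    n_farms: int = 40,
    n_years: int = 10,
    n_empty: int = 8,
    sd_noise: float = 4.05,
    temp_year_share: float = 0.85,
) -> pd.DataFrame:
    """Farm-year summary table drawn directly from the determinants model.

    Covariates are generated already standardized: latitude and elevation are
    farm-level (elevation unrelated to laying in truth), temperature is
    mostly a year-level signal (``temp_year_share`` of its SD) as in real
    spring climate, rainfall and density vary by farm-year. The response adds
    a year random effect (sd ``truth.sd_year``) and farm-year noise
    ``sd_noise`` calibrated so coefficient SEs land near the study's scale.
    """
    farm = np.repeat(np.arange(n_farms), n_years)
    year = np.tile(np.arange(n_years), n_farms)
    lat = rng.normal(0, 1, n_farms)[farm]
    elev = rng.normal(0, 1, n_farms)[farm]
    temp_year = rng.normal(0, 1, n_years)[year]
    temp = temp_year_share * temp_year + np.sqrt(1 - temp_year_share**2) * rng.normal(
        0, 1, len(farm)
    )
    rain = rng.normal(0, 1, len(farm))
    dens = rng.normal(0, 1, len(farm))
    df = pd.DataFrame(
        {
            "farm_id": farm,
            "year": year,
            "latitude": lat,
            "elevation": elev,
            "spring_temp": temp,
            "rainfall": rain,
            "breeder_density": dens,
        }
    )
    if n_empty:
        drop = rng.choice(len(df), size=n_empty, replace=False)
        df = df.drop(index=drop).reset_index(drop=True)
    # standardize on the realized table so the analysis-side standardization
    # is an exact no-op and coefficients sit on the published scale
    for col in ("latitude", "elevation", "spring_temp", "rainfall", "breeder_density"):
        z, _, _ = standardize(df[col].to_numpy())
        df[col] = z
    u_year = rng.normal(0, truth.sd_year, n_years)
    df["mean_lay_date"] = (
        truth.intercept
        + truth.beta_latitude * df["latitude"]
        + truth.beta_density * df["breeder_density"]
        + truth.beta_temperature * df["spring_temp"]
        + truth.beta_temp_x_density * df["spring_temp"] * df["breeder_density"]
        + u_year[df["year"].to_numpy()]
        + rng.normal(0, sd_noise, len(df))
    )
    return df


def simulate_delta_pairs(
    rng: np.random.Generator,
    n_pairs: int = 311,
    intercept: float = -2.415,
    slope_temp: float = -2.338,
    slope_density: float = 0.0,
    sd_delta_covariate: float = 1.27,
    sd_resid: float = 8.8,
) -> pd.DataFrame:
    """Consecutive-year delta dataset (ASY-style) from known slopes."""
    dtemp = rng.normal(0, sd_delta_covariate, n_pairs)
    ddens = rng.normal(0, sd_delta_covariate, n_pairs)
    dlay = (
        intercept
        + slope_temp * dtemp
        + slope_density * ddens
        + rng.normal(0, sd_resid, n_pairs)
    )
    return pd.DataFrame(
        {
            "female_id": [f"B{i:04d}" for i in range(n_pairs)],
            "year1": 1,
            "delta_lay": dlay,
            "delta_temp": dtemp,
            "delta_density": ddens,
            "age_first_year": "ASY",
        }
    )


def simulate_female_table(
    rng: np.random.Generator,
    n_females: int = 370,
    n_years: int = 9,
    n_farms: int = 40,
    mean_obs: float = 2.5,
    beta_within_temp: float = -1.0,
    beta_between_temp: float = -1.0,
    beta_within_dens: float = 0.0,
    beta_between_dens: float = -1.5,
    beta_age: float = -5.683,
    beta_lat: float = 0.479,
    temp_slope_vs_density: float = 0.0,
    sd_year: float = 2.0,
    sd_farm: float = 1.0,
    sd_female: float = 2.2,
    sd_slope_temp: float = 0.0,
    sd_slope_dens: float = 0.0,
    sd_resid: float = 6.0,
) -> pd.DataFrame:
    """Female-year observation table from the reaction-norm model.

    Each female is observed in 2..n consecutive-ish years (at least 2, mean
    ``mean_obs``) on one farm; temperature varies mostly between years and
    density between farm-years, so female means differ across individuals
    (the sampling heterogeneity that makes within-subject centring matter).
    ``temp_slope_vs_density`` tilts each female's within-temperature slope
    by her mean experienced density (a plasticity constraint in poor
    habitat). Columns match
    :func:`phenoplast.pipeline.random_regression_ladder`.
    """
    u_year = rng.normal(0, sd_year, n_years)
    year_temp = rng.normal(0, 0.9, n_years)
    u_farm = rng.normal(0, sd_farm, n_farms)
    farm_lat = rng.normal(0, 1, n_farms)
    rows = []
    for i in range(n_females):
        n_obs = min(n_years, 2 + rng.poisson(max(mean_obs - 2.0, 0.0)))
        start = rng.integers(0, n_years - n_obs + 1)
        farm = int(rng.integers(n_farms))
        asy = float(rng.random() < 0.5)
        u_i = rng.normal(0, sd_female)
        s_temp = rng.normal(0, sd_slope_temp)
        s_dens = rng.normal(0, sd_slope_dens)
        femyears = range(start, start + n_obs)
        temps = np.array([year_temp[y] + rng.normal(0, 0.45) for y in femyears])
        denss = rng.normal(0.4 * (farm / n_farms - 0.5) * 2, 0.9, n_obs)
        t_mean, d_mean = temps.mean(), denss.mean()
        slope_temp_i = beta_within_temp + temp_slope_vs_density * d_mean
        for k, y in enumerate(femyears):
            t_w, d_w = temps[k] - t_mean, denss[k] - d_mean
            lay = (
                141.4
                + slope_temp_i * t_w
                + beta_between_temp * t_mean
                + beta_within_dens * d_w
                + beta_between_dens * d_mean
                + beta_age * asy
                + beta_lat * farm_lat[farm]
                + u_year[y]
                + u_farm[farm]
                + u_i
                + s_temp * t_w
                + s_dens * d_w
                + rng.normal(0, sd_resid)
            )
            rows.append(
                {
                    "female_id": f"B{i:05d}",
                    "farm_id": f"F{farm:02d}",
                    "year": 2005 + y,
                    "age_asy": asy if k == 0 else 1.0,
                    "lat_z": farm_lat[farm],
                    "temp_z": temps[k],
                    "dens_z": denss[k],
                    "lay_date": lay,
                }
            )
    df = pd.DataFrame(rows)
    for col, short in (("temp_z", "temp"), ("dens_z", "dens")):
        means = df.groupby("female_id")[col].transform("mean")
        df[short + "_B"] = means
        df[short + "_W"] = df[col] - means
    return df


def simulate_window_scan_dataset(
    rng: np.random.Generator,
    target_r: float = 0.75,
    window: WindowSpec = WindowSpec(96, 129),
    n_years: int = 10,
    phenology_slope: float = -3.0,
    truth: SyntheticTruth | None = None,
) -> tuple[DailyWeatherSeries, dict[int, float]]:
    """One averaged climate series plus annual phenology with a planted window.

    The annual mean laying dates are a linear function of the mean
    temperature over the planted window, plus noise scaled so the expected
    correlation magnitude is ``target_r``. By default the interannual signal
    is confined to the planted window (no shared warming trend or whole-
    spring year anomaly): any year-level variation shared by all windows
    would be signal for every candidate alike, making the planted window
    unidentifiable in principle; here the remaining variation is AR(1) daily
    noise averaged over three stations.
    """
    if truth is None:
        truth = SyntheticTruth(
            window_temp=window, trend_temp_per_year=0.0, sd_year_anomaly=0.0
        )
    years = list(range(2004, 2004 + n_years))
    stations = pd.DataFrame({"station_id": ["P0", "P1", "P2"]})
    weather = generate_weather(stations, years, truth, rng)
    from .geo import average_stations

    series = average_stations(list(weather.values()))
    yr_arr, mat = series.value_matrix("tmean")
    sl = slice(window.start_day, window.end_day)
    window_mean = np.nanmean(mat[:, sl], axis=1)
    signal = phenology_slope * window_mean
    noise_sd = abs(phenology_slope) * np.std(window_mean, ddof=1) * np.sqrt(
        1.0 / target_r**2 - 1.0
    )
    phen = 141.4 + signal + rng.normal(0, noise_sd, len(yr_arr))
    return series, {int(y): float(v) for y, v in zip(yr_arr, phen)}
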