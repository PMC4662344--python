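"""The analysis stages wired end to end.

Population level: farm-year summaries, temporal trends (laying date,
spring temperature, breeder density), and the environmental-determinants
mixed model with backward elimination. Individual level: consecutive-year
delta analysis, within-subject centring (beta_W vs beta_B), the random
regression ladder testing increasingly rich random structures (year, farm,
female, female-by-environment slopes), the beta_W = beta_B equality test,
and high/low breeder-density subset re-runs.

Laying dates are Julian days; breeder density is the fraction of a farm's
nest boxes occupied in a year; environmental covariates are standardized
once on the full analysis table before any subsetting or centring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from .geo import DailyWeatherSeries, GeoPoint, assign_station_series
from .glmm import FittedBinomialGLMM, fit_binomial_glmm
from .lmm import (
    FittedLMM,
    LRTResult,
    ModelSpec,
    RandomTerm,
    backward_eliminate,
    fit_lmm,
    loglik_ratio_test,
    standardize,
)
from .windows import WindowSpec, aggregate_window

logger = logging.getLogger(__name__)

REQUIRED_RECORD_COLUMNS = [
    "farm_id",
    "nestbox_id",
    "year",
    "female_id",
    "age_class",
    "lay_date",
    "clutch_order",
]


# ---------------------------------------------------------------------------
# Record filtering and summaries
# ---------------------------------------------------------------------------


def first_clutch_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one first clutch per female per season.

    Rows with ``clutch_order > 1`` (replacement/second clutches) are removed;
    if a female still has several same-year rows, only her earliest laying
    date is retained. Records without a female id are kept as long as they
    are first clutches.
    """
    out = records[records["clutch_order"] == 1].copy()
    known = out["female_id"].notna()
    dupes = out.loc[known].sort_values("lay_date")
    dupes = dupes.drop_duplicates(subset=["female_id", "year"], keep="first")
    out = pd.concat([dupes, out.loc[~known]], ignore_index=True)
    n_removed = len(records) - len(out)
    if n_removed:
        logger.info("first-clutch filter removed %d of %d records", n_removed, len(records))
    return out.sort_values(["year", "farm_id", "lay_date"]).reset_index(drop=True)


def farm_year_summaries(
    records: pd.DataFrame,
    farms: pd.DataFrame,
    stations: Mapping[str, GeoPoint],
    weather: Mapping[str, DailyWeatherSeries],
    window_temp: WindowSpec,
    window_rain: WindowSpec,
    station_k: int = 1,
    rain_stat: Literal["sum", "mean"] = "sum",
) -> pd.DataFrame:
    """Per farm-year: mean laying date, occupancy, climate, geography.

    Occupancy (breeder density) is the fraction of the farm's nest boxes with
    any breeding record that year; the laying-date mean uses first clutches
    only. Climate values come from each farm's assigned station(s) (nearest
    station by default). Farm-years without any clutch are omitted.
    """
    farm_points = {
        str(row.farm_id): GeoPoint(row.latitude, row.longitude, row.elevation)
        for row in farms.itertuples()
    }
    n_boxes = dict(zip(farms["farm_id"].astype(str), farms["n_boxes"]))
    per_farm_series = assign_station_series(farm_points, stations, weather, k=station_k)

    firsts = first_clutch_filter(records)
    rows = []
    grouped_first = firsts.groupby(["farm_id", "year"])
    occupancy = records.groupby(["farm_id", "year"])["nestbox_id"].nunique()
    for (farm_id, year), grp in grouped_first:
        farm_id = str(farm_id)
        series = per_farm_series[farm_id]
        temp = aggregate_window(series, window_temp, int(year), stat="mean")
        rain = aggregate_window(
            series, window_rain, int(year), stat=rain_stat, variable="rain"
        )
        point = farm_points[farm_id]
        rows.append(
            {
                "farm_id": farm_id,
                "year": int(year),
                "n_first_clutches": len(grp),
                "mean_lay_date": float(grp["lay_date"].mean()),
                "breeder_density": float(occupancy.loc[(farm_id, year)] / n_boxes[farm_id]),
                "spring_temp": temp,
                "rainfall": rain,
                "latitude": point.latitude,
                "elevation": point.elevation,
            }
        )
    out = pd.DataFrame(rows).sort_values(["farm_id", "year"]).reset_index(drop=True)
    n_possible = len(farms) * records["year"].nunique()
    logger.info(
        "farm-year summaries: %d of %d possible farm-years had breeding records",
        len(out),
        n_possible,
    )
    return out


def standardize_covariates(
    data: pd.DataFrame, columns: Sequence[str], suffix: str = "_z"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Append standardized copies of ``columns``; returns (table, transforms)."""
    out = data.copy()
    transforms: dict[str, tuple[float, float]] = {}
    for col in columns:
        z, mean, sd = standardize(out[col].to_numpy(dtype=float))
        out[col + suffix] = z
        transforms[col] = (mean, sd)
    return out, transforms


# ---------------------------------------------------------------------------
# Population level: trends and determinants
# ---------------------------------------------------------------------------


@dataclass
class TrendResult:
    """Interannual trends in laying date, spring temperature and density."""

    lay_fit: FittedLMM
    temp_fit: FittedLMM
    density_fit: FittedBinomialGLMM
    table: pd.DataFrame


def temporal_trend(summaries: pd.DataFrame, n_boxes: int = 10) -> TrendResult:
    """Fit the three interannual trend models.

    Laying date and temperature: linear mixed models with year (continuous,
    counted from the first study year) as fixed effect and farm identity as a
    random intercept. Breeder density: binomial GLMM (logit link) on
    (occupied, total) nest boxes with the same structure; its slope is on the
    log-odds scale.
    """
    if summaries["year"].nunique() < 3:
        raise ValueError("trend analysis needs at least 3 years")
    d = summaries.copy()
    d["year_c"] = d["year"] - d["year"].min()
    d["occupied"] = (d["breeder_density"] * n_boxes).round().astype(int)
    d["boxes"] = n_boxes
    lay = fit_lmm(d, ModelSpec("mean_lay_date", ["year_c"], [RandomTerm("farm_id")]))
    temp = fit_lmm(d, ModelSpec("spring_temp", ["year_c"], [RandomTerm("farm_id")]))
    dens = fit_binomial_glmm(d, "occupied", "boxes", ["year_c"], "farm_id")
    zt = dens.ztable()
    table = pd.DataFrame(
        [
            {
                "response": "mean_lay_date",
                "slope_per_year": lay.beta["year_c"],
                "se": lay.se["year_c"],
                "stat": lay.beta["year_c"] / lay.se["year_c"],
                "p": lay.fixed_table().loc["year_c", "p"],
                "scale": "days/yr",
            },
            {
                "response": "spring_temp",
                "slope_per_year": temp.beta["year_c"],
                "se": temp.se["year_c"],
                "stat": temp.beta["year_c"] / temp.se["year_c"],
                "p": temp.fixed_table().loc["year_c", "p"],
                "scale": "degC/yr",
            },
            {
                "response": "breeder_density",
                "slope_per_year": dens.beta["year_c"],
                "se": dens.se["year_c"],
                "stat": zt.loc["year_c", "z"],
                "p": zt.loc["year_c", "p"],
                "scale": "logit/yr",
            },
        ]
    )
    return TrendResult(lay, temp, dens, table)


DETERMINANT_COVARIATES = ["spring_temp", "rainfall", "breeder_density", "elevation", "latitude"]


@dataclass
class DeterminantsResult:
    fit: FittedLMM
    trace: pd.DataFrame
    table: pd.DataFrame
    adj_r2_fixed: float
    transforms: dict[str, tuple[float, float]]


def determinants_model(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    farm_random: bool = False,
) -> DeterminantsResult:
    """Environmental determinants of farm-year mean laying date.

    Standardizes the five covariates, fits the full model (all main effects
    and all two-way interactions; year random intercept, optionally farm as
    well) and backward-eliminates at ``alpha``. The returned table mirrors a
    coefficient table with Satterthwaite df.
    """
    d, transforms = standardize_covariates(summaries, DETERMINANT_COVARIATES)
    zcols = [c + "_z" for c in DETERMINANT_COVARIATES]
    fixed = list(zcols) + [
        f"{a}:{b}" for i, a in enumerate(zcols) for b in zcols[i + 1 :]
    ]
    random = [RandomTerm("year")] + ([RandomTerm("farm_id")] if farm_random else [])
    spec = ModelSpec("mean_lay_date", fixed, random)
    fit, trace = backward_eliminate(d, spec, alpha=alpha)
    table = fit.fixed_table()
    # adjusted R^2 of the fixed predictor, in the spirit of a marginal R^2
    design = fit.design_
    yhat = design.X @ fit.beta.to_numpy()
    y = design.y
    r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2) if np.ptp(yhat) > 0 else 0.0
    p = len(fit.beta) - 1
    n = len(y)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else np.nan
    return DeterminantsResult(fit, trace, table, float(adj), transforms)


# ---------------------------------------------------------------------------
# Individual level: deltas, centring, random regression
# ---------------------------------------------------------------------------


def attach_covariates(records: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Merge farm-year covariates onto (first-clutch) breeding records."""
    cols = [
        "farm_id",
        "year",
        "breeder_density",
        "spring_temp",
        "rainfall",
        "latitude",
        "elevation",
    ]
    merged = records.merge(summaries[cols], on=["farm_id", "year"], how="left")
    return merged


def build_individual_table(
    records_with_covariates: pd.DataFrame,
    min_obs: int = 2,
    exclude_years: Sequence[int] = (),
) -> pd.DataFrame:
    """Female-year table for the plasticity analyses.

    Keeps known females with a known age class, excludes the requested years
    (the study's first season has no age information), retains females seen in
    at least ``min_obs`` years, standardizes temperature/density/latitude on
    this table, and applies within-subject centring (``*_W`` deviations carry
    the within-individual effect, ``*_B`` female means the between-individual
    effect). Age enters as an ASY indicator (``age_asy`` = 1 for after-second-
    year females, who lay earlier).
    """
    d = records_with_covariates.copy()
    d = d[d["female_id"].notna() & d["age_class"].isin(["SY", "ASY"])]
    if exclude_years:
        excluded_females = d.loc[d["year"].isin(exclude_years), "female_id"].unique()
        d = d[~d["year"].isin(exclude_years)]
        logger.info(
            "excluded %d years; %d females first seen there lose those records",
            len(exclude_years),
            len(excluded_females),
        )
    counts = d.groupby("female_id")["year"].nunique()
    keep = counts.index[counts >= min_obs]
    d = d[d["female_id"].isin(keep)].copy()
    if d.empty:
        raise ValueError("no females with enough repeat observations")
    d, _ = standardize_covariates(
        d, ["spring_temp", "breeder_density", "latitude"]
    )
    d = d.rename(
        columns={
            "spring_temp_z": "temp_z",
            "breeder_density_z": "dens_z",
            "latitude_z": "lat_z",
        }
    )
    d["age_asy"] = (d["age_class"] == "ASY").astype(float)
    for col, short in (("temp_z", "temp"), ("dens_z", "dens")):
        mean, dev = within_subject_center(d[col], d["female_id"])
        d[short + "_B"] = mean
        d[short + "_W"] = dev
    logger.info(
        "individual table: %d observations on %d females",
        len(d),
        d["female_id"].nunique(),
    )
    return d.reset_index(drop=True)


def within_subject_center(
    values: pd.Series, subjects: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Split a covariate into subject means and within-subject deviations.

    The mean carries the between-individual effect (beta_B), the deviation the
    within-individual effect (beta_W); mean + deviation reconstructs the
    original value exactly.
    """
    values = pd.Series(np.asarray(values, dtype=float), index=subjects.index)
    means = values.groupby(subjects).transform("mean")
    return means, values - means


def consecutive_pairs(records_with_covariates: pd.DataFrame) -> pd.DataFrame:
    """First consecutive-year pair of observations per female.

    Covariate deltas are computed on covariates standardized across the input
    table (so temperature and density deltas are in SD units). Females never
    observed in two consecutive years are excluded; females with several
    consecutive pairs contribute only the first.
    """
    d = records_with_covariates.copy()
    d = d[d["female_id"].notna()]
    d, _ = standardize_covariates(d, ["spring_temp", "breeder_density"])
    rows = []
    for fid, grp in d.sort_values("year").groupby("female_id"):
        years = grp["year"].to_numpy()
        for i in range(len(years) - 1):
            if years[i + 1] == years[i] + 1:
                first, second = grp.iloc[i], grp.iloc[i + 1]
                rows.append(
                    {
                        "female_id": fid,
                        "year1": int(first["year"]),
                        "delta_lay": float(second["lay_date"] - first["lay_date"]),
                        "delta_temp": float(
                            second["spring_temp_z"] - first["spring_temp_z"]
                        ),
                        "delta_density": float(
                            second["breeder_density_z"] - first["breeder_density_z"]
                        ),
                        "age_first_year": str(first["age_class"]),
                    }
                )
                break
    return pd.DataFrame(rows)


@dataclass
class DeltaResult:
    dataset: str
    fit: FittedLMM
    trace: pd.DataFrame
    table: pd.DataFrame
    adj_r2: float
    n_pairs: int


def delta_analysis(
    pairs: pd.DataFrame,
    dataset: Literal["SY", "ASY", "total"] = "total",
    alpha: float = 0.05,
) -> DeltaResult:
    """Change in laying date between consecutive years vs changes in
    temperature and density.

    Ordinary linear regression (a mixed model with no random terms) of
    ``delta_lay`` on ``delta_temp`` and ``delta_density``, backward-eliminated
    at ``alpha``. For the total dataset the female's first-year age class is a
    fixed effect (``age_sy`` = 1 for second-year females, whose laying date
    improves most between years). Subsets: ``SY`` = females SY in the first
    year, ``ASY`` = females already ASY in the first year (hence ASY in both).
    """
    if dataset == "SY":
        d = pairs[pairs["age_first_year"] == "SY"].copy()
        fixed = ["delta_temp", "delta_density"]
    elif dataset == "ASY":
        d = pairs[pairs["age_first_year"] == "ASY"].copy()
        fixed = ["delta_temp", "delta_density"]
    else:
        d = pairs[pairs["age_first_year"].isin(["SY", "ASY"])].copy()
        d["age_sy"] = (d["age_first_year"] == "SY").astype(float)
        fixed = ["age_sy", "delta_temp", "delta_density"]
    if len(d) < 10:
        raise ValueError(f"delta analysis needs >= 10 pairs (got {len(d)})")
    spec = ModelSpec("delta_lay", fixed, reml=False)
    fit, trace = backward_eliminate(d, spec, alpha=alpha, df_method="residual")
    design = fit.design_
    yhat = design.X @ fit.beta.to_numpy()
    resid = design.y - yhat
    tss = float(((design.y - design.y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    p = len(fit.beta) - 1
    n = len(design.y)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else np.nan
    return DeltaResult(dataset, fit, trace, fit.fixed_table("residual"), float(adj), len(d))


# ---------------------------------------------------------------------------
# Random regression ladder and centring decomposition
# ---------------------------------------------------------------------------

LADDER_FIXED = ["temp_W", "temp_B", "dens_W", "dens_B", "age_asy", "lat_z"]


@dataclass
class DecompositionResult:
    """Within- vs between-individual effect of one environmental variable."""

    covariate: str
    beta_within: float
    se_within: float
    beta_between: float
    se_between: float
    equality_estimate: float  # beta_B - beta_W
    equality_se: float
    equality_p: float


@dataclass
class LadderResult:
    models: dict[str, FittedLMM]
    lrts: dict[str, LRTResult]
    table: pd.DataFrame
    final_key: str
    decomposition: dict[str, DecompositionResult] = field(default_factory=dict)

    @property
    def final(self) -> FittedLMM:
        return self.models[self.final_key]


def _ladder_specs() -> dict[str, ModelSpec]:
    base = LADDER_FIXED
    return {
        "1_year": ModelSpec("lay_date", base, [RandomTerm("year")]),
        "2_year_farm": ModelSpec(
            "lay_date", base, [RandomTerm("year"), RandomTerm("farm_id")]
        ),
        "3_year_farm_female": ModelSpec(
            "lay_date",
            base,
            [RandomTerm("year"), RandomTerm("farm_id"), RandomTerm("female_id")],
        ),
        "4_female_x_temp": ModelSpec(
            "lay_date",
            base,
            [
                RandomTerm("year"),
                RandomTerm("farm_id"),
                RandomTerm("female_id", "temp_W"),
            ],
        ),
        "5_female_x_dens": ModelSpec(
            "lay_date",
            base,
            [
                RandomTerm("year"),
                RandomTerm("farm_id"),
                RandomTerm("female_id", "dens_W"),
            ],
        ),
    }


def random_regression_ladder(
    table: pd.DataFrame, alpha: float = 0.05
) -> LadderResult:
    """Fit the five-model random-structure ladder and decompose effects.

    Models (all REML, identical fixed effects: within/between components of
    temperature and density, age class, latitude):

    1. year random intercept
    2. + farm random intercept
    3. + female random intercept
    4. model 3 with a correlated female slope on within-female temperature
    5. model 3 with a correlated female slope on within-female density

    Random structures are compared with REML LRTs (1v2, 2v3, 3v4, 3v5; a
    correlated slope adds 2 df). The best-supported structure keeps a slope
    only when its LRT is significant; with both slopes significant the
    smaller p wins. beta_W/beta_B estimates and the equality tests for both
    covariates come from the selected model.
    """
    specs = _ladder_specs()
    models = {k: fit_lmm(table, s) for k, s in specs.items()}
    lrts = {
        "1v2": loglik_ratio_test(models["2_year_farm"], models["1_year"], "random"),
        "2v3": loglik_ratio_test(
            models["3_year_farm_female"], models["2_year_farm"], "random"
        ),
        "3v4": loglik_ratio_test(
            models["4_female_x_temp"], models["3_year_farm_female"], "random"
        ),
        "3v5": loglik_ratio_test(
            models["5_female_x_dens"], models["3_year_farm_female"], "random"
        ),
    }
    # sequential support, but a significant female term always promotes to
    # model 3 (farm and year are retained as design controls either way)
    final_key = "2_year_farm" if lrts["1v2"].p < alpha else "1_year"
    if lrts["2v3"].p < alpha:
        final_key = "3_year_farm_female"
        slope_p = {
            "4_female_x_temp": lrts["3v4"].p,
            "5_female_x_dens": lrts["3v5"].p,
        }
        significant = {k: p for k, p in slope_p.items() if p < alpha}
        if significant:
            final_key = min(significant, key=significant.get)

    rows = []
    test_for = {
        "2_year_farm": "1v2",
        "3_year_farm_female": "2v3",
        "4_female_x_temp": "3v4",
        "5_female_x_dens": "3v5",
    }
    for key, fit in models.items():
        test = test_for.get(key)
        rows.append(
            {
                "model": key,
                "loglik_reml": fit.loglik_reml,
                "n_params": fit.n_params,
                "test": test or "",
                "lrt": lrts[test].statistic if test else np.nan,
                "p": lrts[test].p if test else np.nan,
            }
        )
    ladder_table = pd.DataFrame(rows)

    final = models[final_key]
    decomposition = {}
    for cov, raw in (("temp", "temp_z"), ("dens", "dens_z")):
        eq = beta_equality_test(table, cov, specs[final_key])
        decomposition[cov] = DecompositionResult(
            covariate=cov,
            beta_within=float(final.beta[f"{cov}_W"]),
            se_within=float(final.se[f"{cov}_W"]),
            beta_between=float(final.beta[f"{cov}_B"]),
            se_between=float(final.se[f"{cov}_B"]),
            equality_estimate=eq.equality_estimate,
            equality_se=eq.equality_se,
            equality_p=eq.equality_p,
        )
    return LadderResult(models, lrts, ladder_table, final_key, decomposition)


def beta_equality_test(
    table: pd.DataFrame, covariate: Literal["temp", "dens"], spec: ModelSpec
) -> DecompositionResult:
    """Wald test of beta_B = beta_W by reparameterization.

    Refits the model with the raw (uncentred) covariate alongside the female
    mean: the coefficient on the mean then estimates beta_B - beta_W directly,
    and its t-test (Satterthwaite df) is the equality test. Algebraically
    identical to differencing the centred fit's coefficients.
    """
    raw_col = {"temp": "temp_z", "dens": "dens_z"}[covariate]
    fixed = [raw_col if t == f"{covariate}_W" else t for t in spec.fixed]
    refit = fit_lmm(table, ModelSpec(spec.response, fixed, spec.random, spec.reml))
    ft = refit.fixed_table()
    mean_term = f"{covariate}_B"
    est = float(refit.beta[mean_term])
    se = float(refit.se[mean_term])
    p = float(ft.loc[mean_term, "p"])
    return DecompositionResult(
        covariate=covariate,
        beta_within=float(refit.beta[raw_col]),
        se_within=float(refit.se[raw_col]),
        beta_between=est + float(refit.beta[raw_col]),
        se_between=np.nan,
        equality_estimate=est,
        equality_se=se,
        equality_p=p,
    )


# ---------------------------------------------------------------------------
# Density-subset robustness
# ---------------------------------------------------------------------------


@dataclass
class DensitySubsetResult:
    split_value: float
    level: str
    low: dict
    high: dict
    temp_slope_low: float
    temp_slope_high: float


def density_subset_analysis(
    table: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    level: Literal["subject", "observation"] = "subject",
    quantile: float = 0.5,
    alpha: float = 0.05,
    min_obs_warn: int = 30,
) -> DensitySubsetResult:
    """Re-run the plasticity analyses on low- vs high-density subsets.

    By default females are split at the median of their mean experienced
    density (the hypothesis concerns birds living on average in low-density
    habitat); ``level='observation'`` splits observation-wise instead. Each
    subset gets the random-regression ladder (and, when ``pairs`` is given,
    the total-dataset delta analysis); the key output is the contrast in
    within-female temperature slope between subsets.
    """
    if level == "subject":
        female_mean = table.groupby("female_id")["dens_B"].first()
        split = float(female_mean.quantile(quantile))
        low_ids = female_mean.index[female_mean <= split]
        masks = {
            "low": table["female_id"].isin(low_ids),
            "high": ~table["female_id"].isin(low_ids),
        }
    else:
        split = float(table["dens_z"].quantile(quantile))
        masks = {"low": table["dens_z"] <= split, "high": table["dens_z"] > split}

    results: dict[str, dict] = {}
    for name, mask in masks.items():
        sub = table.loc[mask].copy()
        if sub.empty:
            raise ValueError(f"{name}-density subset is empty")
        if len(sub) < min_obs_warn:
            logger.warning(
                "%s-density subset has only %d observations; estimates unstable",
                name,
                len(sub),
            )
        # re-centre within the subset so deviations stay mean-zero per female
        for col, short in (("temp_z", "temp"), ("dens_z", "dens")):
            mean, dev = within_subject_center(sub[col], sub["female_id"])
            sub[short + "_B"] = mean
            sub[short + "_W"] = dev
        ladder = random_regression_ladder(sub, alpha=alpha)
        entry: dict = {"ladder": ladder, "n_obs": len(sub)}
        if pairs is not None:
            ids = set(sub["female_id"])
            sub_pairs = pairs[pairs["female_id"].isin(ids)]
            if len(sub_pairs) >= 10:
                entry["delta"] = delta_analysis(sub_pairs, "total", alpha=alpha)
        results[name] = entry

    def temp_slope(entry: dict) -> float:
        return entry["ladder"].decomposition["temp"].beta_within

    return DensitySubsetResult(
        split_value=split,
        level=level,
        low=results["low"],
        high=results["high"],
        temp_slope_low=temp_slope(results["low"]),
        temp_slope_high=temp_slope(results["high"]),
    )
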