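"""Sliding-window scan for the climate period best predicting phenology.

A candidate window is a pair of Julian days ``(start_day, end_day)`` inside a
scan frame; the window aggregates the daily series over days
``start_day + 1 .. end_day`` (a half-open day set of ``end_day - start_day``
days). With the default frame 60..151 and spans 5..91 this enumerates
exactly 3,828 candidate windows. For every window the per-year aggregated
climate value is correlated (Pearson) with the annual mean of the phenological
trait, and windows are ranked by the absolute correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo import DailyWeatherSeries

#: A station-window value is treated as missing when more than this fraction
#: of the window's days have no record.
MAX_MISSING_FRACTION = 0.5

Stat = Literal["mean", "sum"]


@dataclass(frozen=True)
class WindowSpec:
    """A candidate aggregation window: days ``start_day + 1 .. end_day``."""

    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError(f"end_day must exceed start_day: {self}")

    @property
    def span_days(self) -> int:
        return self.end_day - self.start_day

    @property
    def days(self) -> range:
        return range(self.start_day + 1, self.end_day + 1)


@dataclass(frozen=True)
class WindowScanResult:
    window: WindowSpec
    yearly_values: Mapping[int, float]
    r: float
    p: float


def enumerate_windows(
    frame_start: int, frame_end: int, min_span: int, max_span: int
) -> list[WindowSpec]:
    """All windows ``(s, e)`` with span ``e - s`` in ``[min_span, max_span]``.

    Ordered by ascending start day, then ascending end day. The default study
    frame (60, 151, 5, 91) yields sum_{L=5}^{91} (92 - L) = 3,828 windows.
    """
    if frame_start >= frame_end:
        raise ValueError(f"frame_start {frame_start} must be < frame_end {frame_end}")
    if not (1 <= min_span <= max_span <= frame_end - frame_start):
        raise ValueError(
            f"need 1 <= min_span <= max_span <= frame width; got "
            f"spans [{min_span}, {max_span}] in frame [{frame_start}, {frame_end}]"
        )
    return [
        WindowSpec(s, e)
        for s in range(frame_start, frame_end)
        for e in range(s + min_span, min(s + max_span, frame_end) + 1)
    ]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def aggregate_window(
    series: DailyWeatherSeries,
    window: WindowSpec,
    year: int,
    stat: Stat = "mean",
    variable: str = "tmean",
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> float:
    """Aggregate one window for one year; NaN when too many days are missing.

    Missing days are simply excluded from the mean; a sum over partially
    missing days is rescaled by span/available so that the two statistics stay
    mutually consistent under missingness.
    """
    years, mat = series.value_matrix(variable)
    idx = np.flatnonzero(years == year)
    if idx.size == 0:
        return float("nan")
    values = mat[idx[0], window.start_day : window.end_day]  # days s+1..e
    available = np.isfinite(values)
    span = window.span_days
    if available.sum() < span * (1.0 - max_missing_fraction):
        return float("nan")
    mean = float(np.nanmean(values))
    return mean if stat == "mean" else mean * span


def _window_value_matrix(
    series: DailyWeatherSeries,
    windows: Sequence[WindowSpec],
    stat: Stat,
    variable: str,
    max_missing_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(years, n_years x n_windows matrix) of aggregated values, vectorised.

    Uses prefix sums over the daily matrix so the full 3,828-window scan costs
    O(years x days + years x windows).
    """
    years, mat = series.value_matrix(variable)
    finite = np.isfinite(mat)
    filled = np.where(finite, mat, 0.0)
    csum = np.concatenate([np.zeros((len(years), 1)), np.cumsum(filled, axis=1)], axis=1)
    ccount = np.concatenate([np.zeros((len(years), 1)), np.cumsum(finite, axis=1)], axis=1)
    starts = np.array([w.start_day for w in windows])
    ends = np.array([w.end_day for w in windows])
    spans = ends - starts
    sums = csum[:, ends] - csum[:, starts]
    counts = ccount[:, ends] - ccount[:, starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    values = means if stat == "mean" else means * spans
    too_missing = counts < spans * (1.0 - max_missing_fraction)
    values = np.where(too_missing, np.nan, values)
    return years, values


def scan_windows(
    series: DailyWeatherSeries,
    phenology: Mapping[int, float] | pd.Series,
    frame: tuple[int, int] = (60, 151),
    span: tuple[int, int] = (5, 91),
    stat: Stat = "mean",
    variable: str = "tmean",
    permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Correlate every candidate window with annual phenology and rank them.

    Parameters
    ----------
    series
        The daily climate series used for the scan (typically an average of
        the stations nearest the network centroid).
    phenology
        Annual mean of the trait (e.g. mean laying date) keyed by year.

    Returns
    -------
    DataFrame with one row per window (``start_day``, ``end_day``,
    ``span_days``, ``n_years``, ``r``, ``p``), sorted by descending ``|r|``
    with ties broken by earlier start day then smaller span. Windows with an
    undefined correlation (missing climate values leaving <3 years, or a
    constant series) sort last with NaN r.

    ``permutations > 0`` additionally computes a scan-wide permutation null
    (years of the phenology shuffled, max |r| over all windows recorded each
    time) and attaches a familywise ``p_perm`` column: the fraction of
    permutations whose maximum |r| reaches each window's |r|. Off by
    default, matching the original procedure, which applied no correction
    for the 3,828 correlations.
    """
    phen = pd.Series(dict(phenology)).astype(float).sort_index()
    if len(phen) < 3:
        raise ValueError("window scan needs phenology for at least 3 years")
    if np.ptp(phen.to_numpy()) == 0:
        raise ValueError("phenology is constant across years; correlation undefined")

    windows = enumerate_windows(frame[0], frame[1], span[0], span[1])
    years, values = _window_value_matrix(
        series, windows, stat, variable, MAX_MISSING_FRACTION
    )
    keep = np.isin(years, phen.index.to_numpy())
    years = years[keep]
    values = values[keep]
    y = phen.loc[years].to_numpy()

    n_win = len(windows)
    r = np.full(n_win, np.nan)
    p = np.full(n_win, np.nan)
    n_used = np.zeros(n_win, dtype=int)

    finite = np.isfinite(values)
    complete = finite.all(axis=0)
    # Fast path: windows with values for every year, correlated in one shot.
    if complete.any():
        v = values[:, complete]
        sd = v.std(axis=0)
        ok = sd > 0
        vc = (v[:, ok] - v[:, ok].mean(axis=0)) / sd[ok]
        yc = (y - y.mean()) / y.std()
        n = len(y)
        rr = vc.T @ yc / n
        rr = np.clip(rr, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rr * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rr**2))
        pp = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        cols = np.flatnonzero(complete)[ok]
        r[cols], p[cols], n_used[cols] = rr, pp, n
        n_used[np.flatnonzero(complete)[~ok]] = n
    # Slow path: windows with year gaps, pairwise-complete correlation.
    for j in np.flatnonzero(~complete):
        mask = finite[:, j]
        n_used[j] = int(mask.sum())
        if mask.sum() >= 3 and np.ptp(values[mask, j]) > 0 and np.ptp(y[mask]) > 0:
            r[j], p[j] = pearson_r(values[mask, j], y[mask])

    p_perm = None
    if permutations > 0:
        rng = np.random.default_rng() if rng is None else rng
        cols = np.flatnonzero(complete)
        v = values[:, cols]
        sd = v.std(axis=0)
        vc = (v[:, sd > 0] - v[:, sd > 0].mean(axis=0)) / sd[sd > 0]
        null_max = np.empty(permutations)
        n = len(y)
        for b in range(permutations):
            yp = rng.permutation(y)
            ypc = (yp - yp.mean()) / yp.std()
            null_max[b] = np.max(np.abs(vc.T @ ypc / n)) if vc.size else np.nan
        with np.errstate(invalid="ignore"):
            p_perm = (null_max[None, :] >= np.abs(r)[:, None]).mean(axis=1)
        p_perm = np.where(np.isfinite(r), p_perm, np.nan)

    out = pd.DataFrame(
        {
            "start_day": [w.start_day for w in windows],
            "end_day": [w.end_day for w in windows],
            "span_days": [w.span_days for w in windows],
            "n_years": n_used,
            "r": r,
            "p": p,
        }
    )
    if p_perm is not None:
        out["p_perm"] = p_perm
    if len(out) > 1 and not np.isfinite(r).any():
        raise ValueError("no window produced a defined correlation")
    out["abs_r"] = out["r"].abs()
    out = out.sort_values(
        by=["abs_r", "start_day", "span_days"],
        ascending=[False, True, True],
        na_position="last",
        kind="mergesort",
    ).drop(columns="abs_r")
    return out.reset_index(drop=True)


def best_window(scan: pd.DataFrame) -> WindowSpec:
    """The top-ranked window of a :func:`scan_windows` table."""
    row = scan.iloc[0]
    return WindowSpec(int(row["start_day"]), int(row["end_day"]))
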