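import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoplast.geo import DailyWeatherSeries
from phenoplast.windows import (
    WindowSpec,
    aggregate_window,
    best_window,
    enumerate_windows,
    pearson_r,
    scan_windows,
)


def make_series(values_by_year, station="s", variable="tmean"):
    frames = []
    for year, values in values_by_year.items():
        dates = pd.date_range(f"{year}-01-01", periods=len(values))
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "tmean": values if variable == "tmean" else 0.0,
                    "rain": values if variable == "rain" else 0.0,
                }
            )
        )
    return DailyWeatherSeries(station, pd.concat(frames, ignore_index=True))


class TestEnumerateWindows:
    def test_study_frame_count(self):
        # the full March 1 - May 31 frame with 5-91 day spans
        assert len(enumerate_windows(60, 151, 5, 91)) == 3828

    def test_tiny_frames(self):
        got = [(w.start_day, w.end_day) for w in enumerate_windows(1, 3, 1, 2)]
        assert got == [(1, 2), (1, 3), (2, 3)]
        assert len(enumerate_windows(1, 2, 1, 1)) == 1

    @given(
        st.integers(1, 40),
        st.integers(2, 60),
        st.integers(1, 10),
        st.integers(1, 30),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_count_matches_closed_form(self, start, width, min_span, extra):
        end = start + width
        max_span = min(min_span + extra, width)
        if min_span > max_span:
            return
        windows = enumerate_windows(start, end, min_span, max_span)
        expected = sum(width - L + 1 for L in range(min_span, max_span + 1))
        assert len(windows) == expected
        assert len({(w.start_day, w.end_day) for w in windows}) == len(windows)

    def test_invalid_parameters_error(self):
        with pytest.raises(ValueError):
            enumerate_windows(100, 60, 5, 91)
        with pytest.raises(ValueError):
            enumerate_windows(60, 151, 92, 95)


class TestAggregateWindow:
    def test_constant_series_mean(self):
        s = make_series({2005: np.full(20, 3.5)})
        assert aggregate_window(s, WindowSpec(2, 7), 2005) == pytest.approx(3.5)

    def test_arithmetic_sum_and_mean(self):
        # daily values 1..10; the window covering days 3..7 sums to 25
        s = make_series({2005: np.arange(1.0, 11.0)})
        w = WindowSpec(2, 7)
        assert aggregate_window(s, w, 2005, "sum") == pytest.approx(25.0)
        assert aggregate_window(s, w, 2005, "mean") == pytest.approx(5.0)

    def test_missing_day_tolerance(self):
        values = np.arange(1.0, 11.0)
        values[3] = np.nan  # one of five window days missing -> still valid
        s = make_series({2005: values})
        assert aggregate_window(s, WindowSpec(2, 7), 2005, "mean") == pytest.approx(
            np.nanmean([3, np.nan, 5, 6, 7])
        )

    def test_majority_missing_flags_value(self):
        values = np.arange(1.0, 11.0)
        values[2:6] = np.nan  # 4 of 5 window days missing
        s = make_series({2005: values})
        assert np.isnan(aggregate_window(s, WindowSpec(2, 7), 2005))

    def test_absent_year_is_missing(self):
        s = make_series({2005: np.arange(10.0)})
        assert np.isnan(aggregate_window(s, WindowSpec(2, 7), 2004))


class TestPearson:
    def test_exact_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, p = pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)
        assert 0 < p < 1

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestScanWindows:
    def _signal_series(self, rng, n_years=10, n_days=200):
        data = {
            2004 + i: rng.normal(5, 3, n_days) for i in range(n_years)
        }
        return make_series(data)

    def test_recovers_constructed_signal_exactly(self, rng):
        series = self._signal_series(rng)
        _, mat = series.value_matrix("tmean")
        phen = {
            2004 + i: 2.0 * np.nanmean(mat[i, 96:129]) + 3.0
            for i in range(mat.shape[0])
        }
        scan = scan_windows(series, phen)
        top = scan.iloc[0]
        assert (top["start_day"], top["end_day"]) == (96, 129)
        assert top["r"] == pytest.approx(1.0)
        assert best_window(scan) == WindowSpec(96, 129)

    def test_ranking_invariant_to_per_year_affine_shift(self, rng):
        series = self._signal_series(rng)
        _, mat = series.value_matrix("tmean")
        phen = {2004 + i: -1.5 * np.nanmean(mat[i, 96:129]) for i in range(10)}
        base = scan_windows(series, phen)
        shifted = make_series(
            {y: 2.0 * series.data.loc[series.data.year == y, "tmean"].to_numpy() + 7.0
             for y in series.years}
        )
        again = scan_windows(shifted, phen)
        pd.testing.assert_frame_equal(
            base[["start_day", "end_day"]].head(50),
            again[["start_day", "end_day"]].head(50),
        )

    def test_constant_phenology_errors(self, rng):
        series = self._signal_series(rng)
        with pytest.raises(ValueError, match="constant"):
            scan_windows(series, {2004 + i: 140.0 for i in range(10)})

    def test_too_few_years_errors(self, rng):
        series = self._signal_series(rng, n_years=2)
        with pytest.raises(ValueError, match="3 years"):
            scan_windows(series, {2004: 140.0, 2005: 139.0})

    def test_single_candidate_window_ranks_first(self, rng):
        series = self._signal_series(rng)
        phen = {2004 + i: float(i) + rng.normal(0, 1) for i in range(10)}
        scan = scan_windows(series, phen, frame=(96, 101), span=(5, 5))
        assert len(scan) == 1

    def test_permutation_null_calibrates_family_wise_p(self, rng):
        series = self._signal_series(rng)
        _, mat = series.value_matrix("tmean")
        # perfect signal: no permutation can beat the observed max |r|
        phen = {2004 + i: 2.0 * np.nanmean(mat[i, 96:129]) for i in range(10)}
        scan = scan_windows(series, phen, permutations=99, rng=rng)
        assert scan.iloc[0]["p_perm"] <= 0.05
        # pure noise: the top window's familywise p should be large
        noise = {2004 + i: float(v) for i, v in enumerate(rng.normal(140, 3, 10))}
        null_scan = scan_windows(series, noise, permutations=99, rng=rng)
        assert null_scan.iloc[0]["p_perm"] > 0.10

    def test_table_covers_all_windows_sorted_by_abs_r(self, rng):
        series = self._signal_series(rng)
        phen = {2004 + i: rng.normal(140, 3) for i in range(10)}
        scan = scan_windows(series, phen, frame=(60, 100), span=(5, 20))
        assert len(scan) == len(enumerate_windows(60, 100, 5, 20))
        absr = scan["r"].abs().to_numpy()
        assert np.all(np.diff(absr[np.isfinite(absr)]) <= 1e-12)
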