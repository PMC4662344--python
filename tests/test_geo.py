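import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoplast.geo import (
    DailyWeatherSeries,
    GeoPoint,
    assign_station_series,
    average_stations,
    date_from_julian,
    day_length_minutes,
    haversine_km,
    julian_day,
    nearest_stations,
)

import pandas as pd


class TestJulianDay:
    @pytest.mark.parametrize(
        "date,expected",
        [
            ("2005-01-01", 1),
            ("2005-05-20", 140),  # mean laying date of the study population
            ("2005-03-01", 60),  # scan-frame start in a non-leap year
            ("2005-05-31", 151),  # scan-frame end
            ("2005-12-31", 365),
            ("2004-12-31", 366),
            ("2004-02-29", 60),
        ],
    )
    def test_known_days(self, date, expected):
        assert julian_day(date) == expected

    def test_invalid_date_errors(self):
        with pytest.raises(ValueError):
            julian_day("2005-02-30")

    def test_roundtrip_with_inverse(self):
        for year in (2004, 2005):
            for day in (1, 60, 140, 151, 365):
                assert julian_day(date_from_julian(year, day)) == day

    def test_inverse_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            date_from_julian(2005, 366)


class TestHaversine:
    def test_identity_and_known_distances(self):
        a = GeoPoint(45.0, -72.0)
        assert haversine_km(a, a) == 0.0
        # one degree of latitude on a 6371-km sphere: 2*pi*6371/360
        d = haversine_km(GeoPoint(45.0, -72.0), GeoPoint(46.0, -72.0))
        assert d == pytest.approx(111.19492664, abs=1e-6)
        # antipodal on the equator: half the circumference
        assert haversine_km(GeoPoint(0, 0), GeoPoint(0, 180)) == pytest.approx(
            np.pi * 6371.0, rel=1e-9
        )

    @given(
        st.tuples(
            st.floats(-80, 80), st.floats(-179, 179),
            st.floats(-80, 80), st.floats(-179, 179),
            st.floats(-80, 80), st.floats(-179, 179),
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_triangle_inequality(self, coords):
        a = GeoPoint(coords[0], coords[1])
        b = GeoPoint(coords[2], coords[3])
        c = GeoPoint(coords[4], coords[5])
        assert haversine_km(a, c) <= haversine_km(a, b) + haversine_km(b, c) + 1e-6

    def test_symmetry(self):
        a, b = GeoPoint(45.21, -72.1), GeoPoint(45.93, -73.0)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a), rel=1e-12)

    def test_latitude_bounds_enforced(self):
        with pytest.raises(ValueError):
            GeoPoint(91.0, 0.0)
        with pytest.raises(ValueError):
            GeoPoint(0.0, 181.0)


class TestNearestStations:
    def test_single_station(self):
        farm = GeoPoint(45.5, -72.5)
        assert nearest_stations(farm, {"s1": GeoPoint(45.6, -72.4)}, 1) == ["s1"]

    def test_matches_brute_force_on_synthetic_layout(self, rng):
        farm = GeoPoint(45.5, -72.5)
        stations = {
            f"s{i}": GeoPoint(45.5 + rng.uniform(-0.5, 0.5), -72.5 + rng.uniform(-0.5, 0.5))
            for i in range(5)
        }
        got = nearest_stations(farm, stations, 3)
        brute = sorted(stations, key=lambda s: (haversine_km(farm, stations[s]), s))[:3]
        assert got == brute

    def test_equidistant_tie_breaks_lexicographically(self):
        farm = GeoPoint(45.0, -72.0)
        stations = {"b": GeoPoint(45.0, -72.5), "a": GeoPoint(45.0, -71.5)}
        assert nearest_stations(farm, stations, 2) == ["a", "b"]

    def test_empty_and_oversized_k_error(self):
        with pytest.raises(ValueError):
            nearest_stations(GeoPoint(45, -72), {}, 1)
        with pytest.raises(ValueError):
            nearest_stations(GeoPoint(45, -72), {"s": GeoPoint(45, -72)}, 2)


class TestDayLength:
    def test_study_area_latitude_contrast_on_peak_laying_date(self):
        # 80-km latitudinal span around the 45.57 N centroid on May 20
        half = 40.0 / (2 * np.pi * 6371.0 / 360.0)
        lo = day_length_minutes(45.57 - half, "2005-05-20")
        hi = day_length_minutes(45.57 + half, "2005-05-20")
        assert round(hi - lo) == 5

    def test_consecutive_day_contrast_at_centroid(self):
        d1 = day_length_minutes(45.57, "2005-05-20")
        d2 = day_length_minutes(45.57, "2005-05-21")
        assert round(d2 - d1) == 2

    def test_equator_equinox_slightly_over_12h(self):
        # refraction + semidiameter push daylight past 720 min
        d = day_length_minutes(0.0, "2005-03-20")
        assert 720 < d < 735

    def test_monotone_in_latitude_late_may(self):
        lats = np.linspace(40, 60, 21)
        values = [day_length_minutes(lat, "2005-05-25") for lat in lats]
        assert np.all(np.diff(values) > 0)

    def test_polar_latitudes_rejected(self):
        with pytest.raises(ValueError):
            day_length_minutes(67.0, "2005-06-21")


class TestWeatherSeries:
    def _series(self, station="s1", n=10, tmean=None):
        dates = pd.date_range("2005-03-01", periods=n)
        return DailyWeatherSeries(
            station,
            pd.DataFrame(
                {
                    "date": dates,
                    "tmean": np.arange(n, dtype=float) if tmean is None else tmean,
                    "rain": 1.0,
                }
            ),
        )

    def test_rejects_duplicates_and_negative_rain(self):
        dates = ["2005-03-01", "2005-03-01"]
        with pytest.raises(ValueError, match="duplicate"):
            DailyWeatherSeries(
                "s", pd.DataFrame({"date": dates, "tmean": [1.0, 2.0], "rain": [0, 0]})
            )
        with pytest.raises(ValueError, match="negative rainfall"):
            DailyWeatherSeries(
                "s",
                pd.DataFrame(
                    {"date": ["2005-03-01"], "tmean": [1.0], "rain": [-1.0]}
                ),
            )

    def test_value_matrix_day_alignment(self):
        s = self._series()
        years, mat = s.value_matrix("tmean")
        assert list(years) == [2005]
        # March 1 2005 is Julian day 60 -> column 59
        assert mat[0, 59] == 0.0
        assert mat[0, 68] == 9.0
        assert np.isnan(mat[0, 58])

    def test_average_stations_handles_partial_overlap(self):
        a = self._series("a", n=5)
        b = self._series("b", n=5, tmean=np.arange(5) + 2.0)
        avg = average_stations([a, b])
        assert avg.data["tmean"].tolist() == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_assign_station_series_nearest(self):
        farms = {"f": GeoPoint(45.0, -72.0)}
        stations = {"near": GeoPoint(45.01, -72.0), "far": GeoPoint(46.0, -72.0)}
        weather = {"near": self._series("near"), "far": self._series("far")}
        got = assign_station_series(farms, stations, weather, k=1)
        assert got["f"].station_id == "near"
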