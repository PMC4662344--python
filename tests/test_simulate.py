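import numpy as np
import pandas as pd
import pytest

from phenoplast.geo import GeoPoint, haversine_km
from phenoplast.simulate import (
    SyntheticTruth,
    generate_dataset,
    generate_landscape,
    generate_weather,
    simulate_window_scan_dataset,
)
from phenoplast.windows import WindowSpec, aggregate_window


class TestLandscape:
    def test_latitudinal_span_matches_request(self, rng):
        farms, _ = generate_landscape(n_farms=40, lat_span_km=80.0, rng=rng)
        km_per_deg = 2 * np.pi * 6371.0 / 360.0
        span_km = (farms.latitude.max() - farms.latitude.min()) * km_per_deg
        assert span_km == pytest.approx(80.0, abs=0.5)

    def test_every_farm_within_20km_of_a_station(self, rng):
        for _ in range(3):
            farms, stations = generate_landscape(n_farms=40, rng=rng)
            spts = [GeoPoint(r.latitude, r.longitude) for r in stations.itertuples()]
            for r in farms.itertuples():
                fp = GeoPoint(r.latitude, r.longitude)
                assert min(haversine_km(fp, s) for s in spts) <= 20.0

    def test_elevation_longitude_collinearity(self, rng):
        farms, _ = generate_landscape(n_farms=40, rng=rng)
        r = np.corrcoef(farms.longitude, farms.elevation)[0, 1]
        assert abs(r) > 0.9

    def test_minimum_two_farms(self, rng):
        farms, _ = generate_landscape(n_farms=2, rng=rng)
        assert len(farms) == 2
        with pytest.raises(ValueError):
            generate_landscape(n_farms=1, rng=rng)


class TestWeather:
    def test_same_seed_identical_series(self):
        stations = pd.DataFrame({"station_id": ["s0", "s1"]})
        years = range(2004, 2008)
        a = generate_weather(stations, years, rng=np.random.default_rng(9))
        b = generate_weather(stations, years, rng=np.random.default_rng(9))
        for sid in ("s0", "s1"):
            pd.testing.assert_frame_equal(a[sid].data, b[sid].data)

    def test_noiseless_window_mean_is_linear_in_year(self):
        truth = SyntheticTruth(
            sd_window_anomaly=0.0, sd_year_anomaly=0.0,
            ar1_innovation_sd=0.0, station_offset_sd=0.0,
        )
        stations = pd.DataFrame({"station_id": ["s0"]})
        weather = generate_weather(stations, range(2004, 2010), truth,
                                   np.random.default_rng(1))
        w = truth.window_temp
        means = [aggregate_window(weather["s0"], w, y) for y in range(2004, 2010)]
        diffs = np.diff(means)
        np.testing.assert_allclose(diffs, truth.trend_temp_per_year, atol=1e-9)

    def test_warming_trend_moment(self):
        # fitted interannual trend of the window mean matches the truth value
        # within Monte Carlo error over replicates
        slopes = []
        for seed in range(25):
            stations = pd.DataFrame({"station_id": ["s0", "s1", "s2"]})
            weather = generate_weather(
                stations, range(2004, 2014), rng=np.random.default_rng(seed)
            )
            w = SyntheticTruth().window_temp
            means = np.mean(
                [
                    [aggregate_window(weather[s], w, y) for y in range(2004, 2014)]
                    for s in ("s0", "s1", "s2")
                ],
                axis=0,
            )
            slopes.append(np.polyfit(np.arange(10), means, 1)[0])
        assert np.mean(slopes) == pytest.approx(0.183, abs=3 * np.std(slopes) / 5 + 0.05)


class TestPopulation:
    def test_first_clutch_count_near_study_size(self):
        ds = generate_dataset(seed=1)
        firsts = ds.records[ds.records.clutch_order == 1]
        assert 2273 * 0.75 <= len(firsts) <= 2273 * 1.25

    def test_same_seed_reproduces_records(self):
        a = generate_dataset(seed=4, n_farms=8, years=range(2005, 2009))
        b = generate_dataset(seed=4, n_farms=8, years=range(2005, 2009))
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_degenerate_truth_gives_constant_lay_dates(self):
        truth = SyntheticTruth(
            beta_latitude=0.0, beta_density=0.0, beta_density_within=0.0,
            beta_temperature=0.0, beta_temp_x_density=0.0, beta_age_asy=0.0,
            sd_year=0.0, sd_farm=0.0, sd_farmyear=0.0, sd_female=0.0,
            sd_resid=0.0, sd_female_slope_density=0.0,
            lay_trend_direct_per_year=0.0, second_clutch_fraction=0.0,
        )
        ds = generate_dataset(seed=2, n_farms=6, years=range(2005, 2009), truth=truth)
        assert (ds.records["lay_date"] == 141).all()  # intercept 141.415 rounded

    def test_philopatry_rate_close_to_truth(self):
        ds = generate_dataset(seed=3)
        rec = ds.records[ds.records.clutch_order == 1].sort_values("year")
        moves = stays = 0
        for _, grp in rec.groupby("female_id"):
            farms_seen = grp.drop_duplicates("year")["farm_id"].to_numpy()
            for a, b in zip(farms_seen[:-1], farms_seen[1:]):
                if a == b:
                    stays += 1
                else:
                    moves += 1
        rate = stays / (stays + moves)
        assert rate == pytest.approx(0.92, abs=0.05)

    def test_second_clutch_fraction(self):
        ds = generate_dataset(seed=5)
        frac = (ds.records.clutch_order == 2).mean()
        assert frac == pytest.approx(0.127, abs=0.03)

    def test_ages_progress_sy_to_asy(self):
        ds = generate_dataset(seed=6, n_farms=10, years=range(2005, 2010))
        rec = ds.records[ds.records.clutch_order == 1]
        for _, grp in rec.groupby("female_id"):
            ages = grp.sort_values("year")["age_class"].tolist()
            if "SY" in ages:
                assert ages.index("SY") == 0  # SY only in the first season


class TestWindowScanHarness:
    def test_target_correlation_reached_on_average(self, rng):
        rs = []
        for _ in range(20):
            series, phen = simulate_window_scan_dataset(rng)
            _, mat = series.value_matrix("tmean")
            w = WindowSpec(96, 129)
            wm = np.nanmean(mat[:, w.start_day : w.end_day], axis=1)
            y = np.array([phen[k] for k in sorted(phen)])
            rs.append(abs(np.corrcoef(wm, y)[0, 1]))
        assert np.mean(rs) == pytest.approx(0.75, abs=0.07)
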