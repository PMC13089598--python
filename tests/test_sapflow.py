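"""Four-step sap-flow processing: aggregation thresholds, year filtering,
outlier removal, detrending, variance normalization, tree averaging."""

import numpy as np
import pandas as pd
import pytest

import droughtlegacy as dl
from conftest import daily_frame, grid_365


def halfhourly_day(n_daytime=20, n_present=20, date="2003-06-01", value=2.0):
    """One day of half-hourly records with a controllable daytime gap count."""
    ts = pd.date_range(date, periods=48, freq="30min")
    daytime = np.zeros(48, dtype=bool)
    daytime[14:14 + n_daytime] = True
    values = np.full(48, value)
    missing = np.flatnonzero(daytime)[n_present:]
    values[missing] = np.nan
    return pd.DataFrame({"timestamp": ts, "value": values, "daytime_flag": daytime})


class TestAggregateDaily:
    def test_full_day_mean(self):
        frame = halfhourly_day(n_daytime=20, n_present=20)
        frame.loc[frame["daytime_flag"], "value"] = np.arange(20, dtype=float)
        out = dl.aggregate_daily(frame)
        assert out["value"].iloc[0] == pytest.approx(np.arange(20).mean())

    @pytest.mark.parametrize("n_present,expect_value", [
        (13, False),   # 65% < 70% -> missing
        (14, True),    # exactly 70% -> computed (inclusive threshold)
        (20, True),
    ])
    def test_availability_threshold(self, n_present, expect_value):
        out = dl.aggregate_daily(halfhourly_day(n_daytime=20, n_present=n_present))
        assert out["value"].notna().iloc[0] == expect_value

    def test_sub_70_percent_missing(self):
        # 20 of 29 daytime slots (69%) -> below the 70% rule
        out = dl.aggregate_daily(halfhourly_day(n_daytime=29, n_present=20))
        assert out["value"].isna().all()

    def test_daily_passthrough(self):
        frame = pd.DataFrame({
            "timestamp": pd.date_range("2003-01-01", periods=10, freq="D"),
            "value": np.arange(10.0), "daytime_flag": True})
        out = dl.aggregate_daily(frame)
        np.testing.assert_allclose(out["value"], np.arange(10.0))


class TestFilterYears:
    def test_year_coverage_boundary(self):
        rng = np.random.default_rng(0)
        values = np.ones(365 * 3)
        # year 2: keep exactly 39% of days; year 3: full coverage
        drop = rng.choice(365, size=365 - int(np.floor(0.39 * 365)), replace=False)
        v = values.copy()
        v[365 + drop] = np.nan
        out = dl.filter_years(grid_365(v))
        years = pd.DatetimeIndex(out["date"]).year
        assert out.loc[years == 2004, "value"].isna().all()      # 39% -> dropped
        assert out.loc[years == 2005, "value"].notna().all()     # untouched

    def test_retained_years_match_bruteforce(self):
        rng = np.random.default_rng(7)
        values = np.ones(365 * 6)
        values[rng.random(len(values)) < rng.uniform(0.2, 0.8)] = np.nan
        frame = grid_365(values)
        out = dl.filter_years(frame)
        cal = dl.attach_calendar(frame)
        for year, grp in cal.groupby("year"):
            kept = out.loc[pd.DatetimeIndex(out["date"]).year == year, "value"].notna().any()
            assert kept == (grp["value"].notna().mean() >= 0.40)


class TestRemoveOutliers:
    def test_constant_year_untouched(self):
        out, n = dl.remove_outliers(grid_365(np.ones(365)))
        assert n == 0 and out["value"].notna().all()

    def test_injected_spike_removed(self):
        rng = np.random.default_rng(1)
        values = rng.normal(10, 1, 365)
        mean, sd = values.mean(), values.std(ddof=1)
        values[100] = mean + 4 * sd
        out, n = dl.remove_outliers(grid_365(values))
        assert np.isnan(out["value"].iloc[100])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(5, 2, 365 * 4)
        spikes = rng.choice(len(values), 12, replace=False)
        values[spikes] += rng.choice([-1, 1], 12) * 25.0
        frame = grid_365(values)
        out, _ = dl.remove_outliers(frame)
        cal = dl.attach_calendar(frame)
        removed = set()
        for year, grp in cal.groupby("year"):
            m, s = grp["value"].mean(), grp["value"].std(ddof=1)
            removed |= set(grp.index[(grp["value"] - m).abs() > 3 * s])
        expect = frame["value"].copy()
        expect.iloc[sorted(removed)] = np.nan
        np.testing.assert_array_equal(out["value"].isna(), expect.isna())


class TestDetrend:
    def test_constant_series(self):
        out = dl.detrend_longterm(grid_365(np.full(365 * 4, 7.0)))
        assert np.nanmax(np.abs(out["value"])) < 1e-6

    def test_pure_sinusoid_equals_mean_removal(self):
        t = np.arange(365 * 6)
        values = 3.0 + 2.0 * np.sin(2 * np.pi * t / 365)
        out = dl.detrend_longterm(grid_365(values))
        oracle = values - values.mean()
        assert np.nanmax(np.abs(out["value"] - oracle)) < 0.1 * 2.0

    def test_recovers_linear_ramp(self):
        t = np.arange(365 * 10)
        ramp = 0.002 * t
        values = 5.0 + np.sin(2 * np.pi * t / 365) + ramp
        frame = grid_365(values)
        out = dl.detrend_longterm(frame)
        trend = values - out["value"].to_numpy()
        assert np.corrcoef(trend, ramp)[0, 1] > 0.99
        slope = np.polyfit(t, out["value"], 1)[0]
        assert abs(slope) < 0.1 * 0.002

    def test_too_short_record_refused(self):
        with pytest.raises(dl.ProcessingError, match="3 years"):
            dl.detrend_longterm(grid_365(np.ones(365 * 2)))

    def test_gaps_stay_missing(self):
        values = np.sin(2 * np.pi * np.arange(365 * 4) / 365) + 2
        values[50:80] = np.nan
        out = dl.detrend_longterm(grid_365(values))
        assert out["value"].iloc[50:80].isna().all()
        assert out["value"].iloc[80:].notna().all()


class TestNormalizeVariability:
    def test_constant_sd_divides(self):
        rng = np.random.default_rng(3)
        year = rng.normal(0, 1, 365)
        year *= 2.0 / year.std(ddof=1)  # every year identical, SD exactly 2
        values = np.tile(year, 5)
        out = dl.normalize_variability(grid_365(values))
        # pooling identical years changes the (n-1) SD only in the 3rd digit
        np.testing.assert_allclose(out["value"], values / 2.0, rtol=5e-3)

    def test_pooled_window_oracle(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, s, 365) for s in (1.0, 3.0, 0.5)])
        frame = grid_365(values)
        out = dl.normalize_variability(frame)
        v = frame["value"].to_numpy()
        div_y1 = np.std(v[:730], ddof=1)         # years 1-2 (edge truncation)
        div_y2 = np.std(v, ddof=1)               # all three years
        div_y3 = np.std(v[365:], ddof=1)         # years 2-3
        np.testing.assert_allclose(out["value"][:365], v[:365] / div_y1)
        np.testing.assert_allclose(out["value"][365:730], v[365:730] / div_y2)
        np.testing.assert_allclose(out["value"][730:], v[730:] / div_y3)

    def test_trailing_window_option(self):
        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(0, s, 365) for s in (1.0, 2.0, 4.0)])
        frame = grid_365(values)
        out = dl.normalize_variability(frame, align="trailing")
        v = frame["value"].to_numpy()
        np.testing.assert_allclose(out["value"][730:], v[730:] / np.std(v, ddof=1))

    def test_variance_homogenization(self):
        rng = np.random.default_rng(5)
        parts = [rng.normal(0, 2.0 ** -i, 365) for i in range(6)]  # SD halves yearly
        values = np.concatenate(parts)
        frame = grid_365(values)
        out = dl.normalize_variability(frame)
        def sd_ratio(arr):
            sds = [np.std(arr[i * 365:(i + 1) * 365], ddof=1) for i in range(6)]
            return max(sds) / min(sds)
        assert sd_ratio(out["value"].to_numpy()) < sd_ratio(values)

    def test_degenerate_signal_raises(self):
        with pytest.raises(dl.ProcessingError, match="near-constant"):
            dl.normalize_variability(grid_365(np.full(365 * 3, 5.0)))


class TestCombineSensors:
    def test_identical_sensors(self):
        a = daily_frame(np.arange(10.0))
        out = dl.combine_sensors([a, a.copy()], "T1")
        np.testing.assert_allclose(out["value"], a["value"])
        assert (out["n_sensors"] == 2).all()

    def test_available_only_mean(self):
        a = daily_frame([1.0, 1.0])
        b = daily_frame([np.nan, 3.0])
        out = dl.combine_sensors([a, b], "T1")
        assert out["value"].iloc[0] == 1.0 and out["n_sensors"].iloc[0] == 1
        assert out["value"].iloc[1] == 2.0 and out["n_sensors"].iloc[1] == 2

    def test_staggered_gaps_match_rowwise_mean(self):
        rng = np.random.default_rng(6)
        frames = []
        for _ in range(3):
            v = rng.normal(size=50)
            v[rng.random(50) < 0.3] = np.nan
            frames.append(daily_frame(v))
        out = dl.combine_sensors(frames, "T1")
        stacked = np.vstack([f["value"].to_numpy() for f in frames])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            oracle = np.nanmean(stacked, axis=0)
        np.testing.assert_allclose(out["value"], oracle)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            dl.combine_sensors([], "T1")


@pytest.fixture(scope="module")
def degraded_pair():
    rp = dl.ResponseParams(tree_factor_sd=0.0)
    cfg = dl.ScenarioConfig(seed=7, response_params=rp,
                            sensor_spec=dl.SensorSpec(
                                n_trees=1, sensors_per_tree=2,
                                decay_rate_per_year=(0.0, 0.3),
                                replacement_dates=()))
    drivers = dl.generate_drivers(cfg)
    fluxes = dl.generate_fluxes(drivers, cfg)
    sensors = dl.simulate_sensors(fluxes, cfg)
    return cfg, fluxes, sensors


class TestProcessTree:
    def test_degradation_correction(self, degraded_pair):
        _, _, sensors = degraded_pair
        processed = {}
        for sid, grp in sensors.groupby("sensor_id"):
            processed[sid], _ = dl.process_sensor(grp)
        merged = processed["T1S1"].merge(processed["T1S2"], on="date")
        late = merged[pd.DatetimeIndex(merged["date"]).year >= 2020].dropna()
        corr = np.corrcoef(late["value_x"], late["value_y"])[0, 1]
        assert corr > 0.9
        # raw late-record SDs diverge strongly between the sensors
        raw = sensors.copy()
        raw["year"] = pd.DatetimeIndex(raw["timestamp"]).year
        late_raw = raw[raw["year"] >= 2020].groupby("sensor_id")["value"].std()
        assert late_raw["T1S1"] / late_raw["T1S2"] > 5

    def test_identity_sensor_tracks_truth(self):
        rp = dl.ResponseParams(tree_factor_sd=0.0)
        cfg = dl.ScenarioConfig(seed=2, response_params=rp,
                                sensor_spec=dl.SensorSpec(
                                    n_trees=1, sensors_per_tree=1,
                                    decay_rate_per_year=0.0, replacement_dates=(),
                                    gap_prob=0.0, block_gap_per_year=0.0,
                                    outlier_prob=0.0, noise_sd=0.0))
        drivers = dl.generate_drivers(cfg)
        fluxes = dl.generate_fluxes(drivers, cfg)
        sensors = dl.simulate_sensors(fluxes, cfg)
        tree, _ = dl.process_tree(sensors)
        truth = fluxes.rename(columns={"sapflow_T1": "value"})[["date", "value"]]
        truth_proc = dl.normalize_variability(dl.detrend_longterm(truth))
        merged = tree.merge(truth_proc, on="date").dropna()
        assert np.corrcoef(merged["value_x"], merged["value_y"])[0, 1] > 0.99

    def test_outlier_removal_is_rare_under_default_noise(self, degraded_pair):
        _, _, sensors = degraded_pair
        for _, grp in sensors.groupby("sensor_id"):
            _, report = dl.process_sensor(grp)
            assert report["outlier_fraction"] < 0.01

    def test_missingness_never_decreases(self, degraded_pair):
        _, _, sensors = degraded_pair
        grp = sensors[sensors["sensor_id"] == "T1S2"]
        daily = dl.aggregate_daily(grp)
        stages = [daily]
        stages.append(dl.filter_years(stages[-1]))
        stages.append(dl.remove_outliers(stages[-1])[0])
        stages.append(dl.detrend_longterm(stages[-1]))
        stages.append(dl.normalize_variability(stages[-1]))
        missing = [s["value"].isna().mean() for s in stages]
        assert all(b >= a - 1e-12 for a, b in zip(missing, missing[1:]))
        # and no step ever invents a value on a previously missing day
        for a, b in zip(stages, stages[1:]):
            assert not (a["value"].isna() & b["value"].notna()).any()

    def test_multi_tree_orchestration(self):
        cfg = dl.ScenarioConfig(
            start_year=2003, end_year=2008, drought_year=2006,
            post_drought_years=(2007,), seed=9,
            sensor_spec=dl.SensorSpec(n_trees=2, sensors_per_tree=2))
        drivers = dl.generate_drivers(cfg)
        fluxes = dl.generate_fluxes(drivers, cfg)
        sensors = dl.simulate_sensors(fluxes, cfg)
        combined, reports = dl.process_all_trees(sensors)
        assert set(combined["tree_id"]) == {"T1", "T2"}
        assert set(reports) == {"T1", "T2"}
        assert combined["n_sensors"].max() == 2
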