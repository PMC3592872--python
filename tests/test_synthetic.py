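"""The synthetic-data generator: weather statistics, phenology inversion,
and scenario contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenofall as pf


class TestWeatherGenerator:
    def test_seed_determinism(self, weather_cfg):
        a = pf.gen_weather(weather_cfg)
        b = pf.gen_weather(weather_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_long_run_mean_matches_configuration(self):
        cfg = pf.WeatherGenConfig(n_years=100, seed=5)
        wx = pf.gen_weather(cfg)
        # MC standard error of the mean of AR(1) anomalies
        n = len(wx)
        se = cfg.anomaly_sd_c * np.sqrt((1 + cfg.ar1) / (1 - cfg.ar1) / n)
        assert abs(wx["tmean_c"].mean() - cfg.annual_mean_c) < 3 * se + 0.05

    def test_configured_trend_recovered_by_regression(self):
        cfg = pf.WeatherGenConfig(n_years=60, trend_c_per_year=0.05, seed=9)
        wx = pf.gen_weather(cfg)
        annual = wx.groupby("year")["tmean_c"].mean()
        fit = stats.linregress(annual.index.to_numpy(float), annual.to_numpy())
        half = stats.t.ppf(0.975, len(annual) - 2) * fit.stderr
        assert fit.slope - half <= 0.05 <= fit.slope + half

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pf.WeatherGenConfig(ar1=1.0)
        with pytest.raises(ValueError):
            pf.WeatherGenConfig(anomaly_sd_c=-1.0)


class TestPhenologyGenerator:
    def test_daily_noise_free_visits_invert_to_true_dates(
        self, weather18, acru_truth, weather_cfg
    ):
        """With daily visits and no noise, interpolation recovers the
        generating stage dates to better than half a day."""
        cfg = pf.PhenoGenConfig(
            species=(acru_truth,), visit_interval=(1, 1), noise_sd_pct=0.0,
            n_trees=1, seed=2,
        )
        obs, truths = pf.gen_phenology(weather18, cfg, weather_cfg.latitude)
        series = pf.species_series(obs)
        table = pf.threshold_table(series)
        merged = table.merge(
            truths, on=["species", "year", "kind", "level"], suffixes=("_est", "_true")
        ).dropna(subset=["doy_est", "doy_true"])
        assert len(merged) > 100
        assert (merged["doy_est"] - merged["doy_true"]).abs().max() < 0.5

    def test_sparse_visits_bounded_by_half_max_gap(
        self, weather18, acru_truth, weather_cfg
    ):
        cfg = pf.PhenoGenConfig(
            species=(acru_truth,), visit_interval=(3, 7), noise_sd_pct=0.0,
            n_trees=1, seed=3,
        )
        obs, truths = pf.gen_phenology(weather18, cfg, weather_cfg.latitude)
        table = pf.threshold_table(pf.species_series(obs))
        merged = table.merge(
            truths, on=["species", "year", "kind", "level"], suffixes=("_est", "_true")
        ).dropna(subset=["doy_est", "doy_true"])
        assert (merged["doy_est"] - merged["doy_true"]).abs().max() <= 3.5

    def test_early_species_reproduce_missing_first_thresholds(
        self, observations
    ):
        """Some years of the early-coloring species reach 10% before the
        first visit, reproducing the missing-data condition of real records."""
        table = pf.threshold_table(pf.species_series(observations))
        from phenofall.metrics import MISSING_BEFORE_FIRST_VISIT

        early = table[
            (table["missing_reason"] == MISSING_BEFORE_FIRST_VISIT)
            & (table["level"].isin([10, 25]))
        ]
        assert len(early) > 0

    def test_observations_respect_schema_invariants(self, observations):
        assert observations["pct_colored"].between(0, 100).all()
        assert observations["pct_fallen"].between(0, 100).all()
        mono = observations.groupby(["species", "tree_id", "year"])["pct_colored"].apply(
            lambda s: (s.diff().dropna() >= 0).all()
        )
        assert mono.all()

    def test_logistic_shape_option(self, weather18, acru_truth, weather_cfg):
        """The sigmoid trajectory stays monotone and crosses 50% near the
        true mid-date, so downstream interpolation still works."""
        cfg = pf.PhenoGenConfig(
            species=(acru_truth,), trajectory_shape="logistic",
            visit_interval=(1, 1), noise_sd_pct=0.0, n_trees=1, seed=6,
        )
        obs, truths = pf.gen_phenology(weather18, cfg, weather_cfg.latitude)
        table = pf.threshold_table(pf.species_series(obs))
        merged = table.merge(
            truths, on=["species", "year", "kind", "level"], suffixes=("_est", "_true")
        ).dropna(subset=["doy_est", "doy_true"])
        mid = merged[merged["level"] == 50]
        assert (mid["doy_est"] - mid["doy_true"]).abs().max() < 1.5
        with pytest.raises(ValueError, match="trajectory_shape"):
            pf.PhenoGenConfig(trajectory_shape="cubic")

    def test_fall_follows_color_in_expectation(self, true_dates):
        wide = true_dates.pivot_table(
            index=["species", "year", "level"], columns="kind", values="doy"
        ).dropna()
        assert (wide["fall"] >= wide["color"]).mean() > 0.99


class TestScenarioGenerator:
    def test_zero_deltas_are_stationary(self, weather_cfg):
        scen = pf.gen_scenario(weather_cfg, 0.0, 0.0)
        annual = scen.groupby("year")["tmean_c"].mean()
        fit = stats.linregress(annual.index.to_numpy(float), annual.to_numpy())
        half = stats.t.ppf(0.975, len(annual) - 2) * fit.stderr
        assert fit.slope - half <= 0.0 <= fit.slope + half

    def test_a1fi_like_end_of_century_contrast(self, weather_cfg, weather18):
        """2070-2099 mean temperature sits ~4.9 degC above the baseline."""
        scen = pf.scenario_preset("a1fi-like", weather_cfg)
        end = scen[scen["year"] >= 2070]["tmean_c"].mean()
        base = weather18["tmean_c"].mean()
        assert end - base == pytest.approx(4.9, abs=0.35)

    def test_b1_warms_less_than_a1fi_in_every_decade(self, weather_cfg):
        a1 = pf.scenario_preset("a1fi-like", weather_cfg)
        b1 = pf.scenario_preset("b1-like", weather_cfg)
        for start in range(2020, 2100, 10):
            a = a1[(a1["year"] >= start) & (a1["year"] < start + 10)]["tmean_c"].mean()
            b = b1[(b1["year"] >= start) & (b1["year"] < start + 10)]["tmean_c"].mean()
            assert b < a

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            pf.scenario_preset("a2")


class TestEndToEndRecovery:
    def test_generator_to_fit_round_trip(self, weather18, acru_truth, weather_cfg):
        """Zero-noise observations, metrics interpolation, then calibration
        recover the generating node; Y_crit lands within search tolerance."""
        cfg = pf.PhenoGenConfig(
            species=(acru_truth,), visit_interval=(1, 1), noise_sd_pct=0.0,
            n_trees=1, precip_effect_days=0.0, seed=4,
        )
        obs, _ = pf.gen_phenology(weather18, cfg, weather_cfg.latitude)
        table = pf.threshold_table(pf.species_series(obs))
        color = table[table["kind"] == "color"][["year", "level", "doy"]]
        fit = pf.fit_cddp(
            color, weather18, weather_cfg.latitude,
            pstart_grid=(12.0, 13.0, 14.0), tb_grid=(18.0, 20.0, 22.0),
        )
        p = fit.params
        assert (p.p_start, p.t_b, p.x, p.y, p.variant) == (13.0, 20.0, 1, 1, 1)
        for level, y_true in acru_truth.color.y_crit.items():
            assert p.y_crit[level] == pytest.approx(y_true, rel=0.05)
        assert fit.rmse < 0.5
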