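"""The cold-degree-day x photoperiod model: forward runs and calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest

import phenofall as pf
from phenofall import cddp


def constant_weather(year=2001, tmean=19.0):
    return pd.DataFrame(
        {"year": year, "doy": np.arange(1, 366), "tmean_c": tmean, "precip_mm": 0.0}
    )


def make_params(**kwargs):
    defaults = dict(p_start=13.0, t_b=20.0, x=1, y=0, variant=1, y_crit={50: 5.0})
    defaults.update(kwargs)
    return cddp.CDDPParams(**defaults)


class TestPhotoperiodFactor:
    def test_boundary_at_p_start(self):
        assert pf.photoperiod_factor(14.0, 14.0, 1) == pytest.approx(1.0)
        assert pf.photoperiod_factor(14.0, 14.0, 2) == pytest.approx(0.0)

    def test_adopted_arithmetic(self):
        assert pf.photoperiod_factor(11.0, 14.0, 1) == pytest.approx(11 / 14)
        assert pf.photoperiod_factor(11.0, 14.0, 2) == pytest.approx(3 / 14)

    def test_monotonicity_as_days_shorten(self):
        p = np.array([13.0, 12.0, 11.0, 10.0])
        v1 = pf.photoperiod_factor(p, 13.0, 1)
        v2 = pf.photoperiod_factor(p, 13.0, 2)
        assert np.all(np.diff(v1) < 0)
        assert np.all(np.diff(v2) > 0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            pf.photoperiod_factor(12.0, 13.0, 3)


class TestDailyRate:
    def test_zero_at_or_above_base_temperature(self):
        params = make_params(x=1)
        assert pf.daily_rate(20.0, 12.0, params) == 0.0
        assert pf.daily_rate(25.0, 12.0, params) == 0.0

    def test_unit_rate_one_degree_below_base(self):
        assert pf.daily_rate(19.0, 12.0, make_params(x=1, y=0)) == pytest.approx(1.0)

    def test_quadratic_exponent(self):
        assert pf.daily_rate(18.0, 12.0, make_params(x=2, y=0)) == pytest.approx(4.0)

    def test_temperature_independent_when_x_zero(self):
        params = make_params(x=0, y=0)
        assert pf.daily_rate(35.0, 12.0, params) == pytest.approx(1.0)


class TestSimulateYear:
    def test_linear_accumulation_reaches_stage_after_y_crit_days(self):
        """Constant unit rate: the stage lands Y_crit days after D_start."""
        traj = pf.simulate_year(constant_weather(tmean=19.0), make_params(), 42.54)
        assert traj.predicted[50] == traj.d_start + 5

    def test_pure_photoperiod_null_repeats_every_year(self, weather18):
        params = make_params(x=0, y=0, y_crit={50: 20.0})
        dates = set()
        for year in range(1993, 1999):
            sub = weather18[weather18["year"] == year]
            traj = pf.simulate_year(sub, params, 42.54)
            dates.add(traj.predicted[50] - 0 * year)
        assert len(dates) == 1

    def test_doubling_y_crit_never_advances_the_date(self, weather18):
        sub = weather18[weather18["year"] == 1995]
        t1 = pf.simulate_year(sub, make_params(y_crit={50: 10.0}), 42.54)
        t2 = pf.simulate_year(sub, make_params(y_crit={50: 20.0}), 42.54)
        assert t2.predicted[50] >= t1.predicted[50]

    def test_state_nonnegative_nondecreasing_zero_before_d_start(self, weather18):
        for params in [make_params(x=x, y=y, variant=v)
                       for x in (0, 1, 2) for y in (0, 2) for v in (1, 2)]:
            sub = weather18[weather18["year"] == 2000]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = pf.simulate_year(sub, params, 42.54)
            assert np.all(traj.s_sen >= 0)
            assert np.all(np.diff(traj.s_sen) >= 0)
            before = traj.doys <= traj.d_start
            assert np.all(traj.s_sen[before] == 0)

    def test_unreached_threshold_warns_and_is_missing(self):
        params = make_params(y_crit={90: 1e9})
        with pytest.warns(UserWarning, match="never reached"):
            traj = pf.simulate_year(constant_weather(), params, 42.54)
        assert traj.predicted[90] is None

    def test_weather_gap_in_accumulation_window_rejected(self):
        wx = constant_weather()
        wx.loc[wx["doy"] == 250, "tmean_c"] = np.nan
        with pytest.raises(ValueError, match="gap"):
            pf.simulate_year(wx, make_params(), 42.54)

    def test_cooling_never_delays_any_stage(self, weather18):
        """Uniformly 1 degC colder autumns advance (or hold) every stage."""
        params = make_params(x=1, y=1, y_crit={10: 20.0, 50: 60.0, 90: 120.0})
        sub = weather18[weather18["year"] == 1997].copy()
        base = pf.simulate_year(sub, params, 42.54)
        cooler = sub.copy()
        cooler["tmean_c"] -= 1.0
        cooled = pf.simulate_year(cooler, params, 42.54)
        for level in params.y_crit:
            assert cooled.predicted[level] <= base.predicted[level]


class TestFitCDDP:
    REDUCED = dict(
        pstart_grid=(12.0, 13.0, 14.0),
        tb_grid=(16.0, 18.0, 20.0, 22.0),
    )

    def test_exact_recovery_on_reduced_grid(self, weather18, acru_truth, weather_cfg):
        """Noise-free truth generated at a grid node is recovered exactly."""
        truths = pf.true_stage_dates(weather18, [acru_truth], weather_cfg.latitude)
        obs = truths[truths["kind"] == "color"][["year", "level", "doy"]]
        fit = pf.fit_cddp(obs, weather18, weather_cfg.latitude, **self.REDUCED)
        assert (fit.params.p_start, fit.params.t_b) == (13.0, 20.0)
        assert (fit.params.x, fit.params.y, fit.params.variant) == (1, 1, 1)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_parameter_count_is_nine_for_five_stages(self, weather18, acru_truth, weather_cfg):
        truths = pf.true_stage_dates(weather18, [acru_truth], weather_cfg.latitude)
        obs = truths[truths["kind"] == "color"][["year", "level", "doy"]]
        fit = pf.fit_cddp(obs, weather18, weather_cfg.latitude, **self.REDUCED)
        assert fit.K == 9

    def test_identical_dates_fit_by_null_structure(self, weather18, weather_cfg):
        """Year-invariant dates are matched perfectly by an x = 0 node."""
        years = weather_cfg.years
        obs = pd.DataFrame(
            {"year": np.repeat(years, 2), "level": [50, 90] * len(years),
             "doy": [280.0, 300.0] * len(years)}
        )
        fit = pf.fit_cddp(obs, weather18, weather_cfg.latitude, **self.REDUCED)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.params.x == 0

    def test_null_dominance_for_photoperiod_only_data(self, weather18, weather_cfg):
        """With photoperiod-generated data no cold-degree node materially
        beats the null structure (both reach zero error)."""
        years = weather_cfg.years
        obs = pd.DataFrame({"year": years, "level": 50, "doy": 285.0})
        fit = pf.fit_cddp(obs, weather18, weather_cfg.latitude, **self.REDUCED)
        assert fit.params.x == 0
        assert fit.rmse <= 1e-9

    def test_y_crit_nondecreasing_in_level(self, weather18, acru_truth, weather_cfg):
        truths = pf.true_stage_dates(weather18, [acru_truth], weather_cfg.latitude)
        obs = pf.jitter_dates(truths[truths["kind"] == "color"], 2.0, seed=3)
        fit = pf.fit_cddp(obs[["year", "level", "doy"]], weather18, weather_cfg.latitude,
                          **self.REDUCED)
        yc = [fit.params.y_crit[lv] for lv in sorted(fit.params.y_crit)]
        assert all(a <= b for a, b in zip(yc, yc[1:]))

    def test_random_draw_recovery_on_full_grid(self, weather18, weather_cfg):
        """Across random identifiable truths (x >= 1), (x, y) recover exactly
        and (P_start, T_b) within one grid step in >= 95% of draws."""
        rng = np.random.default_rng(2024)
        n_draws = 20
        failures = 0
        for _ in range(n_draws):
            p_start = float(rng.choice(np.arange(12.5, 15.01, 0.5)))
            t_b = float(rng.choice(np.arange(12.0, 26.01, 0.5)))
            x = int(rng.choice([1, 2]))
            y = int(rng.choice([0, 1, 2]))
            variant = int(rng.choice([1, 2]))
            targets = {10: 280.0, 25: 286.0, 50: 292.0, 75: 298.0, 90: 304.0}
            truth = pf.derive_y_crit(p_start, t_b, x, y, variant, targets, weather_cfg)
            dates = cddp.predict_stage_dates(
                truth, weather18, weather_cfg.years, weather_cfg.latitude
            )
            fit = pf.fit_cddp(dates.dropna(), weather18, weather_cfg.latitude)
            ok = (
                fit.params.x == x
                and fit.params.y == y
                and abs(fit.params.p_start - p_start) <= 0.5
                and abs(fit.params.t_b - t_b) <= 0.5
            )
            if not ok:
                failures += 1
        assert failures <= max(1, int(0.05 * n_draws))

    def test_date_noise_propagates_to_rmse(self, weather18, acru_truth, weather_cfg):
        """With 3-day observation noise the refit RMSE sits near 3 days."""
        truths = pf.true_stage_dates(weather18, [acru_truth], weather_cfg.latitude)
        obs = pf.jitter_dates(truths[truths["kind"] == "color"], 3.0, seed=8)
        fit = pf.fit_cddp(obs[["year", "level", "doy"]], weather18, weather_cfg.latitude,
                          **self.REDUCED)
        assert 1.5 < fit.rmse < 4.5

    def test_no_observations_rejected(self, weather18, weather_cfg):
        empty = pd.DataFrame({"year": [], "level": [], "doy": []})
        with pytest.raises(ValueError, match="no stage observations"):
            pf.fit_cddp(empty, weather18, weather_cfg.latitude, **self.REDUCED)
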