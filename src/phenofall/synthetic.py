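"""Synthetic weather, phenology and climate scenarios.

The generator emulates the statistical structure of a long-term New England
phenology record so every pipeline stage is testable without field data:

* daily weather with a sinusoidal seasonal cycle, AR(1)-autocorrelated
  temperature anomalies, i.i.d. gamma daily precipitation, and an optional
  secular warming trend;
* eight tree species whose true stage dates come from forward runs of the
  cold-degree-day x photoperiod model (so calibration can be validated as
  parameter recovery), with structures spanning early and late coloring and
  temperature exponents x in {0, 1, 2} -- including a pure photoperiod-null
  species whose dates repeat every year;
* percent-colored / percent-fallen trajectories built as monotone piecewise
  linear curves through the five true stage dates, sampled at random 3-7-day
  autumn visits for a few trees per species, with truncated-Gaussian
  observer noise (applied to percents, clipped to [0, 100], re-monotonised
  by running maximum);
* scenario weather for 2010-2099 whose warming ramp matches prescribed
  end-of-century contrasts against the baseline climate.

Species whose earliest thresholds fall before the first visit of a year
yield missing stage dates, reproducing the missing-data condition of real
autumn records.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import climate
from .cddp import ACC_DOYS, CDDPParams, d_start_index, daily_rate
from .forecast import reconstruct_curve
from .io_tables import WEATHER_COLUMNS, reindex_calendar


@dataclasses.dataclass
class WeatherGenConfig:
    """Daily-weather generator settings (defaults: a cool-temperate site).

    ``annual_mean_c`` and ``precip`` defaults reproduce a ~7 degC / ~1100 mm
    baseline climate; the AR(1) anomaly model gives weather-like multi-day
    persistence.
    """

    start_year: int = 1993
    n_years: int = 18
    latitude: float = 42.54
    annual_mean_c: float = 7.1
    amplitude_c: float = 13.0
    peak_doy: int = 200
    ar1: float = 0.7
    anomaly_sd_c: float = 3.0
    precip_shape: float = 0.3
    precip_scale_mm: float = 10.0
    trend_c_per_year: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.anomaly_sd_c < 0 or self.precip_scale_mm < 0:
            raise ValueError("spreads must be non-negative")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


def _doy_limit(year: int) -> int:
    return 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365


def seasonal_temperature(config: WeatherGenConfig, doy) -> np.ndarray:
    """Deterministic seasonal cycle: mean + amplitude * cos about the peak day."""
    doy = np.asarray(doy, dtype=float)
    return config.annual_mean_c + config.amplitude_c * np.cos(
        2.0 * np.pi * (doy - config.peak_doy) / 365.0
    )


def gen_weather(
    config: WeatherGenConfig, mean_offset_by_year: dict[int, float] | None = None
) -> pd.DataFrame:
    """Generate a multi-year daily weather table (year, doy, tmean_c, precip_mm).

    Temperature is the seasonal cycle plus stationary AR(1) anomalies (the
    innovation variance is scaled so the marginal anomaly SD equals
    ``anomaly_sd_c``) plus the secular trend; precipitation is i.i.d. gamma.
    Fully reproducible from the seed.  ``mean_offset_by_year`` adds an
    extra per-year shift (used by the scenario generator).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    n_days = sum(_doy_limit(y) for y in config.years)
    innov_sd = config.anomaly_sd_c * np.sqrt(1.0 - config.ar1**2)
    anomalies = signal.lfilter([1.0], [1.0, -config.ar1], rng.normal(0.0, innov_sd, n_days))
    precip = rng.gamma(config.precip_shape, config.precip_scale_mm, n_days)
    pos = 0
    for year in config.years:
        nd = _doy_limit(year)
        doys = np.arange(1, nd + 1)
        base = seasonal_temperature(config, np.minimum(doys, 365))
        shift = config.trend_c_per_year * (year - config.start_year)
        if mean_offset_by_year is not None:
            shift += mean_offset_by_year.get(year, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "year": year,
                    "doy": doys,
                    "tmean_c": base + anomalies[pos : pos + nd] + shift,
                    "precip_mm": precip[pos : pos + nd],
                }
            )
        )
        pos += nd
    return reindex_calendar(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# species truths


@dataclasses.dataclass
class SpeciesTruth:
    """The generating process of one synthetic species."""

    species: str
    color: CDDPParams
    fall: CDDPParams


def derive_y_crit(
    p_start: float,
    t_b: float,
    x: int,
    y: int,
    variant: int,
    target_doys: dict[int, float],
    config: WeatherGenConfig,
) -> CDDPParams:
    """Build a parameter set whose climatological stage dates hit targets.

    The accumulation curve is run over the noise-free seasonal cycle and
    each level's Y_crit is placed between the accumulation values of the
    target day and the previous day, so the first-crossing rule returns the
    target exactly in an average year.
    """
    t = seasonal_temperature(config, ACC_DOYS)
    p = climate.daylength(config.latitude, ACC_DOYS)
    params = CDDPParams(p_start=p_start, t_b=t_b, x=x, y=y, variant=variant, y_crit={})
    ds = d_start_index(p, p_start)
    rate = np.zeros(ACC_DOYS.size)
    if ds + 1 < ACC_DOYS.size:
        rate[ds + 1 :] = daily_rate(t[ds + 1 :], p[ds + 1 :], params)
    s = np.cumsum(rate)
    y_crit = {}
    for level, doy in sorted(target_doys.items()):
        idx = int(round(doy)) - int(ACC_DOYS[0])
        idx = int(np.clip(idx, 1, ACC_DOYS.size - 1))
        y_crit[int(level)] = float(0.5 * (s[idx - 1] + s[idx]))
    return CDDPParams(p_start=p_start, t_b=t_b, x=x, y=y, variant=variant, y_crit=y_crit)


def default_species(config: WeatherGenConfig | None = None) -> list[SpeciesTruth]:
    """Eight synthetic species spanning early/late coloring and model structures.

    Codes follow the four-letter genus-species convention of forest
    phenology records.  One species (QURU) is a pure photoperiod null
    (x = 0): its stage dates repeat identically every year.
    """
    config = config or WeatherGenConfig()
    spec = [
        # name, (p_start, t_b, x, y, variant), color targets c10..c90, fall lag
        ("ACRU", (13.0, 20.0, 1, 1, 1), (258, 264, 271, 277, 283), 14),
        ("ACSA", (12.5, 18.0, 1, 0, 1), (272, 278, 284, 290, 296), 12),
        ("FRAM", (13.5, 22.0, 2, 1, 2), (255, 260, 266, 272, 278), 10),
        ("NYSY", (13.0, 19.0, 1, 2, 1), (263, 269, 275, 281, 287), 13),
        ("PRSE", (14.0, 24.0, 2, 0, 1), (252, 258, 265, 271, 277), 11),
        ("QUAL", (12.0, 17.0, 1, 1, 2), (278, 284, 290, 296, 302), 12),
        ("QURU", (12.5, 15.0, 0, 0, 1), (276, 282, 288, 294, 300), 13),
        ("QUVE", (12.0, 16.5, 2, 2, 1), (274, 280, 286, 292, 298), 12),
    ]
    levels = (10, 25, 50, 75, 90)
    out = []
    for name, (p_start, t_b, x, y, variant), targets, lag in spec:
        color_targets = dict(zip(levels, (float(t) for t in targets)))
        fall_targets = {lv: d + lag for lv, d in color_targets.items()}
        out.append(
            SpeciesTruth(
                species=name,
                color=derive_y_crit(p_start, t_b, x, y, variant, color_targets, config),
                fall=derive_y_crit(p_start, t_b, x, y, variant, fall_targets, config),
            )
        )
    return out


# ---------------------------------------------------------------------------
# phenology observations


@dataclasses.dataclass
class PhenoGenConfig:
    """Observation-process settings for the phenology generator.

    ``precip_effect_days`` adds a moisture pathway the cold-degree-day model
    structurally omits: each year's stage dates shift together by this many
    days per standard deviation of the late-summer (Aug-Sep) precipitation
    anomaly, wetter summers delaying senescence.  Field records show exactly
    such precipitation correlations alongside the temperature signal, so the
    default keeps a modest effect; set 0 for a purely temperature-driven
    truth.
    """

    species: tuple[SpeciesTruth, ...] = ()
    first_visit_doy: int = 244
    last_visit_doy: int = 340
    visit_interval: tuple[int, int] = (3, 7)
    noise_sd_pct: float = 5.0
    n_trees: int = 4
    precip_effect_days: float = 2.0
    trajectory_shape: str = "linear"  # or "logistic", to probe the
    # analysis's piecewise-linear interpolation assumption
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.visit_interval
        if not (1 <= lo <= hi):
            raise ValueError("visit interval must satisfy 1 <= lo <= hi")
        if self.noise_sd_pct < 0:
            raise ValueError("noise SD must be non-negative")
        if self.trajectory_shape not in ("linear", "logistic"):
            raise ValueError("trajectory_shape must be 'linear' or 'logistic'")


def _percent_curve(visits: np.ndarray, dates: dict[int, float], shape: str) -> np.ndarray:
    """Evaluate a species-year percent trajectory at the visit days.

    'linear' threads a monotone piecewise-linear curve through the stage
    dates (matching the interpolation assumption of the analysis);
    'logistic' fits a sigmoid through the 50% date with scale set by the
    10-90% spread, probing robustness to the linearity assumption.
    """
    if not dates:
        return np.zeros(visits.size)
    if shape == "logistic" and {10, 50, 90} <= set(dates):
        spread = max(dates[90] - dates[10], 1e-6)
        scale = spread / (2.0 * np.log(9.0))  # logistic hits 10/90 at +-ln(9)*s
        return 100.0 / (1.0 + np.exp(-(visits - dates[50]) / scale))
    kd, kp = reconstruct_curve(dates)
    if kd.size == 0:
        return np.zeros(visits.size)
    return np.interp(visits, kd, kp, left=0.0, right=100.0)


def true_stage_dates(
    weather: pd.DataFrame, species: Iterable[SpeciesTruth], latitude: float
) -> pd.DataFrame:
    """Forward-run every species' true parameters: long (species, year, kind,
    level, doy) table of generating-process stage dates."""
    from .cddp import predict_stage_dates

    years = sorted(int(v) for v in weather["year"].unique())
    frames = []
    for truth in species:
        for kind, params in (("color", truth.color), ("fall", truth.fall)):
            table = predict_stage_dates(params, weather, years, latitude)
            table["species"] = truth.species
            table["kind"] = kind
            frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    return out[["species", "year", "kind", "level", "doy"]]


def gen_phenology(
    weather: pd.DataFrame,
    config: PhenoGenConfig,
    latitude: float = 42.54,
):
    """Generate per-tree percent observations plus the true stage dates.

    Returns ``(observations, truths)``: observations follow the phenology
    CSV schema; truths is the long true stage-date table.  The percent
    trajectory of each species-year is the monotone piecewise-linear curve
    through its five true stage dates (first segment extended to 0%, last
    to 100%), sampled at shared random visit days and perturbed per tree by
    truncated-Gaussian noise, clipped and re-monotonised.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species or tuple(default_species())
    truths = true_stage_dates(weather, species, latitude)
    years = sorted(int(v) for v in weather["year"].unique())

    if config.precip_effect_days:
        # late-summer moisture delays/advances the whole stage sequence
        aug_sep = weather[(weather["doy"] >= 213) & (weather["doy"] <= 273)]
        totals = aug_sep.groupby("year")["precip_mm"].sum()
        z = (totals - totals.mean()) / max(totals.std(ddof=1), 1e-9)
        shift = truths["year"].map(z) * config.precip_effect_days
        truths = truths.assign(doy=truths["doy"] + shift)

    lo, hi = config.visit_interval
    rows = []
    for year in years:
        # one shared visit schedule per year, as in a single-observer protocol
        visits = [config.first_visit_doy]
        while visits[-1] < config.last_visit_doy:
            visits.append(visits[-1] + int(rng.integers(lo, hi + 1)))
        visits = np.array([v for v in visits if v <= min(config.last_visit_doy + hi, 365)])
        for truth in species:
            curves = {}
            for kind in ("color", "fall"):
                sub = truths[
                    (truths["species"] == truth.species)
                    & (truths["year"] == year)
                    & (truths["kind"] == kind)
                ]
                dates = {int(r.level): float(r.doy) for r in sub.itertuples() if np.isfinite(r.doy)}
                curves[kind] = _percent_curve(visits, dates, config.trajectory_shape)
            for tree in range(1, config.n_trees + 1):
                observed = {}
                for kind in ("color", "fall"):
                    noisy = curves[kind] + rng.normal(0.0, config.noise_sd_pct, visits.size)
                    observed[kind] = np.maximum.accumulate(np.clip(noisy, 0.0, 100.0))
                for i, doy in enumerate(visits):
                    rows.append(
                        {
                            "species": truth.species,
                            "tree_id": f"t{tree}",
                            "year": year,
                            "doy": int(doy),
                            "pct_colored": observed["color"][i],
                            "pct_fallen": observed["fall"][i],
                        }
                    )
    observations = pd.DataFrame(rows)
    return observations, truths


def jitter_dates(truths: pd.DataFrame, sd_days: float, seed: int = 0) -> pd.DataFrame:
    """Add independent Gaussian day noise to a true stage-date table.

    Convenience for calibration experiments where the observation error is
    placed directly on dates rather than on percents.
    """
    rng = np.random.default_rng(seed)
    out = truths.copy()
    noise = rng.normal(0.0, sd_days, len(out))
    out["doy"] = out["doy"] + np.where(np.isfinite(out["doy"]), noise, 0.0)
    return out


# ---------------------------------------------------------------------------
# climate scenarios


#: end-of-century (2070-2099 mean) contrasts vs. baseline: (delta T degC, delta P mm/yr)
SCENARIO_DELTAS = {
    "stationary": (0.0, 0.0),
    "a1fi-like": (4.9, 170.0),
    "b1-like": (2.4, 140.0),
}


def gen_scenario(
    base: WeatherGenConfig,
    delta_t_c: float,
    delta_precip_mm: float = 0.0,
    start_year: int = 2010,
    end_year: int = 2099,
) -> pd.DataFrame:
    """Daily scenario weather whose warming ramp hits a prescribed contrast.

    The per-year mean offset rises linearly from zero in ``start_year`` so
    that the mean over the reference period -- the final 30 scenario years,
    i.e. 2070-2099 for the standard 2010-2099 horizon -- exceeds the
    baseline by ``delta_t_c`` (and annual precipitation by
    ``delta_precip_mm``).
    """
    config = dataclasses.replace(
        base, start_year=start_year, n_years=end_year - start_year + 1, trend_c_per_year=0.0
    )
    ref_years = np.arange(max(start_year, end_year - 29), end_year + 1)
    ramp_norm = float(np.mean(ref_years - start_year))
    offsets = {
        y: delta_t_c * (y - start_year) / ramp_norm for y in config.years
    }
    weather = gen_weather(config, mean_offset_by_year=offsets)
    if delta_precip_mm:
        baseline_annual = base.precip_shape * base.precip_scale_mm * 365.0
        factor = weather["year"].map(
            lambda y: 1.0 + (delta_precip_mm / baseline_annual) * (y - start_year) / ramp_norm
        )
        weather["precip_mm"] = weather["precip_mm"] * factor
    return weather


def scenario_preset(name: str, base: WeatherGenConfig | None = None) -> pd.DataFrame:
    """Generate a named scenario: 'stationary', 'a1fi-like' or 'b1-like'."""
    if name not in SCENARIO_DELTAS:
        raise ValueError(f"unknown scenario preset {name!r}")
    base = base or WeatherGenConfig()
    dt, dp = SCENARIO_DELTAS[name]
    return gen_scenario(base, dt, dp)
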