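"""Shared fixtures: synthetic weather, species truths and observation sets."""

import numpy as np
import pandas as pd
import pytest

import phenofall as pf


@pytest.fixture(scope="session")
def weather_cfg():
    return pf.WeatherGenConfig(seed=42)


@pytest.fixture(scope="session")
def weather18(weather_cfg):
    """18 years of stationary synthetic daily weather."""
    return pf.gen_weather(weather_cfg)


@pytest.fixture(scope="session")
def species_truths(weather_cfg):
    return pf.default_species(weather_cfg)


@pytest.fixture(scope="session")
def acru_truth(species_truths):
    """An early-coloring species with x = 1, y = 1, variant 1."""
    return species_truths[0]


@pytest.fixture(scope="session")
def true_dates(weather18, species_truths, weather_cfg):
    return pf.true_stage_dates(weather18, species_truths, weather_cfg.latitude)


@pytest.fixture(scope="session")
def observations(weather18, species_truths, weather_cfg):
    """Noisy per-tree percent observations for all eight species."""
    cfg = pf.PhenoGenConfig(species=tuple(species_truths), seed=7)
    obs, _ = pf.gen_phenology(weather18, cfg, latitude=weather_cfg.latitude)
    return obs


@pytest.fixture(scope="session")
def predictors(weather18, weather_cfg):
    return pf.predictor_table(weather18, weather_cfg.years).set_index("year")
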