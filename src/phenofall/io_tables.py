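"""Tabular input/output and run configuration.

The pipeline exchanges three flat CSV schemas (comma-separated, header row,
UTF-8):

* phenology observations: ``species,tree_id,year,doy,pct_colored,pct_fallen``
* daily weather: ``year,doy,tmean_c,precip_mm``
* run configuration: YAML mapping onto :class:`RunConfig`

Dates are carried as ``(year, doy)`` with an integer, 1-based day of year
scoped to the calendar year; fractional days of year appear only in derived
threshold dates.  Weather series are re-indexed onto a contiguous calendar so
that gaps are explicit ``NaN`` rows, never silently dropped days.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

PHENOLOGY_COLUMNS = ["species", "tree_id", "year", "doy", "pct_colored", "pct_fallen"]
WEATHER_COLUMNS = ["year", "doy", "tmean_c", "precip_mm"]

#: threshold levels (percent) at which stage dates are interpolated
DEFAULT_LEVELS = (10, 25, 50, 75, 90)

#: leaf-on months whose climate means act as regression candidates
DEFAULT_MLR_MONTHS = (5, 6, 7, 8, 9, 10)


class TableFormatError(ValueError):
    """A CSV did not satisfy the schema or its value constraints."""


@dataclasses.dataclass
class RunConfig:
    """Configuration shared across pipeline stages.

    Parameters
    ----------
    latitude
        Site latitude in degrees north; drives the photoperiod calculation.
        Default is a mid-latitude New England hardwood site.
    levels
        Percent thresholds at which color/fall stage dates are interpolated.
    mlr_months
        Calendar months (1-12) whose mean temperature and precipitation are
        regression candidates; defaults to the May-October leaf-on period.
    alpha
        Two-sided significance level used for correlation masking.
    p_enter, p_remove
        Entry and removal p-values of the stepwise regression.
    pstart_grid, tb_grid
        Search grids for the photoperiod threshold (hours) and base
        temperature (deg C) of the process model.
    exponents
        Admissible temperature/photoperiod exponents of the process model.
    window_min_fraction
        Minimum fraction of non-missing days for a trailing window mean.
    refraction
        Include standard atmospheric refraction in the daylength formula.
    seed
        Base seed for every stochastic component.
    """

    latitude: float = 42.54
    levels: tuple[int, ...] = DEFAULT_LEVELS
    mlr_months: tuple[int, ...] = DEFAULT_MLR_MONTHS
    alpha: float = 0.05
    p_enter: float = 0.20
    p_remove: float = 0.05
    pstart_grid: tuple[float, ...] = tuple(np.arange(10.0, 16.0 + 1e-9, 0.5))
    tb_grid: tuple[float, ...] = tuple(np.arange(7.0, 30.0 + 1e-9, 0.5))
    exponents: tuple[int, ...] = (0, 1, 2)
    window_min_fraction: float = 0.9
    refraction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(sorted(self.levels)) != tuple(self.levels):
            raise ValueError("threshold levels must be sorted ascending")
        if not self.pstart_grid or not self.tb_grid or not self.exponents:
            raise ValueError("optimizer grids must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("levels", "mlr_months", "pstart_grid", "tb_grid", "exponents"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = [float(v) if isinstance(v, (np.floating, float)) else v for v in value]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _doy_limit(year: int) -> int:
    return 366 if pd.Timestamp(year=int(year), month=12, day=31).dayofyear == 366 else 365


def _validate_phenology(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in PHENOLOGY_COLUMNS if c not in df.columns and c != "tree_id"]
    if missing:
        raise TableFormatError(f"{source}: missing required columns {missing}")
    if "tree_id" not in df.columns:
        df = df.assign(tree_id="t1")
    df = df[PHENOLOGY_COLUMNS].copy()
    for col in ("year", "doy"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based

            raise TableFormatError(f"{source}, line {line}: non-integer {col!r}")
        df[col] = vals.astype(int)
    for col in ("pct_colored", "pct_fallen"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2
            raise TableFormatError(f"{source}, line {line}: non-numeric {col!r}")
        out = (vals < 0) | (vals > 100)
        if out.any():
            line = int(df.index[out][0]) + 2
            raise TableFormatError(f"{source}, line {line}: {col} outside [0, 100]")
        df[col] = vals.astype(float)
    limits = df["year"].map(_doy_limit)
    bad = (df["doy"] < 1) | (df["doy"] > limits)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise TableFormatError(f"{source}, line {line}: doy outside the calendar year")
    dup = df.duplicated(subset=["species", "tree_id", "year", "doy"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise TableFormatError(f"{source}, line {line}: duplicate (tree, date) record")
    return df.sort_values(["species", "tree_id", "year", "doy"]).reset_index(drop=True)


def read_phenology(path: str | Path) -> pd.DataFrame:
    """Read and validate per-tree phenology observations.

    Returns a DataFrame with columns ``species, tree_id, year, doy,
    pct_colored, pct_fallen`` sorted by tree and date.  Percentages outside
    [0, 100], duplicate (tree, date) pairs, and malformed rows raise
    :class:`TableFormatError` naming the offending line.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableFormatError(f"{path}: unreadable CSV ({exc})") from exc
    return _validate_phenology(df, str(path))


def write_phenology(df: pd.DataFrame, path: str | Path) -> None:
    df[PHENOLOGY_COLUMNS].to_csv(path, index=False)


def species_series(observations: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-tree records to species-level percent trajectories.

    The species value for a visit date is the unweighted mean over the trees
    observed on that date (typically the 3-5 tagged individuals).
    """
    grouped = (
        observations.groupby(["species", "year", "doy"], as_index=False)[
            ["pct_colored", "pct_fallen"]
        ].mean()
    )
    return grouped.sort_values(["species", "year", "doy"]).reset_index(drop=True)


def read_weather(path: str | Path) -> pd.DataFrame:
    """Read a daily weather series and make calendar gaps explicit.

    Returns a DataFrame with columns ``year, doy, tmean_c, precip_mm`` on a
    contiguous calendar index covering every day from the first to the last
    observed year; days absent from the file carry ``NaN``.  Duplicate dates
    and non-numeric temperatures are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    df = df[WEATHER_COLUMNS].copy()
    for col in ("year", "doy"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals != vals.round()).any():
            raise TableFormatError(f"{path}: non-integer {col!r}")
        df[col] = vals.astype(int)
    for col in ("tmean_c", "precip_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and df[col].notna().any() and vals.isna().ne(df[col].isna()).any():
            raise TableFormatError(f"{path}: non-numeric {col!r}")
        df[col] = vals.astype(float)
    if df.duplicated(subset=["year", "doy"]).any():
        raise TableFormatError(f"{path}: duplicate (year, doy) record")
    limits = df["year"].map(_doy_limit)
    if ((df["doy"] < 1) | (df["doy"] > limits)).any():
        raise TableFormatError(f"{path}: doy outside the calendar year")
    return reindex_calendar(df)


def reindex_calendar(df: pd.DataFrame) -> pd.DataFrame:
    """Re-index a weather table onto a contiguous (year, doy) calendar."""
    frames = []
    for year in range(int(df["year"].min()), int(df["year"].max()) + 1):
        frames.append(pd.DataFrame({"year": year, "doy": np.arange(1, _doy_limit(year) + 1)}))
    calendar = pd.concat(frames, ignore_index=True)
    out = calendar.merge(df, on=["year", "doy"], how="left")
    return out[WEATHER_COLUMNS]


def write_weather(df: pd.DataFrame, path: str | Path) -> None:
    df[WEATHER_COLUMNS].to_csv(path, index=False)


def weather_gaps(weather: pd.DataFrame) -> pd.DataFrame:
    """Rows of the contiguous calendar whose temperature is missing."""
    return weather[weather["tmean_c"].isna()][["year", "doy"]].reset_index(drop=True)
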