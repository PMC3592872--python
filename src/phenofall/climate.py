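"""Climate predictors: trailing-window means, monthly means and daylength.

Window means average daily temperature or precipitation over 1-52 week
trailing windows (``weeks x 7`` calendar days, ending at and including the
end day, reaching into the previous calendar year when needed).  Monthly
means over the May-October leaf-on period supply the candidate predictors of
the empirical regression model.  Daylength comes from a standard
solar-declination formula (the Forsythe et al. CBM model) and drives the
photoperiod term of the process model.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

MONTH_ABBR = {5: "may", 6: "jun", 7: "jul", 8: "aug", 9: "sep", 10: "oct",
              1: "jan", 2: "feb", 3: "mar", 4: "apr", 11: "nov", 12: "dec"}

#: sun-centre horizon crossing vs. upper-limb with standard refraction
DAYLENGTH_COEF = {"center": 0.0, "refraction": 0.8333}


def daylength(latitude_deg: float, doy, refraction: bool = False) -> np.ndarray | float:
    """Hours of daylight P(doy) at a latitude, CBM solar-declination model.

    Smooth and annual-periodic; by default daylength is the interval during
    which the sun's centre is above the horizon (no refraction correction).

    Raises ``ValueError`` for polar latitudes (|lat| >= 66.5) where day or
    night can span full days.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("polar latitudes are not supported")
    doy_arr = np.asarray(doy, dtype=float)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy_arr - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    p = DAYLENGTH_COEF["refraction" if refraction else "center"]
    lat = np.deg2rad(latitude_deg)
    cos_ha = (np.sin(np.deg2rad(p)) + np.sin(lat) * np.sin(phi)) / (np.cos(lat) * np.cos(phi))
    hours = 24.0 - (24.0 / np.pi) * np.arccos(np.clip(cos_ha, -1.0, 1.0))
    return float(hours) if np.isscalar(doy) else hours


def _calendar_positions(weather: pd.DataFrame) -> dict[tuple[int, int], int]:
    return {(int(y), int(d)): i for i, (y, d) in enumerate(zip(weather["year"], weather["doy"]))}


def window_mean(
    weather: pd.DataFrame,
    year: int,
    end_doy: int,
    weeks: int,
    variable: str = "tmean_c",
    min_fraction: float = 0.9,
) -> float:
    """Mean of a daily variable over the ``weeks``-week window ending at
    ``(year, end_doy)`` inclusive.

    The window spans ``weeks * 7`` consecutive calendar days and may reach
    into the previous calendar year.  Returns NaN when fewer than
    ``min_fraction`` of the window's days are available (missing days inside
    the window are tolerated by pairwise deletion up to that tolerance).
    """
    if not 1 <= weeks <= 52:
        raise ValueError("weeks must be in 1..52")
    positions = _calendar_positions(weather)
    key = (int(year), int(end_doy))
    if key not in positions:
        return float("nan")
    end = positions[key]
    start = end - weeks * 7 + 1
    if start < 0:
        return float("nan")
    values = weather[variable].to_numpy(dtype=float)[start : end + 1]
    ok = np.isfinite(values)
    if ok.sum() < min_fraction * values.size:
        return float("nan")
    return float(values[ok].mean())


def window_mean_grid(
    weather: pd.DataFrame,
    years: Iterable[int],
    variable: str = "tmean_c",
    min_fraction: float = 0.9,
) -> np.ndarray:
    """All trailing-window means at once: array ``[n_years, 365, 52]``.

    Cell ``[i, d-1, w-1]`` is the mean over the ``w``-week window ending at
    day ``d`` of ``years[i]``; day 366 of leap years participates inside
    windows but is folded out of the end-day axis.  Cells whose window is
    incomplete beyond tolerance (or precedes the series) are NaN.
    """
    years = [int(y) for y in years]
    values = weather[variable].to_numpy(dtype=float)
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccount = np.concatenate([[0], np.cumsum(finite)])
    positions = _calendar_positions(weather)

    grid = np.full((len(years), 365, 52), np.nan)
    wlen = (np.arange(1, 53) * 7)[None, :]  # [1, 52]
    for i, year in enumerate(years):
        ends = np.array([positions.get((year, d), -1) for d in range(1, 366)])
        starts = ends[:, None] - wlen + 1  # [365, 52]
        valid = (ends[:, None] >= 0) & (starts >= 0)
        s = np.where(valid, starts, 0)
        e = np.where(valid, ends[:, None] + 1, 0)
        counts = ccount[e] - ccount[s]
        sums = csum[e] - csum[s]
        enough = valid & (counts >= min_fraction * wlen)
        with np.errstate(invalid="ignore", divide="ignore"):
            grid[i] = np.where(enough, sums / np.maximum(counts, 1), np.nan)
    return grid


def monthly_means(
    weather: pd.DataFrame,
    year: int,
    months: Iterable[int] = (5, 6, 7, 8, 9, 10),
    min_fraction: float = 0.9,
) -> dict[str, float]:
    """Monthly mean temperature and precipitation for one year.

    Returns ``{"t_may": ..., "p_may": ..., ...}`` with one temperature and
    one precipitation entry per requested month (daily means, deg C and
    mm/day).  A month with too many missing days yields NaN, which drops the
    year from any regression using that predictor.
    """
    sub = weather[weather["year"] == int(year)]
    if sub.empty:
        return {f"{v}_{MONTH_ABBR[m]}": float("nan") for m in months for v in ("t", "p")}
    dates = pd.to_datetime(sub["year"].astype(str)) + pd.to_timedelta(sub["doy"] - 1, unit="D")
    month_of = dates.dt.month.to_numpy()
    out: dict[str, float] = {}
    for m in months:
        mask = month_of == m
        for prefix, col in (("t", "tmean_c"), ("p", "precip_mm")):
            vals = sub.loc[mask, col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            good = vals.size > 0 and ok.sum() >= min_fraction * vals.size
            out[f"{prefix}_{MONTH_ABBR[m]}"] = float(vals[ok].mean()) if good else float("nan")
    return out


def predictor_table(
    weather: pd.DataFrame,
    years: Iterable[int],
    months: Iterable[int] = (5, 6, 7, 8, 9, 10),
    min_fraction: float = 0.9,
) -> pd.DataFrame:
    """Long table of monthly-mean predictors: one row per year.

    Columns are ``year`` followed by ``t_<mon>`` and ``p_<mon>`` for each
    requested month (12 candidates for the default May-October set).
    """
    rows = []
    for year in years:
        row = {"year": int(year)}
        row.update(monthly_means(weather, year, months, min_fraction))
        rows.append(row)
    return pd.DataFrame(rows)
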