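"""Stage dates and color-abundance metrics from percent trajectories.

A species-year trajectory is a sequence of field visits carrying the percent
of leaves colored (r_n) and fallen (j_n).  Assuming percents change linearly
between visits, the stage date c_x (or f_x) is the day of year on which the
trajectory first reaches x percent, found by linear interpolation between
the bracketing visits.  Two abundance measures derive from the trajectory:

* duration d_x = f_90 - c_x, the days between x% coloration and 90% fall;
* amount of color A, the time-integral of the per-visit color intensity
  y_n = r_n * (1 - j_n / 100): the area under the piecewise-linear y curve,
  calibrated so that 100 units of A equal one calendar day with every leaf
  red and retained.

Thresholds reached before the first visit are treated as missing rather than
extrapolated backwards; for non-monotone series (observer corrections) the
first upward crossing is used.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tables import DEFAULT_LEVELS

MISSING_BEFORE_FIRST_VISIT = "reached_before_first_visit"
MISSING_NEVER_REACHED = "never_reached"
MISSING_TOO_FEW_VISITS = "fewer_than_two_visits"


@dataclasses.dataclass
class ThresholdDate:
    """Interpolated day of year at which a percent level is first reached."""

    species: str
    year: int
    kind: str  # "color" | "fall"
    level: int
    doy: float | None
    missing_reason: str | None = None


def interpolate_threshold(doys: Sequence[float], percents: Sequence[float], x: float):
    """Fractional day of year of the first upward crossing of ``x`` percent.

    Returns ``(doy, None)`` on success or ``(None, reason)`` when the level
    cannot be located: the first visit already at or above ``x`` (no backward
    extrapolation), the level never reached, or fewer than two visits.
    """
    doys = np.asarray(doys, dtype=float)
    percents = np.asarray(percents, dtype=float)
    if doys.size < 2:
        return None, MISSING_TOO_FEW_VISITS
    if percents[0] >= x:
        return None, MISSING_BEFORE_FIRST_VISIT
    for n in range(1, doys.size):
        if percents[n] >= x:
            lo, hi = percents[n - 1], percents[n]
            if hi == lo:  # flat segment ending exactly at x
                return float(doys[n]), None
            frac = (x - lo) / (hi - lo)
            return float(doys[n - 1] + frac * (doys[n] - doys[n - 1])), None
    return None, MISSING_NEVER_REACHED


def duration(c_x: float | None, f_90: float | None):
    """Color duration d_x = f_90 - c_x in days.

    Returns ``(days, anomaly_flag)``; the flag marks the (physically odd)
    case of 90% fall preceding the coloration stage.  Missing inputs yield
    ``(None, False)``.
    """
    if c_x is None or f_90 is None or not (np.isfinite(c_x) and np.isfinite(f_90)):
        return None, False
    d = float(f_90) - float(c_x)
    return d, d < 0


def color_intensity(pct_colored, pct_fallen) -> np.ndarray:
    """Daily amount of color y_n = r_n * (1 - j_n/100), on a 0-100 scale."""
    r = np.asarray(pct_colored, dtype=float)
    j = np.asarray(pct_fallen, dtype=float)
    return r * (1.0 - j / 100.0)


def amount_of_color(doys, pct_colored, pct_fallen) -> float:
    """Yearly amount of color A: area under the piecewise-linear y curve.

    ``y_n = pct_colored * (1 - pct_fallen/100)`` per visit; A is the
    trapezoidal area across the observed visit span (no extrapolation
    beyond the first or last visit).  100 units of A correspond to one
    calendar day in which all leaves are retained and red.  A single visit
    spans no time and contributes A = 0 (with a warning).
    """
    doys = np.asarray(doys, dtype=float)
    y = color_intensity(pct_colored, pct_fallen)
    if doys.size < 2:
        warnings.warn("amount_of_color: fewer than two visits, A = 0", stacklevel=2)
        return 0.0
    return float(np.trapezoid(y, doys))


def threshold_table(
    series: pd.DataFrame, levels: Iterable[int] = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Interpolate every stage date for species-level trajectories.

    ``series`` is a species-level table (``species, year, doy, pct_colored,
    pct_fallen``); the result is long format with one row per
    (species, year, kind, level): columns ``species, year, kind, level, doy,
    missing_reason``.
    """
    rows = []
    for (species, year), group in series.groupby(["species", "year"]):
        group = group.sort_values("doy")
        doys = group["doy"].to_numpy(dtype=float)
        for kind, col in (("color", "pct_colored"), ("fall", "pct_fallen")):
            pct = group[col].to_numpy(dtype=float)
            for level in levels:
                doy, reason = interpolate_threshold(doys, pct, level)
                rows.append(
                    {
                        "species": species,
                        "year": int(year),
                        "kind": kind,
                        "level": int(level),
                        "doy": doy if doy is not None else np.nan,
                        "missing_reason": reason,
                    }
                )
    return pd.DataFrame(rows)


def metrics_table(
    series: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
    levels: Iterable[int] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Per species-year abundance metrics: d_10..d_90 and A.

    ``d_x = f_90 - c_x`` uses the interpolated stage dates; ``A`` integrates
    the observed trajectory directly.  Missing stage dates propagate to NaN
    durations.
    """
    if thresholds is None:
        thresholds = threshold_table(series, levels)
    wide = thresholds.pivot_table(
        index=["species", "year"], columns=["kind", "level"], values="doy", dropna=False
    )
    rows = []
    for (species, year), group in series.groupby(["species", "year"]):
        group = group.sort_values("doy")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a_value = amount_of_color(
                group["doy"], group["pct_colored"], group["pct_fallen"]
            )
        row = {"species": species, "year": int(year), "A": a_value}
        f90 = wide.loc[(species, year)].get(("fall", 90), np.nan) if (species, year) in wide.index else np.nan
        for level in levels:
            cx = wide.loc[(species, year)].get(("color", level), np.nan) if (species, year) in wide.index else np.nan
            d, _ = duration(
                None if pd.isna(cx) else float(cx),
                None if pd.isna(f90) else float(f90),
            )
            row[f"d_{level}"] = np.nan if d is None else d
        rows.append(row)
    cols = ["species", "year"] + [f"d_{lv}" for lv in levels] + ["A"]
    return pd.DataFrame(rows)[cols]
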