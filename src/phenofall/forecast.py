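"""Scenario projection, trend estimation and internal-consistency checks.

Fitted models (empirical regression suites or calibrated CDD/P suites) are
run forward over daily scenario weather, typically 2010-2099.  Rates of
change are the OLS slopes of each projected quantity against calendar year,
with t-based 95% confidence intervals (slope uncertainty only -- no account
of parameter or structural uncertainty).  Because the two model families
project each stage independently, a projection can become internally
inconsistent ("crossing-over": a later threshold predicted before an
earlier one, or 90% coloration after 90% fall); those violations are
detected and reported per year rather than silently absorbed.

Durations d_x and the amount of color A are not projected directly: they
are recomputed from the projected stage dates by reconstructing piecewise
linear percent trajectories through the five levels (extrapolating the
first segment back to 0% and the last segment on to 100%) and applying the
same metric definitions used on observations.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cddp as cddp_mod
from . import climate, metrics, mlr


@dataclasses.dataclass
class TrendEstimate:
    """Days-per-year (or A-units-per-year) rate of change over projection years."""

    quantity: str
    slope: float
    ci_low: float
    ci_high: float
    n_years: int
    scenario: str = ""
    species: str = ""


@dataclasses.dataclass
class ConsistencyReport:
    """Crossing-over violations found in a projected stage table."""

    violations: pd.DataFrame  # year, kind, description
    n_order_violations: int
    n_color_after_fall: int
    first_year: int | None

    @property
    def clean(self) -> bool:
        return self.violations.empty


def project_cddp(
    fit: "cddp_mod.CDDPFit | cddp_mod.CDDPParams",
    weather: pd.DataFrame,
    latitude: float,
    refraction: bool = False,
) -> pd.DataFrame:
    """Predicted stage dates per year for a fitted CDD/P suite."""
    params = fit.params if isinstance(fit, cddp_mod.CDDPFit) else fit
    years = sorted(int(v) for v in weather["year"].unique())
    out = cddp_mod.predict_stage_dates(params, weather, years, latitude, refraction)
    return out


def project_mlr(
    suite: Mapping[int, mlr.MLRModel],
    weather: pd.DataFrame,
    months: Sequence[int] = (5, 6, 7, 8, 9, 10),
) -> pd.DataFrame:
    """Predicted stage dates per year for a per-level regression suite."""
    years = sorted(int(v) for v in weather["year"].unique())
    predictors = climate.predictor_table(weather, years, months).set_index("year")
    rows = []
    for year in years:
        row = predictors.loc[year]
        for level, model in suite.items():
            rows.append(
                {"year": year, "level": int(level), "doy": mlr.predict_mlr(model, row)}
            )
    return pd.DataFrame(rows)


def reconstruct_curve(stage_dates: Mapping[int, float]):
    """Piecewise-linear percent trajectory through projected stage dates.

    Levels map to (doy, percent) knots; the first segment is extrapolated
    backwards to 0% and the last forwards to 100%, giving a complete 0-100
    trajectory.  Non-monotone date sequences (crossing-over) are repaired by
    a running maximum before reconstruction; callers should consult
    :func:`check_consistency` to know when that happened.

    Returns ``(doys, percents)`` arrays of knots.
    """
    levels = np.array(sorted(stage_dates), dtype=float)
    doys = np.array([stage_dates[int(lv)] for lv in levels], dtype=float)
    ok = np.isfinite(doys)
    levels, doys = levels[ok], doys[ok]
    if levels.size == 0:
        return np.array([]), np.array([])
    doys = np.maximum.accumulate(doys)
    if levels.size == 1:
        return np.array([doys[0] - 1.0, doys[0]]), np.array([0.0, levels[0]])
    knots_d = [float(d) for d in doys]
    knots_p = [float(p) for p in levels]
    # extend first segment back to 0%
    slope0 = (knots_p[1] - knots_p[0]) / max(knots_d[1] - knots_d[0], 1e-9)
    knots_d.insert(0, knots_d[0] - knots_p[0] / max(slope0, 1e-9))
    knots_p.insert(0, 0.0)
    # extend last segment on to 100%
    slope1 = (knots_p[-1] - knots_p[-2]) / max(knots_d[-1] - knots_d[-2], 1e-9)
    knots_d.append(knots_d[-1] + (100.0 - knots_p[-1]) / max(slope1, 1e-9))
    knots_p.append(100.0)
    return np.array(knots_d), np.array(knots_p)


def projected_metrics(
    color_dates: Mapping[int, float], fall_dates: Mapping[int, float]
) -> dict[str, float]:
    """Recompute d_x and A from projected stage dates of one year.

    The color and fall trajectories are reconstructed through the projected
    levels and sampled daily; A is the trapezoidal area under
    ``colored * (1 - fallen/100)`` -- identical in definition to the metric
    computed from field observations.
    """
    out: dict[str, float] = {}
    f90 = fall_dates.get(90, np.nan)
    for level, c in color_dates.items():
        d, _ = metrics.duration(
            None if not np.isfinite(c) else c, None if not np.isfinite(f90) else f90
        )
        out[f"d_{level}"] = np.nan if d is None else d
    cd, cp = reconstruct_curve(color_dates)
    fd, fp = reconstruct_curve(fall_dates)
    if cd.size == 0 or fd.size == 0:
        out["A"] = float("nan")
        return out
    lo = np.floor(min(cd[0], fd[0]))
    hi = np.ceil(max(cd[-1], fd[-1]))
    grid = np.arange(lo, hi + 1.0)
    colored = np.interp(grid, cd, cp, left=0.0, right=100.0)
    fallen = np.interp(grid, fd, fp, left=0.0, right=100.0)
    y = colored * (1.0 - fallen / 100.0)
    out["A"] = float(np.trapezoid(y, grid))
    return out


def projection_table(
    color_proj: pd.DataFrame, fall_proj: pd.DataFrame, species: str = ""
) -> pd.DataFrame:
    """Combine per-kind stage projections and derive d_x and A per year.

    Inputs are long tables (``year, level, doy``), one for coloration and
    one for fall.  Output is wide per year: ``c_10..c_90, f_10..f_90,
    d_10..d_90, A``.
    """
    rows = []
    years = sorted(set(color_proj["year"]).union(fall_proj["year"]))
    for year in years:
        c = {
            int(r.level): float(r.doy)
            for r in color_proj[color_proj["year"] == year].itertuples()
        }
        f = {
            int(r.level): float(r.doy)
            for r in fall_proj[fall_proj["year"] == year].itertuples()
        }
        row: dict[str, float] = {"year": year}
        for lv, v in c.items():
            row[f"c_{lv}"] = v
        for lv, v in f.items():
            row[f"f_{lv}"] = v
        row.update(projected_metrics(c, f))
        if species:
            row["species"] = species
        rows.append(row)
    return pd.DataFrame(rows)


def trend(values_by_year: pd.Series, quantity: str = "", scenario: str = "",
          species: str = "", alpha: float = 0.05) -> TrendEstimate:
    """OLS slope of a projected quantity on calendar year, with 95% CI.

    Requires at least 10 non-missing years.  The CI is the t-based interval
    from the slope's standard error; exactly linear input yields a
    zero-width interval.
    """
    s = values_by_year.dropna()
    if len(s) < 10:
        raise ValueError("need at least 10 non-missing years for a trend")
    years = s.index.to_numpy(dtype=float)
    vals = s.to_numpy(dtype=float)
    fit = stats.linregress(years, vals)
    tcrit = stats.t.ppf(1 - alpha / 2, len(s) - 2)
    half = tcrit * fit.stderr
    return TrendEstimate(
        quantity=quantity,
        slope=float(fit.slope),
        ci_low=float(fit.slope - half),
        ci_high=float(fit.slope + half),
        n_years=int(len(s)),
        scenario=scenario,
        species=species,
    )


def check_consistency(stage_table: pd.DataFrame) -> ConsistencyReport:
    """Detect crossing-over in a projected stage table.

    ``stage_table`` is long format (``year, kind, level, doy``).  Two kinds
    of violation are flagged per year: a later threshold level predicted
    strictly before an earlier one within a kind (e.g. f_50 before f_25),
    and 90% coloration predicted strictly after 90% fall.
    """
    rows = []
    n_order = n_caf = 0
    for year, group in stage_table.groupby("year"):
        for kind, sub in group.groupby("kind"):
            sub = sub.dropna(subset=["doy"]).sort_values("level")
            doys = sub["doy"].to_numpy(dtype=float)
            levels = sub["level"].to_numpy()
            for i in range(1, len(doys)):
                if doys[i] < doys[i - 1]:
                    n_order += 1
                    prefix = "c" if kind == "color" else "f"
                    rows.append(
                        {
                            "year": int(year),
                            "kind": kind,
                            "description": f"{prefix}_{levels[i]} before {prefix}_{levels[i-1]}",
                        }
                    )
        c90 = group[(group["kind"] == "color") & (group["level"] == 90)]["doy"]
        f90 = group[(group["kind"] == "fall") & (group["level"] == 90)]["doy"]
        if len(c90) and len(f90) and np.isfinite(c90.iloc[0]) and np.isfinite(f90.iloc[0]):
            if c90.iloc[0] > f90.iloc[0]:
                n_caf += 1
                rows.append(
                    {"year": int(year), "kind": "cross-kind", "description": "c_90 after f_90"}
                )
    violations = pd.DataFrame(rows, columns=["year", "kind", "description"])
    first_year = int(violations["year"].min()) if len(violations) else None
    return ConsistencyReport(
        violations=violations,
        n_order_violations=n_order,
        n_color_after_fall=n_caf,
        first_year=first_year,
    )
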