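"""Process-oriented senescence model: cold-degree-days x photoperiod (CDD/P).

Senescence state S_sen accumulates daily once the photoperiod P(doy) drops
to a critical value P_start (defining the start day D_start, taken on the
autumn side of the solstice).  The daily increment is

    R_sen(doy) = max(0, T_b - T(doy))^x * f[P(doy)]^y,      doy > D_start

with T_b the maximum temperature at which senescence is effective, x and y
dummy exponents in {0, 1, 2}, and f a photoperiod function in one of two
variants: f1 = P / P_start (shrinking with daylength) or f2 = 1 - P / P_start
(growing as days shorten).  A stage (a threshold level of coloration or
fall) is predicted on the first day S_sen reaches its own threshold Y_crit;
one model structure carries five Y_crit values, one per observed stage, so a
fitted suite has 9 parameters (P_start, T_b, x, y + five Y_crit).

With x = 0 temperature drops out entirely and the model collapses to the
photoperiod-only null: stage dates repeat identically every year.

Calibration explores the full discrete grid over P_start (10-16 h, 0.5-h
step), T_b (7-30 degC, 0.5-deg step), x, y and the two photoperiod variants;
at each node the five Y_crit are located by a deterministic 1-D search over
the accumulation curve against the pooled root-mean-square error of all
stages, with a dense refinement at the winning node.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import climate

#: first accumulation day: the day after the summer solstice
SOLSTICE_DOY = 172
ACC_DOYS = np.arange(SOLSTICE_DOY + 1, 366)  # 173..365
_MISS_DOY = 366.0  # penalty date for thresholds never reached in a year


@dataclasses.dataclass
class CDDPParams:
    """The five-parameter process model (Y_crit carried per stage level)."""

    p_start: float  # hours
    t_b: float  # deg C
    x: int  # temperature exponent
    y: int  # photoperiod exponent
    variant: int  # photoperiod function: 1 -> P/P_start, 2 -> 1 - P/P_start
    y_crit: dict[int, float]  # level (percent) -> accumulation threshold

    def __post_init__(self) -> None:
        if self.x not in (0, 1, 2) or self.y not in (0, 1, 2):
            raise ValueError("exponents x, y must be in {0, 1, 2}")
        if self.variant not in (1, 2):
            raise ValueError("photoperiod variant must be 1 or 2")

    @property
    def n_parameters(self) -> int:
        """Fitted parameter count: P_start, T_b, x, y plus one Y_crit per stage."""
        return 4 + len(self.y_crit)

    def to_dict(self) -> dict:
        return {
            "p_start": self.p_start,
            "t_b": self.t_b,
            "x": self.x,
            "y": self.y,
            "variant": self.variant,
            "y_crit": {int(k): float(v) for k, v in self.y_crit.items()},
        }


@dataclasses.dataclass
class SenescenceTrajectory:
    """One year's accumulated senescence state and predicted stage dates."""

    year: int
    doys: np.ndarray  # accumulation day axis (173..365)
    s_sen: np.ndarray  # accumulated state, same length
    d_start: int
    predicted: dict[int, float | None]  # level -> doy (None if never reached)


def photoperiod_factor(p_hours, p_start: float, variant: int):
    """Dimensionless photoperiod function f[P(doy)].

    Variant 1 is ``P / P_start`` (in (0, 1] once P <= P_start); variant 2 is
    ``1 - P / P_start`` (in [0, 1)).  Values are clamped at zero.
    """
    p = np.asarray(p_hours, dtype=float)
    if variant == 1:
        f = p / p_start
    elif variant == 2:
        f = 1.0 - p / p_start
    else:
        raise ValueError("photoperiod variant must be 1 or 2")
    f = np.maximum(f, 0.0)
    return float(f) if np.isscalar(p_hours) else f


def daily_rate(t_c, p_hours, params: CDDPParams):
    """Daily senescence increment R_sen for the days following D_start.

    ``max(0, T_b - T)^x * f(P)^y``; with x = 0 the temperature term is 1 and
    accumulation is purely photoperiod-driven.
    """
    t = np.asarray(t_c, dtype=float)
    cold = np.maximum(params.t_b - t, 0.0)
    temp_term = np.ones_like(cold) if params.x == 0 else cold**params.x
    photo = photoperiod_factor(p_hours, params.p_start, params.variant)
    photo_term = np.ones_like(temp_term) if params.y == 0 else np.asarray(photo) ** params.y
    rate = temp_term * photo_term
    return float(rate) if np.isscalar(t_c) else rate


def d_start_index(p_curve: np.ndarray, p_start: float) -> int:
    """Index into ACC_DOYS of the first post-solstice day with P <= P_start."""
    hit = np.nonzero(p_curve <= p_start)[0]
    if hit.size == 0:
        return len(p_curve)  # photoperiod threshold never reached
    return int(hit[0])


def _year_temperatures(weather: pd.DataFrame, years: Sequence[int]) -> np.ndarray:
    """Temperature matrix [n_years, len(ACC_DOYS)]; gaps are an error.

    Accumulation is path-dependent, so any missing day in the accumulation
    window invalidates the whole year.
    """
    t = np.full((len(years), ACC_DOYS.size), np.nan)
    lookup = weather.set_index(["year", "doy"])["tmean_c"]
    for i, year in enumerate(years):
        try:
            vals = lookup.loc[int(year)].reindex(ACC_DOYS).to_numpy(dtype=float)
        except KeyError:
            raise ValueError(f"no weather for year {year}")
        if not np.isfinite(vals).all():
            raise ValueError(f"weather gap in the accumulation window of year {year}")
        t[i] = vals
    return t


def temperature_matrix(weather: pd.DataFrame, years: Sequence[int]):
    """Precompute the accumulation-window temperature matrix for reuse.

    Returns ``(years, matrix)`` suitable for the ``temperatures`` argument
    of :func:`fit_cddp`, so repeated fits on subsets of the same record
    (e.g. cross-validation folds) skip the per-fit weather extraction.
    """
    years = [int(y) for y in years]
    return years, _year_temperatures(weather, years)


def simulate_year(
    weather_year: pd.DataFrame,
    params: CDDPParams,
    latitude: float,
    refraction: bool = False,
) -> SenescenceTrajectory:
    """Forward-run the model for one calendar year of daily weather.

    Returns the accumulated state S_sen on the post-solstice day axis and
    the first day each Y_crit level is reached (None, with a warning, for
    levels the accumulation never attains).
    """
    year = int(weather_year["year"].iloc[0])
    t = _year_temperatures(weather_year, [year])[0]
    p = climate.daylength(latitude, ACC_DOYS, refraction=refraction)
    ds = d_start_index(p, params.p_start)
    rate = np.zeros_like(t)
    if ds + 1 < ACC_DOYS.size:  # accumulation starts the day after D_start
        rate[ds + 1 :] = daily_rate(t[ds + 1 :], p[ds + 1 :], params)
    s_sen = np.cumsum(rate)
    predicted: dict[int, float | None] = {}
    for level, y_crit in params.y_crit.items():
        idx = int(np.searchsorted(s_sen, y_crit, side="left"))
        if idx >= s_sen.size or s_sen[-1] < y_crit:
            warnings.warn(
                f"year {year}: level {level} never reached (Y_crit={y_crit:g})",
                stacklevel=2,
            )
            predicted[level] = None
        else:
            predicted[level] = float(ACC_DOYS[idx])
    d_start_doy = int(ACC_DOYS[ds]) if ds < ACC_DOYS.size else int(ACC_DOYS[-1]) + 1
    return SenescenceTrajectory(
        year=year, doys=ACC_DOYS.copy(), s_sen=s_sen, d_start=d_start_doy, predicted=predicted
    )


@dataclasses.dataclass
class CDDPFit:
    """A calibrated CDD/P suite with its in-sample diagnostics."""

    species: str
    kind: str
    params: CDDPParams
    rmse: float
    n: int
    predictions: pd.DataFrame  # year, level, observed, predicted
    y_crit_adjusted: bool = False

    @property
    def K(self) -> int:
        return self.params.n_parameters


def _level_search(
    s_block: np.ndarray,
    obs_rows: np.ndarray,
    obs_vals: np.ndarray,
    candidates: np.ndarray,
):
    """SSE over a candidate Y_crit set for one level.

    ``s_block[i]`` is a non-decreasing accumulation curve; predictions use
    the first-crossing (integer-day) rule, with unreached thresholds
    penalised at the day after year end.  Returns (best Y, best SSE).

    The per-year first-crossing searches collapse into a single
    ``searchsorted`` by shifting each year's (non-decreasing) curve into a
    disjoint value range.
    """
    if candidates.size == 0:
        resid = _MISS_DOY - obs_vals
        return np.nan, float(np.sum(resid**2))
    curves = s_block[obs_rows]  # [R, D]
    n_rows, n_days = curves.shape
    big = float(curves.max()) + 1.0
    offsets = np.arange(n_rows) * big
    flat = (curves + offsets[:, None]).ravel()
    queries = (candidates[None, :] + offsets[:, None]).ravel()
    idx = np.searchsorted(flat, queries, side="left").reshape(n_rows, candidates.size)
    col = idx - np.arange(n_rows)[:, None] * n_days
    reached = (col >= 0) & (col < n_days)
    pred = np.where(reached, ACC_DOYS[np.clip(col, 0, n_days - 1)], _MISS_DOY)
    sse = ((pred - obs_vals[:, None]) ** 2).sum(axis=0)
    best = int(np.argmin(sse))
    return float(candidates[best]), float(sse[best])


def _predict_from_curves(s_block, rows, y_crit):
    idx = np.array([np.searchsorted(s_block[r], y_crit, side="left") for r in rows])
    return np.where(idx < s_block.shape[1], ACC_DOYS[np.minimum(idx, s_block.shape[1] - 1)], _MISS_DOY)


def fit_cddp(
    stage_dates: pd.DataFrame,
    weather: pd.DataFrame,
    latitude: float,
    species: str = "",
    kind: str = "",
    pstart_grid: Iterable[float] = tuple(np.arange(10.0, 16.0 + 1e-9, 0.5)),
    tb_grid: Iterable[float] = tuple(np.arange(7.0, 30.0 + 1e-9, 0.5)),
    exponents: Iterable[int] = (0, 1, 2),
    variants: Iterable[int] = (1, 2),
    refraction: bool = False,
    refine: bool = True,
    temperatures: tuple[Sequence[int], np.ndarray] | None = None,
) -> CDDPFit:
    """Calibrate the CDD/P suite for one species and stage kind.

    ``stage_dates`` is a long table (``year, level, doy``) of observed stage
    dates; NaN rows are dropped (missing stages simply do not constrain the
    fit).  The discrete grid over (P_start, T_b, x, y, variant) is searched
    exhaustively; per node each level's Y_crit is located by a deterministic
    1-D search over candidate accumulation values, minimising the RMSE
    pooled over all stage observations with equal weight.  Ties between
    nodes break toward the smallest (P_start, T_b, x, y, variant) in fixed
    iteration order.  Y_crit is forced non-decreasing in level afterwards
    (isotonic adjustment, logged) when violated.
    """
    obs = stage_dates.dropna(subset=["doy"]).copy()
    if obs.empty:
        raise ValueError("no stage observations to fit on")
    levels = sorted(int(v) for v in obs["level"].unique())
    years = sorted(int(v) for v in obs["year"].unique())
    year_row = {y: i for i, y in enumerate(years)}
    if temperatures is not None:
        # precomputed (years, matrix) pair, e.g. shared across LOOCV folds
        all_years, all_mat = temperatures
        pos = {int(y): i for i, y in enumerate(all_years)}
        t_mat = all_mat[[pos[y] for y in years]]
    else:
        t_mat = _year_temperatures(weather, years)  # [Y, D]
    p_curve = climate.daylength(latitude, ACC_DOYS, refraction=refraction)

    # per-level observation bookkeeping
    level_obs = {}
    for level in levels:
        sub = obs[obs["level"] == level]
        rows = np.array([year_row[int(y)] for y in sub["year"]])
        vals = sub["doy"].to_numpy(dtype=float)
        cols = np.clip(np.round(vals).astype(int) - ACC_DOYS[0], 0, ACC_DOYS.size - 1)
        level_obs[level] = (rows, vals, cols)
    n_obs = sum(v[1].size for v in level_obs.values())

    pstart_grid = [float(v) for v in pstart_grid]
    tb_grid = [float(v) for v in tb_grid]
    exponents = [int(v) for v in exponents]
    variants = [int(v) for v in variants]

    day_idx = np.arange(ACC_DOYS.size)
    best_rmse = np.inf
    best_node = None
    best_ycrit: dict[int, float] = {}
    best_sblock = None
    for p_start in pstart_grid:
        ds = d_start_index(p_curve, p_start)
        mask = (day_idx > ds).astype(float)  # accumulation follows D_start
        for t_b in tb_grid:
            cold = np.maximum(t_b - t_mat, 0.0)  # [Y, D]
            for x in exponents:
                temp_term = np.ones_like(cold) if x == 0 else cold**x
                for y in exponents:
                    for variant in variants:
                        if y == 0:
                            photo_term = 1.0
                        else:
                            photo_term = photoperiod_factor(p_curve, p_start, variant) ** y
                        s_block = np.cumsum(temp_term * photo_term * mask, axis=1)
                        sse_total = 0.0
                        y_crit: dict[int, float] = {}
                        for level in levels:
                            rows, vals, cols = level_obs[level]
                            cands = np.unique(s_block[rows, cols])
                            cands = cands[cands > 0]
                            yc, sse = _level_search(s_block, rows, vals, cands)
                            y_crit[level] = yc
                            sse_total += sse
                        rmse = float(np.sqrt(sse_total / n_obs))
                        if rmse < best_rmse - 1e-12:
                            best_rmse = rmse
                            best_node = (p_start, t_b, x, y, variant)
                            best_ycrit = y_crit
                            best_sblock = s_block

    assert best_node is not None
    p_start, t_b, x, y, variant = best_node

    if refine:
        # dense pass over every accumulation value near the observations
        sse_total = 0.0
        for level in levels:
            rows, vals, cols = level_obs[level]
            lo = max(int(cols.min()) - 10, 0)
            hi = min(int(cols.max()) + 11, ACC_DOYS.size)
            cands = np.unique(best_sblock[rows][:, lo:hi].ravel())
            cands = cands[cands > 0]
            yc, sse = _level_search(best_sblock, rows, vals, cands)
            if np.isfinite(yc):
                best_ycrit[level] = yc
            sse_total += sse
        best_rmse = float(np.sqrt(sse_total / n_obs))

    # enforce Y_crit non-decreasing in level
    adjusted = False
    yc_arr = np.array([best_ycrit[lv] for lv in levels], dtype=float)
    finite = np.isfinite(yc_arr)
    if finite.any():
        iso = np.maximum.accumulate(np.where(finite, yc_arr, -np.inf))
        iso = np.where(finite, np.maximum(yc_arr, iso), yc_arr)
        if np.any(iso[finite] != yc_arr[finite]):
            adjusted = True
            warnings.warn("Y_crit not monotone in level; isotonic adjustment applied", stacklevel=2)
            yc_arr = iso
    best_ycrit = {lv: float(v) for lv, v in zip(levels, yc_arr)}

    # final in-sample predictions and RMSE with the adjusted thresholds
    levels_all, obs_all, pred_all, years_all = [], [], [], []
    sse_total = 0.0
    for level in levels:
        rows, vals, _ = level_obs[level]
        yc = best_ycrit[level]
        if np.isfinite(yc):
            preds = _predict_from_curves(best_sblock, rows, yc)
        else:
            preds = np.full(vals.size, _MISS_DOY)
        sse_total += float(np.sum((preds - vals) ** 2))
        years_all.extend(years[r] for r in rows)
        levels_all.extend([level] * vals.size)
        obs_all.extend(vals.tolist())
        pred_all.extend(preds.tolist())
    rmse = float(np.sqrt(sse_total / n_obs))

    params = CDDPParams(
        p_start=p_start, t_b=t_b, x=x, y=y, variant=variant, y_crit=best_ycrit
    )
    predictions = pd.DataFrame(
        {"year": years_all, "level": levels_all, "observed": obs_all, "predicted": pred_all}
    )
    return CDDPFit(
        species=species,
        kind=kind,
        params=params,
        rmse=rmse,
        n=n_obs,
        predictions=predictions,
        y_crit_adjusted=adjusted,
    )


def predict_stage_dates(
    params: CDDPParams,
    weather: pd.DataFrame,
    years: Sequence[int],
    latitude: float,
    refraction: bool = False,
) -> pd.DataFrame:
    """Forward-run a fitted suite over many years: long (year, level, doy).

    Levels whose threshold is never reached in a year come back as NaN.
    """
    rows = []
    for year in years:
        sub = weather[weather["year"] == int(year)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = simulate_year(sub, params, latitude, refraction=refraction)
        for level, doy in traj.predicted.items():
            rows.append({"year": int(year), "level": int(level),
                         "doy": np.nan if doy is None else doy})
    return pd.DataFrame(rows)
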