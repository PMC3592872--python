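"""Sliding-window climate-correlation fingerprints.

For an interannual phenology metric (a stage date c_x / f_x, a duration d_x,
or the amount of color A) and a daily climate variable, the fingerprint is
the Pearson correlation between the metric and the trailing-window climate
mean, evaluated on the full (end day 1..365) x (window length 1..52 weeks)
grid.  Cells are masked at the pointwise two-sided critical value
r_crit(alpha, n - 2); no multiple-testing correction is applied (the map is
exploratory).  Years with a missing metric or window value are dropped
pairwise, so the effective n (and the mask threshold) varies by cell.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import climate


def pearson_r(xs, ys) -> float:
    """Pearson product-moment correlation after pairwise deletion.

    Returns NaN when fewer than three complete pairs remain or either
    vector has zero variance.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    ok = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[ok], ys[ok]
    if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def critical_r(alpha: float, df: int) -> float:
    """Two-sided critical Pearson r: |r| above this is significant at alpha.

    ``r_crit = sqrt(t^2 / (t^2 + df))`` with t the (1 - alpha/2) quantile of
    Student's t with ``df`` degrees of freedom (df = n - 2 pairs).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(np.sqrt(t * t / (t * t + df)))


@dataclasses.dataclass
class CorrelationMap:
    """Pearson-r fingerprint over the (end day x window length) grid."""

    species: str
    metric: str
    variable: str
    alpha: float
    r: np.ndarray  # [365, 52]
    n: np.ndarray  # [365, 52] complete pairs per cell
    significant: np.ndarray  # [365, 52] bool, |r| > r_crit(alpha, n-2)
    best_positive: tuple[int, int] | None  # (end_doy, weeks)
    best_negative: tuple[int, int] | None

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: end_doy, weeks, r, n, significant."""
        end_doy, weeks = np.meshgrid(np.arange(1, 366), np.arange(1, 53), indexing="ij")
        return pd.DataFrame(
            {
                "species": self.species,
                "metric": self.metric,
                "variable": self.variable,
                "end_doy": end_doy.ravel(),
                "weeks": weeks.ravel(),
                "r": self.r.ravel(),
                "n": self.n.ravel(),
                "significant": self.significant.ravel(),
            }
        )


def correlation_map(
    metric_by_year: pd.Series,
    weather: pd.DataFrame,
    variable: str = "tmean_c",
    alpha: float = 0.05,
    species: str = "",
    metric: str = "",
    min_fraction: float = 0.9,
) -> CorrelationMap:
    """Correlate an interannual metric with every trailing climate window.

    ``metric_by_year`` is indexed by calendar year (NaN allowed; those years
    are deleted pairwise per cell).  Requires at least four years carrying
    both the metric and the window value; cells with fewer are undefined.
    Window-grid extrema are reported only among cells with the full number
    of complete years, to avoid unstable small-n extremes.
    """
    years = [int(y) for y in metric_by_year.index]
    values = metric_by_year.to_numpy(dtype=float)
    if not np.isfinite(values).any():
        raise ValueError("metric missing for all years")
    grid = climate.window_mean_grid(weather, years, variable, min_fraction)  # [Y,365,52]

    v = values[:, None, None]
    ok = np.isfinite(grid) & np.isfinite(v)
    n = ok.sum(axis=0)  # [365, 52]
    gz = np.where(ok, grid, 0.0)
    vz = np.where(ok, np.broadcast_to(v, grid.shape), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gm = gz.sum(axis=0) / n
        vm = vz.sum(axis=0) / n
        gc = np.where(ok, grid - gm, 0.0)
        vc = np.where(ok, v - vm, 0.0)
        cov = (gc * vc).sum(axis=0)
        denom = np.sqrt((gc * gc).sum(axis=0) * (vc * vc).sum(axis=0))
        r = np.where((n >= 4) & (denom > 0), cov / denom, np.nan)

    df = np.maximum(n - 2, 1)
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    r_crit = np.sqrt(t * t / (t * t + df))
    significant = np.isfinite(r) & (np.abs(r) > r_crit)

    full_n = n.max() if n.size else 0
    eligible = np.isfinite(r) & (n == full_n)
    best_pos = best_neg = None
    if eligible.any():
        masked = np.where(eligible, r, np.nan)
        imax = np.nanargmax(masked)
        imin = np.nanargmin(masked)
        best_pos = (int(imax // 52) + 1, int(imax % 52) + 1)
        best_neg = (int(imin // 52) + 1, int(imin % 52) + 1)

    return CorrelationMap(
        species=species,
        metric=metric,
        variable=variable,
        alpha=alpha,
        r=r,
        n=n,
        significant=significant,
        best_positive=best_pos,
        best_negative=best_neg,
    )
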