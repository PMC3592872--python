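"""Empirical model: stepwise multiple linear regression on monthly climate.

Each stage date (one threshold level of coloration or fall, per species) is
regressed on the 12 candidate predictors -- mean temperature and mean
precipitation of each leaf-on month (May-October).  Selection is
bidirectional from the empty model: at each iteration the single candidate
with the smallest partial-t p-value enters if p <= p_enter (default 0.20),
then every retained variable with p > p_remove (default 0.05) is purged,
until the selection stabilises.  With no candidate admissible the model is
intercept-only with R^2 = 0.

The liberal entry / strict retention thresholds mirror common phenology
practice; restricting candidates to monthly leaf-on means (rather than
weekly windows) limits the type-1 error inherent in stepwise search.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class MLRModel:
    """A fitted stepwise regression for one species x stage."""

    species: str
    kind: str
    level: int
    intercept: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int
    sse: float
    years: tuple[int, ...]

    @property
    def K(self) -> int:
        """Number of fitted parameters, including the intercept."""
        return 1 + len(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "kind": self.kind,
            "level": self.level,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "n": self.n,
            "K": self.K,
        }


def _ols_pvalues(X: np.ndarray, y: np.ndarray):
    """OLS fit returning (beta, partial-t p-values, sse).

    X carries the intercept in column 0.  Rank-deficient designs return
    ``None`` so callers can reject the candidate that caused them.
    """
    n, k = X.shape
    if n <= k:
        return None
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(xtx) > 1e12:
        return None
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sigma2 = sse / (n - k)
    if sigma2 <= 0:
        pvals = np.zeros(k)  # perfect fit: every term maximally significant
    else:
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), n - k)
    return beta, pvals, sse


def _sse(X: np.ndarray, y: np.ndarray) -> float | None:
    n, k = X.shape
    if n <= k:
        return None
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e12:
        return None
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    return float(resid @ resid)


def _partial_f_p(sse_restricted: float, sse_full: float, df_full: int) -> float:
    """p-value of one added/dropped term from the SSE change (partial F test,
    identical to the squared partial t for a single term).

    Degenerate perfect fits are handled explicitly: a term that leaves an
    already-zero SSE unchanged is useless (p = 1); one that removes the last
    residual variance is maximally significant (p = 0).
    """
    if df_full <= 0:
        return 1.0
    gain = max(sse_restricted - sse_full, 0.0)
    scale = max(sse_restricted, 1.0)
    if sse_full <= 1e-12 * scale:
        return 0.0 if gain > 1e-12 * scale else 1.0
    f = gain * df_full / sse_full
    return float(stats.f.sf(f, 1, df_full))


def stepwise_fit(
    response_by_year: pd.Series,
    predictors: pd.DataFrame,
    p_enter: float = 0.20,
    p_remove: float = 0.05,
    species: str = "",
    kind: str = "",
    level: int = 0,
) -> MLRModel:
    """Bidirectional stepwise OLS of a stage date on monthly climate means.

    ``response_by_year`` is indexed by year; ``predictors`` has one row per
    year (index) and one column per candidate.  Years with a missing
    response or any missing candidate are dropped listwise.  Ties in the
    forward step break by the fixed column order of ``predictors``,
    making the procedure deterministic given the data.
    """
    joined = predictors.copy()
    joined["_y"] = response_by_year.reindex(joined.index)
    joined = joined.dropna()
    if joined.empty:
        raise ValueError("no complete years to fit on")
    names = [c for c in predictors.columns]
    y = joined["_y"].to_numpy(dtype=float)
    Xall = joined[names].to_numpy(dtype=float)
    n = y.size

    def design(subset: list[str]) -> np.ndarray:
        cols = [names.index(s) for s in subset]
        return np.column_stack([np.ones(n)] + [Xall[:, c] for c in cols])

    selected: list[str] = []
    seen_states: set[tuple[str, ...]] = set()
    while True:
        state = tuple(sorted(selected))
        if state in seen_states:  # add/remove cycle: selection has converged
            break
        seen_states.add(state)
        changed = False
        # forward: admit the single smallest-p candidate (partial F on the
        # SSE change; ties break by the fixed candidate order)
        sse_base = _sse(design(selected), y)
        best_name, best_p = None, np.inf
        for name in names:
            if name in selected or sse_base is None:
                continue
            sse_with = _sse(design(selected + [name]), y)
            if sse_with is None:  # collinear with the retained set
                continue
            p_cand = _partial_f_p(sse_base, sse_with, n - len(selected) - 2)
            if p_cand < best_p:
                best_name, best_p = name, p_cand
        if best_name is not None and best_p <= p_enter:
            selected.append(best_name)
            changed = True
        # backward: purge anything whose partial p exceeds p_remove
        while selected:
            sse_full = _sse(design(selected), y)
            if sse_full is None:
                warnings.warn(
                    "collinear retained set; dropping latest-entering variable",
                    stacklevel=2,
                )
                selected.pop()
                changed = True
                continue
            pvals = []
            for s in selected:
                rest = [v for v in selected if v != s]
                sse_without = _sse(design(rest), y)
                pvals.append(
                    1.0 if sse_without is None
                    else _partial_f_p(sse_without, sse_full, n - len(selected) - 1)
                )
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        cols = [names.index(s) for s in selected]
        X = np.column_stack([np.ones(n)] + [Xall[:, c] for c in cols])
        beta, pvals, sse = _ols_pvalues(X, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / tss if tss > 0 else 0.0
        coefficients = {s: float(b) for s, b in zip(selected, beta[1:])}
        p_values = {s: float(p) for s, p in zip(selected, pvals[1:])}
        intercept = float(beta[0])
    else:
        intercept = float(y.mean())
        sse = float(np.sum((y - intercept) ** 2))
        coefficients, p_values, r2 = {}, {}, 0.0

    return MLRModel(
        species=species,
        kind=kind,
        level=level,
        intercept=intercept,
        coefficients=coefficients,
        p_values=p_values,
        r_squared=float(r2),
        n=int(n),
        sse=float(sse),
        years=tuple(int(v) for v in joined.index),
    )


def predict_mlr(model: MLRModel, predictors: Mapping[str, float] | pd.Series) -> float:
    """Linear prediction for one year; NaN if a selected predictor is missing."""
    value = model.intercept
    for name, coef in model.coefficients.items():
        x = predictors.get(name, np.nan) if hasattr(predictors, "get") else predictors[name]
        if x is None or not np.isfinite(x):
            return float("nan")
        value += coef * float(x)
    return float(value)


def fit_stage_suite(
    thresholds: pd.DataFrame,
    predictors: pd.DataFrame,
    species: str,
    kind: str,
    levels: Sequence[int] = (10, 25, 50, 75, 90),
    p_enter: float = 0.20,
    p_remove: float = 0.05,
) -> dict[int, MLRModel]:
    """Fit one independent stepwise model per threshold level."""
    sub = thresholds[(thresholds["species"] == species) & (thresholds["kind"] == kind)]
    suite: dict[int, MLRModel] = {}
    for level in levels:
        series = (
            sub[sub["level"] == level].set_index("year")["doy"].astype(float).sort_index()
        )
        suite[level] = stepwise_fit(
            series, predictors, p_enter, p_remove, species=species, kind=kind, level=level
        )
    return suite
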