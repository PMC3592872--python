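"""Goodness-of-fit, information criteria, and one-out cross-validation.

The empirical (stepwise regression) and process (CDD/P) models are compared
on three axes: root-mean-square error (days), Nash-Sutcliffe model
efficiency (1 = perfect, 0 = no better than the observed mean), and the
small-sample Akaike information criterion

    AICc = n ln(sse / n) + 2K + 2K(K + 1) / (n - K - 1)

computed from the Gaussian sse-based log-likelihood up to additive
constants, which cancel in differences (delta-AIC is reported as
AICc(empirical) - AICc(process), so positive values favour the process
model).  Robustness is probed by leave-one-out cross-validation that holds
out a whole year at a time -- all stages of that year leave the calibration
set together -- and scores the pooled held-out predictions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class FitDiagnostics:
    """Summary statistics of one model on one dataset."""

    rmse: float
    me: float
    aicc: float
    K: int
    n: int
    context: str = "in-sample"  # or "loocv"


def _paired(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ok = np.isfinite(o) & np.isfinite(p)
    return o[ok], p[ok]


def rmse(observed, predicted) -> float:
    """Root-mean-square error over paired, non-missing values."""
    o, p = _paired(observed, predicted)
    if o.size == 0:
        raise ValueError("no complete (observed, predicted) pairs")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def model_efficiency(observed, predicted) -> float:
    """Nash-Sutcliffe efficiency: 1 - sum(o-p)^2 / sum(o-mean(o))^2.

    Undefined (NaN) when the observations carry no variance.
    """
    o, p = _paired(observed, predicted)
    if o.size < 2:
        raise ValueError("need at least two pairs")
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum((o - p) ** 2) / denom)


def aicc(n: int, K: int, sse: float) -> float:
    """Small-sample-corrected Akaike criterion from a Gaussian SSE.

    Undefined (NaN) when the correction denominator n - K - 1 is not
    positive or the SSE is not positive.
    """
    if n <= K + 1 or sse <= 0:
        return float("nan")
    return float(n * np.log(sse / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1))


def diagnostics(observed, predicted, K: int, context: str = "in-sample") -> FitDiagnostics:
    """Bundle RMSE, ME and AICc for a set of paired values."""
    o, p = _paired(observed, predicted)
    sse = float(np.sum((o - p) ** 2))
    return FitDiagnostics(
        rmse=rmse(o, p),
        me=model_efficiency(o, p),
        aicc=aicc(o.size, K, sse),
        K=K,
        n=int(o.size),
        context=context,
    )


def loocv(
    years: Sequence[int],
    fit_predict: Callable[[list[int], int], tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Leave-one-year-out cross-validation.

    ``fit_predict(train_years, held_out_year)`` refits the model on the
    training years and returns ``(observed, predicted)`` arrays for the
    held-out year (all its stages at once).  Runs exactly ``len(years)``
    folds so every year is validated once; a fold that fails to fit is
    logged and skipped, with diagnostics computed over the remaining folds.

    Returns a long DataFrame (``year, observed, predicted``) of pooled
    held-out values.
    """
    years = [int(y) for y in years]
    if len(years) < 5:
        raise ValueError("cross-validation needs at least 5 years")
    rows = []
    for held_out in years:
        train = [y for y in years if y != held_out]
        try:
            observed, predicted = fit_predict(train, held_out)
        except Exception as exc:
            warnings.warn(f"LOOCV fold {held_out} failed to fit: {exc}", stacklevel=2)
            continue
        o = np.asarray(observed, dtype=float)
        p = np.asarray(predicted, dtype=float)
        for oi, pi in zip(o, p):
            rows.append({"year": held_out, "observed": oi, "predicted": pi})
    return pd.DataFrame(rows, columns=["year", "observed", "predicted"])
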