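"""Linear probability model (LPM) benchmarks.

Two ordinary-least-squares summaries of a simulated population:

* the share of treatment-choice variance explained by the true effect
  (R² of T on TE, reported as a percent) — the package's headline measure
  of sorting on the gain; and
* the LPM coefficient of the outcome on treatment (adjusting for
  severity), a consistent estimator of the average treatment effect on
  the treated under the simulator's choice model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .overlap import EstimationError


@dataclass(frozen=True)
class LpmFit:
    """Coefficients, R² and sample size of one OLS fit."""

    coefficients: dict[str, float]
    r_squared: float
    n: int


def _ols(y: np.ndarray, regressors: dict[str, np.ndarray]) -> LpmFit:
    X = sm.add_constant(
        pd.DataFrame(regressors), has_constant="add"
    )
    res = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise EstimationError("design matrix is rank deficient")
    return LpmFit(
        coefficients={k: float(v) for k, v in res.params.items()},
        r_squared=float(res.rsquared),
        n=int(res.nobs),
    )


def te_choice_r2(population: pd.DataFrame) -> float:
    """Percent of treatment-choice variation explained by the true effect.

    OLS of T on TE alone; with a single regressor the squared semipartial
    correlation equals the model R².  Returns NaN if either variable is
    constant (the share is undefined, not zero).
    """
    t = population["t"].to_numpy(dtype=float)
    te = population["te"].to_numpy(dtype=float)
    if np.var(t) < 1e-24 or np.var(te) < 1e-24:
        return float("nan")
    return 100.0 * _ols(t, {"te": te}).r_squared


def att_lpm(population: pd.DataFrame) -> float:
    """LPM estimate of the average treatment effect on the treated.

    OLS of the outcome on an intercept, treatment and severity; returns
    the treatment coefficient.
    """
    t = population["t"].to_numpy(dtype=float)
    if t.min() == t.max():
        raise EstimationError("both treatment arms are required")
    fit = _ols(
        population["y"].to_numpy(dtype=float),
        {"t": t, "s": population["s"].to_numpy(dtype=float)},
    )
    return fit.coefficients["t"]
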