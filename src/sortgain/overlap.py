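"""Propensity-score estimation and overlap (common support) diagnostics.

Treatment-choice simulations naturally thin the common support as sorting
on the gain strengthens: covariate cells whose expected effect is far from
the population mean become almost-always (or almost-never) treated.  This
module estimates the propensity score from the factors the researcher
observes, flags patients whose score lies strictly inside an overlap band
(default (0.05, 0.95)), and summarizes true effects by treatment-choice ×
overlap subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

SUBSET_LABELS = (
    "treated-overlap",
    "untreated-overlap",
    "treated-nonoverlap",
    "untreated-nonoverlap",
)

#: Coefficient magnitude beyond which a main-effects logit on binary
#: factors is taken to have separated (fitted cell odds beyond ~e^15).
_SEPARATION_COEF = 15.0


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated (e.g. single-arm data)."""


def classify_overlap(propensity: np.ndarray,
                     lower: float = 0.05,
                     upper: float = 0.95) -> np.ndarray:
    """Flag scores strictly inside (lower, upper) as overlapped.

    Boundary values count as non-overlapped; exact boundary hits have
    measure zero under a continuous score.
    """
    if not (0.0 < lower < upper < 1.0):
        raise ValueError(f"invalid overlap bounds ({lower}, {upper})")
    p = np.asarray(propensity, dtype=float)
    return ((p > lower) & (p < upper)).astype(np.int64)


class PropensityOverlap(BaseEstimator):
    """Main-effects logistic propensity model with an overlap band.

    Fits an unpenalized logit of treatment on the observed factors.  If the
    likelihood separates (some factor cell is deterministically treated or
    untreated, so maximum-likelihood coefficients diverge), the model falls
    back to empirical treatment frequencies over the observed factor cells,
    which is deterministic and exactly reproduces degenerate cells.

    Parameters
    ----------
    lower, upper : float
        Overlap band; a patient overlaps iff lower < score < upper
        (strict).
    max_iter : int
        Iteration cap for the logit fit.

    Attributes
    ----------
    propensity_ : ndarray of shape (n,)
        Fitted treatment probability per training patient.
    overlapped_ : ndarray of shape (n,)
        1 if the score lies strictly inside the band.
    method_ : str
        "logit" or "cell-frequency" (separation fallback).
    """

    def __init__(self, lower: float = 0.05, upper: float = 0.95,
                 max_iter: int = 100):
        self.lower = lower
        self.upper = upper
        self.max_iter = max_iter

    def fit(self, X, t):
        X = np.asarray(X, dtype=float)
        t = np.asarray(t, dtype=float)
        if X.ndim != 2 or len(X) != len(t):
            raise ValueError("X must be 2-D and aligned with t")
        if t.min() == t.max():
            raise EstimationError("treatment vector has a single class")
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ValueError(
                f"invalid overlap bounds ({self.lower}, {self.upper})"
            )

        p, method = self._fit_logit(X, t)
        if p is None:
            p = self._cell_frequencies(X, t)
            method = "cell-frequency"
        self.n_features_in_ = X.shape[1]
        self.propensity_ = p
        self.overlapped_ = classify_overlap(p, self.lower, self.upper)
        self.method_ = method
        return self

    def _fit_logit(self, X, t):
        design = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(t, design).fit(
                    disp=False, maxiter=self.max_iter
                )
            except Exception:
                return None, None
        if (not res.mle_retvals.get("converged", False)
                or np.max(np.abs(res.params)) > _SEPARATION_COEF
                or not np.all(np.isfinite(res.params))):
            return None, None
        return np.asarray(res.predict(design)), "logit"

    @staticmethod
    def _cell_frequencies(X, t):
        cells = pd.DataFrame(X)
        rates = pd.Series(t).groupby([cells[c] for c in cells.columns]) \
                            .transform("mean")
        return rates.to_numpy(dtype=float)


@dataclass
class OverlapReport:
    """Per-patient propensity scores, overlap flags and subset labels."""

    propensity: np.ndarray
    overlapped: np.ndarray
    subset: pd.Series           # one of SUBSET_LABELS per patient
    observed_factors: str       # "full" | "partial"
    bounds: tuple[float, float] = (0.05, 0.95)
    method: str = "logit"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "propensity": self.propensity,
            "overlapped": self.overlapped,
            "subset": self.subset,
        })


def fit_propensity(population: pd.DataFrame,
                   observed_factors: str = "full",
                   lower: float = 0.05,
                   upper: float = 0.95) -> OverlapReport:
    """Estimate propensity scores from the observed factor set and label
    each patient's treatment-choice × overlap subset.

    ``observed_factors="full"`` uses x1..x6; ``"partial"`` uses x1..x4.
    """
    from .config import OBSERVED_FACTOR_SETS

    cols = OBSERVED_FACTOR_SETS[observed_factors]
    model = PropensityOverlap(lower=lower, upper=upper).fit(
        population.loc[:, list(cols)].to_numpy(), population["t"].to_numpy()
    )
    treated = population["t"].to_numpy() == 1
    over = model.overlapped_ == 1
    subset = np.where(
        treated,
        np.where(over, "treated-overlap", "treated-nonoverlap"),
        np.where(over, "untreated-overlap", "untreated-nonoverlap"),
    )
    return OverlapReport(
        propensity=model.propensity_,
        overlapped=model.overlapped_,
        subset=pd.Series(subset, index=population.index),
        observed_factors=observed_factors,
        bounds=(lower, upper),
        method=model.method_,
    )


def subset_summary(population: pd.DataFrame,
                   report: OverlapReport) -> pd.DataFrame:
    """Mean true effect and patient share (%) for the treatment-choice and
    treatment-choice × overlap subsets.

    Empty subsets get share 0 and mean NaN (an explicit undefined marker,
    never a silent zero).
    """
    if len(report.subset) != len(population):
        raise ValueError("report is not aligned with the population")
    te = population["te"].to_numpy()
    treated = population["t"].to_numpy() == 1
    n = len(population)

    masks = {
        "treated": treated,
        "untreated": ~treated,
        "treated-overlap": report.subset.to_numpy() == "treated-overlap",
        "untreated-overlap": report.subset.to_numpy() == "untreated-overlap",
        "treated-nonoverlap": report.subset.to_numpy() == "treated-nonoverlap",
        "untreated-nonoverlap":
            report.subset.to_numpy() == "untreated-nonoverlap",
    }
    rows = []
    for label, mask in masks.items():
        k = int(mask.sum())
        rows.append({
            "subset": label,
            "mean_te": float(te[mask].mean()) if k else np.nan,
            "share_pct": 100.0 * k / n,
            "n": k,
        })
    return pd.DataFrame(rows).set_index("subset")
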