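"""Treatment-choice population simulator.

The generative model, per patient i:

* six binary effect modifiers ``x1..x6 ~ Bernoulli(0.5)``;
* true treatment effect ``te = sum_k beta_k * x_k`` (absolute risk units);
* severity ``s ~ Uniform(-0.5, 0.5)``, affecting cure but not choice;
* valuation noise ``u ~ Normal(0, noise_sd^2)`` (currency units);
* the decision maker's expected effect
  ``ete = K * (te - mean_te) + mean_te`` — an affine shrinkage of the true
  effect toward the population mean, with the knowledge share K in [0, 1];
* expected value of treatment ``evt = V * ete - C + u``; the patient is
  treated iff ``evt > 0`` (watchful waiting otherwise);
* cure probability ``p = alpha_0 + alpha_S * s + te * t``; the outcome
  ``y ~ Bernoulli(p)``.

At K = 0 choice depends only on the noise (ignorability holds in the
observed data); as K grows, patients increasingly sort on their own gain,
producing essential heterogeneity whenever some effect modifiers are
unobserved by the researcher.
"""

from __future__ import annotations

from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ScenarioConfig, ConfigurationError

#: Column order of a Population frame (also the on-disk CSV order).
POPULATION_COLUMNS = (
    "x1", "x2", "x3", "x4", "x5", "x6",
    "s", "u", "te", "ete", "evt", "t", "p_cure", "y",
)


# ---------------------------------------------------------------------------
# elementary operations

def true_te(factors: Sequence[float] | np.ndarray,
            betas: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """True treatment effect: inner product of the binary factors with the
    per-factor increments.

    ``factors`` may be a single length-6 vector or an (n, 6) array.
    """
    factors = np.asarray(factors, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if not np.isin(factors, (0.0, 1.0)).all():
        raise ValueError("factors must be binary 0/1")
    return factors @ betas


def expected_te(true_te_value: float | np.ndarray,
                knowledge_share: float,
                mean_te: float = 0.25) -> float | np.ndarray:
    """Decision maker's expected treatment effect: affine shrinkage of the
    true effect toward the population mean, ``K*(te - mean) + mean``.

    ``K = 0`` collapses every expectation to the mean; ``K = 1`` is exact
    knowledge.
    """
    if not 0.0 <= knowledge_share <= 1.0:
        raise ValueError(
            f"knowledge_share must be in [0, 1], got {knowledge_share}"
        )
    te = np.asarray(true_te_value, dtype=float)
    out = knowledge_share * (te - mean_te) + mean_te
    return float(out) if np.isscalar(true_te_value) else out


def treatment_value(expected_te_value: float | np.ndarray,
                    cure_value: float,
                    treatment_cost: float,
                    valuation_noise: float | np.ndarray) -> float | np.ndarray:
    """Expected value of treatment: ``V * ete - C + u`` (currency units)."""
    return cure_value * np.asarray(expected_te_value, dtype=float) \
        - treatment_cost + valuation_noise


def choose_treatment(evt: float | np.ndarray) -> int | np.ndarray:
    """Treat iff the expected value of treatment is strictly positive.

    An exact zero (probability-zero under continuous noise) resolves to
    watchful waiting.
    """
    out = (np.asarray(evt, dtype=float) > 0.0).astype(np.int64)
    return int(out) if np.isscalar(evt) else out


def cure_probability(te: float | np.ndarray,
                     treated: int | np.ndarray,
                     severity: float | np.ndarray,
                     cure_intercept: float = 0.1,
                     severity_slope: float = -0.1) -> float | np.ndarray:
    """Cure probability ``alpha_0 + alpha_S * s + te * t``.

    Raises :class:`ConfigurationError` if any value leaves [0, 1]: that
    signals inconsistent generative parameters, never data to be clamped.
    """
    p = cure_intercept + severity_slope * np.asarray(severity, dtype=float) \
        + np.asarray(te, dtype=float) * np.asarray(treated, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ConfigurationError(
            "cure probability outside [0, 1]; betas / intercept / slope "
            "are inconsistent"
        )
    scalar = np.isscalar(te) and np.isscalar(severity)
    return float(p) if scalar else p


# ---------------------------------------------------------------------------
# population generation

def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Independent component substreams from one master seed, so toggling
    one component (e.g. the noise scale) leaves the others' draws intact."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("factors", "severity", "noise", "outcome")
    return {k: np.random.default_rng(c) for k, c in zip(names, children)}


def simulate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate one population under the treatment-choice model.

    Returns a DataFrame with one row per patient and columns
    ``x1..x6, s, u, te, ete, evt, t, p_cure, y``.  Bit-reproducible from
    ``config.seed``.
    """
    n = config.n_patients
    rng = _substreams(config.seed)
    factors = rng["factors"].integers(0, 2, size=(n, 6)).astype(np.int64)
    severity = rng["severity"].uniform(-0.5, 0.5, size=n)
    noise = rng["noise"].normal(0.0, config.noise_sd, size=n)

    te = true_te(factors, config.betas)
    ete = expected_te(te, config.knowledge_share, mean_te=config.mean_te)
    evt = treatment_value(ete, config.cure_value, config.treatment_cost, noise)
    t = choose_treatment(evt)
    p_cure = cure_probability(
        te, t, severity, config.cure_intercept, config.severity_slope
    )
    y = (rng["outcome"].random(n) < p_cure).astype(np.int64)

    return pd.DataFrame({
        **{f"x{k + 1}": factors[:, k] for k in range(6)},
        "s": severity, "u": noise,
        "te": te, "ete": ete, "evt": evt,
        "t": t, "p_cure": p_cure, "y": y,
    }, columns=list(POPULATION_COLUMNS))


def enumerate_te_distribution(betas: Sequence[float]) -> pd.DataFrame:
    """Exact distribution of the true treatment effect over the 2^6
    equiprobable factor combinations.

    Returns a DataFrame with columns ``te`` (ascending, duplicates merged)
    and ``probability`` (multiples of 1/64, summing to 1).  Serves as the
    closed-form oracle for the simulator's mean/range invariants.
    """
    betas = np.asarray(betas, dtype=float)
    combos = np.array(list(product((0, 1), repeat=6)), dtype=float)
    te = np.round(combos @ betas, 12)  # merge float-equal sums
    values, counts = np.unique(te, return_counts=True)
    return pd.DataFrame({
        "te": values,
        "probability": counts / counts.sum(),
    })


def calibrate_noise_sd(target_r2: float,
                       config: ScenarioConfig,
                       grid: Sequence[float] | None = None) -> float:
    """Choose the valuation-noise scale that makes the simple regression of
    treatment on the true effect explain ``target_r2`` of choice variance.

    The calibration runs at full knowledge (K = 1), where sorting on the
    gain is strongest, and returns the grid candidate whose simulated R²
    is closest to the target.  Deterministic given ``config.seed``: every
    candidate reuses the same underlying draws (common random numbers), so
    the R² is monotone decreasing in the candidate sd.

    Parameters
    ----------
    target_r2 : float in (0, 1)
        Target share of choice variance (proportion, not percent).
    config : ScenarioConfig
        Template scenario; its seed, n_patients and betas are used.
    grid : sequence of positive floats, optional
        Candidate sd values (currency units).  Default: 30 to 100 in
        steps of 0.5.
    """
    from .parametric import te_choice_r2

    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    if grid is None:
        grid = np.arange(30.0, 100.0 + 1e-9, 0.5)
    grid = [float(g) for g in grid]
    if len(grid) == 0:
        raise ValueError("candidate grid is empty")

    best_sd, best_gap = grid[0], np.inf
    for sd in grid:
        pop = simulate_population(
            config.with_(knowledge_share=1.0, noise_sd=sd)
        )
        r2 = te_choice_r2(pop) / 100.0
        gap = abs(r2 - target_r2)
        if gap < best_gap:
            best_sd, best_gap = sd, gap
    return best_sd


# ---------------------------------------------------------------------------
# I/O

def write_population(population: pd.DataFrame, path: str | Path) -> None:
    """Write a population to CSV in the canonical column order."""
    population.loc[:, list(POPULATION_COLUMNS)].to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    """Read a population CSV written by :func:`write_population`."""
    pop = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(pop.columns)
    if missing:
        raise ValueError(f"population file missing columns: {sorted(missing)}")
    return pop.loc[:, list(POPULATION_COLUMNS)]
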