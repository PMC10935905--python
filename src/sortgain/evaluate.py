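"""Bias evaluation of patient-specific effect estimates over the
knowledge grid.

For each knowledge share K the experiment simulates one population, then —
for each observed-factor set (all six factors, or only the first four) —
estimates propensity/overlap, the parametric summaries, and an honest
causal forest with out-of-bag patient-level effect estimates.  Bias is
reported per treatment-choice × overlap subset as the signed mean of
(estimate − truth) on the absolute-risk scale, and as a percentage of the
subset's mean *true* effect.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig, DEFAULT_K_GRID, DEFAULT_BETAS
from .simulate import simulate_population, calibrate_noise_sd
from .overlap import OverlapReport, fit_propensity, subset_summary
from .parametric import te_choice_r2, att_lpm
from .forest import HonestCausalForest

logger = logging.getLogger("sortgain")

BIAS_SUBSETS = (
    "full", "treated", "untreated",
    "treated-overlap", "untreated-overlap",
    "treated-nonoverlap", "untreated-nonoverlap",
)

#: Named experiment profiles: reference scale and a desk scale that
#: preserves every qualitative pattern at a fraction of the cost.
PROFILES = {
    "paper": {"n_patients": 50_000, "n_trees": 4000},
    "desk": {"n_patients": 10_000, "n_trees": 500},
}


def bias_table(tau_hat: np.ndarray,
               population: pd.DataFrame,
               report: OverlapReport) -> pd.DataFrame:
    """Signed mean difference and percentage difference per subset.

    ``pct_diff = 100 * mean(tau_hat - te) / mean(te)`` within the subset,
    using the subset's mean true effect as denominator.  Patients with an
    undefined estimate (no usable tree) are excluded and counted in
    ``n_undefined``.  Empty subsets report NaN.
    """
    tau_hat = np.asarray(tau_hat, dtype=float)
    if len(tau_hat) != len(population) or len(report.subset) != len(population):
        raise ValueError("tau_hat / report not aligned with population")
    te = population["te"].to_numpy()
    treated = population["t"].to_numpy() == 1
    labels = report.subset.to_numpy()
    defined = np.isfinite(tau_hat)

    masks = {
        "full": np.ones(len(population), dtype=bool),
        "treated": treated,
        "untreated": ~treated,
        **{lab: labels == lab for lab in (
            "treated-overlap", "untreated-overlap",
            "treated-nonoverlap", "untreated-nonoverlap")},
    }
    rows = []
    for label in BIAS_SUBSETS:
        mask = masks[label]
        use = mask & defined
        k = int(use.sum())
        if k == 0:
            mean_diff = pct = mean_te = np.nan
        else:
            mean_te = float(te[use].mean())
            mean_diff = float((tau_hat[use] - te[use]).mean())
            pct = 100.0 * mean_diff / mean_te if mean_te != 0 else np.nan
        rows.append({
            "subset": label,
            "n": int(mask.sum()),
            "n_undefined": int((mask & ~defined).sum()),
            "mean_te": mean_te,
            "mean_diff": mean_diff,
            "pct_diff": pct,
        })
    return pd.DataFrame(rows).set_index("subset")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a full knowledge-grid sweep."""

    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    n_patients: int = 10_000
    betas: tuple[float, ...] = DEFAULT_BETAS
    n_trees: int = 500
    min_leaf: int = 50
    subsample_fraction: float = 0.25
    noise_sd: float | None = None      # None -> calibrate at run time
    calibration_target_r2: float = 0.48
    calibration_n: int = 50_000
    observation_sets: tuple[str, ...] = ("full", "partial")
    seed: int = 0

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "ExperimentConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        return cls(**{**PROFILES[profile], **overrides})


@dataclass
class ExperimentResult:
    """All summaries for one (knowledge share, observed-factor set)."""

    knowledge_share: float
    observed_factors: str
    noise_sd: float
    seed: int
    summary: pd.DataFrame          # subset_summary output
    overlap_pct: float
    r2_pct: float
    att: float
    bias: pd.DataFrame             # bias_table output
    error: str | None = None


def forest_covariates(population: pd.DataFrame,
                      observed_factors: str) -> np.ndarray:
    """Covariate matrix the researcher hands to the forest: the observed
    factor set plus severity."""
    from .config import OBSERVED_FACTOR_SETS
    cols = list(OBSERVED_FACTOR_SETS[observed_factors]) + ["s"]
    return population.loc[:, cols].to_numpy(dtype=float)


_forest_covariates = forest_covariates  # internal alias


def run_experiment(config: ExperimentConfig) -> list[ExperimentResult]:
    """Sweep the knowledge grid.

    One population is simulated per K (scenario seeds are derived from
    the master seed) and reused across both observed-factor sets, so each
    patient receives two effect estimates.  A failure in one scenario is
    recorded in its result rather than aborting the sweep.
    """
    logger.info("sweep config: %s", config)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.k_grid) + 1
    ) % (2 ** 31)
    noise_sd = config.noise_sd
    if noise_sd is None:
        t0 = time.perf_counter()
        noise_sd = calibrate_noise_sd(
            config.calibration_target_r2,
            ScenarioConfig(
                knowledge_share=1.0, n_patients=config.calibration_n,
                betas=config.betas, seed=int(seeds[-1]),
            ),
        )
        logger.info("calibrated noise_sd=%.2f (%.1fs)",
                    noise_sd, time.perf_counter() - t0)

    results: list[ExperimentResult] = []
    for k, scen_seed in zip(config.k_grid, seeds[:-1]):
        scenario = ScenarioConfig(
            knowledge_share=float(k), n_patients=config.n_patients,
            betas=config.betas, noise_sd=float(noise_sd),
            seed=int(scen_seed),
        )
        population = simulate_population(scenario)
        for obs in config.observation_sets:
            t0 = time.perf_counter()
            try:
                results.append(_run_cell(
                    population, scenario, obs, config
                ))
                logger.info("K=%.1f %s done (%.1fs)",
                            k, obs, time.perf_counter() - t0)
            except Exception as exc:   # record, keep sweeping
                logger.error("K=%.1f %s failed: %s", k, obs, exc)
                results.append(ExperimentResult(
                    knowledge_share=float(k), observed_factors=obs,
                    noise_sd=float(noise_sd), seed=int(scen_seed),
                    summary=pd.DataFrame(), overlap_pct=np.nan,
                    r2_pct=np.nan, att=np.nan, bias=pd.DataFrame(),
                    error=str(exc),
                ))
    return results


def _run_cell(population: pd.DataFrame, scenario: ScenarioConfig,
              observed_factors: str,
              config: ExperimentConfig) -> ExperimentResult:
    report = fit_propensity(population, observed_factors)
    summary = subset_summary(population, report)
    forest = HonestCausalForest(
        n_trees=config.n_trees, min_leaf=config.min_leaf,
        subsample_fraction=config.subsample_fraction,
        random_state=scenario.seed,
    ).fit(
        _forest_covariates(population, observed_factors),
        population["y"].to_numpy(dtype=float),
        population["t"].to_numpy(dtype=float),
    )
    tau_hat = forest.predict_oob()
    return ExperimentResult(
        knowledge_share=scenario.knowledge_share,
        observed_factors=observed_factors,
        noise_sd=scenario.noise_sd,
        seed=scenario.seed,
        summary=summary,
        overlap_pct=100.0 * float(np.mean(report.overlapped)),
        r2_pct=te_choice_r2(population),
        att=att_lpm(population),
        bias=bias_table(tau_hat, population, report),
    )


# ---------------------------------------------------------------------------
# report surface

def _round(x, k):
    return np.nan if x is None or not np.isfinite(x) else round(float(x), k)


def population_summary_frame(results: list[ExperimentResult]) -> pd.DataFrame:
    """One row per K: sorting/overlap summaries and parametric estimates
    (full-observation propensity for the overlap column; a separate
    column carries the partial-observation overlap share)."""
    by_k: dict[float, dict] = {}
    for r in results:
        if r.error:
            continue
        row = by_k.setdefault(r.knowledge_share, {"k": r.knowledge_share})
        row[f"overlap_pct_{r.observed_factors}"] = _round(r.overlap_pct, 1)
        if r.observed_factors == "full":
            row["r2_pct"] = _round(r.r2_pct, 4)
            row["att_lpm"] = _round(r.att, 3)
            for sub in ("treated", "untreated", "treated-overlap",
                        "untreated-overlap", "treated-nonoverlap",
                        "untreated-nonoverlap"):
                s = r.summary.loc[sub]
                key = sub.replace("-", "_")
                row[f"mean_te_{key}"] = _round(s["mean_te"], 3)
                row[f"share_pct_{key}"] = _round(s["share_pct"], 1)
    return pd.DataFrame(sorted(by_k.values(), key=lambda d: d["k"]))


def bias_frame(results: list[ExperimentResult], observed_factors: str,
               value: str = "pct_diff") -> pd.DataFrame:
    """One row per K for one observed-factor set; columns are the bias
    subsets.  ``value`` selects percentage ("pct_diff") or absolute-risk
    ("mean_diff") differences."""
    digits = 2 if value == "pct_diff" else 4
    rows = []
    for r in sorted(results, key=lambda r: r.knowledge_share):
        if r.error or r.observed_factors != observed_factors:
            continue
        row = {"k": r.knowledge_share,
               "r2_pct": _round(r.r2_pct, 4),
               "overlap_pct": _round(r.overlap_pct, 1)}
        for sub in BIAS_SUBSETS:
            row[sub.replace("-", "_")] = _round(
                r.bias.loc[sub, value], digits
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(results: list[ExperimentResult],
                  outdir: str | Path) -> dict[str, Path]:
    """Write the sweep surface: population summary, percentage-bias tables
    for both observed-factor sets, absolute differences under full
    observation, and a JSON bundle of everything."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    frames = {
        "population_summary.csv": population_summary_frame(results),
        "bias_full_observed.csv": bias_frame(results, "full"),
        "bias_partial_observed.csv": bias_frame(results, "partial"),
        "abs_diff_full_observed.csv":
            bias_frame(results, "full", value="mean_diff"),
    }
    for name, frame in frames.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        paths[name] = path

    bundle = [{
        "knowledge_share": r.knowledge_share,
        "observed_factors": r.observed_factors,
        "noise_sd": r.noise_sd,
        "seed": r.seed,
        "overlap_pct": None if not np.isfinite(r.overlap_pct)
        else r.overlap_pct,
        "r2_pct": None if not np.isfinite(r.r2_pct) else r.r2_pct,
        "att": None if not np.isfinite(r.att) else r.att,
        "summary": None if r.summary.empty
        else json.loads(r.summary.to_json(orient="index")),
        "bias": None if r.bias.empty
        else json.loads(r.bias.to_json(orient="index")),
        "error": r.error,
    } for r in results]
    path = outdir / "experiment_results.json"
    path.write_text(json.dumps(bundle, indent=1))
    paths["experiment_results.json"] = path
    return paths
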