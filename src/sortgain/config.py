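"""Scenario configuration for the treatment-choice simulator.

A :class:`ScenarioConfig` fully determines one simulated population: the
six effect-modifier increments, the cure-probability intercept and severity
slope, the economic parameters of the choice rule (cure value ``V`` and
treatment cost ``C``), the knowledge share ``K``, the valuation-noise scale
and the master seed.  Configurations round-trip through YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import yaml

#: Default per-factor treatment-effect increments (absolute risk units).
#: Six independent Bernoulli(0.5) factors with these increments give a true
#: effect ranging over [0, 0.5] with population mean 0.25.
DEFAULT_BETAS: tuple[float, ...] = (0.024, 0.048, 0.071, 0.095, 0.119, 0.143)

#: The eleven-point knowledge grid swept by the default experiment.
DEFAULT_K_GRID: tuple[float, ...] = (
    0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)

OBSERVED_FACTOR_SETS = {
    "full": ("x1", "x2", "x3", "x4", "x5", "x6"),
    "partial": ("x1", "x2", "x3", "x4"),
}


class ConfigurationError(ValueError):
    """Raised when generative parameters are mutually inconsistent
    (e.g. a cure probability that can leave [0, 1])."""


@dataclass(frozen=True)
class ScenarioConfig:
    """All generative parameters for one simulated population.

    Parameters
    ----------
    knowledge_share : float
        K in [0, 1]; the share of each patient's true effect (vs. the
        population mean effect) entering the decision maker's expected
        treatment effect.
    n_patients : int
        Population size.
    betas : sequence of 6 floats
        Per-factor treatment-effect increments, probability units.
    cure_intercept : float
        Untreated cure probability at mean severity (alpha_0).
    severity_slope : float
        Change in cure probability per unit severity (alpha_S).
    cure_value : float
        Currency value of a cure (V).
    treatment_cost : float
        Currency cost of treatment (C).
    noise_sd : float
        Standard deviation of the valuation noise U (currency units).
        The default (60) is roughly the scale at which, under full
        knowledge and the default betas, the true effect explains 48% of
        choice variance; experiment sweeps re-derive it at run time via
        :func:`sortgain.simulate.calibrate_noise_sd` and store the
        resolved value in their metadata.
    seed : int
        Master seed; component draws use independent substreams.
    observed_factors : {"full", "partial"}
        Which factors the researcher observes: all six, or only the
        first four.
    """

    knowledge_share: float
    n_patients: int = 50_000
    betas: tuple[float, ...] = DEFAULT_BETAS
    cure_intercept: float = 0.1
    severity_slope: float = -0.1
    cure_value: float = 800.0
    treatment_cost: float = 200.0
    noise_sd: float = 60.0
    seed: int = 0
    observed_factors: str = "full"

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if not 0.0 <= self.knowledge_share <= 1.0:
            raise ConfigurationError(
                f"knowledge_share must be in [0, 1], got {self.knowledge_share}"
            )
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if len(self.betas) != 6:
            raise ConfigurationError("betas must have length 6")
        if any(b <= 0 for b in self.betas):
            raise ConfigurationError("betas must all be > 0")
        # cure probability must stay within [0, 1] for every factor
        # combination, severity in [-.5, .5] and either treatment arm
        headroom = 1.0 - self.cure_intercept - abs(self.severity_slope) * 0.5
        if sum(self.betas) > headroom + 1e-12:
            raise ConfigurationError(
                "sum(betas) exceeds the cure-probability headroom "
                f"({sum(self.betas):.3f} > {headroom:.3f})"
            )
        if self.cure_intercept - abs(self.severity_slope) * 0.5 < -1e-12:
            raise ConfigurationError("cure probability can fall below 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.observed_factors not in OBSERVED_FACTOR_SETS:
            raise ConfigurationError(
                f"observed_factors must be one of {sorted(OBSERVED_FACTOR_SETS)}"
            )

    @property
    def mean_te(self) -> float:
        """Population-mean true treatment effect, sum(betas) / 2."""
        return sum(self.betas) / 2.0

    @property
    def observed_columns(self) -> tuple[str, ...]:
        return OBSERVED_FACTOR_SETS[self.observed_factors]

    def with_(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["betas"] = list(d["betas"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
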