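"""Validated simulation configuration.

`ModelConfig` gathers every parameter of a single run; its defaults are the
reference experimental protocol (n=100 agents, convergence speed mu=0.5,
t=100000 steps, dyadic interactions on a complete graph).  Unknown keys are
rejected so that typos in config files fail loudly.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

NoiseType = Literal["none", "ambiguity", "selectivity", "adaptation", "exogenous"]
NoiseDistribution = Literal["gaussian", "bounded_uniform"]
Regime = Literal["one_to_one", "many_to_one", "one_to_many"]
Topology = Literal["complete", "small_world"]
Initializer = Literal["uniform", "six_americas"]

#: Attitude segments ordered from lowest to highest concern.
CATEGORIES = ("dismissive", "doubtful", "disengaged", "cautious",
              "concerned", "alarmed")


class CategoryProfile(BaseModel):
    """Population shares of the six climate-attitude segments
    ("six Americas"), ordered from dismissive to alarmed.

    Defaults are the survey shares used to calibrate initial opinions:
    7% dismissive, 11% doubtful, 12% disengaged, 19% cautious,
    33% concerned, 18% alarmed.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dismissive: float = Field(0.07, ge=0.0)
    doubtful: float = Field(0.11, ge=0.0)
    disengaged: float = Field(0.12, ge=0.0)
    cautious: float = Field(0.19, ge=0.0)
    concerned: float = Field(0.33, ge=0.0)
    alarmed: float = Field(0.18, ge=0.0)

    @model_validator(mode="after")
    def _check_sum(self) -> "CategoryProfile":
        total = sum(self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {total}")
        return self

    @property
    def proportions(self) -> tuple[float, ...]:
        """Shares ordered low -> high concern."""
        return tuple(getattr(self, c) for c in CATEGORIES)


class NoiseSpec(BaseModel):
    """Which noise operator acts, at what level, with which deviation law.

    ``level`` is nu, the standard deviation of the Gaussian deviations (or
    the half-width of the bounded-uniform variant).  For exogenous noise nu
    doubles as the per-agent, per-step jump probability omega = nu and must
    therefore not exceed 1.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    noise_type: NoiseType = "none"
    level: float = Field(0.0, ge=0.0)
    distribution: NoiseDistribution = "gaussian"

    @model_validator(mode="after")
    def _check_exogenous_probability(self) -> "NoiseSpec":
        if self.noise_type == "exogenous" and self.level > 1.0:
            raise ValueError(
                "exogenous noise level doubles as a jump probability and "
                f"must be <= 1, got {self.level}")
        return self


class ModelConfig(BaseModel):
    """Full parameterization of one simulation run."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(100, ge=2, description="number of agents")
    mu: float = Field(0.5, gt=0.0, le=0.5, description="convergence speed")
    epsilon: float = Field(0.2, ge=0.0, le=1.0, description="confidence bound")
    steps: int = Field(100_000, ge=0, description="total time steps")
    noise: NoiseSpec = NoiseSpec()
    regime: Regime = "one_to_one"
    regime_k: int = Field(10, ge=2, description="fan-in/out for non-dyadic regimes")
    topology: Topology = "complete"
    sw_degree: int = Field(10, ge=2, description="Watts-Strogatz ring degree")
    sw_rewire: float = Field(0.1, ge=0.0, le=1.0, description="Watts-Strogatz rewiring prob.")
    init: Initializer = "uniform"
    profile: CategoryProfile = CategoryProfile()
    seed: int = 0
    snapshot_every: int = Field(1000, ge=1, description="recording cadence in steps")

    @model_validator(mode="after")
    def _check_consistency(self) -> "ModelConfig":
        if self.regime != "one_to_one":
            if self.regime_k >= self.n:
                raise ValueError(
                    f"regime_k={self.regime_k} must be < n={self.n}")
            if self.topology != "complete":
                raise ValueError(
                    "many-to-one / one-to-many regimes are only defined on "
                    "the complete topology")
        if self.topology == "small_world" and self.sw_degree >= self.n:
            raise ValueError(f"sw_degree={self.sw_degree} must be < n={self.n}")
        return self


class GridSpec(BaseModel):
    """An (epsilon, nu) ensemble sweep: one ensemble of ``replicates``
    seeded runs per (noise_type, epsilon, nu) cell, all sharing ``base``
    for every other parameter (including the initializer choice)."""

    model_config = ConfigDict(extra="forbid")

    epsilons: list[float] = Field(min_length=1)
    nus: list[float] = Field(min_length=1)
    noise_types: list[NoiseType] = Field(min_length=1)
    replicates: int = Field(100, ge=1)
    base: ModelConfig = ModelConfig()

    @model_validator(mode="after")
    def _check_ranges(self) -> "GridSpec":
        for e in self.epsilons:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"epsilon values must lie in [0, 1], got {e}")
        for v in self.nus:
            if v < 0.0:
                raise ValueError(f"nu values must be >= 0, got {v}")
        return self
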