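"""Initial opinion distributions.

Two initializers are provided: i.i.d. Uniform[0, 1] opinions (the
hypothetical baseline, initial dispersion 1/sqrt(12) ~ 0.289), and a
survey-calibrated distribution for the climate-change scenario built from
the six-segment "six Americas" attitude shares.  The calibrated sampler
draws each agent's segment from the profile's proportions and then places
the opinion uniformly within that segment's sixth of the opinion space,
which reproduces the reported initial moments (mean ~0.607, s.d. ~0.253).
"""

from __future__ import annotations

import math

import numpy as np

from .config import CATEGORIES, CategoryProfile, ModelConfig


def init_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Uniform[0, 1] opinions."""
    if n < 2:
        raise ValueError(f"need at least 2 agents, got {n}")
    return rng.random(n)


def init_six_americas(n: int, profile: CategoryProfile | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Opinions calibrated to the six-segment attitude profile.

    Each agent independently draws a segment k in 1..6 (low -> high concern)
    with the profile's probabilities and then an opinion uniform on
    ((k-1)/6, k/6).
    """
    if n < 2:
        raise ValueError(f"need at least 2 agents, got {n}")
    if profile is None:
        profile = CategoryProfile()
    if rng is None:
        rng = np.random.default_rng()
    k = rng.choice(6, size=n, p=np.asarray(profile.proportions))
    return (k + rng.random(n)) / 6.0


def init_opinions(config: ModelConfig, rng: np.random.Generator) -> np.ndarray:
    """Dispatch on the config's initializer choice."""
    if config.init == "uniform":
        return init_uniform(config.n, rng)
    return init_six_americas(config.n, config.profile, rng)


def category_of_opinion(x: float) -> str:
    """Map an opinion to its attitude segment.

    Segments own half-open intervals ((k-1)/6, k/6]; x = 0 belongs to the
    lowest segment ("dismissive").  E.g. opinions above 4/6 are at least
    "concerned", above 5/6 "alarmed".
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"opinion must lie in [0, 1], got {x}")
    k = max(1, min(math.ceil(6 * x), 6))
    return CATEGORIES[k - 1]


def calibrated_moments(profile: CategoryProfile | None = None) -> tuple[float, float]:
    """Exact mean and standard deviation of the calibrated density.

    Closed form: mean = sum_k p_k (2k-1)/12; variance = within-segment
    uniform variance 1/432 plus the between-segment variance of the
    segment centres.
    """
    if profile is None:
        profile = CategoryProfile()
    p = np.asarray(profile.proportions)
    centres = (2 * np.arange(1, 7) - 1) / 12.0
    mean = float(p @ centres)
    var = 1.0 / 432.0 + float(p @ centres**2) - mean**2
    return mean, math.sqrt(var)
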