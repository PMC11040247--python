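"""Bounded-confidence opinion model with noisy social interaction.

The model follows the pairwise-assimilation rule of Deffuant-style bounded
confidence: agents hold scalar opinions on [0, 1]; in each time step a pair
of agents is drawn and each member moves a fraction mu toward the other's
message if that message lies within the confidence bound epsilon.  Noise
can enter the interaction at four distinct points:

* **ambiguity** — the transmitted message is a truncated-Gaussian blur of
  the sender's opinion,
* **selectivity** — the confidence bound is perturbed per interaction,
* **adaptation** — the receiver's post-update opinion is perturbed,
* **exogenous** — agents occasionally jump, independent of interaction.

The public functions here are thin validated wrappers over the compiled
kernels in :mod:`noisybc._kernels`; `run_simulation` is the main entry
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import _kernels
from .config import ModelConfig, NoiseSpec

_NOISE_CODES = {
    "none": _kernels.NONE,
    "ambiguity": _kernels.AMBIGUITY,
    "selectivity": _kernels.SELECTIVITY,
    "adaptation": _kernels.ADAPTATION,
    "exogenous": _kernels.EXOGENOUS,
}
_DIST_CODES = {"gaussian": _kernels.GAUSSIAN,
               "bounded_uniform": _kernels.BOUNDED_UNIFORM}
_REGIME_CODES = {"one_to_one": _kernels.ONE_TO_ONE,
                 "many_to_one": _kernels.MANY_TO_ONE,
                 "one_to_many": _kernels.ONE_TO_MANY}

_NO_EDGES = np.empty((0, 2), dtype=np.int64)


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


def bc_pair_update(x_i: float, m_j: float, epsilon: float, mu: float) -> float:
    """One-directional bounded-confidence update.

    Returns ``x_i + mu*(m_j - x_i)`` if ``|m_j - x_i| <= epsilon`` (non-strict)
    and ``x_i`` unchanged otherwise.  The result is a convex combination and
    therefore stays in [0, 1].
    """
    x_i = _check_unit(x_i, "x_i")
    m_j = _check_unit(m_j, "m_j")
    epsilon = _check_unit(epsilon, "epsilon")
    if not 0.0 < mu <= 0.5:
        raise ValueError(f"mu must lie in (0, 0.5], got {mu}")
    return _kernels.bc_update(x_i, m_j, epsilon, mu)


def draw_ambiguous_message(x_j: float, nu: float, rng: np.random.Generator,
                           distribution: str = "gaussian") -> float:
    """Draw the noisy message a sender at opinion ``x_j`` emits.

    The message is ``x_j`` plus a zero-mean deviation of scale ``nu``,
    resampled until it lies in [0, 1] (a truncated distribution realized by
    rejection, never by clipping).  ``nu=0`` returns ``x_j`` exactly.
    """
    x_j = _check_unit(x_j, "x_j")
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    return _kernels.truncated_shift(x_j, float(nu), _DIST_CODES[distribution], rng)


def accept_selectivity(x_i: float, x_j: float, epsilon: float, nu: float,
                       rng: np.random.Generator,
                       distribution: str = "gaussian") -> bool:
    """Noisy partner acceptance: true iff ``|x_j - x_i| <= epsilon + xi``
    with a fresh un-truncated deviation ``xi`` of scale ``nu``.  A negative
    effective bound always rejects."""
    x_i = _check_unit(x_i, "x_i")
    x_j = _check_unit(x_j, "x_j")
    epsilon = _check_unit(epsilon, "epsilon")
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    return bool(_kernels.selectivity_accept(
        x_i, x_j, epsilon, float(nu), _DIST_CODES[distribution], rng))


def adaptation_shift(x_post: float, nu: float, rng: np.random.Generator,
                     distribution: str = "gaussian") -> float:
    """Perturb a post-interaction opinion by a zero-mean deviation of scale
    ``nu``, resampled until the result stays in [0, 1]."""
    x_post = _check_unit(x_post, "x_post")
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    return _kernels.truncated_shift(x_post, float(nu), _DIST_CODES[distribution], rng)


def apply_exogenous_jumps(opinions: np.ndarray, nu: float,
                          rng: np.random.Generator,
                          distribution: str = "gaussian") -> np.ndarray:
    """Let each agent independently jump with probability omega = nu by a
    truncated deviation of scale nu.  Returns a new array."""
    x = np.array(opinions, dtype=np.float64)
    if x.min(initial=0.0) < 0 or x.max(initial=0.0) > 1:
        raise ValueError("opinions must lie in [0, 1]")
    if not 0.0 <= nu <= 1.0:
        raise ValueError(
            f"exogenous nu doubles as a probability and must lie in [0, 1], got {nu}")
    _kernels.exogenous_sweep(x, float(nu), _DIST_CODES[distribution], rng)
    return x


def build_edges(config: ModelConfig, seed: int | None = None) -> np.ndarray:
    """Edge list for the interaction topology, as an (m, 2) int64 array.

    The complete topology is represented by an empty edge list (pairs are
    then sampled directly, which is equivalent and avoids materializing
    n*(n-1)/2 edges).
    """
    if config.topology == "complete":
        return _NO_EDGES
    graph = nx.watts_strogatz_graph(
        config.n, config.sw_degree, config.sw_rewire,
        seed=config.seed if seed is None else seed)
    return np.array(list(graph.edges()), dtype=np.int64).reshape(-1, 2)


def simulation_step(state: np.ndarray, config: ModelConfig,
                    rng: np.random.Generator,
                    noise_rng: np.random.Generator | None = None,
                    edges: np.ndarray | None = None) -> np.ndarray:
    """Advance one time step and return the new opinion vector.

    ``rng`` drives partner selection; ``noise_rng`` (defaulting to the same
    generator) drives all noise draws.  Dyadic steps update both pair
    members symmetrically from each other's pre-step opinions.
    """
    x = np.array(state, dtype=np.float64)
    if x.size != config.n:
        raise ValueError(f"state has {x.size} agents, config says n={config.n}")
    if config.n < 2:
        raise ValueError("need at least 2 agents")
    if edges is None:
        edges = build_edges(config)
    counts = np.zeros(config.n, dtype=np.int64)
    scratch = np.empty(config.n, dtype=np.int64)
    _kernels.step(
        x, config.mu, config.epsilon,
        _NOISE_CODES[config.noise.noise_type], config.noise.level,
        _DIST_CODES[config.noise.distribution],
        _REGIME_CODES[config.regime], config.regime_k, edges,
        rng, noise_rng if noise_rng is not None else rng, counts, scratch)
    return x


@dataclass
class SimulationResult:
    """Opinion snapshots plus per-snapshot summary metrics for one run."""

    config: ModelConfig
    seed: int
    snapshot_steps: np.ndarray
    snapshot_matrix: np.ndarray          # (n_snapshots, n)
    interactions: np.ndarray             # per-agent interaction counts
    summary: pd.DataFrame = field(repr=False, default=None)

    @property
    def snapshots(self) -> Mapping[int, np.ndarray]:
        """Map from time step to the opinion vector recorded there."""
        return {int(s): self.snapshot_matrix[i]
                for i, s in enumerate(self.snapshot_steps)}

    @property
    def initial(self) -> np.ndarray:
        return self.snapshot_matrix[0]

    @property
    def final(self) -> np.ndarray:
        return self.snapshot_matrix[-1]


def _snapshot_steps(steps: int, every: int) -> np.ndarray:
    if every <= 0:
        raise ValueError(f"snapshot_every must be positive, got {every}")
    pts = np.arange(0, steps + 1, every, dtype=np.int64)
    if pts[-1] != steps:
        pts = np.append(pts, steps)
    return pts


def run_simulation(config: ModelConfig, summarize: bool = True) -> SimulationResult:
    """Run a full seeded simulation.

    The run seed fully determines every random draw: an initialization
    stream, a pairing stream and a noise stream are split from it via
    ``SeedSequence.spawn``, so repeated calls with the same config are
    bit-reproducible.
    """
    from .initialization import init_opinions
    from .metrics import summary_table

    ss = np.random.SeedSequence(config.seed)
    init_ss, pair_ss, noise_ss, graph_ss = ss.spawn(4)
    x0 = init_opinions(config, np.random.default_rng(init_ss))
    edges = build_edges(config, seed=int(graph_ss.generate_state(1)[0]))
    snap_steps = _snapshot_steps(config.steps, config.snapshot_every)
    snaps, counts = _kernels.run(
        x0, config.steps, config.mu, config.epsilon,
        _NOISE_CODES[config.noise.noise_type], config.noise.level,
        _DIST_CODES[config.noise.distribution],
        _REGIME_CODES[config.regime], config.regime_k, edges, snap_steps,
        np.random.default_rng(pair_ss), np.random.default_rng(noise_ss))
    result = SimulationResult(config=config, seed=config.seed,
                              snapshot_steps=snap_steps,
                              snapshot_matrix=snaps, interactions=counts)
    if summarize:
        result.summary = summary_table(result.snapshot_steps,
                                       result.snapshot_matrix)
    return result
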