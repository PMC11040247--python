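"""Config loading, result writers, seed-stream management.

Reproducibility contract: a master seed plus a replicate index determines a
replicate seed through a counter-based `SeedSequence` derivation, so
ensemble results do not depend on execution order; a written manifest
(config echo + master seed + derived seeds) suffices to replay every
output byte-for-byte.  The manifest is written last and therefore doubles
as a completion marker.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import tomllib
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GridSpec, ModelConfig
from .model import SimulationResult


def derive_seed(master: int, replicate_index: int) -> int:
    """Replicate seed from (master seed, counter), order-independent."""
    if replicate_index < 0:
        raise ValueError("replicate_index must be >= 0")
    ss = np.random.SeedSequence(entropy=master, spawn_key=(replicate_index,))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _package_version() -> str:
    try:
        return version("noisybc")
    except PackageNotFoundError:
        return "unknown"


def load_config(path: str | Path) -> ModelConfig | GridSpec:
    """Load and validate a run or sweep configuration (TOML or JSON).

    A file containing grid keys (``epsilons``/``nus``/``noise_types``) is
    parsed as a `GridSpec`, anything else as a `ModelConfig`.  Missing keys
    take the reference-protocol defaults (n=100, mu=0.5, steps=100000);
    unknown keys and out-of-range values raise descriptive errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    if {"epsilons", "nus", "noise_types"} & data.keys():
        return GridSpec.model_validate(data)
    return ModelConfig.model_validate(data)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for a set of outputs."""

    config: dict
    master_seed: int
    derived_seeds: list[int]
    code_version: str
    created: str
    outputs: list[str]

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def snapshots_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format snapshot table (step, agent_id, opinion)."""
    n_snap, n = result.snapshot_matrix.shape
    return pd.DataFrame({
        "step": np.repeat(result.snapshot_steps, n),
        "agent_id": np.tile(np.arange(n), n_snap),
        "opinion": result.snapshot_matrix.ravel(),
    })


def write_results(obj: SimulationResult | pd.DataFrame,
                  out_dir: str | Path,
                  derived_seeds: list[int] | None = None,
                  config: dict | None = None,
                  master_seed: int | None = None) -> dict[str, Path]:
    """Write results and a manifest to ``out_dir``; returns written paths.

    `SimulationResult` -> snapshots.csv + summary.csv; an ensemble table
    (DataFrame) -> ensemble.csv.  manifest.json is always written last.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if isinstance(obj, SimulationResult):
        paths["snapshots"] = out_dir / "snapshots.csv"
        snapshots_frame(obj).to_csv(paths["snapshots"], index=False)
        paths["summary"] = out_dir / "summary.csv"
        obj.summary.to_csv(paths["summary"], index=False)
        config = obj.config.model_dump()
        master_seed = obj.seed
        derived_seeds = derived_seeds or []
    elif isinstance(obj, pd.DataFrame):
        paths["ensemble"] = out_dir / "ensemble.csv"
        obj.to_csv(paths["ensemble"], index=False)
        config = config or {}
        derived_seeds = derived_seeds or []
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    manifest = RunManifest(
        config=config,
        master_seed=int(master_seed) if master_seed is not None else 0,
        derived_seeds=[int(s) for s in derived_seeds],
        code_version=_package_version(),
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=[str(p) for p in paths.values()],
    )
    paths["manifest"] = out_dir / "manifest.json"
    manifest.write(paths["manifest"])
    return paths
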