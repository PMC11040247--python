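"""Summary statistics of opinion vectors.

Dispersion (the population standard deviation of opinions) is the model's
disagreement metric: small dispersion means a narrow, largely agreeing
distribution; large dispersion means polarization into clusters or a
diffuse spread.  The pro-environmental-agreement (PEA) predicate combines
dispersion with the mean-concern threshold of the climate scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: Mean-opinion threshold for "at least concerned" (segment boundary 4/6).
PEA_MEAN_THRESHOLD = 4.0 / 6.0
#: Dispersion threshold below which the population counts as agreeing.
PEA_DISPERSION_THRESHOLD = 0.1


class ZeroDispersionError(ValueError):
    """Raised where a statistic is undefined for a degenerate distribution."""


def _as_opinions(opinions, min_n: int) -> np.ndarray:
    x = np.asarray(opinions, dtype=np.float64)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"need a 1-d vector of at least {min_n} opinions")
    return x


def dispersion(opinions) -> float:
    """Population standard deviation of the opinions (ddof=0)."""
    return float(np.std(_as_opinions(opinions, 2)))


def excess_kurtosis(opinions) -> float:
    """Fisher excess kurtosis of the opinions (normal -> 0), population
    moments.  Undefined (raises) when dispersion is zero."""
    x = _as_opinions(opinions, 4)
    if np.std(x) == 0.0:
        raise ZeroDispersionError("kurtosis undefined for zero dispersion")
    return float(stats.kurtosis(x, fisher=True, bias=True))


def count_clusters(opinions, gap: float = 0.05, min_size: int = 2) -> int:
    """Number of opinion clusters by sorted-gap splitting.

    Opinions are sorted and split wherever consecutive values differ by
    more than ``gap``; groups with fewer than ``min_size`` members are not
    counted.
    """
    if gap <= 0:
        raise ValueError(f"gap must be positive, got {gap}")
    x = np.sort(np.asarray(opinions, dtype=np.float64))
    if x.size == 0:
        return 0
    boundaries = np.flatnonzero(np.diff(x) > gap)
    sizes = np.diff(np.concatenate(([0], boundaries + 1, [x.size])))
    return int(np.sum(sizes >= min_size))


def is_pea(opinions) -> bool:
    """Pro-environmental agreement: mean opinion >= 4/6 (at least
    "concerned" on average) and dispersion <= 0.1 (largely agreeing).
    Both comparisons are non-strict."""
    x = _as_opinions(opinions, 2)
    return bool(x.mean() >= PEA_MEAN_THRESHOLD
                and np.std(x) <= PEA_DISPERSION_THRESHOLD)


def summary_row(step: int, opinions) -> dict:
    """One summary-table row; kurtosis is NaN where undefined."""
    x = _as_opinions(opinions, 2)
    try:
        kurt = excess_kurtosis(x)
    except (ZeroDispersionError, ValueError):
        kurt = float("nan")
    return {"step": int(step), "mean": float(x.mean()),
            "dispersion": dispersion(x), "kurtosis": kurt,
            "n_clusters": count_clusters(x)}


def summary_table(snapshot_steps, snapshot_matrix) -> pd.DataFrame:
    """Per-snapshot summary series (step, mean, dispersion, kurtosis,
    n_clusters), recomputable from the snapshots."""
    rows = [summary_row(s, snapshot_matrix[i])
            for i, s in enumerate(snapshot_steps)]
    return pd.DataFrame(rows)
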