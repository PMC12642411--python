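"""Insertion-age inference by simulation grid search and an
establishment-conditioned drift test for trait frequency.

The age of an insertion is estimated by simulating carrier-class variation at
each candidate insertion time T (conditioned on the insertion surviving to
the present, since the observed data exist only because it did), summarising
each replicate as a vector of per-window segregating sites over the flanking
sequence, and taking the grid point whose replicates lie closest (Euclidean
distance by default) to the observed summary.

The drift test asks whether the observed trait (carrier) frequency is
unexpectedly high given the insertion's age: forward Wright-Fisher replicates
are started from one copy at time T, those that establish (frequency > 0 at
present) form the conditional null for the dominant-trait carrier frequency
1 - (1 - p)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Demography
from .popgen import segregating_sites
from .wright_fisher import (
    carrier_genealogy,
    drop_mutations,
    final_allele_counts,
    surviving_trajectories,
)

__all__ = [
    "summarize_observed",
    "grid_search_insertion_time",
    "GridSearchResult",
    "establishment_frequency_test",
    "FrequencyTestResult",
]


def summarize_observed(
    carrier_alignment: list[str], window: int = 5000
) -> np.ndarray:
    """Observed summary vector: per-window segregating sites over the carrier
    flanking alignment, with the total appended."""
    if len(carrier_alignment) < 2:
        raise ValueError("need at least two carrier haplotypes")
    length = len(carrier_alignment[0])
    values = [
        segregating_sites([s[start : min(start + window, length)] for s in carrier_alignment])
        for start in range(0, length, window)
    ]
    return np.asarray(values + [sum(values)], dtype=float)


def _replicate_summary(
    positions: np.ndarray,
    carriers: list[np.ndarray],
    n_tips: int,
    flank_length: int,
    window: int,
) -> np.ndarray:
    """Window segregating-site vector of one simulated carrier sample."""
    n_windows = -(-flank_length // window)
    counts = np.zeros(n_windows + 1)
    for pos, tips in zip(positions, carriers):
        if 0 < tips.size < n_tips:  # segregating among the carriers
            counts[pos // window] += 1
            counts[-1] += 1
    return counts


@dataclass
class GridSearchResult:
    """Grid of candidate insertion times with replicate distance summaries."""

    grid: np.ndarray
    mean_distance: np.ndarray
    distances: pd.DataFrame
    argmin_time: int
    n_replicates: int

    def __post_init__(self) -> None:
        best = self.mean_distance.min()
        if self.mean_distance[np.searchsorted(self.grid, self.argmin_time)] != best:
            raise ValueError("argmin_time does not attain the minimal mean distance")

    def times_within(self, tolerance: float) -> np.ndarray:
        """Grid points whose mean distance is within ``tolerance`` of the
        minimum (an upper-bound summary for the insertion time)."""
        return self.grid[self.mean_distance <= self.mean_distance.min() + tolerance]


def grid_search_insertion_time(
    observed_summary: np.ndarray,
    demography: Demography,
    mu: float,
    flank_length: int,
    n_carriers: int,
    grid: list[int] | np.ndarray,
    reps: int = 200,
    window: int = 5000,
    distance: str = "euclidean",
    seed: int = 0,
    retry_factor: int = 10_000,
) -> GridSearchResult:
    """Point estimate of the insertion time by simulation grid search.

    For each candidate time T, ``reps`` replicates of the carrier-class
    simulation are run conditioned on survival to the present (rejection
    sampling capped at ``retry_factor * reps`` raw trajectories per grid
    point); each replicate's window-S summary is compared with the observed
    one. Ties in the argmin go to the smallest T.
    """
    grid = np.sort(np.asarray(grid, dtype=int))
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if reps < 10:
        raise ValueError("need at least 10 replicates per grid point")
    observed = np.asarray(observed_summary, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    means = np.empty(grid.size)
    for gi, t_ins in enumerate(grid):
        trajectories = surviving_trajectories(
            demography,
            int(t_ins),
            reps,
            rng,
            min_final=n_carriers,
            max_raw=retry_factor * reps,
        )
        for r in range(reps):
            tree = carrier_genealogy(trajectories[r], n_carriers, rng)
            positions, carriers = drop_mutations(tree, mu, flank_length, rng)
            summary = _replicate_summary(
                positions, carriers, n_carriers, flank_length, window
            )
            if summary.size != observed.size:
                raise ValueError(
                    "summary length mismatch: observed uses a different "
                    "window/flank configuration"
                )
            diff = summary - observed
            if distance == "euclidean":
                d = float(np.sqrt((diff**2).sum()))
            elif distance == "l1":
                d = float(np.abs(diff).sum())
            elif distance == "total_s":
                d = float(abs(diff[-1]))
            else:
                raise ValueError(f"unknown distance: {distance}")
            rows.append({"T": int(t_ins), "replicate": r, "distance": d})
        means[gi] = np.mean([row["distance"] for row in rows[-reps:]])
    argmin_time = int(grid[int(np.argmin(means))])  # first = smallest T on ties
    return GridSearchResult(
        grid=grid,
        mean_distance=means,
        distances=pd.DataFrame(rows),
        argmin_time=argmin_time,
        n_replicates=int(reps),
    )


@dataclass
class FrequencyTestResult:
    """Establishment-conditioned drift test for the trait frequency."""

    observed_carrier_freq: float
    established_freqs: np.ndarray
    p_value: float
    n_total: int
    n_established: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


def establishment_frequency_test(
    demography: Demography,
    t_insertion: int,
    observed_carrier_freq: float,
    reps: int = 1000,
    seed: int = 0,
) -> FrequencyTestResult:
    """One-sided drift test of the trait frequency, conditional on
    establishment.

    ``reps`` forward Wright-Fisher replicates start from one copy at time T;
    a replicate is established when its allele frequency is positive at
    present. Under dominance the trait (carrier) frequency of an established
    replicate with allele frequency p is 1 - (1 - p)^2. The one-sided p-value
    is (1 + #{established with carrier freq >= observed}) / (1 + #established).
    """
    if not 0.0 <= observed_carrier_freq <= 1.0:
        raise ValueError("observed carrier frequency must be in [0,1]")
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    counts = final_allele_counts(demography, t_insertion, reps, rng)
    established = counts[counts > 0]
    if established.size == 0:
        raise RuntimeError("no replicate established; increase reps")
    p = established / (2.0 * demography.size_at(0))
    carrier_freqs = 1.0 - (1.0 - p) ** 2
    n_ge = int((carrier_freqs >= observed_carrier_freq).sum())
    p_value = (1 + n_ge) / (1 + established.size)
    return FrequencyTestResult(
        observed_carrier_freq=observed_carrier_freq,
        established_freqs=carrier_freqs,
        p_value=p_value,
        n_total=reps,
        n_established=int(established.size),
    )
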