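"""Cross-sectional study design: allocation and current-status tabulation.

An aggregated current-status (ACS) study observes each subject exactly
once, at one of K monitoring ages, and records only the model state
occupied at that age.  The resulting K x 4 count table is the entire
data set: no individual follow-up exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .microsim import LifeCourse, state_at

__all__ = [
    "ACSTable",
    "STATE_LABELS",
    "allocate_cross_sections",
    "tabulate_acs",
    "observed_fractions",
]

#: Column labels of the count table, in state order 1-4.
STATE_LABELS = ("S", "C", "D0", "D1")


@dataclass(frozen=True)
class ACSTable:
    """Counts of subjects per state at each monitoring age.

    ``counts[k, j]`` is the number of subjects observed at age
    ``times[k]`` in state ``j+1`` (columns ordered S, C, D0, D1).
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (times.size, 4):
            raise ValueError("counts must have shape (len(times), 4)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.array_equal(counts, counts.astype(np.int64)):
                raise ValueError("counts must be integers")
        counts = counts.astype(np.int64).reshape(times.size, 4)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("monitoring times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        """Per-cross-section sample sizes ``N_k``."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def allocate_cross_sections(
    n: int, k: int, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Assign each of ``n`` subjects to one of ``k`` cross-sections.

    Allocation is iid uniform over the cross-sections (so the per-section
    totals are multinomial, not a forced equal split).  Returns an array
    of ``n`` zero-based cross-section indices, one per subject in id
    order.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if k < 1:
        raise ValueError("k must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.integers(0, k, size=n)


def tabulate_acs(
    population: Sequence[LifeCourse],
    assignment: Sequence[int],
    times: Sequence[float],
) -> ACSTable:
    """Count subjects per state at their assigned monitoring age."""
    times = np.asarray(times, dtype=float)
    assignment = np.asarray(assignment)
    if assignment.shape != (len(population),):
        raise ValueError(
            f"assignment covers {assignment.size} subjects but the "
            f"population has {len(population)}"
        )
    if assignment.size and (
        assignment.min() < 0 or assignment.max() >= times.size
    ):
        raise ValueError("assignment indexes a non-existent cross-section")
    counts = np.zeros((times.size, 4), dtype=np.int64)
    for course, k in zip(population, assignment):
        j = state_at(course, float(times[k]))
        counts[k, j - 1] += 1
    return ACSTable(times=times, counts=counts)


def observed_fractions(acs: ACSTable) -> np.ndarray:
    """Per-cross-section state fractions ``p_obs[k, j] = x[k, j] / N_k``."""
    totals = acs.row_totals
    if np.any(totals == 0):
        empty = acs.times[totals == 0]
        raise ValueError(
            f"cross-section(s) at t={empty.tolist()} contain no subjects; "
            "fractions are undefined there"
        )
    return acs.counts / totals[:, None]
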