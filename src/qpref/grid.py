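"""Forced-distribution Q-sorting grids.

A Q-sorting grid is the fixed, quasi-normal arrangement of rank slots into
which participants must place every stimulus: each rank value (e.g. -5 ... +5)
has a fixed number of slots, with more slots in the middle of the continuum
than in the tails.  Because every participant fills the same grid, every
completed sort is a permutation of the same rank multiset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["QGrid", "default_grid"]


@dataclass(frozen=True)
class QGrid:
    """A forced rank distribution: ordered rank values with slot counts.

    Parameters
    ----------
    rank_values : tuple of int
        Strictly increasing rank values (unitless ranks, e.g. -5 ... +5).
    multiplicities : tuple of int
        Number of slots per rank value; all positive.  The total number of
        slots equals the number of stimuli the grid accommodates.
    """

    rank_values: tuple[int, ...]
    multiplicities: tuple[int, ...]

    def __post_init__(self) -> None:
        rv = tuple(int(r) for r in self.rank_values)
        mult = tuple(int(m) for m in self.multiplicities)
        object.__setattr__(self, "rank_values", rv)
        object.__setattr__(self, "multiplicities", mult)
        if len(rv) != len(mult):
            raise ValueError("rank_values and multiplicities differ in length")
        if len(rv) == 0:
            raise ValueError("empty grid")
        if any(m < 1 for m in mult):
            raise ValueError("multiplicities must be positive")
        if any(b <= a for a, b in zip(rv, rv[1:])):
            raise ValueError("rank_values must be strictly increasing")

    @property
    def n_stimuli(self) -> int:
        return int(sum(self.multiplicities))

    @property
    def max_rank(self) -> int:
        return self.rank_values[-1]

    def multiset(self) -> np.ndarray:
        """All slot ranks expanded with multiplicity, ascending."""
        return np.repeat(self.rank_values, self.multiplicities)

    def rank_sum(self) -> int:
        """Sum of all slot ranks (every valid sort's column sum)."""
        return int(np.dot(self.rank_values, self.multiplicities))

    def top_sum(self, k: int) -> int:
        """Sum of the k largest slot ranks (taken with multiplicity)."""
        if not 0 <= k <= self.n_stimuli:
            raise ValueError(f"k={k} outside [0, {self.n_stimuli}]")
        return int(self.multiset()[::-1][:k].sum())

    def matches(self, ranks) -> bool:
        """True iff `ranks` is a permutation of the grid multiset."""
        ranks = np.asarray(ranks)
        return ranks.size == self.n_stimuli and np.array_equal(
            np.sort(ranks), self.multiset()
        )

    def is_symmetric(self) -> bool:
        return (
            self.multiplicities == self.multiplicities[::-1]
            and all(a + b == 0 for a, b in zip(self.rank_values, self.rank_values[::-1]))
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"ranks": list(self.rank_values), "counts": list(self.multiplicities)}
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "QGrid":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(tuple(obj["ranks"]), tuple(obj["counts"]))


def default_grid(n_stimuli: int, n_ranks: int) -> QGrid:
    """Build the canonical symmetric, unimodal grid for a study size.

    Slot counts are allocated to the ``n_ranks`` rank values (centered at 0)
    proportionally to a triangular weight that decreases from the center
    outwards, with at least one slot per rank and the integer remainder
    distributed center-out.  For 32 stimuli over 11 ranks this yields the
    canonical quasi-normal grid (1, 2, 3, 3, 4, 6, 4, 3, 3, 2, 1).

    Parameters
    ----------
    n_stimuli : int
        Total number of slots (positive).
    n_ranks : int
        Number of distinct rank values; must be odd and <= n_stimuli.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be positive")
    if n_ranks < 1 or n_ranks % 2 == 0:
        raise ValueError("n_ranks must be an odd positive integer")
    if n_ranks > n_stimuli:
        raise ValueError("n_ranks may not exceed n_stimuli (every rank needs a slot)")

    half = n_ranks // 2  # max distance from center
    # triangular weights by distance from center: w(d) = half + 1 - d
    weights = np.array([half + 1 - d for d in range(half + 1)], dtype=float)
    total_w = weights[0] + 2 * weights[1:].sum()
    expected = n_stimuli * weights / total_w
    counts = np.maximum(np.floor(expected).astype(int), 1)

    def total(c):
        return int(c[0] + 2 * c[1:].sum())

    # distribute the remainder largest-fractional-part first; a symmetric
    # pair consumes 2 slots, the center slot consumes 1
    # allocate by deficit so slots already lifted to the minimum of 1
    # (tails with expected < 1) come last
    frac_order = np.argsort(-(expected - counts))
    remainder = n_stimuli - total(counts)
    if remainder < 0:
        raise ValueError(f"infeasible grid: {n_stimuli} stimuli over {n_ranks} ranks")
    while remainder > 0:
        placed = False
        for d in frac_order:
            if remainder == 0:
                break
            cost = 1 if d == 0 else 2
            if cost <= remainder:
                counts[d] += 1
                remainder -= cost
                placed = True
        if not placed:  # remainder 1 but only pairs affordable: center takes it
            counts[0] += 1
            remainder -= 1
    # enforce unimodality: largest counts nearest the center
    counts = np.sort(counts)[::-1]

    mult = tuple(int(x) for x in np.concatenate([counts[::-1][:-1], counts]))
    ranks = tuple(range(-half, half + 1))
    grid = QGrid(ranks, mult)
    assert grid.n_stimuli == n_stimuli
    return grid
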