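"""Enumeration of joint edge-type assignments of a subgraph.

A *realization* assigns one of K interaction types to every incoming edge of
a node; a subgraph with in-degree g has exactly ``K**g`` realizations. The
enumeration is the mixed-radix (base-K) expansion of the realization index
with slot 0 as the most significant digit, so index 0 is "all edges type 0"
and the order is lexicographic in the assignment tuple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RealizationTable", "enumerate_realizations"]

DEFAULT_CAP = 65536


@dataclass
class RealizationTable:
    """Complete, deterministically ordered table of subgraph realizations."""

    n_types: int
    degree: int
    assignments: np.ndarray  # (K**degree, degree) int

    @property
    def n_realizations(self) -> int:
        return self.assignments.shape[0]

    def phi(self, realization: int, slot: int) -> int:
        """Type of the edge in neighbor slot ``slot`` under ``realization``."""
        return int(self.assignments[realization, slot])

    @property
    def one_hot(self) -> np.ndarray:
        """(R, degree, K) indicator; cached for vectorized contractions."""
        if not hasattr(self, "_one_hot"):
            oh = np.zeros((self.n_realizations, self.degree, self.n_types))
            r = np.arange(self.n_realizations)
            for s in range(self.degree):
                oh[r, s, self.assignments[:, s]] = 1.0
            self._one_hot = oh
        return self._one_hot


def enumerate_realizations(n_types: int, degree: int,
                           cap: int = DEFAULT_CAP) -> RealizationTable:
    """Enumerate all ``K**degree`` joint type assignments.

    Raises if the table would exceed ``cap`` entries — exact collective
    inference scales as O(K^degree) and is meant for sparse neighborhoods;
    use the evolving (sequential) path for denser ones.
    """
    if n_types < 1 or degree < 1:
        raise ValueError("need n_types >= 1 and degree >= 1")
    size = n_types**degree
    if size > cap:
        raise ValueError(
            f"{n_types}^{degree} = {size} realizations exceeds the cap {cap}; "
            "exact enumeration is infeasible for this in-degree — consider the "
            "sequential (evolving) inference path or a smaller neighborhood"
        )
    idx = np.arange(size)
    assign = np.empty((size, degree), dtype=int)
    for s in range(degree - 1, -1, -1):
        assign[:, s] = idx % n_types
        idx = idx // n_types
    return RealizationTable(n_types, degree, assign)
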