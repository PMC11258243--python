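"""Containers for trajectories, interaction graphs and stacked datasets.

Conventions used throughout the package:

* a directed edge ``(i, j)`` means "node j acts on node i" — i is the
  *receiver*;
* interaction types are 0-based integers ``0..K-1``;
* the ground-truth state increment at step ``t`` is the finite difference
  ``(v[t+1] - v[t]) / dt`` (for time series, ``x[t+1] - x[t]``), defined for
  ``t = 0..T-2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParticleTrajectory",
    "InteractionGraph",
    "ParticleDataset",
    "SeriesDataset",
    "complete_edges",
]


def complete_edges(n_nodes: int) -> np.ndarray:
    """All ordered pairs ``(receiver, sender)`` of a complete directed graph,
    in lexicographic order."""
    e = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if j != i]
    return np.array(e, dtype=int)


@dataclass
class InteractionGraph:
    """Static directed interaction graph with optional ground-truth types.

    ``edges`` is (E, 2) of ``(receiver, sender)``; ``true_types`` is (E,)
    integers in ``0..K-1`` and is only ever used for evaluation, never by the
    inference algorithms.
    """

    n_nodes: int
    edges: np.ndarray
    true_types: np.ndarray | None = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        if self.true_types is not None:
            self.true_types = np.asarray(self.true_types, dtype=int)
            if self.true_types.shape != (len(self.edges),):
                raise ValueError("true_types must align with edges")

    def incoming(self, i: int) -> np.ndarray:
        """Indices into ``edges`` of the incoming edges of node ``i``,
        ordered by sender index (the canonical slot order)."""
        idx = np.nonzero(self.edges[:, 0] == i)[0]
        return idx[np.argsort(self.edges[idx, 1], kind="stable")]

    @property
    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)


@dataclass
class ParticleTrajectory:
    """States of an N-particle system over T time steps in d dimensions.

    ``increments`` holds the ground-truth accelerations
    ``(velocities[t+1] - velocities[t]) / dt`` and is derived on construction
    when not supplied.
    """

    positions: np.ndarray  # (T, N, d)
    velocities: np.ndarray  # (T, N, d)
    masses: np.ndarray  # (N,)
    dt: float
    increments: np.ndarray | None = None  # (T-1, N, d)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must share shape")
        if self.positions.ndim != 3 or self.positions.shape[0] < 2:
            raise ValueError("expected (T, N, d) arrays with T >= 2")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        if self.increments is None:
            self.increments = np.diff(self.velocities, axis=0) / self.dt
        else:
            self.increments = np.asarray(self.increments, dtype=float)

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def ndim(self) -> int:
        return self.positions.shape[2]


@dataclass
class ParticleDataset:
    """A stack of simulations sharing one edge layout.

    All simulations have the same number of particles and the same directed
    edge set (e.g. the complete graph); the ground-truth edge types vary per
    simulation. This is the input container for the fixed-topology model.
    """

    positions: np.ndarray  # (S, T, N, d)
    velocities: np.ndarray  # (S, T, N, d)
    masses: np.ndarray  # (S, N)
    dt: float
    edges: np.ndarray  # (E, 2)
    true_types: np.ndarray  # (S, E)
    increments: np.ndarray = field(default=None)  # (S, T-1, N, d)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.true_types = np.asarray(self.true_types, dtype=int)
        if self.increments is None:
            self.increments = np.diff(self.velocities, axis=1) / self.dt
        else:
            self.increments = np.asarray(self.increments, dtype=float)

    @property
    def n_sims(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[2]

    @property
    def ndim(self) -> int:
        return self.positions.shape[3]

    def graph(self, sim: int) -> InteractionGraph:
        return InteractionGraph(self.n_particles, self.edges, self.true_types[sim])

    def features(self) -> np.ndarray:
        """Node features [position, velocity, mass] aligned with the
        increment targets: shape (S, T-1, N, 2d+1)."""
        pos = self.positions[:, :-1]
        vel = self.velocities[:, :-1]
        m = np.broadcast_to(
            self.masses[:, None, :, None], pos.shape[:3] + (1,)
        )
        return np.concatenate([pos, vel, m], axis=-1)

    def targets(self) -> np.ndarray:
        return self.increments

    def subset(self, sims) -> "ParticleDataset":
        sims = np.asarray(sims)
        return ParticleDataset(
            self.positions[sims],
            self.velocities[sims],
            self.masses[sims],
            self.dt,
            self.edges,
            self.true_types[sims],
            self.increments[sims],
        )


@dataclass
class SeriesDataset:
    """Multivariate time series with a shared candidate edge layout.

    For causality discovery the node feature is the series value itself and
    the increment is the first difference of the series.
    """

    values: np.ndarray  # (S, T, N)
    edges: np.ndarray  # (E, 2)
    true_types: np.ndarray  # (S, E); 1 = causal link present, 0 = absent

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.true_types = np.asarray(self.true_types, dtype=int)

    @property
    def n_sims(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[2]

    def features(self) -> np.ndarray:
        return self.values[:, :-1, :, None]

    def targets(self) -> np.ndarray:
        return np.diff(self.values, axis=1)[..., None]

    def subset(self, sims) -> "SeriesDataset":
        sims = np.asarray(sims)
        return SeriesDataset(self.values[sims], self.edges, self.true_types[sims])
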