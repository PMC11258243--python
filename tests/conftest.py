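"""Shared fixtures: tiny systems used across the suite.

Everything is generated programmatically and seeded; nothing is read from
disk.
"""

import numpy as np
import pytest
from hypothesis import settings

from relinf.data import InteractionGraph, ParticleDataset, complete_edges
from relinf.simulators import SPRING_TYPES_K2, SpringSpec, simulate_particles

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def tiny_spring_dataset():
    """3 particles, complete graph, 2 spring types, 4 time steps — small
    enough for brute-force oracles."""
    edges = complete_edges(3)
    tt = np.array([0, 1, 0, 0, 1, 0])  # symmetric pair types
    graph = InteractionGraph(3, edges, tt)
    traj = simulate_particles(
        SpringSpec(SPRING_TYPES_K2), graph, n_steps=4, dt=0.01, seed=7
    )
    return ParticleDataset(
        traj.positions[None], traj.velocities[None], traj.masses[None],
        traj.dt, edges, tt[None],
    )


@pytest.fixture(scope="session")
def small_spring_dataset():
    """One 5-particle spring simulation (complete graph), 30 steps."""
    from relinf.simulators import spring_dataset

    return spring_dataset(3, 5, SPRING_TYPES_K2, n_steps=30, seed=11)
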