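"""Synthetic benchmark systems with known ground-truth interaction types.

Four generators are provided, each a pure function of its spec and seed:

* heterogeneous springs — complete graphs of particles coupled by springs
  whose (stiffness, balance length) pair differs per edge type;
* signed charges — inverse-square attraction/repulsion induced by per-particle
  charges of +/-1 (the two effective edge types);
* crystallization — two particle kinds interacting through a Lennard-Jones
  core plus an attractive (same kind) or repulsive (different kind)
  dipole-dipole tail, with a local, hence time-evolving, interaction graph;
* first-order vector autoregression — linear stochastic dynamics on a known
  causal graph (edge types: link present / absent).

Force-direction convention: every pairwise force below is the force exerted
ON the receiver ``i`` of edge ``(i, j)`` BY the sender ``j``; a stretched
spring pulls i toward j and like charges push i away from j.

Integration uses semi-implicit (symplectic) Euler,
``v[t+1] = v[t] + a[t] dt``, ``r[t+1] = r[t] + v[t+1] dt``, which keeps
oscillatory spring systems stable at dt = 0.01 and makes the finite-difference
increment ``(v[t+1] - v[t]) / dt`` recover the applied acceleration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    InteractionGraph,
    ParticleDataset,
    ParticleTrajectory,
    SeriesDataset,
    complete_edges,
)

__all__ = [
    "SpringSpec",
    "ChargeSpec",
    "CrystallizationSpec",
    "VARSpec",
    "SPRING_TYPES_K2",
    "SPRING_TYPES_K4",
    "spring_pairwise_force",
    "charge_pairwise_force",
    "crystallization_potential",
    "crystallization_pairwise_force",
    "simulate_particles",
    "spring_dataset",
    "charge_dataset",
    "charge_edge_types",
    "simulate_crystallization",
    "evolving_spring_benchmark",
    "build_knn_graph",
    "knn_neighbors",
    "simulate_var",
    "var_dataset",
    "ground_truth_increments",
    "spring_total_energy",
]

# Benchmark spring types: (stiffness k, balance length L) per type.
SPRING_TYPES_K2 = ((0.5, 2.0), (2.0, 1.0))
SPRING_TYPES_K4 = ((0.5, 2.0), (2.0, 1.0), (2.5, 1.0), (2.5, 2.0))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SpringSpec:
    """Heterogeneous spring system; ``types[z] = (k_z, L_z)``."""

    types: tuple = SPRING_TYPES_K2

    def __post_init__(self):
        if len(self.types) < 1 or any(k <= 0 for k, _ in self.types):
            raise ValueError("need >= 1 spring type with positive stiffness")

    @property
    def n_types(self) -> int:
        return len(self.types)


@dataclass
class ChargeSpec:
    """Signed-charge system; ``charges`` are +/-1 per particle."""

    charges: np.ndarray
    c: float = 1.0
    delta: float = 0.01

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isin(self.charges, (-1.0, 1.0))):
            raise ValueError("charges must be +1 or -1")
        if self.c <= 0 or self.delta <= 0:
            raise ValueError("c and delta must be positive")

    @property
    def n_types(self) -> int:
        return 2


@dataclass
class CrystallizationSpec:
    """Two particle kinds with LJ + dipole-dipole interactions.

    ``kinds`` is a 0/1 vector; same-kind pairs attract (dipole potential
    -C r^-4), different-kind pairs repel (+C r^-4), and the LJ core acts on
    every nearby pair. Interactions act only within ``cutoff``; the inference
    input graph connects each particle to its ``n_neighbors`` closest
    neighbors.
    """

    kinds: np.ndarray
    sigma_lj: float = 0.3
    eps_lj: float = 1e-5
    C: float = 0.02
    # the cutoff is matched to the nearest-neighbor input graph: at ~unit
    # number density a 1.5 cutoff keeps the k-nearest-neighbor edge set an
    # accurate summary of the interacting pairs, so the unmodeled far-field
    # dipole tail stays well below the near-field discrimination signal
    cutoff: float = 1.5
    n_neighbors: int = 5

    def __post_init__(self):
        self.kinds = np.asarray(self.kinds, dtype=int)
        for name in ("sigma_lj", "eps_lj", "C", "cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class VARSpec:
    """First-order vector autoregression x[t] = A x[t-1] + eps.

    ``adjacency[i, j] = 1`` means series j drives series i; ``coefficients``
    carries the matching entries of A and must vanish off the adjacency.
    Stationarity requires the spectral radius of A below 0.98.
    """

    adjacency: np.ndarray
    coefficients: np.ndarray
    noise_sd: float = 0.1
    n_steps: int = 200

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.adjacency.shape != self.coefficients.shape:
            raise ValueError("adjacency and coefficients must share shape")
        if np.any((self.adjacency == 0) & (self.coefficients != 0)):
            raise ValueError("coefficients must be zero off the adjacency")
        rho = np.max(np.abs(np.linalg.eigvals(self.coefficients)))
        if rho >= 0.98:
            raise ValueError(f"unstable coefficient matrix (spectral radius {rho:.3f})")

    @property
    def n_series(self) -> int:
        return self.adjacency.shape[0]


# ---------------------------------------------------------------------------
# pairwise force laws
# ---------------------------------------------------------------------------


def _unit(pos_i, pos_j):
    diff = np.asarray(pos_j, dtype=float) - np.asarray(pos_i, dtype=float)
    r = np.linalg.norm(diff)
    if r == 0.0:
        raise ValueError("coincident positions: pairwise force is undefined")
    return diff / r, r


def spring_pairwise_force(pos_i, pos_j, k: float, L: float) -> np.ndarray:
    """Spring force ``k (r - L) n_ij`` on the receiver i.

    Positive when stretched (r > L): i is pulled toward j. Exactly
    antisymmetric under exchanging i and j.
    """
    n_ij, r = _unit(pos_i, pos_j)
    return k * (r - L) * n_ij


def charge_pairwise_force(pos_i, pos_j, q_i, q_j, c: float = 1.0, delta: float = 0.01) -> np.ndarray:
    """Softened Coulomb force ``-c q_i q_j n_ij / (r + delta)^2`` on i.

    Like charges push i away from j; the softening ``delta`` enters the
    denominator only, the direction uses the raw separation.
    """
    if q_i not in (-1, 1) or q_j not in (-1, 1):
        raise ValueError("charges must be +1 or -1")
    n_ij, r = _unit(pos_i, pos_j)
    return -c * q_i * q_j * n_ij / (r + delta) ** 2


def crystallization_potential(r, same_type: bool, sigma_lj=0.3, eps_lj=1e-5, C=0.02):
    """LJ plus dipole pair potential: ``V_LJ(r) -/+ C r^-4`` (same/different)."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma_lj / r) ** 6
    v_lj = 4.0 * eps_lj * (sr6**2 - sr6)
    v_dip = -C / r**4 if same_type else C / r**4
    return v_lj + v_dip


def crystallization_pairwise_force(pos_i, pos_j, same_type: bool,
                                   sigma_lj=0.3, eps_lj=1e-5, C=0.02) -> np.ndarray:
    """Force ``-grad_{r_i} [V_LJ + V_dip]`` on i; equals ``V'(r) n_ij``."""
    n_ij, r = _unit(pos_i, pos_j)
    sr6 = (sigma_lj / r) ** 6
    dv_lj = 4.0 * eps_lj * (-12.0 * sr6**2 + 6.0 * sr6) / r
    dv_dip = 4.0 * C / r**5 if same_type else -4.0 * C / r**5
    return (dv_lj + dv_dip) * n_ij


# ---------------------------------------------------------------------------
# fixed-topology integration
# ---------------------------------------------------------------------------


def _edge_forces(spec, graph: InteractionGraph, pos: np.ndarray) -> np.ndarray:
    """Vectorized per-edge forces on the receivers at one time step."""
    recv, send = graph.edges[:, 0], graph.edges[:, 1]
    diff = pos[send] - pos[recv]
    r = np.linalg.norm(diff, axis=-1)
    if np.any(r == 0.0):
        raise ValueError("coincident particles: degenerate geometry")
    n_ij = diff / r[:, None]
    if isinstance(spec, SpringSpec):
        kL = np.array(spec.types, dtype=float)[graph.true_types]
        return (kL[:, 0] * (r - kL[:, 1]))[:, None] * n_ij
    if isinstance(spec, ChargeSpec):
        qq = spec.charges[recv] * spec.charges[send]
        return (-spec.c * qq / (r + spec.delta) ** 2)[:, None] * n_ij
    raise TypeError(f"unsupported spec for static integration: {type(spec)!r}")


def simulate_particles(spec, graph: InteractionGraph, n_steps: int = 100,
                       dt: float = 0.01, seed: int = 0, d: int = 2,
                       masses: np.ndarray | None = None,
                       init: tuple | None = None) -> ParticleTrajectory:
    """Integrate Newtonian dynamics on a static interaction graph.

    Masses default to exp(U(-1, 1)) (log-uniform over [1/e, e]); initial
    positions and velocities default to standard Gaussians. Bitwise
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    if masses is None:
        masses = np.exp(rng.uniform(-1.0, 1.0, size=n))
    masses = np.asarray(masses, dtype=float)
    if init is None:
        pos0 = rng.standard_normal((n, d))
        vel0 = rng.standard_normal((n, d))
    else:
        pos0, vel0 = (np.asarray(a, dtype=float) for a in init)

    positions = np.empty((n_steps, n, d))
    velocities = np.empty((n_steps, n, d))
    positions[0], velocities[0] = pos0, vel0
    recv = graph.edges[:, 0]
    for t in range(n_steps - 1):
        forces = _edge_forces(spec, graph, positions[t])
        net = np.zeros((n, d))
        np.add.at(net, recv, forces)
        acc = net / masses[:, None]
        velocities[t + 1] = velocities[t] + acc * dt
        positions[t + 1] = positions[t] + velocities[t + 1] * dt
        if not np.all(np.isfinite(positions[t + 1])):
            raise FloatingPointError(f"simulation blew up at step {t + 1}")
    return ParticleTrajectory(positions, velocities, masses, dt)


def ground_truth_increments(trajectory: ParticleTrajectory) -> np.ndarray:
    """Finite-difference accelerations ``(v[t+1] - v[t]) / dt``; also stored
    on the trajectory."""
    inc = np.diff(trajectory.velocities, axis=0) / trajectory.dt
    trajectory.increments = inc
    return inc


def spring_total_energy(spec: SpringSpec, graph: InteractionGraph,
                        trajectory: ParticleTrajectory) -> np.ndarray:
    """Kinetic plus spring potential energy per time step (each undirected
    pair counted once)."""
    kin = 0.5 * np.einsum(
        "n,tnd->t", trajectory.masses, trajectory.velocities**2
    )
    recv, send = graph.edges[:, 0], graph.edges[:, 1]
    once = recv < send
    kL = np.array(spec.types, dtype=float)[graph.true_types[once]]
    diff = trajectory.positions[:, send[once]] - trajectory.positions[:, recv[once]]
    r = np.linalg.norm(diff, axis=-1)
    pot = 0.5 * (kL[:, 0] * (r - kL[:, 1]) ** 2).sum(axis=1)
    return kin + pot


# ---------------------------------------------------------------------------
# dataset builders (study conditions as defaults)
# ---------------------------------------------------------------------------


def spring_dataset(n_sims: int, n_particles: int = 5,
                   types: tuple = SPRING_TYPES_K2, n_steps: int = 100,
                   dt: float = 0.01, seed: int = 0, d: int = 2) -> ParticleDataset:
    """Complete-graph spring simulations with symmetric random edge types.

    Every unordered pair is connected by a spring whose type is drawn
    uniformly from ``types``; both directed edges of a pair share the type.
    """
    rng = np.random.default_rng(seed)
    spec = SpringSpec(types)
    edges = complete_edges(n_particles)
    k = len(types)
    pos, vel, mas, tts = [], [], [], []
    for _ in range(n_sims):
        pair_type = {}
        for i in range(n_particles):
            for j in range(i + 1, n_particles):
                pair_type[(i, j)] = rng.integers(k)
        tt = np.array([pair_type[(min(i, j), max(i, j))] for i, j in edges])
        graph = InteractionGraph(n_particles, edges, tt)
        traj = simulate_particles(
            spec, graph, n_steps=n_steps, dt=dt,
            seed=int(rng.integers(2**31)), d=d,
        )
        pos.append(traj.positions)
        vel.append(traj.velocities)
        mas.append(traj.masses)
        tts.append(tt)
    return ParticleDataset(
        np.stack(pos), np.stack(vel), np.stack(mas), dt, edges, np.stack(tts)
    )


def charge_edge_types(charges: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0 = repulsive (like charges), 1 = attractive (opposite charges)."""
    charges = np.asarray(charges)
    qq = charges[edges[:, 0]] * charges[edges[:, 1]]
    return (qq < 0).astype(int)


def charge_dataset(n_sims: int, n_particles: int = 5, c: float = 1.0,
                   delta: float = 0.01, n_steps: int = 100, dt: float = 0.01,
                   seed: int = 0, d: int = 2) -> ParticleDataset:
    """Complete-graph signed-charge simulations (charges +/-1 uniform)."""
    rng = np.random.default_rng(seed)
    edges = complete_edges(n_particles)
    pos, vel, mas, tts = [], [], [], []
    for _ in range(n_sims):
        charges = rng.choice([-1.0, 1.0], size=n_particles)
        spec = ChargeSpec(charges, c=c, delta=delta)
        tt = charge_edge_types(charges, edges)
        graph = InteractionGraph(n_particles, edges, tt)
        traj = simulate_particles(
            spec, graph, n_steps=n_steps, dt=dt,
            seed=int(rng.integers(2**31)), d=d,
        )
        pos.append(traj.positions)
        vel.append(traj.velocities)
        mas.append(traj.masses)
        tts.append(tt)
    return ParticleDataset(
        np.stack(pos), np.stack(vel), np.stack(mas), dt, edges, np.stack(tts)
    )


# ---------------------------------------------------------------------------
# evolving-topology crystallization
# ---------------------------------------------------------------------------


def knn_neighbors(positions: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Senders of the k nearest neighbors of each node, (N, k), sorted by
    sender index per node; distance ties break toward the lower index."""
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the number of nodes")
    diff = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    out = np.empty((n, n_neighbors), dtype=int)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))  # distance, then index
        out[i] = np.sort(order[:n_neighbors])
    return out


def build_knn_graph(positions: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Directed edge set (N*k, 2) of ``(receiver, sender)`` pairs where every
    node receives exactly ``n_neighbors`` incoming edges from its nearest
    neighbors by Euclidean distance."""
    nbr = knn_neighbors(positions, n_neighbors)
    n, k = nbr.shape
    recv = np.repeat(np.arange(n), k)
    return np.column_stack([recv, nbr.ravel()])


def _crystallization_forces(spec: CrystallizationSpec, pos: np.ndarray) -> np.ndarray:
    """Net force per particle from all pairs within the cutoff."""
    n = pos.shape[0]
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = r_j - r_i
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if np.any(dist == 0.0):
        raise ValueError("coincident particles: degenerate geometry")
    active = dist < spec.cutoff
    sr6 = np.where(active, (spec.sigma_lj / dist) ** 6, 0.0)
    dv_lj = 4.0 * spec.eps_lj * (-12.0 * sr6**2 + 6.0 * sr6) / dist
    same = spec.kinds[:, None] == spec.kinds[None, :]
    dv_dip = np.where(same, 4.0 * spec.C, -4.0 * spec.C) / dist**5
    mag = np.where(active, dv_lj + dv_dip, 0.0)
    unit = diff / dist[..., None]
    return np.einsum("ij,ijd->id", mag, unit)


def simulate_crystallization(spec: CrystallizationSpec, n_steps: int = 500_000,
                             dt: float = 1e-5, downsample: int = 50,
                             seed: int = 0) -> tuple[ParticleTrajectory, np.ndarray]:
    """Crystallization run with unit masses and a local interaction graph.

    Integrates at the raw step ``dt`` and retains every ``downsample``-th
    state; increments are computed on the retained grid. Initial positions
    are a jittered square lattice of ~unit number density — random uniform
    placement can start particles inside the steep Lennard-Jones core, which
    produces unphysical force spikes; the lattice keeps every initial pair
    separation well outside it. Initial velocities are N(0, 0.1^2). Returns
    the downsampled trajectory and the per-step nearest-neighbor sender
    array (T, N, n_neighbors) for the retained steps.
    """
    rng = np.random.default_rng(seed)
    n = len(spec.kinds)
    side = int(np.ceil(np.sqrt(n)))
    grid = np.stack(
        np.meshgrid(np.arange(side), np.arange(side)), axis=-1
    ).reshape(-1, 2)[:n].astype(float)
    pos = grid + rng.uniform(-0.1, 0.1, size=(n, 2))
    vel = rng.normal(0.0, 0.1, size=(n, 2))
    masses = np.ones(n)

    keep = range(0, n_steps, downsample)
    positions = np.empty((len(keep), n, 2))
    velocities = np.empty((len(keep), n, 2))
    ki = 0
    for t in range(n_steps):
        if t % downsample == 0:
            positions[ki], velocities[ki] = pos, vel
            ki += 1
        force = _crystallization_forces(spec, pos)
        vel = vel + force * dt  # unit mass
        pos = pos + vel * dt
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError(f"simulation blew up at raw step {t + 1}")
    traj = ParticleTrajectory(positions, velocities, masses, dt * downsample)
    neighbors = np.stack(
        [knn_neighbors(positions[t], spec.n_neighbors) for t in range(len(keep))]
    )
    return traj, neighbors


def evolving_spring_benchmark(n_nodes: int = 12, n_traj: int = 8,
                              n_steps: int = 100, n_neighbors: int = 3,
                              types: tuple = ((1.0, 2.0), (2.0, 0.5)),
                              dt: float = 0.01, seed: int = 0):
    """Small benchmark for evolving-topology inference with known types.

    A single system of heterogeneous springs (one fixed type per unordered
    pair) observed over several independent trajectories, concatenated in
    time; at every step only each particle's ``n_neighbors`` closest
    neighbors act on it, so the active edge set changes while the pair types
    do not. The default spring types produce forces of opposite sign over
    the nearest-neighbor distance range, and several trajectories give every
    pair enough active steps to be identifiable.

    Returns ``(features, targets, neighbors, masses, true_types)`` with
    ``features`` (T, N, 2d+1), ``targets`` (T, N, d) increments restricted
    to the active edges, ``neighbors`` (T, N, n_neighbors) and
    ``true_types`` a dict mapping unordered pairs to their type.
    """
    rng = np.random.default_rng(seed)
    edges = complete_edges(n_nodes)
    k = len(types)
    pair_type = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            pair_type[(i, j)] = int(rng.integers(k))
    tt = np.array([pair_type[(min(i, j), max(i, j))] for i, j in edges])
    graph = InteractionGraph(n_nodes, edges, tt)
    spec = SpringSpec(types)
    kL = np.array(types, dtype=float)
    feats, nbrs, targs = [], [], []
    masses = None
    for _ in range(n_traj):
        traj = simulate_particles(
            spec, graph, n_steps=n_steps + 1, dt=dt,
            seed=int(rng.integers(2**31)), masses=masses,
        )
        masses = traj.masses  # one system: masses shared across trajectories
        fe = np.concatenate(
            [traj.positions[:-1], traj.velocities[:-1],
             np.broadcast_to(traj.masses[None, :, None],
                             traj.positions[:-1].shape[:2] + (1,))],
            axis=-1,
        )
        nb = np.stack(
            [knn_neighbors(traj.positions[t], n_neighbors)
             for t in range(n_steps)]
        )
        tg = np.zeros((n_steps, n_nodes, traj.ndim))
        for t in range(n_steps):
            pos = traj.positions[t]
            for i in range(n_nodes):
                js = nb[t, i]
                diff = pos[js] - pos[i]
                r = np.linalg.norm(diff, axis=1, keepdims=True)
                z = np.array(
                    [pair_type[(min(i, int(j)), max(i, int(j)))] for j in js]
                )
                f = kL[z, 0][:, None] * (r - kL[z, 1][:, None]) * diff / r
                tg[t, i] = f.sum(axis=0) / traj.masses[i]
        feats.append(fe)
        nbrs.append(nb)
        targs.append(tg)
    return (
        np.concatenate(feats), np.concatenate(targs), np.concatenate(nbrs),
        masses, pair_type,
    )


# ---------------------------------------------------------------------------
# vector autoregression
# ---------------------------------------------------------------------------


def simulate_var(spec: VARSpec, seed: int = 0,
                 x0: np.ndarray | None = None) -> np.ndarray:
    """One realization x[t] = A x[t-1] + eps[t], eps ~ N(0, noise_sd^2 I).

    Returns a (T, N) array. The initial state defaults to a standard normal
    draw.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_series
    x = np.empty((spec.n_steps, n))
    x[0] = rng.standard_normal(n) if x0 is None else np.asarray(x0, dtype=float)
    for t in range(1, spec.n_steps):
        x[t] = spec.coefficients @ x[t - 1] + rng.normal(0.0, spec.noise_sd, size=n)
    return x


def var_dataset(n_sims: int, spec: VARSpec, seed: int = 0) -> SeriesDataset:
    """Stack of VAR realizations; edge type 1 where the adjacency has a
    causal link (sender drives receiver), 0 elsewhere."""
    rng = np.random.default_rng(seed)
    edges = complete_edges(spec.n_series)
    tt = spec.adjacency[edges[:, 0], edges[:, 1]].astype(int)
    values = np.stack(
        [simulate_var(spec, seed=int(rng.integers(2**31))) for _ in range(n_sims)]
    )
    return SeriesDataset(values, edges, np.tile(tt, (n_sims, 1)))
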