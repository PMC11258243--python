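"""Generative module: per-type edge networks and the increment likelihood.

The bank holds K edge networks of identical architecture and independent
parameters. Two aggregation modes are supported:

* ``"physics"`` — the predicted state increment of a node is the sum of the
  per-edge messages divided by the node's mass (force interpretation; no node
  network). Per-edge forces are identifiable and can be checked against
  Newton's third law.
* ``"mpnn"`` — messages are summed and passed, together with the node's own
  features, through an additional node-update network. Forces are not
  identifiable in this mode.

The observed increment is modelled as an isotropic Gaussian centred on the
prediction with pre-set variance sigma^2.
"""

from __future__ import annotations

import numpy as np

from ._nn import MLP

__all__ = [
    "EdgeModelBank",
    "predict_increment_fixed",
    "predict_increment_evolving",
    "log_likelihood_increment",
    "pairwise_force_eval",
]


class EdgeModelBank:
    """K per-type edge functions (x_i, x_j) -> d-vector, plus an optional
    node-update network in mpnn mode.

    Parameters
    ----------
    n_types : int
        Number of interaction types K.
    node_dim : int
        Dimension of one node's feature vector.
    out_dim : int
        Dimension of the predicted increment (spatial dimension d).
    hidden, depth : int
        Width and number of hidden layers of every network.
    mode : {"physics", "mpnn"}
    pair_transform : {"geometry", "raw"}
        Input representation handed to the edge networks. "raw" is the bare
        concatenation [x_i, x_j]. "geometry" (particle features laid out as
        [position, velocity, mass]) appends the translation-invariant pair
        geometry [r_j - r_i, ||r_j - r_i||, v_j - v_i], which makes radial
        force laws nearly linear in the inputs and speeds up learning
        considerably; it is a deterministic function of (x_i, x_j), so the
        (x_i, x_j) contract is unchanged.
    space_dim : int
        Spatial dimension d of the position block (geometry mode only).
    seed : int
        Initialization seed (standard small-random init).
    """

    def __init__(self, n_types, node_dim, out_dim, hidden=128, depth=3,
                 mode="physics", pair_transform="raw", space_dim=None, seed=0):
        if mode not in ("physics", "mpnn"):
            raise ValueError("mode must be 'physics' or 'mpnn'")
        if pair_transform not in ("raw", "geometry"):
            raise ValueError("pair_transform must be 'raw' or 'geometry'")
        if pair_transform == "geometry":
            if space_dim is None:
                space_dim = out_dim
            if node_dim < 2 * space_dim:
                raise ValueError(
                    "geometry transform expects features [position, velocity, ...]"
                )
        rng = np.random.default_rng(seed)
        in_dim = 2 * node_dim
        if pair_transform == "geometry":
            in_dim += 2 * space_dim + 1
        sizes = [in_dim] + [hidden] * depth + [out_dim]
        self.n_types = n_types
        self.node_dim = node_dim
        self.out_dim = out_dim
        self.mode = mode
        self.pair_transform = pair_transform
        self.space_dim = space_dim
        self.in_dim = in_dim
        self.nets = [MLP(sizes, rng) for _ in range(n_types)]
        self.node_net = (
            MLP([out_dim + node_dim] + [hidden] * depth + [out_dim], rng)
            if mode == "mpnn" else None
        )

    def pair_inputs(self, x_i, x_j):
        """Edge-network input for batches of receiver/sender features."""
        x_i = np.atleast_2d(np.asarray(x_i, dtype=float))
        x_j = np.atleast_2d(np.asarray(x_j, dtype=float))
        base = np.concatenate([x_i, x_j], axis=-1)
        if self.pair_transform == "raw":
            return base
        d = self.space_dim
        dr = x_j[..., :d] - x_i[..., :d]
        r = np.linalg.norm(dr, axis=-1, keepdims=True)
        dv = x_j[..., d:2 * d] - x_i[..., d:2 * d]
        return np.concatenate([base, dr, r, dv], axis=-1)

    # -- parameters ---------------------------------------------------------
    @property
    def params(self):
        out = []
        for net in self.nets:
            out.extend(net.params)
        if self.node_net is not None:
            out.extend(self.node_net.params)
        return out

    def set_params(self, params):
        k = len(self.nets[0].params)
        for z, net in enumerate(self.nets):
            net.set_params(params[z * k:(z + 1) * k])
        if self.node_net is not None:
            self.node_net.set_params(params[len(self.nets) * k:])

    def copy(self):
        out = EdgeModelBank.__new__(EdgeModelBank)
        out.n_types = self.n_types
        out.node_dim = self.node_dim
        out.out_dim = self.out_dim
        out.mode = self.mode
        out.pair_transform = self.pair_transform
        out.space_dim = self.space_dim
        out.in_dim = self.in_dim
        out.nets = [net.copy() for net in self.nets]
        out.node_net = self.node_net.copy() if self.node_net is not None else None
        return out

    def permute_types(self, perm):
        """Return a bank whose type-z network is this bank's net perm[z]."""
        out = self.copy()
        out.nets = [self.nets[p].copy() for p in perm]
        return out

    # -- evaluation ---------------------------------------------------------
    def message(self, z, x_i, x_j):
        """Edge message NN^z(x_i, x_j); accepts single vectors or batches."""
        return self.nets[z](self.pair_inputs(x_i, x_j))

    def all_messages(self, x_i, x_j):
        """All K messages for batches of receiver/sender features:
        returns (B, K, out_dim)."""
        pairs = self.pair_inputs(x_i, x_j)
        return np.stack([net(pairs) for net in self.nets], axis=1)

    def node_update(self, aggregated, x_i):
        if self.node_net is None:
            raise ValueError("physics mode has no node-update network")
        agg = np.atleast_2d(np.asarray(aggregated, dtype=float))
        x_i = np.atleast_2d(np.asarray(x_i, dtype=float))
        return self.node_net(np.concatenate([agg, x_i], axis=-1))


def predict_increment_fixed(x_center, x_neighbors, realization, bank,
                            mass=None):
    """Predicted increment of one node given a full subgraph realization.

    ``x_neighbors`` is (g, node_dim) in slot order and ``realization`` a
    length-g type assignment. In physics mode the result is the force sum
    divided by the node's mass; in mpnn mode the aggregated message and the
    node state go through the node network.
    """
    x_neighbors = np.atleast_2d(np.asarray(x_neighbors, dtype=float))
    realization = np.asarray(realization, dtype=int)
    if realization.shape != (x_neighbors.shape[0],):
        raise ValueError(
            f"realization assigns {realization.size} types but the subgraph "
            f"has {x_neighbors.shape[0]} edges"
        )
    agg = np.zeros(bank.out_dim)
    for x_j, z in zip(x_neighbors, realization):
        agg = agg + bank.message(int(z), x_center, x_j)[0]
    if bank.mode == "physics":
        if mass is None:
            raise ValueError("physics mode needs the receiver mass")
        return agg / float(mass)
    return bank.node_update(agg, x_center)[0]


def predict_increment_evolving(x_center, x_active_neighbors, types, bank,
                               mass=None):
    """Same aggregation as :func:`predict_increment_fixed` but over the
    neighbors active at the current time step (possibly none)."""
    x_active = np.asarray(x_active_neighbors, dtype=float).reshape(-1, bank.node_dim)
    types = np.asarray(types, dtype=int).reshape(-1)
    if types.shape[0] != x_active.shape[0]:
        raise ValueError("one type per active edge is required")
    if x_active.shape[0] == 0:
        if bank.mode == "physics":
            return np.zeros(bank.out_dim)
        return bank.node_update(np.zeros(bank.out_dim), x_center)[0]
    return predict_increment_fixed(x_center, x_active, types, bank, mass)


def log_likelihood_increment(observed, predicted, sigma2):
    """log N(observed | predicted, sigma^2 I) for d-vectors or batches.

    Equals ``-(d/2) log(2 pi sigma^2) - ||obs - pred||^2 / (2 sigma^2)``.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(predicted))):
        raise ValueError("non-finite increment passed to the likelihood")
    d = observed.shape[-1]
    sq = np.sum((observed - predicted) ** 2, axis=-1)
    return -0.5 * d * np.log(2.0 * np.pi * sigma2) - sq / (2.0 * sigma2)


def pairwise_force_eval(z, x_i, x_j, bank):
    """Learned pairwise force NN^z(x_i, x_j); physics mode only.

    In mpnn mode per-edge forces are entangled with the node-update network
    and are not identifiable, so this raises.
    """
    if bank.mode != "physics":
        raise ValueError(
            "pairwise forces are only identifiable with the physics-consistent "
            "decoder; the mpnn decoder mixes messages through the node network"
        )
    return bank.message(z, x_i, x_j)
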