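"""Evaluation metrics for relational inference.

Edge-type labels are only identified up to permutation, so classification
accuracy is maximized over relabelings of the K inferred types. Force-level
metrics (pairwise-force error and the Newton's-third-law symmetry violation)
require the physics-consistent decoder, where per-edge forces are
identifiable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EvaluationReport",
    "permutation_accuracy",
    "mae_state",
    "mae_ef",
    "mae_symm",
    "mae_acceleration",
    "edge_forces_from_bank",
]


@dataclass
class EvaluationReport:
    """Bundle of evaluation results; ``state_error_at_final_step`` records
    that the rollout error is measured at the final horizon step only."""

    accuracy: float
    best_permutation: tuple
    mae_state: float | None = None
    mae_ef: float | None = None
    mae_symm: float | None = None
    mae_acceleration: float | None = None
    horizon: int = 10
    state_error_at_final_step: bool = True

    def to_dict(self):
        return asdict(self)


def permutation_accuracy(predicted, true, n_types):
    """Permutation-invariant accuracy and the best relabeling.

    Maximizes ``mean(alpha(predicted) == true)`` over permutations ``alpha``
    of the type labels — exhaustively for K <= 6, by optimal assignment on
    the confusion matrix for larger K. Returns ``(accuracy, alpha)`` with
    alpha a tuple such that label z is relabeled to ``alpha[z]``.
    """
    predicted = np.asarray(predicted).ravel()
    true = np.asarray(true).ravel()
    if predicted.shape != true.shape:
        raise ValueError("predicted and true must cover the same edge set")
    conf = np.zeros((n_types, n_types))
    np.add.at(conf, (predicted, true), 1)
    n = len(predicted)
    if n_types <= 6:
        best_acc, best_alpha = -1.0, None
        for alpha in itertools.permutations(range(n_types)):
            acc = sum(conf[z, alpha[z]] for z in range(n_types)) / n
            if acc > best_acc:
                best_acc, best_alpha = acc, alpha
        return float(best_acc), tuple(best_alpha)
    rows, cols = linear_sum_assignment(-conf)
    alpha = [0] * n_types
    for r, c in zip(rows, cols):
        alpha[r] = int(c)
    acc = conf[rows, cols].sum() / n
    return float(acc), tuple(alpha)


def _decoded_accel_fn(bank, types_e, edges, masses):
    """Net-acceleration closure from a physics bank and fixed edge types."""
    recv, send = edges[:, 0], edges[:, 1]

    def accel(pos, vel):
        n, d = pos.shape
        feats = np.concatenate([pos, vel, masses[:, None]], axis=-1)
        pair = bank.pair_inputs(feats[recv], feats[send])
        force = np.empty((len(edges), d))
        for k in range(bank.n_types):
            sel = types_e == k
            if np.any(sel):
                force[sel] = bank.nets[k](pair[sel])
        net = np.zeros((n, d))
        np.add.at(net, recv, force)
        return net / masses[:, None]

    return accel


def mae_state(bank, decoded_types, dataset, horizon=10, accel_fn=None):
    """Rollout state error: integrate the learned model ``horizon`` steps
    from each simulation's initial state (same symplectic Euler scheme as
    the simulators) and report the mean absolute error of positions and
    velocities, concatenated, at the final step.

    ``accel_fn(sim) -> f(pos, vel) -> (N, d)`` may override the decoder (an
    oracle for testing).
    """
    if dataset.positions.shape[1] <= horizon:
        raise ValueError("trajectory shorter than the rollout horizon")
    errs = []
    for s in range(dataset.n_sims):
        if accel_fn is not None:
            fn = accel_fn(s)
        else:
            fn = _decoded_accel_fn(
                bank, decoded_types[s], dataset.edges, dataset.masses[s]
            )
        pos = dataset.positions[s, 0].copy()
        vel = dataset.velocities[s, 0].copy()
        dt = dataset.dt
        for _ in range(horizon):
            acc = fn(pos, vel)
            vel = vel + acc * dt
            pos = pos + vel * dt
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError(f"rollout blew up for simulation {s}")
        err = np.concatenate(
            [
                np.abs(pos - dataset.positions[s, horizon]).ravel(),
                np.abs(vel - dataset.velocities[s, horizon]).ravel(),
            ]
        )
        errs.append(err)
    return float(np.mean(np.concatenate(errs)))


def edge_forces_from_bank(bank, types, dataset, t_steps=None):
    """Per-edge learned forces (S, T*, E, d) for given per-edge net indices
    (S, E); physics decoder only."""
    if bank.mode != "physics":
        raise ValueError("per-edge forces require the physics decoder")
    types = np.asarray(types)
    edges = dataset.edges
    feats = dataset.features()  # (S, T', N, f)
    if t_steps is not None:
        feats = feats[:, t_steps]
    S, Tp, N, f = feats.shape
    pair = bank.pair_inputs(
        feats[:, :, edges[:, 0]].reshape(-1, f),
        feats[:, :, edges[:, 1]].reshape(-1, f),
    ).reshape(S, Tp, len(edges), -1)
    out = np.empty((S, Tp, len(edges), dataset.ndim))
    for k in range(bank.n_types):
        sel = types == k  # (S, E)
        for s in range(S):
            cols = np.nonzero(sel[s])[0]
            if cols.size:
                out[s][:, cols] = bank.nets[k](
                    pair[s][:, cols].reshape(-1, pair.shape[-1])
                ).reshape(Tp, cols.size, -1)
    return out


def mae_ef(bank, alpha, dataset, true_forces, t_steps=None):
    """Pairwise-force error against the ground-truth force law.

    For every edge the learned network matched to the edge's ground-truth
    type through the accuracy permutation ``alpha`` (net index z with
    ``alpha[z] = true type``) is evaluated, so the metric reflects the
    quality of the learned interaction functions independently of the type
    predictions. ``true_forces`` is (S, T', E, d) (e.g. from the simulator
    force laws).
    """
    inv = np.empty(len(alpha), dtype=int)
    for z, az in enumerate(alpha):
        inv[az] = z
    net_idx = inv[dataset.true_types]  # (S, E)
    pred = edge_forces_from_bank(bank, net_idx, dataset, t_steps)
    tf = np.asarray(true_forces)
    if t_steps is not None:
        tf = tf[:, t_steps]
    return float(np.mean(np.abs(pred - tf)))


def mae_symm(forces, edges):
    """Newton's-third-law violation: mean absolute value of
    ``f(i<-j) + f(j<-i)`` over edge pairs (componentwise), given per-edge
    forces (..., E, d)."""
    edges = np.asarray(edges)
    index = {(int(i), int(j)): e for e, (i, j) in enumerate(edges)}
    fwd, rev = [], []
    for e, (i, j) in enumerate(edges):
        r = index.get((int(j), int(i)))
        if r is not None and e < r:
            fwd.append(e)
            rev.append(r)
    if not fwd:
        raise ValueError("no reciprocal edge pairs present")
    f = np.asarray(forces)
    return float(np.mean(np.abs(f[..., fwd, :] + f[..., rev, :])))


def mae_acceleration(predicted_increments, true_increments):
    """One-step increment error (the headline metric for evolving graphs,
    where multi-step rollouts are ill-defined)."""
    return float(
        np.mean(np.abs(np.asarray(predicted_increments) - np.asarray(true_increments)))
    )
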