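"""Sequential collective inference for evolving interaction graphs.

When nodes interact with different neighbors at different times, the exact
subgraph enumeration of the fixed-topology algorithm no longer applies.
Instead every directed edge carries its own categorical posterior over the K
types, updated sequentially: at each time step, for every edge active at that
step, the posterior is multiplied by the marginal likelihood of the observed
increment with the co-active edges' current posteriors marginalized out
(assuming the joint posterior factorizes over edges), then renormalized.

Updates within one time step are synchronous — every update at time t reads
the posterior state from before t — so the within-step processing order is
irrelevant. Edge types are constant over time: a re-appearing edge resumes
its posterior.

The M-step mirrors the fixed-topology case: the type prior tau has the
analytic solution (posterior average over edges) and the edge networks take
gradient ascent steps on the expected log-likelihood under the product of
per-edge posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._nn import Adam
from .decoders import EdgeModelBank
from .realizations import enumerate_realizations

__all__ = [
    "EdgePosteriors",
    "EdgeTypePrior",
    "init_edge_posteriors",
    "sequential_update",
    "q_evolving",
    "update_tau",
    "decode_edge_types_evolving",
    "predict_increments_evolving",
    "EvolvingCRI",
    "EvolvingCRIResults",
]

PRIOR_FLOOR = 1e-8
ENUM_CAP = 1024


@dataclass
class EdgeTypePrior:
    """Prior tau over the K interaction types of a single edge."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)

    @classmethod
    def uniform(cls, n_types):
        return cls(np.full(n_types, 1.0 / n_types))

    @property
    def n_types(self):
        return len(self.probs)

    def copy(self):
        return EdgeTypePrior(self.probs.copy())


class EdgePosteriors:
    """Per-directed-edge categorical posteriors over the K types.

    Edges are identified by the pair ``(receiver, sender)`` across all time
    steps; ``last_update[e]`` records the last time step whose observation
    touched edge e (-1 before any data).
    """

    def __init__(self, pairs, probs, last_update=None):
        self.pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        self.probs = np.asarray(probs, dtype=float)
        self.index = {tuple(p): e for e, p in enumerate(self.pairs)}
        self.last_update = (
            np.full(len(self.pairs), -1, dtype=int)
            if last_update is None else np.asarray(last_update, dtype=int)
        )

    def __getitem__(self, pair):
        return self.probs[self.index[tuple(pair)]]

    @property
    def n_types(self):
        return self.probs.shape[1]

    def copy(self):
        return EdgePosteriors(self.pairs.copy(), self.probs.copy(),
                              self.last_update.copy())


def init_edge_posteriors(pairs, tau):
    """Every edge's posterior starts at the prior tau (independent copies)."""
    tau = tau.probs if isinstance(tau, EdgeTypePrior) else np.asarray(tau, dtype=float)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return EdgePosteriors(pairs, np.tile(tau, (len(pairs), 1)))


def _active_pairs(neighbors):
    """Union of directed (receiver, sender) pairs over all time steps, in
    first-appearance order."""
    seen, pairs = set(), []
    T, N, g = neighbors.shape
    for t in range(T):
        for i in range(N):
            for j in neighbors[t, i]:
                p = (i, int(j))
                if p not in seen:
                    seen.add(p)
                    pairs.append(p)
    return np.asarray(pairs, dtype=int)


def sequential_update(posteriors, features_t, targets_t, neighbors_t, bank,
                      sigma2, masses=None, t=0, cap=ENUM_CAP):
    """One synchronous posterior update over the edges active at step t.

    For each node i with active senders ``neighbors_t[i]`` the joint weight
    of realization r is ``prod_slots p_old(type) * N(obs_i | pred_r, s2 I)``;
    each active edge's new posterior is the per-slot marginal of those
    weights, normalized. Inactive edges are untouched. Updates posteriors in
    place and returns them.
    """
    feats = np.asarray(features_t, dtype=float)
    obs = np.asarray(targets_t, dtype=float)
    neighbors_t = np.asarray(neighbors_t, dtype=int)
    N, g = neighbors_t.shape
    if g == 0:
        return posteriors
    K = bank.n_types
    if K**g > cap:
        raise ValueError(
            f"{K}^{g} co-realizations exceed the cap {cap}; "
            "reduce the neighborhood size"
        )
    table = enumerate_realizations(K, g)
    oh = table.one_hot  # (R, g, K)

    edge_idx = np.empty((N, g), dtype=int)
    for i in range(N):
        for s, j in enumerate(neighbors_t[i]):
            edge_idx[i, s] = posteriors.index[(i, int(j))]

    xi = np.repeat(feats[:, None, :], g, axis=1).reshape(N * g, -1)
    xj = feats[neighbors_t].reshape(N * g, -1)
    M = bank.all_messages(xi, xj).reshape(N, g, K, bank.out_dim)
    agg = np.einsum("rgk,ngkd->nrd", oh, M)
    if bank.mode == "physics":
        pred = agg / np.asarray(masses, dtype=float)[:, None, None]
    else:
        R = table.n_realizations
        xc = np.broadcast_to(feats[:, None, :], (N, R, feats.shape[-1]))
        inp = np.concatenate([agg, xc], axis=-1).reshape(N * R, -1)
        pred = bank.node_net(inp).reshape(N, R, bank.out_dim)
    d = obs.shape[-1]
    loglik = (
        -0.5 * d * np.log(2.0 * np.pi * sigma2)
        - np.sum((obs[:, None, :] - pred) ** 2, axis=-1) / (2.0 * sigma2)
    )  # (N, R)
    if not np.all(np.isfinite(loglik)):
        raise FloatingPointError(f"non-finite likelihood at step {t}")

    log_old = np.log(np.maximum(posteriors.probs[edge_idx], 1e-300))  # (N, g, K)
    logW = np.einsum("rgk,ngk->nr", oh, log_old) + loglik  # (N, R)

    # per-slot marginals of the joint weights, in log space
    new_logp = np.empty((N, g, K))
    for s in range(g):
        for z in range(K):
            mask = table.assignments[:, s] == z
            new_logp[:, s, z] = logsumexp(logW[:, mask], axis=-1)
    new_logp -= logsumexp(new_logp, axis=-1, keepdims=True)
    posteriors.probs[edge_idx] = np.exp(new_logp)
    posteriors.last_update[edge_idx] = t
    return posteriors


def update_tau(posteriors, floor=PRIOR_FLOOR):
    """Analytic prior update: tau_z = mean over edges of p*(z), floored and
    renormalized. With no edges observed the maximum-entropy (uniform) prior
    is returned."""
    if posteriors.probs.shape[0] == 0:
        return EdgeTypePrior.uniform(posteriors.probs.shape[1])
    tau = posteriors.probs.mean(axis=0)
    tau = np.maximum(tau, floor)
    return EdgeTypePrior(tau / tau.sum())


def decode_edge_types_evolving(posteriors):
    """Per-edge argmax type (ties to the lowest index); dict pair -> type."""
    best = np.argmax(posteriors.probs, axis=1)
    return {tuple(p): int(z) for p, z in zip(posteriors.pairs, best)}


def predict_increments_evolving(bank, types, features, neighbors, masses=None,
                                default_type=0):
    """One-step increment predictions under fixed per-edge types.

    ``types`` maps directed pairs (i, j) to a type; pairs absent from the
    map (edges never seen during training) fall back to ``default_type``.
    Returns a (T', N, d) array.
    """
    features = np.asarray(features, dtype=float)
    neighbors = np.asarray(neighbors, dtype=int)
    Tp, N, g = neighbors.shape
    out = np.empty((Tp, N, bank.out_dim))
    for t in range(Tp):
        feats = features[t]
        nbr = neighbors[t]
        z = np.array(
            [[types.get((i, int(j)), default_type) for j in nbr[i]]
             for i in range(N)]
        )
        xi = np.repeat(feats[:, None, :], g, axis=1).reshape(N * g, -1)
        xj = feats[nbr].reshape(N * g, -1)
        M = bank.all_messages(xi, xj).reshape(N, g, bank.n_types, -1)
        msg = np.take_along_axis(M, z[:, :, None, None], axis=2)[:, :, 0]
        agg = msg.sum(axis=1)
        if bank.mode == "physics":
            out[t] = agg / np.asarray(masses, dtype=float)[:, None]
        else:
            out[t] = bank.node_update(agg, feats)
    return out


def q_evolving(posteriors, tau, bank, features, targets, neighbors, sigma2,
               masses=None, cap=ENUM_CAP, n_samples=256, seed=0):
    """Q function of the sequential algorithm.

    First term: sum over edges of E_{z ~ p*}[log tau_z]. Second term: for
    every (node, time), the expectation of the log-likelihood over the
    product of the active edges' posteriors — exact enumeration while
    ``K**g <= cap``, otherwise posterior-product sampling with a fixed seed.
    With no observations the second term is 0 and the analytic tau update
    yields the maximum-entropy (uniform) prior.
    """
    tau_p = tau.probs if isinstance(tau, EdgeTypePrior) else np.asarray(tau)
    q = float(np.sum(posteriors.probs * np.log(np.maximum(tau_p, 1e-300))))
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    neighbors = np.asarray(neighbors, dtype=int)
    Tp = targets.shape[0]
    rng = np.random.default_rng(seed)
    K = bank.n_types
    d = targets.shape[-1]
    const = -0.5 * d * np.log(2.0 * np.pi * sigma2)
    for t in range(Tp):
        N, g = neighbors[t].shape
        feats = features[t]
        for i in range(N):
            senders = neighbors[t, i]
            p_edges = np.stack(
                [posteriors[(i, int(j))] for j in senders]
            )  # (g, K)
            x_n = feats[senders]
            if K**g <= cap:
                table = enumerate_realizations(K, g)
                M = bank.all_messages(
                    np.repeat(feats[i][None], g, axis=0), x_n
                )  # (g, K, d)
                agg = np.einsum("rgk,gkd->rd", table.one_hot, M)
                if bank.mode == "physics":
                    pred = agg / float(masses[i])
                else:
                    xc = np.repeat(feats[i][None], len(agg), axis=0)
                    pred = bank.node_update(agg, xc)
                ll = const - np.sum((targets[t, i] - pred) ** 2, axis=-1) / (2 * sigma2)
                w = np.prod(
                    np.take_along_axis(
                        p_edges[None], table.assignments[:, :, None], axis=2
                    )[:, :, 0],
                    axis=1,
                )
                q += float(w @ ll)
            else:
                draws = np.stack(
                    [rng.choice(K, size=n_samples, p=p) for p in p_edges], axis=1
                )  # (n_samples, g)
                vals = []
                for r in draws:
                    from .decoders import predict_increment_evolving

                    pred = predict_increment_evolving(
                        feats[i], x_n, r, bank,
                        None if masses is None else masses[i],
                    )
                    vals.append(
                        const - np.sum((targets[t, i] - pred) ** 2) / (2 * sigma2)
                    )
                q += float(np.mean(vals))
    return q


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class EvolvingCRI:
    """Relational inference for one trajectory with time-varying neighbors.

    Parameters
    ----------
    features : (T', N, f) array
        Node features aligned with the targets.
    targets : (T', N, d) array
        Ground-truth state increments.
    neighbors : (T', N, g) int array
        Senders active at each step (the cutoff/kNN graph).
    n_types : int
        Number of interaction types K.
    masses : (N,) array, optional; required by the physics decoder.
    """

    def __init__(self, features, targets, neighbors, n_types, masses=None,
                 decoder="physics", sigma2=0.01, hidden=128, depth=3,
                 pair_transform=None, prior_floor=PRIOR_FLOOR):
        self.features = np.asarray(features, dtype=float)
        self.targets = np.asarray(targets, dtype=float)
        self.neighbors = np.asarray(neighbors, dtype=int)
        self.n_types = n_types
        self.masses = None if masses is None else np.asarray(masses, dtype=float)
        if decoder == "physics" and self.masses is None:
            raise ValueError("physics mode requires masses")
        self.decoder = decoder
        self.sigma2 = float(sigma2)
        self._sigma2_now = self.sigma2
        self.hidden = hidden
        self.depth = depth
        if pair_transform is None:
            particle_layout = (
                self.features.shape[-1] == 2 * self.targets.shape[-1] + 1
            )
            pair_transform = (
                "geometry" if decoder == "physics" and particle_layout else "raw"
            )
        self.pair_transform = pair_transform
        self.prior_floor = prior_floor
        self.pairs = _active_pairs(self.neighbors)
        self._edge_index = {tuple(p): e for e, p in enumerate(self.pairs)}

    # -- incremental E: per-receiver refresh of the full time evidence ----
    def _node_batch_update(self, bank, tau, posteriors, nodes, optimizer):
        """Fresh posteriors for the incoming edges of a batch of receivers,
        from their full time evidence, followed by one gradient step.

        Edges partition by receiver, so refreshing one receiver's edges
        touches no other edge's evidence: this is the evolving analogue of
        the per-subgraph incremental E-step of the fixed-topology model.
        Co-active edges are weighted by their current posteriors (mean-field
        style); the gradient step uses the freshly updated posteriors.
        Returns the marginal-evidence contribution and the Q likelihood term
        of the batch.
        """
        nodes = np.asarray(nodes)
        Tp = self.targets.shape[0]
        b = len(nodes)
        g = self.neighbors.shape[2]
        K = bank.n_types
        d = self.targets.shape[-1]
        table = enumerate_realizations(K, g)
        oh = table.one_hot
        R = table.n_realizations

        nbr_b = self.neighbors[:, nodes, :]  # (Tp, b, g)
        t_idx = np.arange(Tp)
        feats_i = self.features[:, nodes, :]  # (Tp, b, f)
        feats_j = self.features[t_idx[:, None, None], nbr_b]  # (Tp, b, g, f)
        f = feats_i.shape[-1]
        xi = np.broadcast_to(feats_i[:, :, None, :], feats_j.shape)
        pair = bank.pair_inputs(
            xi.reshape(-1, f), feats_j.reshape(-1, f)
        )
        caches, outs = [], []
        for net in bank.nets:
            c = []
            outs.append(net.forward(pair, c))
            caches.append(c)
        M = np.stack(outs, axis=1).reshape(Tp, b, g, K, d)
        agg = np.einsum("rgk,tbgkd->tbrd", oh, M)
        if bank.mode == "physics":
            m_b = self.masses[nodes]
            pred = agg / m_b[None, :, None, None]
            node_cache = None
        else:
            xc = np.broadcast_to(
                feats_i[:, :, None, :], (Tp, b, R, f)
            )
            inp = np.concatenate([agg, xc], axis=-1).reshape(-1, d + f)
            node_cache = []
            pred = bank.node_net.forward(inp, node_cache).reshape(Tp, b, R, d)
        obs = self.targets[:, nodes, :]  # (Tp, b, d)
        resid = obs[:, :, None, :] - pred
        ll = (
            -0.5 * d * np.log(2.0 * np.pi * self._sigma2_now)
            - np.sum(resid**2, axis=-1) / (2.0 * self._sigma2_now)
        )  # (Tp, b, R)
        if not np.all(np.isfinite(ll)):
            raise FloatingPointError("non-finite likelihood in E-update")

        # slot -> edge index lookup, (Tp, b, g)
        edge_idx = np.empty((Tp, b, g), dtype=int)
        for a, i in enumerate(nodes):
            for t in range(Tp):
                for s in range(g):
                    edge_idx[t, a, s] = self._edge_index[
                        (int(i), int(nbr_b[t, a, s]))
                    ]
        log_p = np.log(np.maximum(posteriors.probs[edge_idx], 1e-300))
        logW = np.einsum("rgk,tbgk->tbr", oh, log_p) + ll
        # per-slot exclusion contributions, accumulated over time per edge
        log_tau = np.log(np.maximum(
            tau.probs if isinstance(tau, EdgeTypePrior) else tau, 1e-300
        ))
        contrib = np.empty((Tp, b, g, K))
        for s in range(g):
            for z in range(K):
                mask = table.assignments[:, s] == z
                contrib[:, :, s, z] = logsumexp(logW[:, :, mask], axis=-1)
        contrib -= log_p  # divide out each edge's own posterior
        flat_edges = edge_idx.reshape(-1)
        flat_c = contrib.reshape(-1, K)
        batch_edges = np.unique(flat_edges)
        acc = np.zeros((len(posteriors.pairs), K))
        np.add.at(acc, flat_edges, flat_c)
        logits = log_tau + acc[batch_edges]
        logits -= logsumexp(logits, axis=-1, keepdims=True)
        posteriors.probs[batch_edges] = np.exp(logits)

        # gradient step with the fresh posteriors
        log_p_new = np.log(np.maximum(posteriors.probs[edge_idx], 1e-300))
        w = np.exp(np.einsum("rgk,tbgk->tbr", oh, log_p_new))  # (Tp, b, R)
        const = -0.5 * d * np.log(2.0 * np.pi * self._sigma2_now)
        q2 = float(
            np.sum(w * (const - np.sum(resid**2, axis=-1)
                        / (2.0 * self._sigma2_now)))
        )
        dpred = w[..., None] * resid / self._sigma2_now
        if bank.mode == "physics":
            dagg = dpred / m_b[None, :, None, None]
            node_grads = None
        else:
            node_grads, dinp = bank.node_net.backward(
                node_cache, dpred.reshape(-1, d)
            )
            dagg = dinp[:, :d].reshape(Tp, b, R, d)
        dM = np.einsum("rgk,tbrd->tbgkd", oh, dagg)
        grads = []
        for k, net in enumerate(bank.nets):
            g_k, _ = net.backward(
                caches[k], dM[:, :, :, k, :].reshape(-1, d)
            )
            grads.extend(g_k)
        if bank.node_net is not None:
            grads.extend(node_grads)
        if not all(np.all(np.isfinite(gr)) for gr in grads):
            raise FloatingPointError("non-finite gradient in M-update")
        params = bank.params
        optimizer.step(params, [-gr for gr in grads])
        bank.set_params(params)
        return q2

    # -- E pass ---------------------------------------------------------
    def _forward_pass(self, bank, tau, t_steps=None):
        posteriors = init_edge_posteriors(self.pairs, tau)
        steps = range(self.targets.shape[0]) if t_steps is None else t_steps
        for t in steps:
            sequential_update(
                posteriors, self.features[t], self.targets[t],
                self.neighbors[t], bank, self._sigma2_now, self.masses, t=t,
            )
        return posteriors

    # -- M pieces --------------------------------------------------------
    def _q2_and_grads(self, bank, posteriors, t_idx):
        """Gradient of the expected log-likelihood over a batch of steps,
        with realization weights from the product of per-edge posteriors."""
        K = bank.n_types
        d = self.targets.shape[-1]
        f = self.features.shape[-1]
        const = -0.5 * d * np.log(2.0 * np.pi * self._sigma2_now)
        grads = None
        node_grads = None
        q2 = 0.0
        for t in t_idx:
            nbr = self.neighbors[t]
            N, g = nbr.shape
            table = enumerate_realizations(K, g)
            oh = table.one_hot
            feats = self.features[t]
            edge_idx = np.empty((N, g), dtype=int)
            for i in range(N):
                for s, j in enumerate(nbr[i]):
                    edge_idx[i, s] = self._edge_index[(i, int(j))]
            pair_in = bank.pair_inputs(
                np.repeat(feats[:, None, :], g, axis=1).reshape(N * g, f),
                feats[nbr].reshape(N * g, f),
            )
            caches = []
            outs = []
            for net in bank.nets:
                c = []
                outs.append(net.forward(pair_in, c))
                caches.append(c)
            # outs[k] is (N*g, d); stack to (N, g, K, d)
            M = np.stack(outs, axis=1).reshape(N, g, K, d)
            agg = np.einsum("rgk,ngkd->nrd", oh, M)
            if bank.mode == "physics":
                pred = agg / self.masses[:, None, None]
            else:
                R = table.n_realizations
                xc = np.broadcast_to(feats[:, None, :], (N, R, f))
                inp = np.concatenate([agg, xc], axis=-1).reshape(N * R, d + f)
                ncache = []
                pred = bank.node_net.forward(inp, ncache).reshape(N, R, d)
            resid = self.targets[t][:, None, :] - pred  # (N, R, d)
            p_edges = posteriors.probs[edge_idx]  # (N, g, K)
            w = np.prod(
                np.take_along_axis(
                    p_edges[:, None, :, :],
                    table.assignments[None, :, :, None], axis=3,
                )[:, :, :, 0],
                axis=2,
            )  # (N, R)
            q2 += float(
                np.sum(w * (const - np.sum(resid**2, axis=-1) / (2 * self._sigma2_now)))
            )
            dpred = w[:, :, None] * resid / self._sigma2_now
            if bank.mode == "physics":
                dagg = dpred / self.masses[:, None, None]
            else:
                gn, dinp = bank.node_net.backward(ncache, dpred.reshape(N * R, d))
                node_grads = gn if node_grads is None else [
                    a + b for a, b in zip(node_grads, gn)
                ]
                dagg = dinp[:, :d].reshape(N, -1, d)
            dM = np.einsum("rgk,nrd->ngkd", oh, dagg)
            step_grads = []
            for k, net in enumerate(bank.nets):
                gk, _ = net.backward(caches[k], dM[:, :, k, :].reshape(N * g, d))
                step_grads.extend(gk)
            grads = step_grads if grads is None else [
                a + b for a, b in zip(grads, step_grads)
            ]
        if bank.node_net is not None and node_grads is not None:
            grads = grads + node_grads
        return q2, grads

    # -- fit --------------------------------------------------------------
    def fit(self, epochs=100, lr=1e-3, seed=0, batch_steps=16,
            schedule="incremental", max_updates=None, anneal=None,
            val_steps=None, val_every=10, verbose=False):
        """Generalized EM with a sequential E pass.

        Each epoch reruns the posterior recursion from the tau-initialized
        state over all training steps (the recursion conditions on the
        current parameters, so stale posteriors would mix parameter
        generations) and updates tau analytically at the epoch end.

        ``schedule`` controls how the recursion and the gradient steps
        interleave:

        * ``"incremental"`` (default) — every time step's per-edge
          log-likelihood contribution (with co-active edges marginalized
          under their current posteriors) is stored and replaced in place
          as its block is revisited, so each edge's posterior always
          reflects the full accumulated evidence while it co-evolves with
          the networks (partial E-steps in the Neal-Hinton sense). One Adam
          step per block of ``batch_steps`` time steps. Keeping posteriors
          and parameters coupled is what lets the type networks specialize;
          training them to convergence against a frozen posterior collapses
          the types onto the mean interaction.
        * ``"streaming"`` — the sequential recursion is advanced
          ``batch_steps`` steps at a time with one Adam step after each
          advance, weighted by the running posterior state.
        * ``"epoch"`` — full recursion first, then gradient steps over
          shuffled minibatches of time steps against the finished posterior
          (at most ``max_updates`` of them when set).

        ``anneal=(sigma2_start, n_epochs)`` applies the same deterministic
        variance annealing as the fixed-topology model. Model selection:
        lowest one-step increment MAE on ``val_steps`` (defaults to the
        training steps).
        """
        rng = np.random.default_rng(seed)
        d = self.targets.shape[-1]
        bank = EdgeModelBank(
            self.n_types, self.features.shape[-1], d, hidden=self.hidden,
            depth=self.depth, mode=self.decoder,
            pair_transform=self.pair_transform,
            seed=int(rng.integers(2**31)),
        )
        tau = EdgeTypePrior.uniform(self.n_types)
        optimizer = Adam(bank.params, lr=lr)
        Tp = self.targets.shape[0]
        history = {"epoch": [], "q": [], "val_metric": []}
        best = {"metric": np.inf, "bank": None, "tau": None, "epoch": -1}

        posteriors = self._forward_pass(bank, tau) if Tp else init_edge_posteriors(
            self.pairs, tau
        )
        for epoch in range(epochs):
            if anneal is not None:
                s2_start, n_anneal = anneal
                frac = min(epoch, n_anneal) / n_anneal
                self._sigma2_now = s2_start * (self.sigma2 / s2_start) ** frac
            q2 = 0.0
            if Tp and schedule == "incremental":
                if epoch == 0:
                    posteriors = init_edge_posteriors(self.pairs, tau)
                N = self.neighbors.shape[1]
                perm = rng.permutation(N)
                nodes_per_batch = max(1, batch_steps * N // max(Tp, 1))
                for start in range(0, N, nodes_per_batch):
                    nodes = perm[start:start + nodes_per_batch]
                    q2 += self._node_batch_update(
                        bank, tau, posteriors, nodes, optimizer
                    )
            elif Tp and schedule == "streaming":
                posteriors = init_edge_posteriors(self.pairs, tau)
                for start in range(0, Tp, batch_steps):
                    idx = np.arange(start, min(start + batch_steps, Tp))
                    for t in idx:
                        sequential_update(
                            posteriors, self.features[t], self.targets[t],
                            self.neighbors[t], bank, self._sigma2_now,
                            self.masses, t=int(t),
                        )
                    q2b, grads = self._q2_and_grads(bank, posteriors, idx)
                    if not all(np.all(np.isfinite(g)) for g in grads):
                        raise FloatingPointError(
                            f"non-finite gradient at epoch {epoch}"
                        )
                    q2 += q2b
                    params = bank.params
                    optimizer.step(params, [-g for g in grads])
                    bank.set_params(params)
            else:
                posteriors = (
                    self._forward_pass(bank, tau) if Tp
                    else init_edge_posteriors(self.pairs, tau)
                )
                if Tp:
                    starts = list(range(0, Tp, batch_steps))
                    if max_updates is not None and len(starts) > max_updates:
                        starts = starts[:max_updates]
                    perm = rng.permutation(Tp)
                    for start in starts:
                        idx = perm[start:start + batch_steps]
                        q2b, grads = self._q2_and_grads(bank, posteriors, idx)
                        if not all(np.all(np.isfinite(g)) for g in grads):
                            raise FloatingPointError(
                                f"non-finite gradient at epoch {epoch}"
                            )
                        q2 += q2b
                        params = bank.params
                        optimizer.step(params, [-g for g in grads])
                        bank.set_params(params)
            tau = update_tau(posteriors, self.prior_floor)
            q1 = float(
                np.sum(posteriors.probs * np.log(np.maximum(tau.probs, 1e-300)))
            )
            history["epoch"].append(epoch)
            history["q"].append(q1 + q2)
            if Tp and (epoch % val_every == 0 or epoch == epochs - 1):
                metric = self._one_step_mae(bank, posteriors, val_steps)
                history["val_metric"].append((epoch, metric))
                if metric < best["metric"]:
                    best.update(metric=metric, bank=bank.copy(),
                                tau=tau.copy(), epoch=epoch)
            if verbose:
                print(f"epoch {epoch}: q={q1 + q2:.2f}")

        self._sigma2_now = self.sigma2  # final posteriors at the set variance
        if best["bank"] is not None:
            bank, tau = best["bank"], best["tau"]
            best_epoch = best["epoch"]
        else:
            best_epoch = epochs - 1
        posteriors = (
            self._forward_pass(bank, tau) if Tp
            else init_edge_posteriors(self.pairs, tau)
        )
        return EvolvingCRIResults(
            model=self, bank=bank, tau=tau, posteriors=posteriors,
            history=history, best_epoch=best_epoch,
        )

    def _one_step_mae(self, bank, posteriors, t_steps=None):
        types = decode_edge_types_evolving(posteriors)
        steps = range(self.targets.shape[0]) if t_steps is None else t_steps
        err, count = 0.0, 0
        for t in steps:
            nbr = self.neighbors[t]
            N, g = nbr.shape
            feats = self.features[t]
            z = np.array(
                [[types[(i, int(j))] for j in nbr[i]] for i in range(N)]
            )
            xi = np.repeat(feats[:, None, :], g, axis=1).reshape(N * g, -1)
            xj = feats[nbr].reshape(N * g, -1)
            M = bank.all_messages(xi, xj).reshape(N, g, bank.n_types, -1)
            msg = np.take_along_axis(M, z[:, :, None, None], axis=2)[:, :, 0]
            agg = msg.sum(axis=1)
            if bank.mode == "physics":
                pred = agg / self.masses[:, None]
            else:
                pred = bank.node_update(agg, feats)
            err += float(np.abs(self.targets[t] - pred).sum())
            count += self.targets[t].size
        return err / max(count, 1)


@dataclass
class EvolvingCRIResults:
    """Fitted state of a sequential (evolving-topology) inference run."""

    model: EvolvingCRI
    bank: EdgeModelBank
    tau: EdgeTypePrior
    posteriors: EdgePosteriors
    history: dict
    best_epoch: int

    def decode_edge_types(self):
        return decode_edge_types_evolving(self.posteriors)

    def accuracy(self, true_type_fn):
        """Permutation-invariant accuracy; ``true_type_fn(i, j)`` returns the
        ground-truth type of directed edge (i, j)."""
        from .metrics import permutation_accuracy

        decoded = self.decode_edge_types()
        pred = np.array([decoded[tuple(p)] for p in self.posteriors.pairs])
        true = np.array(
            [true_type_fn(int(p[0]), int(p[1])) for p in self.posteriors.pairs]
        )
        return permutation_accuracy(pred, true, self.model.n_types)

    def mae_acceleration(self, t_steps=None):
        """One-step increment MAE under the decoded types."""
        return self.model._one_step_mae(self.bank, self.posteriors, t_steps)

    def summary(self):
        h = self.history
        return "\n".join([
            "Evolving collective relational inference — fit summary",
            "------------------------------------------------------",
            f"decoder: {self.model.decoder}   K = {self.model.n_types}   "
            f"sigma^2 = {self.model.sigma2}",
            f"edges tracked: {len(self.posteriors.pairs)}   "
            f"epochs run: {len(h['epoch'])}   best epoch: {self.best_epoch}",
            "tau: " + ", ".join(f"{p:.3f}" for p in self.tau.probs),
        ])
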