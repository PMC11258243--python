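"""Dataset and checkpoint serialization.

HDF5 is the primary trajectory format (dataset names below; schema version
``relinf-1``), with an NPZ fallback selected by file extension. The exact
layout is documented in ``docs/data_schema.md``.

Particle datasets: ``positions`` (S,T,N,d), ``velocities`` (S,T,N,d),
``masses`` (S,N), ``increments`` (S,T-1,N,d), ``edges`` (E,2),
``true_types`` (S,E); attrs ``dt``, ``kind="particles"``.
Series datasets: ``values`` (S,T,N), ``edges``, ``true_types``;
attr ``kind="series"``.

Checkpoints are NPZ archives holding every network parameter array, the
prior tables, sigma^2 and the architecture config.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .cri import RealizationPrior
from .data import ParticleDataset, SeriesDataset
from .decoders import EdgeModelBank
from .evolving import EdgeTypePrior

__all__ = [
    "SCHEMA_VERSION",
    "save_trajectories",
    "load_trajectories",
    "save_checkpoint",
    "load_checkpoint",
]

SCHEMA_VERSION = "relinf-1"


def _dataset_arrays(data):
    if isinstance(data, ParticleDataset):
        return "particles", {
            "positions": data.positions,
            "velocities": data.velocities,
            "masses": data.masses,
            "increments": data.increments,
            "edges": data.edges,
            "true_types": data.true_types,
        }, {"dt": data.dt}
    if isinstance(data, SeriesDataset):
        return "series", {
            "values": data.values,
            "edges": data.edges,
            "true_types": data.true_types,
        }, {}
    raise TypeError(f"cannot serialize {type(data)!r}")


def save_trajectories(path, data):
    """Write a dataset to ``path`` (.h5/.hdf5 or .npz by extension)."""
    path = Path(path)
    kind, arrays, attrs = _dataset_arrays(data)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["schema"] = SCHEMA_VERSION
            f.attrs["kind"] = kind
            for k, v in attrs.items():
                f.attrs[k] = v
            for name, arr in arrays.items():
                f.create_dataset(name, data=arr)
    elif path.suffix == ".npz":
        meta = {"schema": SCHEMA_VERSION, "kind": kind, **attrs}
        np.savez(path, _meta=json.dumps(meta), **arrays)
    else:
        raise ValueError(f"unsupported extension: {path.suffix!r}")
    return path


def load_trajectories(path):
    """Load a dataset written by :func:`save_trajectories` (lossless)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            schema = f.attrs.get("schema")
            if schema != SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported schema {schema!r} (expected {SCHEMA_VERSION!r})"
                )
            kind = f.attrs["kind"]
            arrays = {name: f[name][()] for name in f}
            attrs = {k: f.attrs[k] for k in f.attrs if k not in ("schema", "kind")}
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            if "_meta" not in f:
                raise ValueError("not a relinf dataset archive (missing _meta)")
            meta = json.loads(str(f["_meta"]))
            if meta.get("schema") != SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported schema {meta.get('schema')!r} "
                    f"(expected {SCHEMA_VERSION!r})"
                )
            kind = meta["kind"]
            arrays = {name: f[name] for name in f.files if name != "_meta"}
            attrs = {k: v for k, v in meta.items() if k not in ("schema", "kind")}
    else:
        raise ValueError(f"unsupported extension: {path.suffix!r}")

    if kind == "particles":
        return ParticleDataset(
            arrays["positions"], arrays["velocities"], arrays["masses"],
            float(attrs["dt"]), arrays["edges"], arrays["true_types"],
            arrays["increments"],
        )
    if kind == "series":
        return SeriesDataset(arrays["values"], arrays["edges"], arrays["true_types"])
    raise ValueError(f"unknown dataset kind {kind!r}")


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, bank, priors, sigma2, extra=None):
    """Archive all edge-network parameters, the prior and sigma^2."""
    arrays = {}
    for z, net in enumerate(bank.nets):
        for li, (w, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"net{z}_w{li}"] = w
            arrays[f"net{z}_b{li}"] = b
    if bank.node_net is not None:
        for li, (w, b) in enumerate(zip(bank.node_net.weights, bank.node_net.biases)):
            arrays[f"node_w{li}"] = w
            arrays[f"node_b{li}"] = b
    if isinstance(priors, RealizationPrior):
        prior_meta = {"kind": "realization", "degrees": sorted(priors.probs)}
        for g, p in priors.probs.items():
            arrays[f"prior_deg{g}"] = p
    elif isinstance(priors, EdgeTypePrior):
        prior_meta = {"kind": "edge"}
        arrays["prior_tau"] = priors.probs
    else:
        raise TypeError(f"unsupported prior {type(priors)!r}")
    config = {
        "schema": SCHEMA_VERSION,
        "n_types": bank.n_types,
        "node_dim": bank.node_dim,
        "out_dim": bank.out_dim,
        "mode": bank.mode,
        "pair_transform": bank.pair_transform,
        "space_dim": bank.space_dim,
        "sizes": bank.nets[0].sizes,
        "sigma2": float(sigma2),
        "prior": prior_meta,
        "extra": extra or {},
    }
    np.savez(path, _config=json.dumps(config), **arrays)
    return Path(path)


def load_checkpoint(path):
    """Restore ``(bank, priors, sigma2, extra)`` from an archive."""
    with np.load(path, allow_pickle=False) as f:
        config = json.loads(str(f["_config"]))
        if config.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {config.get('schema')!r}")
        sizes = config["sizes"]
        hidden = sizes[1] if len(sizes) > 2 else 0
        depth = len(sizes) - 2
        bank = EdgeModelBank(
            config["n_types"], config["node_dim"], config["out_dim"],
            hidden=hidden, depth=depth, mode=config["mode"],
            pair_transform=config.get("pair_transform", "raw"),
            space_dim=config.get("space_dim"), seed=0,
        )
        for z, net in enumerate(bank.nets):
            net.weights = [f[f"net{z}_w{li}"] for li in range(len(net.weights))]
            net.biases = [f[f"net{z}_b{li}"] for li in range(len(net.biases))]
        if bank.node_net is not None:
            nn = bank.node_net
            nn.weights = [f[f"node_w{li}"] for li in range(len(nn.weights))]
            nn.biases = [f[f"node_b{li}"] for li in range(len(nn.biases))]
        pm = config["prior"]
        if pm["kind"] == "realization":
            priors = RealizationPrior(
                config["n_types"],
                {int(g): f[f"prior_deg{g}"] for g in pm["degrees"]},
            )
        else:
            priors = EdgeTypePrior(f["prior_tau"])
    return bank, priors, config["sigma2"], config["extra"]
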