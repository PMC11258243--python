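# Trajectory archive schema (`relinf-1`)

`relinf.io.save_trajectories` / `load_trajectories` read and write HDF5
(`.h5`/`.hdf5`) with an NPZ fallback (`.npz`). Both carry the schema tag
`relinf-1` (HDF5: root attribute `schema`; NPZ: JSON in the `_meta` entry)
and a `kind` tag.

## kind = "particles"  (ParticleDataset)

| dataset       | shape          | meaning                                   |
|---------------|----------------|-------------------------------------------|
| `positions`   | (S, T, N, d)   | particle positions per simulation/step     |
| `velocities`  | (S, T, N, d)   | particle velocities                        |
| `masses`      | (S, N)         | particle masses (strictly positive)        |
| `increments`  | (S, T−1, N, d) | ground-truth accelerations (v[t+1]−v[t])/dt |
| `edges`       | (E, 2)         | directed edges (receiver, sender), shared across simulations |
| `true_types`  | (S, E)         | 0-based ground-truth edge types (evaluation only) |

Root attributes: `dt` (float step size).

## kind = "series"  (SeriesDataset)

| dataset      | shape     | meaning                                        |
|--------------|-----------|------------------------------------------------|
| `values`     | (S, T, N) | multivariate time series                       |
| `edges`      | (E, 2)    | candidate directed edges (receiver, sender)    |
| `true_types` | (S, E)    | 1 = causal link present, 0 = absent            |

## Checkpoints

`save_checkpoint` / `load_checkpoint` use NPZ with a JSON `_config` entry
(schema `relinf-1`) holding the architecture (layer sizes, mode, pair
transform), σ², and the prior kind; arrays `net{z}_w{l}` / `net{z}_b{l}`
store each type network's weights and biases, `node_w{l}` / `node_b{l}` the
optional node-update network, `prior_deg{g}` or `prior_tau` the prior
tables.
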