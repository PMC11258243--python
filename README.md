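# relinf — collective relational inference for heterogeneous interactions

Interacting systems — particles coupled by pairwise forces, functionally
connected brain regions, coupled economic indicators — are usually observed
only through the states of their parts over time. When several *types* of
interaction coexist, understanding the system means solving two problems at
once: which type acts on each pair, and what law governs each type.

`relinf` infers both from trajectories alone. Its central idea is
*collective* inference: the incoming interactions of a node are observed
only through their summed effect on that node, so their types must be
inferred jointly. The package treats each node's incoming-edge subgraph as
one latent categorical variable over all K^|Γ(i)| joint type assignments
("realizations") and fits, by generalized expectation-maximization:

* an exact **E-step** — per-subgraph posteriors p(z_(i) | ẍ_i^{1:T}) over
  realizations, from a Gaussian likelihood N(ẍ_i | x̂_i(z), σ²I) centred on
  the decoder prediction;
* an **M-step** — a closed-form update of the realization prior π and Adam
  gradient steps on the K per-type edge networks NN¹…NN^K that parameterize
  the interaction functions.

Two decoders are available: a *physics-consistent* one, x̂_i = Σ_j
NN^{z_ij}(x_i, x_j)/m_i, whose per-edge messages are identifiable forces
that can be checked against Newton's third law, and a generic
message-passing one with a node-update network for time-series data. A
sequential variant (`EvolvingCRI`) handles systems whose active edge set
changes over time (e.g. nearest-neighbor interactions): each directed edge
carries its own posterior over the K types, updated step by step with the
co-active edges marginalized out.

Everything needed to exercise the method ships with the package: spring,
charge and crystallization particle simulators and a vector-autoregression
generator, all with known ground-truth edge types; permutation-invariant
accuracy and force/state error metrics; experiment presets with seeded,
bitwise-reproducible runs.

## Worked example

Recover two spring types from 60 simulated trajectories of a five-particle
system (every pair coupled by a spring of type (k, L) = (0.5, 2.0) or
(2.0, 1.0); only positions, velocities and masses are observed):

```python
from relinf.experiment import (
    ExperimentConfig, apply_time_stride, fit_with_restarts, make_dataset,
)
from relinf.metrics import permutation_accuracy

cfg = ExperimentConfig()  # desk-scale defaults: 3 annealed probes + continuation
train = apply_time_stride(
    make_dataset("spring-n5k2", 100, 100, seed=1), cfg.time_stride
)
val = make_dataset("spring-n5k2", 20, 100, seed=2)
test = make_dataset("spring-n5k2", 50, 100, seed=3)
result = fit_with_restarts(train, val, cfg, seed=0)
print(result.summary())
acc, alpha = permutation_accuracy(
    result.decode_edge_types(test).ravel(), test.true_types.ravel(), 2
)
print(f"test edge-type accuracy: {acc:.3f} (label map {alpha})")
```

This takes a few minutes on one CPU and prints:

```
Collective relational inference — fit summary
---------------------------------------------
decoder: physics   K = 2   sigma^2 = 0.02
edge net: 2 hidden layer(s) x 64
epochs run: 200   best epoch: 150
marginal log-likelihood: -52349.30 -> 3090.85
prior (degree 4): top realization masses 0.094, 0.092, 0.074
test edge-type accuracy: 0.967 (label map (0, 1))
```

96.7% of the 1000 directed test edges are typed correctly; the accuracy is
permutation-invariant (type labels are only identified up to relabeling).
The driver probes three random restarts through a deterministic-annealing
phase of the likelihood variance — the mechanism that lets the
expectation-maximization loop escape the symmetric "all networks equal"
optimum, see `docs/methods.md` — then trains the restart with the lowest
validation error to completion; the summary shows that continuation. At
this desk scale repetitions land between roughly 0.92 and 0.98 (the
full-scale benchmark configuration reaches ~0.99).

The command line mirrors the library for shell-driven use:

```sh
relinf simulate --system spring-n5k2 --n-sims 100 --seed 0 --out data.h5
relinf train --data data.h5 --k 2 --epochs 250 --seed 0 --out ckpt.npz
relinf evaluate --ckpt ckpt.npz --data data.h5 --system spring-n5k2 --report report.json
relinf reproduce --preset spring-n5k2
```

## Layout

```
src/relinf/
  simulators.py   benchmark generators (springs, charges, crystallization, VAR)
  data.py         trajectory / graph / dataset containers
  decoders.py     per-type edge networks and the increment likelihood
  realizations.py subgraph realization enumeration
  cri.py          fixed-topology model: exact E-step, priors, EM loop
  evolving.py     evolving-topology model: sequential per-edge posteriors
  metrics.py      permutation accuracy, rollout/force/symmetry errors
  io.py           HDF5/NPZ datasets and checkpoints (docs/data_schema.md)
  experiment.py   presets, seeded end-to-end runs, run records
  cli.py          relinf simulate / train / train-evolving / evaluate / reproduce
```

The benchmark suite replicated here is fully synthetic; for the original
full-scale spring/charge trajectory archive, download it manually from the
ETH Research Collection (handle 20.500.11850/610139) and convert it to the
schema in `docs/data_schema.md`.
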