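# Methods

This note documents the model, the numerical and design choices behind
the implementation, what the synthetic benchmark does and does not
show, and the known limitations.  Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Model

### Message passing

One GNN module runs `K` iterations (default `K = 3`) of a
mean-aggregator update on node states `H` (rows are nodes):

```
H(k) = ReLU( M_A(H(k-1)) W(k) + b(k) ),
M_A(H)_v = (h_v + Σ_u A_vu h_u) / (1 + Σ_u A_vu)
```

Choices worth making explicit:

* **Self-inclusion at weight 1.**  The combine step is folded into the
  mean, so an isolated node (or a single-cluster coarse graph) simply
  keeps its own state.  Zero-weight edges are exactly equivalent to
  absent edges.
* **One learned map per iteration, applied after the mean.**  A
  variant that additionally rectifies the incoming states before
  aggregation is available (`ModelConfig.inner_relu`); it adds no
  parameters and is off by default.
* **Distinct `W(k), b(k)` per iteration**, Glorot-uniform weights
  seeded from the run seed.  Biases initialise at `+0.01` rather
  than 0: a dataset whose features standardise to exactly zero (see
  *Feature standardisation* below) would otherwise place every ReLU at
  an exact-zero pre-activation, where the subgradient convention makes
  the whole network permanently untrainable.
* **Dense float64 matrices throughout.**  The intended graphs have at
  most a few hundred nodes, where dense algebra is both faster and
  simpler than sparse bookkeeping, and float64 keeps the
  finite-difference gradient checks tight (1e-4 relative).

### Pooling layers

Both architectures emit node embeddings `Z` (n×d) and a row-stochastic
assignment `S` (n×c), and coarsen with `X' = SᵀZ`, `A' = SᵀAS`.

* **FPool:** one merged GNN; `S = softmax(Z W + B)` with `W ∈ R^{d×c}`.
* **DiffPool baseline:** two GNN modules of identical shape (embed and
  pool); the pooling module's output is projected to cluster logits by
  a linear map of the same `d×c` shape as FPool's.  Counting only
  GNN-module entries (the assignment projections and the head excluded
  on both sides), one FPool layer therefore carries exactly half the
  GNN parameters of one DiffPool layer — the acceptance script
  recomputes this 50% reduction.  At whole-model scope the final,
  non-pooled stage has a single GNN in both architectures, so the
  full-model GNN ratio is 3/5 at the default three stages; the
  total parameter count of FPool is strictly smaller at every tested
  configuration.
* Coarse adjacencies are kept dense and real-valued with their
  (generally nonzero) diagonal; the self-inclusion rule of the mean
  handles them uniformly, with no re-binarisation.  Empty clusters are
  retained — the entropy loss is expected to empty most of the 25
  clusters on small graphs, and that sparsity is part of what the
  argmax cluster export visualises.
* Softmax rows are computed with the per-row maximum subtracted
  (detached), which is exact for both the value and the gradient.

### Readout and head

The graph embedding concatenates, over all `L` stages,

```
h_G = [ MEAN(Z(1)/‖Z(1)‖_F), …, MEAN(Z(L)/‖Z(L)‖_F) ]
```

(`MEAN` is the column mean; an all-zero matrix contributes an all-zero
segment).  The division uses the **matrix** Frobenius norm; per-row L2
normalisation is available as `ModelConfig.row_normalize` since the
prose description of the method and its equation differ on this point.
The DiffPool baseline reads out the final stage only (the multi-level
concatenation is the FPool contribution); `ModelConfig.concat_readout`
gives it the concatenated readout for ablations.  The head is
`Linear(Σd_l → 64) → ReLU → Linear(64 → n_classes) → log-softmax`; the
head width reuses the GNN width because no separate value is
specified.

### Losses

`total = classification + λ_LP · L_LP + λ_E · L_E` with defaults
`λ_LP = λ_E = 1`:

* classification: mean negative log-likelihood under the log-softmax
  head;
* link prediction: `L_LP = ‖A − SSᵀ‖_F` per pooling level, raw (a
  variant normalised by n² is available for cross-dataset
  comparability);
* entropy: mean per-row natural-log entropy of `S` (natural log only
  rescales `λ_E`).

Auxiliary terms are averaged (not summed) over pooling levels so the
λ's mean the same thing at any depth.  Note two optimisation facts
that matter in practice: a uniform assignment is a stationary point of
the entropy term (its gradient with respect to the logits vanishes
there, so sharpening from a symmetric start is slow), and on sparse
graphs the diagonal discrepancy (`A` has zero diagonal, `SSᵀ` does
not) puts a floor under `L_LP` even for a perfect hard clustering.

## Feature standardisation

Initial node features (attribute vector ++ one-hot node label, or the
constant `[1, 1]` when neither exists) are standardised per column to
zero mean and unit **population** variance.  The statistics are fitted
over the full dataset at load time, matching the method's description
of normalisation as an initialisation step; a leakage-free variant
that fits on the training split only is available
(`repeated_evaluation(..., normalize="train")`).  Zero-variance
columns are mapped to zero (guard divisor 1).  Two consequences are
worth knowing:

* a constant feature column (e.g. the `[1, 1]` initialisation for
  unattributed graphs) standardises to exactly zero — the model then
  runs on structure alone, carried by the biases;
* a constant-plus-noise column standardises to pure unit-variance
  noise *regardless of the original noise scale*, because the
  informative constant is exactly what the mean subtraction removes.

## Training and evaluation protocol

Stratified 8:1:1 split (validation and test each receive ⌊n/10⌋
graphs, allocated across classes by largest remainder; classes with
fewer than 3 graphs stay whole in train with a warning).  Training uses
Adam at step size 1e-3 for 100 epochs with mini-batches of 20 graphs
processed as per-graph forward/backward passes with gradient
accumulation (graphs have varying node counts; nothing is padded).
After each epoch validation accuracy is measured; the parameters
returned are those of the highest-validation epoch (earliest on ties).
Repeated evaluation re-splits and re-initialises with seeds
`base_seed + r` and reports mean ± population standard deviation of
test accuracy.  Everything is deterministic given the seeds.

## The synthetic benchmark

`generate_planted_hierarchy` emits balanced 20-node graphs: 4 cliques
of 5 nodes joined by one junction edge per adjacent pair, in a ring
(class 0, 44 edges) or a chain (class 1, 43 edges).  Defaults: 200
graphs, constant `[1, 1]` features perturbed by Gaussian noise of
sd 0.1.  The noise exists because exactly-constant features make all
graphs of a class bitwise identical (a two-point dataset); the
geometry follows the documented 4×5, one-junction layout.  Both
classes share every node-level distribution up to the junction nodes,
so the class is decided purely by meso-scale topology.
`generate_separable_sanity` is the opposite control: the class is
encoded in the feature mean (+2 per class), and any competent
classifier reaches accuracy 1.0 — the training loop is validated
against it.

**What this task shows and does not show.**  The task is
deterministically separable from structure — a ring has 8
junction-incident node slots where a chain has 6, and a plain degree
histogram classifies it perfectly.  The mean aggregator, however,
normalises degree away to first order (the mean of a neighbourhood is
insensitive to its size), and after standardisation the features carry
no signal at all; the remaining structural trace in the embeddings is
second-order and empirically too small to learn from: in our
experiments end-to-end training does not exceed chance on held-out
graphs even with 1800 training graphs, and a linear probe on the graph
embedding under a *forced* perfect clique assignment is also at
chance.  This is the known expressiveness ceiling of mean-aggregation
GNNs (they capture proportions of a multiset, not counts), and it is
why the learnability check in the acceptance suite fails by design of
the architecture rather than by an implementation defect: the
structure-blind control sits at chance, as asserted, but so does the
hierarchical model.  The gradient, equivariance and oracle tests — not
this benchmark — are what establish that the implementation computes
the specified model correctly.  On real benchmarks the discriminative
signal lives largely in node labels/attributes, which this task
deliberately withholds.

## Numerical choices and degenerate inputs

* ReLU and the Frobenius `sqrt` use subgradient 0 at 0; an all-zero
  embedding matrix reads out as an all-zero segment with no fault.
* Entropy uses the `0·ln 0 = 0` convention, implemented with an exact
  `x ln x` primitive (no epsilon smoothing), so one-hot rows cost
  exactly zero.
* Argmax cluster export breaks ties toward the lowest cluster index.
* Self-loops in input TU files are dropped at load; input adjacencies
  must be symmetric; graph labels are remapped to contiguous 0-based
  classes sorted by raw value, node-label one-hots use the global
  ascending alphabet.
* Checkpoints are flat named-parameter `.npz` archives with the
  configuration embedded as JSON.

## Known limitations

* GraphSAGE-MAX / LSTM aggregators, neighbourhood sampling, edge
  labels and directed graphs are out of scope.
* Dense adjacencies make the cost quadratic in nodes per graph; fine
  for TU-scale benchmarks, unsuitable for very large graphs.
* The cluster counts (25; 125 for large protein graphs) are fixed per
  dataset, not learned; most clusters end up empty on small graphs.
* Wall-clock training-time comparisons are hardware-bound and are
  reported for information only (`hierpool train` logs per-epoch
  losses; no timing claims are asserted anywhere).
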