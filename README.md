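# hierpool

Hierarchical differentiable graph pooling for whole-graph classification
of molecular, protein and social-network graphs.

Many graph neural networks are "flat": they propagate information along
edges and then average all node embeddings into one vector, which
discards the meso-scale organisation (functional groups in a molecule,
secondary-structure clusters in a protein) that often determines the
graph label.  Hierarchical pooling addresses this by repeatedly
coarsening the graph: a row-stochastic **assignment matrix** `S(l)`
softly maps every node at level `l-1` to a cluster at level `l`, and the
coarser graph is built as

```
X(l) = S(l)ᵀ Z(l)          (cluster features)
A(l) = S(l)ᵀ A(l-1) S(l)   (cluster adjacency)
```

This package implements two ways of producing `Z` and `S`, both built on
GraphSAGE-MEAN message passing (`K` iterations of
`H ← ReLU(MEAN_A(H) W + b)` with the node itself included in its
neighbourhood at weight 1):

* **DiffPool** (baseline): two independent GNN modules per pooling
  layer — `Z = GNN_embed(A, X)`, and cluster logits from a separate
  `GNN_pool(A, X)`.
* **FPool**: a single merged GNN module per pooling layer; cluster
  assignment is computed directly from the embeddings,
  `S = softmax(Z W + B)`.  This halves the GNN-module parameter count
  per pooling layer (exactly 50%, which `scripts/acceptance.py`
  recomputes) and adds a skip-connection-style readout: each level's
  embedding matrix is divided by its Frobenius norm, reduced to its
  column mean, and all `L` levels are concatenated into the graph
  embedding `h_G` of length `d₁+…+d_L` (192 at the default width 64
  with 3 stages).

Training combines three losses: negative log-likelihood of the
classification head (`Linear → ReLU → Linear → log-softmax`), a
link-prediction regulariser `‖A − S Sᵀ‖_F` that encourages connected
nodes to share clusters, and the mean per-node assignment entropy that
pushes `S` toward one-hot.  The evaluation protocol is a stratified
8:1:1 train/validation/test split, best-on-validation model selection,
and repeated runs summarised as mean ± (population) standard deviation
of exact-match accuracy.

The networks and their gradients are implemented on a small
reverse-mode autodiff engine over dense numpy arrays
(`hierpool.autodiff`); gradient correctness is pinned to central finite
differences and a straight-line fixture oracle in the test suite.

## Data

`hierpool.graph_io.read_tu_dataset` reads the TU Dortmund graph-kernel
flat-file format (`DS_A.txt`, `DS_graph_indicator.txt`,
`DS_graph_labels.txt`, optional node labels/attributes) used by MUTAG,
ENZYMES, IMDB-BINARY and D&D.  Node features are the concatenation of
the attribute vector and the one-hot node label (constant `[1, 1]` when
neither exists) and are standardised column-wise to zero mean and unit
variance before training.

Because those benchmarks require a download, the package bundles a
generator (`hierpool.synthetic`) for a planted two-level-hierarchy task:
each graph is a set of equal-size cliques joined either in a **ring**
(class 0) or a **chain** (class 1).  Both classes share clique count,
clique size and feature distribution, so meso-scale structure is the
only discriminative signal.  Datasets round-trip through the same TU
files as the real benchmarks.

## Worked example

```bash
hierpool generate --kind planted --n-graphs 40 --seed 0 --out /tmp/planted
hierpool train --dataset /tmp/planted --arch fpool --clusters 25,25 \
    --hidden 64 --k 3 --epochs 3 --seed 0 --out /tmp/fpool.npz
```

prints one log line per epoch and a summary (output of the run above):

```
epoch=1 cls=0.6944 lp=5.7347 ent=3.2178 train_acc=0.4688 val_acc=0.2500
epoch=2 cls=0.6921 lp=5.7324 ent=3.2178 train_acc=0.5000 val_acc=0.5000
epoch=3 cls=0.6886 lp=5.7309 ent=3.2177 train_acc=0.5000 val_acc=0.5000
best_epoch=2 val_acc=0.5000 test_acc=0.5000
```

`cls`, `lp` and `ent` are the classification, link-prediction and
entropy losses averaged over the epoch's training graphs; `lp` starts
near `‖A‖_F` (here ≈ 5.7 for 20-node clique graphs) and `ent` at
`ln 25 ≈ 3.22` because the assignment starts uniform over 25 clusters.
`test_acc` is the accuracy of the best-on-validation model on the
held-out 10%.  A real run uses the default 100 epochs;
`hierpool benchmark --repeats 10` reproduces the full repeated
protocol, and `hierpool export-assignments` writes per-node argmax
cluster labels for visualising the learned hierarchy.

The library surface mirrors the CLI: see
`hierpool.train_eval.repeated_evaluation` for the programmatic
protocol and `hierpool.model.forward` for a single classification with
its full `PoolingTrace` (assignments, embeddings and coarsened graphs
per level).

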