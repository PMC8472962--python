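"""Reading and writing graph-classification datasets in the TU flat-file format.

The TU Dortmund graph-kernel collection stores a whole dataset ``DS`` as a
handful of plain-text files:

``DS_A.txt``
    comma-separated 1-based node-id pairs; every undirected edge appears in
    both directions.
``DS_graph_indicator.txt``
    one 1-based graph id per node line.
``DS_graph_labels.txt``
    one integer class label per graph.
``DS_node_labels.txt`` (optional)
    one integer label per node.
``DS_node_attributes.txt`` (optional)
    comma-separated real attribute vector per node.

Initial node features are the concatenation of the attribute vector and the
one-hot-encoded node label; graphs with neither get the constant vector
``[1, 1]``.  Features are standardised column-wise to zero mean and unit
(population) variance before training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Graph",
    "GraphDataset",
    "FeatureNormalizer",
    "TUFormatError",
    "read_tu_dataset",
    "write_tu_dataset",
    "build_feature_matrix",
    "fit_feature_normalizer",
    "apply_feature_normalizer",
    "standardize_dataset",
]


class TUFormatError(ValueError):
    """A TU flat-file directory is missing a file or malformed."""


@dataclass
class Graph:
    """One labelled undirected graph.

    ``adjacency`` is a dense symmetric non-negative matrix with zero
    diagonal at load time (coarsened graphs produced later in the pipeline
    may carry nonzero diagonals).  ``features`` holds one row per node.
    ``node_labels`` / ``node_attributes`` keep the raw per-node data so a
    dataset can be round-tripped back to TU files.
    """

    adjacency: np.ndarray
    features: np.ndarray
    label: int
    graph_id: int
    node_labels: np.ndarray | None = None
    node_attributes: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def validate(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if self.features.shape[0] != a.shape[0]:
            raise ValueError("features must have one row per node")
        if a.shape[0] < 1:
            raise ValueError("graph must have at least one node")


@dataclass
class GraphDataset:
    """An ordered collection of graphs sharing feature/label alphabets."""

    graphs: list[Graph]
    n_classes: int
    node_label_alphabet: tuple[int, ...] = ()
    attribute_dim: int = 0
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.graphs)

    def __getitem__(self, i: int) -> Graph:
        return self.graphs[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs], dtype=int)

    @property
    def feature_dim(self) -> int:
        return self.graphs[0].features.shape[1]


@dataclass
class FeatureNormalizer:
    """Column means and population standard deviations of node features.

    Columns with zero standard deviation are mapped to all-zero on apply
    (the guard divisor is 1, and the centred numerator vanishes on the
    fitting set).
    """

    mu: np.ndarray
    sigma: np.ndarray


# ---------------------------------------------------------------------
# parsing


def _read_int_lines(path: Path) -> list[int]:
    values = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(int(float(line)))
            except ValueError as exc:
                raise TUFormatError(
                    f"{path.name}: line {line_no}: expected an integer, got {line!r}"
                ) from exc
    return values


def read_tu_dataset(root_path, name: str) -> GraphDataset:
    """Load a TU flat-file directory into a :class:`GraphDataset`.

    Node ids are converted to 0-based per-graph indices, the edge list to a
    symmetric 0/1 adjacency with zero diagonal (self-loops dropped), and
    graph labels remapped to contiguous 0-based class indices.
    """
    root = Path(root_path)

    def required(suffix: str) -> Path:
        p = root / f"{name}_{suffix}.txt"
        if not p.exists():
            raise TUFormatError(f"missing required file: {p}")
        return p

    indicator = _read_int_lines(required("graph_indicator"))
    raw_graph_labels = _read_int_lines(required("graph_labels"))
    edge_path = required("A")

    n_nodes_total = len(indicator)
    graph_ids = sorted(set(indicator))
    if len(raw_graph_labels) != len(graph_ids):
        raise TUFormatError(
            f"{name}_graph_labels.txt has {len(raw_graph_labels)} entries for "
            f"{len(graph_ids)} graphs"
        )

    # global (1-based) node id -> (graph index, local 0-based node index)
    node_graph = np.empty(n_nodes_total, dtype=int)
    node_local = np.empty(n_nodes_total, dtype=int)
    counts: dict[int, int] = {}
    gid_index = {gid: i for i, gid in enumerate(graph_ids)}
    for node, gid in enumerate(indicator):
        gi = gid_index[gid]
        node_graph[node] = gi
        node_local[node] = counts.get(gi, 0)
        counts[gi] = counts.get(gi, 0) + 1
    sizes = [counts[i] for i in range(len(graph_ids))]

    adjacencies = [np.zeros((n, n)) for n in sizes]
    with open(edge_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise TUFormatError(
                    f"{edge_path.name}: line {line_no}: expected two node ids"
                )
            u, v = (int(p) for p in parts)
            if not (1 <= u <= n_nodes_total and 1 <= v <= n_nodes_total):
                raise TUFormatError(
                    f"{edge_path.name}: line {line_no}: node id out of range"
                )
            gu, gv = node_graph[u - 1], node_graph[v - 1]
            if gu != gv:
                raise TUFormatError(
                    f"{edge_path.name}: line {line_no}: edge ({u}, {v}) spans "
                    f"two graphs"
                )
            if u == v:
                continue  # drop self-loops at load
            a = adjacencies[gu]
            a[node_local[u - 1], node_local[v - 1]] = 1.0
            a[node_local[v - 1], node_local[u - 1]] = 1.0

    node_labels_path = root / f"{name}_node_labels.txt"
    node_attr_path = root / f"{name}_node_attributes.txt"
    all_node_labels = (
        _read_int_lines(node_labels_path) if node_labels_path.exists() else None
    )
    all_node_attrs = None
    attribute_dim = 0
    if node_attr_path.exists():
        rows = []
        with open(node_attr_path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append([float(x) for x in line.replace(",", " ").split()])
                except ValueError as exc:
                    raise TUFormatError(
                        f"{node_attr_path.name}: line {line_no}: bad attribute row"
                    ) from exc
        all_node_attrs = np.array(rows, dtype=np.float64)
        if all_node_attrs.ndim == 1:
            all_node_attrs = all_node_attrs[:, None]
        attribute_dim = all_node_attrs.shape[1]
        if all_node_attrs.shape[0] != n_nodes_total:
            raise TUFormatError(
                f"{node_attr_path.name}: {all_node_attrs.shape[0]} rows for "
                f"{n_nodes_total} nodes"
            )
    if all_node_labels is not None and len(all_node_labels) != n_nodes_total:
        raise TUFormatError(
            f"{node_labels_path.name}: {len(all_node_labels)} rows for "
            f"{n_nodes_total} nodes"
        )

    alphabet: tuple[int, ...] = ()
    if all_node_labels is not None:
        alphabet = tuple(sorted(set(all_node_labels)))

    class_alphabet = sorted(set(raw_graph_labels))
    class_index = {c: i for i, c in enumerate(class_alphabet)}

    graphs = []
    for gi, n in enumerate(sizes):
        members = np.flatnonzero(node_graph == gi)
        labels_g = (
            np.array([all_node_labels[m] for m in members], dtype=int)
            if all_node_labels is not None
            else None
        )
        attrs_g = all_node_attrs[members] if all_node_attrs is not None else None
        features = build_feature_matrix(labels_g, attrs_g, alphabet, n_nodes=n)
        graphs.append(
            Graph(
                adjacency=adjacencies[gi],
                features=features,
                label=class_index[raw_graph_labels[gi]],
                graph_id=gi,
                node_labels=labels_g,
                node_attributes=attrs_g,
            )
        )

    return GraphDataset(
        graphs=graphs,
        n_classes=len(class_alphabet),
        node_label_alphabet=alphabet,
        attribute_dim=attribute_dim,
        name=name,
    )


def write_tu_dataset(dataset: GraphDataset, root_path, name: str | None = None) -> Path:
    """Write a dataset back out as a TU flat-file directory."""
    name = name or dataset.name
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)

    offsets = np.cumsum([0] + [g.n_nodes for g in dataset.graphs])
    with open(root / f"{name}_A.txt", "w") as fh:
        for gi, g in enumerate(dataset.graphs):
            rows, cols = np.nonzero(g.adjacency)
            for u, v in zip(rows, cols):
                fh.write(f"{offsets[gi] + u + 1}, {offsets[gi] + v + 1}\n")
    with open(root / f"{name}_graph_indicator.txt", "w") as fh:
        for gi, g in enumerate(dataset.graphs):
            fh.writelines(f"{gi + 1}\n" for _ in range(g.n_nodes))
    with open(root / f"{name}_graph_labels.txt", "w") as fh:
        fh.writelines(f"{g.label}\n" for g in dataset.graphs)

    if any(g.node_labels is not None for g in dataset.graphs):
        with open(root / f"{name}_node_labels.txt", "w") as fh:
            for g in dataset.graphs:
                fh.writelines(f"{int(lab)}\n" for lab in g.node_labels)
    if any(g.node_attributes is not None for g in dataset.graphs):
        with open(root / f"{name}_node_attributes.txt", "w") as fh:
            for g in dataset.graphs:
                for row in np.atleast_2d(g.node_attributes):
                    fh.write(", ".join(f"{x:.17g}" for x in row) + "\n")
    return root


# ---------------------------------------------------------------------
# features


def build_feature_matrix(
    node_labels: Sequence[int] | None,
    node_attributes: np.ndarray | None,
    node_label_alphabet: Sequence[int],
    n_nodes: int | None = None,
) -> np.ndarray:
    """Initial node features: ``[attribute vector, one-hot node label]``.

    If both labels and attributes are absent every node gets the constant
    vector ``[1, 1]``.
    """
    if node_labels is None and node_attributes is None:
        if n_nodes is None:
            raise ValueError("n_nodes required when labels and attributes are absent")
        return np.ones((n_nodes, 2))

    blocks = []
    n = None
    if node_attributes is not None:
        attrs = np.atleast_2d(np.asarray(node_attributes, dtype=np.float64))
        n = attrs.shape[0]
        blocks.append(attrs)
    if node_labels is not None:
        labels = np.asarray(node_labels, dtype=int)
        if n is not None and labels.shape[0] != n:
            raise ValueError("node label/attribute row counts disagree")
        n = labels.shape[0]
        index = {lab: j for j, lab in enumerate(node_label_alphabet)}
        onehot = np.zeros((n, len(node_label_alphabet)))
        for i, lab in enumerate(labels):
            if lab not in index:
                raise ValueError(f"node label {lab} outside alphabet {node_label_alphabet}")
            onehot[i, index[lab]] = 1.0
        blocks.append(onehot)
    return np.concatenate(blocks, axis=1)


def fit_feature_normalizer(
    dataset: GraphDataset, indices: Sequence[int] | None = None
) -> FeatureNormalizer:
    """Column mean/std over all nodes of all (selected) graphs.

    Standard deviation is the population form (divisor N) so the fitting
    set has exactly unit variance after application.
    """
    graphs = dataset.graphs if indices is None else [dataset.graphs[i] for i in indices]
    if not graphs:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    stacked = np.concatenate([g.features for g in graphs], axis=0)
    return FeatureNormalizer(mu=stacked.mean(axis=0), sigma=stacked.std(axis=0))


def apply_feature_normalizer(graph: Graph, norm: FeatureNormalizer) -> Graph:
    """Return a copy of ``graph`` with standardised features.

    Zero-variance columns are set to zero rather than divided by zero.
    """
    if graph.features.shape[1] != norm.mu.shape[0]:
        raise ValueError(
            f"feature dimension {graph.features.shape[1]} does not match "
            f"normalizer length {norm.mu.shape[0]}"
        )
    safe_sigma = np.where(norm.sigma == 0, 1.0, norm.sigma)
    features = (graph.features - norm.mu) / safe_sigma
    features[:, norm.sigma == 0] = 0.0
    return dataclasses.replace(graph, features=features)


def standardize_dataset(
    dataset: GraphDataset, fit_indices: Sequence[int] | None = None
) -> tuple[GraphDataset, FeatureNormalizer]:
    """Fit a normalizer (on all graphs, or ``fit_indices``) and apply to all."""
    norm = fit_feature_normalizer(dataset, fit_indices)
    graphs = [apply_feature_normalizer(g, norm) for g in dataset.graphs]
    return dataclasses.replace(dataset, graphs=graphs), norm
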