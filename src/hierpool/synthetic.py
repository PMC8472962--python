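"""Download-free benchmark data: planted-hierarchy graphs and fixtures.

Three generators support fully offline testing and experimentation:

* :func:`generate_planted_hierarchy` — graphs whose class is decided
  purely by meso-scale structure: a set of equal-size cliques joined
  either in a ring or in a chain.  Node-level statistics and feature
  distributions are (near-)identical between classes, so only an
  architecture that reasons about the coarse clique-level graph can
  separate them — exactly the capability hierarchical pooling claims
  over flat readouts.
* :func:`generate_separable_sanity` — a trivially learnable control task
  where the class is encoded directly in the node-feature mean.
* :func:`worked_fixture` — a fixed 5-node graph with fixed tiny
  parameters and every forward-pass intermediate frozen as literals
  (values computed by an independent straight-line script kept with the
  test suite), used as the numerical oracle for the pooling pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .graph_io import Graph, GraphDataset

__all__ = [
    "SynthSpec",
    "generate_planted_hierarchy",
    "generate_separable_sanity",
    "worked_fixture",
    "write_metadata",
]


@dataclass
class SynthSpec:
    """Parameters of the planted two-level-hierarchy task.

    Both classes share every structural and feature parameter except the
    clique topology (ring vs chain), so structure is the only
    discriminative signal.  Defaults give balanced 20-node graphs: 4
    cliques of 5 nodes joined by single junction edges, with constant
    base features perturbed by mild Gaussian noise (exactly constant
    features would make all graphs of a class identical, collapsing the
    task to two points).
    """

    n_graphs: int = 200
    n_cliques: int = 4
    clique_size: int = 5
    topology_per_class: dict[int, str] = field(
        default_factory=lambda: {0: "ring", 1: "chain"}
    )
    inter_clique_edges: int = 1
    feature_mode: str = "noisy"
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cliques < 3 or self.clique_size < 3:
            raise ValueError("need n_cliques >= 3 and clique_size >= 3")
        if self.n_graphs % 2 != 0 or self.n_graphs < 2:
            raise ValueError("n_graphs must be even (balanced classes)")
        if set(self.topology_per_class) != {0, 1} or not set(
            self.topology_per_class.values()
        ) <= {"ring", "chain"}:
            raise ValueError("topology_per_class must map {0, 1} to ring/chain")
        if self.feature_mode not in ("constant", "noisy"):
            raise ValueError("feature_mode must be 'constant' or 'noisy'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.inter_clique_edges < 1:
            raise ValueError("need at least one junction edge")


def _clique_graph(
    rng: np.random.Generator, spec: SynthSpec, topology: str
) -> np.ndarray:
    m, s = spec.n_cliques, spec.clique_size
    n = m * s
    A = np.zeros((n, n))
    for c in range(m):
        lo = c * s
        for i in range(lo, lo + s):
            for j in range(i + 1, lo + s):
                A[i, j] = A[j, i] = 1.0
    junctions = (
        [(c, (c + 1) % m) for c in range(m)]
        if topology == "ring"
        else [(c, c + 1) for c in range(m - 1)]
    )
    for a, b in junctions:
        for _ in range(spec.inter_clique_edges):
            u = a * s + int(rng.integers(s))
            v = b * s + int(rng.integers(s))
            while A[u, v] == 1.0:  # resample duplicates of this junction pair
                u = a * s + int(rng.integers(s))
                v = b * s + int(rng.integers(s))
            A[u, v] = A[v, u] = 1.0
    return A


def generate_planted_hierarchy(spec: SynthSpec | None = None) -> GraphDataset:
    """Balanced ring-vs-chain-of-cliques dataset, deterministic given seed."""
    spec = spec or SynthSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cliques * spec.clique_size
    graphs = []
    for g in range(spec.n_graphs):
        label = g % 2
        A = _clique_graph(rng, spec, spec.topology_per_class[label])
        base = np.ones((n, 2))
        if spec.feature_mode == "noisy":
            attrs = base + spec.noise_sd * rng.standard_normal((n, 2))
        else:
            attrs = None
        features = attrs if attrs is not None else base
        graphs.append(
            Graph(
                adjacency=A,
                features=features.copy(),
                label=label,
                graph_id=g,
                node_attributes=attrs,
            )
        )
    return GraphDataset(
        graphs=graphs,
        n_classes=2,
        node_label_alphabet=(),
        attribute_dim=2 if spec.feature_mode == "noisy" else 0,
        name="planted_hierarchy",
    )


def generate_separable_sanity(n_graphs: int = 40, seed: int = 0) -> GraphDataset:
    """Linearly separable control task: class encoded in the feature mean.

    Class-c graphs carry node features centred at 2c; the topology is an
    uninformative sparse random graph shared across classes.  Any
    competent classifier reaches test accuracy 1.0.
    """
    if n_graphs < 10:
        raise ValueError("need at least 10 graphs")
    rng = np.random.default_rng(seed)
    graphs = []
    for g in range(n_graphs):
        label = g % 2
        n = int(rng.integers(8, 13))
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    A[i, j] = A[j, i] = 1.0
        attrs = 2.0 * label + 0.25 * rng.standard_normal((n, 2))
        graphs.append(
            Graph(
                adjacency=A,
                features=attrs.copy(),
                label=label,
                graph_id=g,
                node_attributes=attrs,
            )
        )
    return GraphDataset(
        graphs=graphs,
        n_classes=2,
        node_label_alphabet=(),
        attribute_dim=2,
        name="separable_sanity",
    )


def write_metadata(spec: SynthSpec, root_path, name: str) -> None:
    """Echo the generating spec (including seed) next to the TU files."""
    payload = asdict(spec)
    payload["topology_per_class"] = {
        str(k): v for k, v in payload["topology_per_class"].items()
    }
    with open(Path(root_path) / f"{name}_meta.json", "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------
# the worked 5-node fixture


def worked_fixture() -> tuple[Graph, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Fixed 5-node graph, tiny parameters, and frozen expected values.

    The model is one merged-GNN pooling pass at its smallest useful size
    (K = 1, width 2, 2 clusters, 2 classes) followed by coarsening, both
    auxiliary losses, the single-level normalised readout (so the graph
    embedding has length 2) and the classification head.  The expected
    intermediates were computed by the independent straight-line script
    shipped with the test suite and are frozen here to full precision.
    """
    adjacency = np.zeros((5, 5))
    for u, v in [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2)]:
        adjacency[u, v] = adjacency[v, u] = 1.0
    features = np.array(
        [
            [1.0, 0.5],
            [0.2, -0.3],
            [-0.5, 1.2],
            [0.8, 0.1],
            [-0.2, -0.7],
        ]
    )
    graph = Graph(adjacency=adjacency, features=features, label=1, graph_id=0)

    params = {
        "gnn.w1": np.array([[0.5, -0.3], [0.2, 0.4]]),
        "gnn.b1": np.array([0.1, -0.1]),
        "assign.W": np.array([[0.7, -0.2], [-0.5, 0.6]]),
        "assign.B": np.array([0.05, -0.05]),
        "head.W1": np.array([[0.3, -0.4], [0.6, 0.2]]),
        "head.b1": np.array([0.01, -0.02]),
        "head.W2": np.array([[-0.5, 0.5], [0.4, -0.1]]),
        "head.b2": np.array([0.0, 0.1]),
    }

    expected = _FIXTURE_EXPECTED
    return graph, params, {k: np.array(v) for k, v in expected.items()}


# Frozen output of tests/straightline_oracle.single_level_intermediates on
# the fixture above (full float64 precision).
_FIXTURE_EXPECTED: dict = {
    "Z": [
        [0.31, 0.016666666666666663],
        [0.31, 0.016666666666666663],
        [0.36250000000000004, 0.0],
        [0.15666666666666668, 0.0],
        [0.19000000000000003, 0.0],
    ],
    "S": [
        [0.5892018056743576, 0.41079819432564235],
        [0.5892018056743576, 0.41079819432564235],
        [0.6049778484437449, 0.3950221515562551],
        [0.5599600688121389, 0.44003993118786106],
        [0.5673383870169968, 0.4326616129830031],
    ],
    "X1": [
        [0.7801309605594239, 0.01964006018914525],
        [0.5490357061072428, 0.013693273144188075],
    ],
    "A1": [
        [3.4330342581603857, 2.4259650345095545],
        [2.425965034509554, 1.7150356728205054],
    ],
    "L_LP": 2.5092018739242303,
    "L_E": 0.6790454386109539,
    "hG": [0.4285370527167215, 0.010747010726438152],
    "log_probs": [-0.8231368439699668, -0.5781275217190874],
    "loss_classification": 0.5781275217190874,
    "loss_total": 3.7663748342542718,
}
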