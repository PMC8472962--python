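"""Full hierarchical pooling classifiers.

An L-stage model (default L = 3) runs a pooling layer followed by
coarsening after each of the first L-1 GNN stages and a plain GNN at the
final stage.  The graph embedding is read out from the per-stage node
embeddings and classified by a two-layer head with log-softmax output.

Architectures:

``fpool``
    merged-GNN pooling layers; readout concatenates the
    Frobenius-normalised column means of all L embedding matrices
    (skip-connection-style multi-level readout), so the graph embedding
    has length d_1 + ... + d_L.
``diffpool``
    two-GNN pooling layers; the baseline readout uses the final stage's
    (normalised) embeddings only.  ``concat_readout`` gives DiffPool the
    multi-level readout for ablations.
``mean_baseline``
    structure-blind control: the same head applied to the column mean of
    the raw node features, with no message passing at all.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .graph_io import Graph
from .losses import LossBreakdown, total_loss
from .message_passing import (
    GnnModuleParams,
    NodeEmbeddings,
    glorot,
    gnn_forward,
    init_gnn_params,
)
from .pooling import (
    AssignmentMatrix,
    CoarsenedGraph,
    FPoolAssignParams,
    coarsen,
    diffpool_layer,
    fpool_layer,
)

__all__ = [
    "ModelConfig",
    "PoolingTrace",
    "init_parameters",
    "init_fpool_layer_params",
    "init_diffpool_layer_params",
    "forward",
    "forward_tensors",
    "loss_for_graph",
    "readout",
    "count_parameters",
    "argmax_assignment",
    "save_checkpoint",
    "load_checkpoint",
]

_ARCHITECTURES = ("fpool", "diffpool", "mean_baseline")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the benchmark protocol: K = 3 message-passing
    iterations per GNN module, 64 hidden units, 3 GNN stages with 25
    clusters at each of the two pooling levels, and unit weights on the
    auxiliary losses.
    """

    architecture: str = "fpool"
    input_dim: int = 2
    n_classes: int = 2
    n_stages: int = 3
    k: int = 3
    hidden: int = 64
    clusters: tuple[int, ...] = (25, 25)
    head_hidden: int = 64
    lp_weight: float = 1.0
    ent_weight: float = 1.0
    seed: int = 0
    inner_relu: bool = False
    row_normalize: bool = False
    concat_readout: bool = False  # give DiffPool the multi-level readout
    normalize_lp: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in _ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture != "mean_baseline":
            if len(self.clusters) != self.n_stages - 1:
                raise ValueError(
                    f"{len(self.clusters)} cluster counts for "
                    f"{self.n_stages - 1} pooling levels"
                )
            if any(c < 1 for c in self.clusters):
                raise ValueError("cluster counts must be positive")
        if min(self.k, self.hidden, self.head_hidden, self.n_stages) < 1:
            raise ValueError("k, hidden, head_hidden, n_stages must be positive")

    @property
    def embedding_size(self) -> int:
        """Length of the graph embedding fed to the classification head."""
        if self.architecture == "mean_baseline":
            return self.input_dim
        if self.architecture == "fpool" or self.concat_readout:
            return self.hidden * self.n_stages
        return self.hidden


@dataclass
class PoolingTrace:
    """All intermediates of one forward pass, for inspection and export."""

    assignments: list[AssignmentMatrix]
    embeddings: list[NodeEmbeddings]
    coarsened: list[CoarsenedGraph]
    graph_embedding: np.ndarray


# ---------------------------------------------------------------------
# parameter construction


def _stage_dims(config: ModelConfig, stage: int) -> list[int]:
    first = config.input_dim if stage == 1 else config.hidden
    return [first] + [config.hidden] * config.k


def init_parameters(config: ModelConfig) -> dict[str, Tensor]:
    """Glorot-initialised flat parameter dict, seeded from the config.

    Naming: ``stage{l}.{gnn|embed|pool}.{w|b}{k}``, ``stage{l}.assign.{W|B}``
    and ``head.{W1|b1|W2|b2}``.  The second name segment decides whether an
    entry counts as a GNN parameter (``gnn``/``embed``/``pool``) or not.
    """
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}

    def add_gnn(prefix: str, dims: list[int]) -> None:
        module = init_gnn_params(rng, dims)
        for k, (w, b) in enumerate(zip(module.weights, module.biases), start=1):
            params[f"{prefix}.w{k}"] = w
            params[f"{prefix}.b{k}"] = b

    if config.architecture != "mean_baseline":
        for stage in range(1, config.n_stages + 1):
            dims = _stage_dims(config, stage)
            if config.architecture == "fpool":
                add_gnn(f"stage{stage}.gnn", dims)
            else:
                add_gnn(f"stage{stage}.embed", dims)
                if stage < config.n_stages:
                    add_gnn(f"stage{stage}.pool", dims)
            if stage < config.n_stages:
                n_clusters = config.clusters[stage - 1]
                params[f"stage{stage}.assign.W"] = Tensor(
                    glorot(rng, config.hidden, n_clusters), requires_grad=True
                )
                params[f"stage{stage}.assign.B"] = Tensor(
                    np.zeros(n_clusters), requires_grad=True
                )

    params["head.W1"] = Tensor(
        glorot(rng, config.embedding_size, config.head_hidden), requires_grad=True
    )
    params["head.b1"] = Tensor(
        np.full(config.head_hidden, 0.01), requires_grad=True
    )  # positive start: head stays trainable even for an all-zero embedding
    params["head.W2"] = Tensor(
        glorot(rng, config.head_hidden, config.n_classes), requires_grad=True
    )
    params["head.b2"] = Tensor(np.zeros(config.n_classes), requires_grad=True)
    return params


def init_fpool_layer_params(
    rng: np.random.Generator, input_dim: int, hidden: int, k: int, n_clusters: int
) -> dict[str, Tensor]:
    """Parameters of a single stand-alone FPool pooling layer."""
    params: dict[str, Tensor] = {}
    module = init_gnn_params(rng, [input_dim] + [hidden] * k)
    for i, (w, b) in enumerate(zip(module.weights, module.biases), start=1):
        params[f"gnn.w{i}"] = w
        params[f"gnn.b{i}"] = b
    params["assign.W"] = Tensor(glorot(rng, hidden, n_clusters), requires_grad=True)
    params["assign.B"] = Tensor(np.zeros(n_clusters), requires_grad=True)
    return params


def init_diffpool_layer_params(
    rng: np.random.Generator, input_dim: int, hidden: int, k: int, n_clusters: int
) -> dict[str, Tensor]:
    """Parameters of a single stand-alone DiffPool pooling layer."""
    params: dict[str, Tensor] = {}
    for name in ("embed", "pool"):
        module = init_gnn_params(rng, [input_dim] + [hidden] * k)
        for i, (w, b) in enumerate(zip(module.weights, module.biases), start=1):
            params[f"{name}.w{i}"] = w
            params[f"{name}.b{i}"] = b
    params["assign.W"] = Tensor(glorot(rng, hidden, n_clusters), requires_grad=True)
    params["assign.B"] = Tensor(np.zeros(n_clusters), requires_grad=True)
    return params


def _gnn_module(params: dict[str, Tensor], prefix: str, k: int) -> GnnModuleParams:
    return GnnModuleParams(
        weights=[params[f"{prefix}.w{i}"] for i in range(1, k + 1)],
        biases=[params[f"{prefix}.b{i}"] for i in range(1, k + 1)],
    )


def _assign_params(params: dict[str, Tensor], stage: int) -> FPoolAssignParams:
    return FPoolAssignParams(
        W=params[f"stage{stage}.assign.W"], B=params[f"stage{stage}.assign.B"]
    )


# ---------------------------------------------------------------------
# readout and head


def readout(
    embeddings: Sequence[NodeEmbeddings], *, row_normalize: bool = False
) -> Tensor:
    """Normalised multi-level mean readout.

    Each embedding matrix is divided by its Frobenius norm (an all-zero
    matrix stays all-zero), reduced to its column mean, and the per-level
    means are concatenated in layer order.  With ``row_normalize`` each
    row is divided by its own L2 norm instead of the matrix norm.
    """
    if not embeddings:
        raise ValueError("readout needs at least one embedding matrix")
    segments = []
    for emb in embeddings:
        Z = emb.tensor
        n = Z.shape[0]
        if row_normalize:
            norms = ad.sqrt((Z * Z).sum(axis=1, keepdims=True))
            guard = (norms.data == 0).astype(float)  # zero rows divide by 1
            ZF = Z / (norms + guard)
        else:
            norm = ad.sqrt((Z * Z).sum())
            if norm.data == 0:
                segments.append(Tensor(np.zeros(Z.shape[1])))
                continue
            ZF = Z / norm
        segments.append(ZF.sum(axis=0) / float(n))
    return ad.concat(segments)


def _head(params: dict[str, Tensor], hG: Tensor) -> Tensor:
    """Linear -> ReLU -> Linear -> log-softmax over one graph embedding."""
    row = ad.reshape(hG, (1, hG.data.size))
    hidden = ad.relu(row @ params["head.W1"] + params["head.b1"])
    logits = hidden @ params["head.W2"] + params["head.b2"]
    return ad.log_softmax_rows(logits)


# ---------------------------------------------------------------------
# forward passes


def forward_tensors(
    adjacency, features, params: dict[str, Tensor], config: ModelConfig
) -> dict:
    """Differentiable forward pass; returns all intermediates as tensors."""
    A = as_tensor(adjacency)
    X = as_tensor(features)
    if config.architecture == "mean_baseline":
        hG = ad.reshape(X.sum(axis=0) / float(X.shape[0]), (config.input_dim,))
        return {
            "log_probs": _head(params, hG),
            "graph_embedding": hG,
            "assignments": [],
            "embeddings": [],
            "coarsened": [],
            "level_inputs": [],
        }

    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"graph feature width {X.shape[1]} does not match config input_dim "
            f"{config.input_dim}"
        )

    assignments: list[AssignmentMatrix] = []
    embeddings: list[NodeEmbeddings] = []
    coarsened: list[CoarsenedGraph] = []
    level_inputs: list[tuple[Tensor, AssignmentMatrix]] = []

    for stage in range(1, config.n_stages + 1):
        if stage < config.n_stages:
            if config.architecture == "fpool":
                Z, S = fpool_layer(
                    A,
                    X,
                    _gnn_module(params, f"stage{stage}.gnn", config.k),
                    _assign_params(params, stage),
                    inner_relu=config.inner_relu,
                    layer_index=stage,
                )
            else:
                Z, S = diffpool_layer(
                    A,
                    X,
                    _gnn_module(params, f"stage{stage}.embed", config.k),
                    _gnn_module(params, f"stage{stage}.pool", config.k),
                    _assign_params(params, stage),
                    inner_relu=config.inner_relu,
                    layer_index=stage,
                )
            embeddings.append(Z)
            assignments.append(S)
            level_inputs.append((A, S))
            pooled = coarsen(S, Z, A)
            coarsened.append(pooled)
            A = pooled.adjacency_tensor
            X = pooled.features_tensor
        else:
            prefix = "gnn" if config.architecture == "fpool" else "embed"
            Z = gnn_forward(
                A,
                X,
                _gnn_module(params, f"stage{stage}.{prefix}", config.k),
                inner_relu=config.inner_relu,
                layer_index=stage,
            )
            embeddings.append(Z)

    if config.architecture == "fpool" or config.concat_readout:
        hG = readout(embeddings, row_normalize=config.row_normalize)
    else:
        hG = readout(embeddings[-1:], row_normalize=config.row_normalize)

    return {
        "log_probs": _head(params, hG),
        "graph_embedding": hG,
        "assignments": assignments,
        "embeddings": embeddings,
        "coarsened": coarsened,
        "level_inputs": level_inputs,
    }


def forward(
    graph: Graph, params: dict[str, Tensor], config: ModelConfig
) -> tuple[np.ndarray, PoolingTrace]:
    """Classify one graph: log-probability vector plus the pooling trace."""
    out = forward_tensors(graph.adjacency, graph.features, params, config)
    trace = PoolingTrace(
        assignments=out["assignments"],
        embeddings=out["embeddings"],
        coarsened=out["coarsened"],
        graph_embedding=out["graph_embedding"].data.copy(),
    )
    return out["log_probs"].data.ravel().copy(), trace


def loss_for_graph(
    graph: Graph, params: dict[str, Tensor], config: ModelConfig
) -> LossBreakdown:
    """Combined training loss of one graph (differentiable total kept)."""
    out = forward_tensors(graph.adjacency, graph.features, params, config)
    return total_loss(
        out["level_inputs"],
        out["log_probs"],
        [graph.label],
        lp_weight=config.lp_weight,
        ent_weight=config.ent_weight,
        normalize_lp=config.normalize_lp,
    )


# ---------------------------------------------------------------------
# inspection


def count_parameters(params: dict[str, Tensor], scope: str = "all") -> int:
    """Count trainable entries.

    ``gnn_only`` restricts to GNN-module weights and biases (name segments
    ``gnn``, ``embed`` or ``pool``), excluding assignment maps and the
    classification head.
    """
    if scope == "all":
        return sum(p.data.size for p in params.values())
    if scope == "gnn_only":
        return sum(
            p.data.size
            for name, p in params.items()
            if name.split(".")[-2] in ("gnn", "embed", "pool")
        )
    raise ValueError(f"unknown scope {scope!r}; use 'all' or 'gnn_only'")


def argmax_assignment(assignment) -> np.ndarray:
    """Hard cluster per node: index of each row's maximum entry.

    Ties break toward the lowest cluster index.
    """
    values = (
        assignment.values
        if isinstance(assignment, AssignmentMatrix)
        else np.asarray(assignment)
    )
    return np.argmax(values, axis=1)


# ---------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig) -> None:
    """Flat named-parameter archive with the config embedded as JSON."""
    arrays = {name: p.data for name, p in params.items()}
    cfg = dataclasses.asdict(config)
    cfg["clusters"] = list(cfg["clusters"])
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig]:
    with np.load(path) as archive:
        cfg = json.loads(bytes(archive["__config__"]).decode())
        cfg["clusters"] = tuple(cfg["clusters"])
        config = ModelConfig(**cfg)
        params = {
            name: Tensor(archive[name], requires_grad=True)
            for name in archive.files
            if name != "__config__"
        }
    return params, config
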