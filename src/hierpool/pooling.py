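"""Soft cluster assignment and graph coarsening.

Both pooling layers produce node embeddings Z and a row-stochastic
assignment matrix S whose entry (i, j) is the probability that node i
belongs to cluster j of the next, coarser level:

* DiffPool runs two GNN modules — one for embeddings, one for pooling —
  and turns the pooling module's output into cluster logits through a
  linear projection.
* FPool runs a single merged GNN module and assigns clusters directly
  from the embeddings, ``S = softmax(Z W + B)``, halving the GNN
  parameter count.

The shared coarsening step ("GenerateGraph") builds the next level:
``X' = S^T Z`` and ``A' = S^T A S``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .message_passing import GnnModuleParams, NodeEmbeddings, gnn_forward

__all__ = [
    "AssignmentMatrix",
    "FPoolAssignParams",
    "CoarsenedGraph",
    "row_softmax",
    "fpool_layer",
    "diffpool_layer",
    "coarsen",
]


@dataclass
class AssignmentMatrix:
    """Row-stochastic soft assignment of nodes to clusters."""

    tensor: Tensor
    source_layer: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.tensor.data

    @property
    def n_clusters(self) -> int:
        return self.tensor.shape[1]


@dataclass
class FPoolAssignParams:
    """Linear cluster-logit map: weight d x n_clusters, bias n_clusters."""

    W: Tensor
    B: Tensor

    def entry_count(self) -> int:
        return self.W.data.size + self.B.data.size


@dataclass
class CoarsenedGraph:
    """Adjacency and features of the pooled graph at one level."""

    adjacency_tensor: Tensor
    features_tensor: Tensor
    level: int

    @property
    def adjacency(self) -> np.ndarray:
        return self.adjacency_tensor.data

    @property
    def features(self) -> np.ndarray:
        return self.features_tensor.data


def row_softmax(logits, source_layer: int = 0) -> AssignmentMatrix:
    """Numerically stable softmax over every row of a logit matrix."""
    return AssignmentMatrix(
        tensor=ad.softmax_rows(as_tensor(logits)), source_layer=source_layer
    )


def fpool_layer(
    adjacency,
    features,
    merged_params: GnnModuleParams,
    assign_params: FPoolAssignParams,
    *,
    inner_relu: bool = False,
    layer_index: int = 0,
) -> tuple[NodeEmbeddings, AssignmentMatrix]:
    """One merged-GNN pooling layer: Z from one GNN, S directly from Z."""
    if assign_params.W.shape[0] != merged_params.weights[-1].shape[1]:
        raise ValueError(
            f"assignment weight rows {assign_params.W.shape[0]} do not match "
            f"GNN output width {merged_params.weights[-1].shape[1]}"
        )
    Z = gnn_forward(
        adjacency, features, merged_params, inner_relu=inner_relu, layer_index=layer_index
    )
    S = row_softmax(Z.tensor @ assign_params.W + assign_params.B, source_layer=layer_index)
    return Z, S


def diffpool_layer(
    adjacency,
    features,
    embed_params: GnnModuleParams,
    pool_params: GnnModuleParams,
    assign_params: FPoolAssignParams,
    *,
    inner_relu: bool = False,
    layer_index: int = 0,
) -> tuple[NodeEmbeddings, AssignmentMatrix]:
    """One DiffPool layer: two independent GNN modules.

    The pooling module mirrors the embedding module's shape and its output
    is projected to cluster logits by ``assign_params`` (counted as
    assignment parameters, not GNN parameters — exactly as FPool's
    assignment map is).
    """
    if assign_params.W.shape[0] != pool_params.weights[-1].shape[1]:
        raise ValueError(
            f"cluster-logit projection rows {assign_params.W.shape[0]} do not "
            f"match pooling-GNN output width {pool_params.weights[-1].shape[1]}"
        )
    Z = gnn_forward(
        adjacency, features, embed_params, inner_relu=inner_relu, layer_index=layer_index
    )
    P = gnn_forward(
        adjacency, features, pool_params, inner_relu=inner_relu, layer_index=layer_index
    )
    S = row_softmax(P.tensor @ assign_params.W + assign_params.B, source_layer=layer_index)
    return Z, S


def coarsen(
    assignment: AssignmentMatrix, embeddings: NodeEmbeddings, adjacency
) -> CoarsenedGraph:
    """GenerateGraph: features S^T Z and adjacency S^T A S of the next level.

    For a row-stochastic S the total edge mass sum_ij A_ij is conserved
    and a symmetric parent adjacency yields a symmetric coarsened one.
    """
    S = assignment.tensor
    Z = embeddings.tensor
    A = as_tensor(adjacency)
    if S.shape[0] != Z.shape[0] or S.shape[0] != A.shape[0]:
        raise ValueError(
            f"assignment rows {S.shape[0]} must match node count "
            f"({Z.shape[0]} embeddings, adjacency {A.shape[0]})"
        )
    return CoarsenedGraph(
        adjacency_tensor=S.T @ A @ S,
        features_tensor=S.T @ Z,
        level=assignment.source_layer + 1,
    )
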