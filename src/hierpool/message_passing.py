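"""GraphSAGE-style mean-aggregator message passing.

One GNN module runs K message-passing iterations; each iteration replaces
every node state by a weighted mean over the node's neighbourhood (self
included at weight 1) followed by a learned linear map and ReLU:

    H(k) = ReLU( MEAN_A(H(k-1)) W(k) + b(k) )

The weighted mean accepts any non-negative adjacency, so the same module
runs on the hard 0/1 adjacency of an input graph and on the dense
real-valued adjacency of a coarsened graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

__all__ = [
    "GnnModuleParams",
    "NodeEmbeddings",
    "glorot",
    "init_gnn_params",
    "weighted_neighbor_mean",
    "gnn_forward",
]


@dataclass
class GnnModuleParams:
    """Weights and biases of the K linear maps of one GNN module."""

    weights: list[Tensor]
    biases: list[Tensor]

    @property
    def K(self) -> int:
        return len(self.weights)

    def validate(self) -> None:
        if len(self.biases) != len(self.weights):
            raise ValueError("one bias vector per weight matrix required")
        for k in range(len(self.weights) - 1):
            if self.weights[k].shape[1] != self.weights[k + 1].shape[0]:
                raise ValueError(f"dimension chain broken between W({k+1}) and W({k+2})")

    def entry_count(self) -> int:
        return sum(w.data.size for w in self.weights) + sum(
            b.data.size for b in self.biases
        )


@dataclass
class NodeEmbeddings:
    """Per-node embedding rows produced by one GNN module."""

    tensor: Tensor
    layer_index: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.tensor.data


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Symmetric uniform initialisation scaled by fan-in and fan-out."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


BIAS_INIT = 0.01
"""Small positive bias so an all-zero feature block (e.g. a standardised
constant column) does not start every ReLU at a dead zero-subgradient
point."""


def init_gnn_params(rng: np.random.Generator, dims: list[int]) -> GnnModuleParams:
    """Glorot-initialised module mapping dims[0] -> ... -> dims[-1]."""
    weights = [
        Tensor(glorot(rng, dims[k], dims[k + 1]), requires_grad=True)
        for k in range(len(dims) - 1)
    ]
    biases = [
        Tensor(np.full(dims[k + 1], BIAS_INIT), requires_grad=True)
        for k in range(len(dims) - 1)
    ]
    return GnnModuleParams(weights=weights, biases=biases)


def weighted_neighbor_mean(adjacency, states) -> Tensor:
    """Weighted neighbourhood mean with the node itself included at weight 1.

    Row v of the result is ``(h_v + sum_u A_vu h_u) / (1 + sum_u A_vu)``;
    an isolated node therefore keeps its own state, and zero-weight edges
    are exactly equivalent to absent edges.
    """
    A = as_tensor(adjacency)
    H = as_tensor(states)
    numer = H + A @ H
    denom = A.sum(axis=1, keepdims=True) + 1.0
    return numer / denom


def gnn_forward(
    adjacency,
    features,
    params: GnnModuleParams,
    *,
    inner_relu: bool = False,
    layer_index: int = 0,
) -> NodeEmbeddings:
    """Run K message-passing iterations and return the final node states.

    With ``inner_relu`` the incoming states are rectified before
    aggregation as well (a variant reading of the mean-aggregator update);
    the default applies one learned linear map per iteration, after the
    weighted mean.
    """
    A = as_tensor(adjacency)
    H = as_tensor(features)
    if H.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"feature width {H.shape[1]} does not match W(1) rows "
            f"{params.weights[0].shape[0]}"
        )
    for W, b in zip(params.weights, params.biases):
        incoming = ad.relu(H) if inner_relu else H
        H = ad.relu(weighted_neighbor_mean(A, incoming) @ W + b)
    return NodeEmbeddings(tensor=H, layer_index=layer_index)
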