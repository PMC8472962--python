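import numpy as np
import pytest

from hierpool import autodiff as ad
from hierpool.autodiff import Tensor
from hierpool.graph_io import Graph
from hierpool.losses import classification_loss, entropy_loss, link_prediction_loss
from hierpool.message_passing import GnnModuleParams
from hierpool.model import readout
from hierpool.pooling import FPoolAssignParams, coarsen, fpool_layer
from hierpool.synthetic import worked_fixture


def random_graph(rng, n=8, d=3, p=0.3, label=0):
    """Random undirected graph with Gaussian node features."""
    upper = np.triu((rng.random((n, n)) < p).astype(float), 1)
    adjacency = upper + upper.T
    return Graph(
        adjacency=adjacency,
        features=rng.standard_normal((n, d)),
        label=label,
        graph_id=0,
    )


def single_level_pipeline(graph, params):
    """The package-side forward pass of the 5-node worked fixture.

    Composes the public operations (merged-GNN pooling layer, coarsening,
    auxiliary losses, normalised single-level readout and the
    classification head) exactly as the straight-line oracle does, and
    returns every intermediate plus the differentiable combined loss.
    """
    tensors = {
        name: v if isinstance(v, Tensor) else Tensor(v, requires_grad=True)
        for name, v in params.items()
    }
    gnn = GnnModuleParams(weights=[tensors["gnn.w1"]], biases=[tensors["gnn.b1"]])
    assign = FPoolAssignParams(W=tensors["assign.W"], B=tensors["assign.B"])
    Z, S = fpool_layer(graph.adjacency, graph.features, gnn, assign)
    pooled = coarsen(S, Z, graph.adjacency)
    lp = link_prediction_loss(graph.adjacency, S)
    ent = entropy_loss(S)
    hG = readout([Z])
    row = ad.reshape(hG, (1, hG.data.size))
    hidden = ad.relu(row @ tensors["head.W1"] + tensors["head.b1"])
    log_probs = ad.log_softmax_rows(hidden @ tensors["head.W2"] + tensors["head.b2"])
    cls = classification_loss(log_probs, [graph.label])
    total = cls + lp + ent
    return {
        "params": tensors,
        "Z": Z,
        "S": S,
        "X1": pooled.features_tensor,
        "A1": pooled.adjacency_tensor,
        "L_LP": lp,
        "L_E": ent,
        "hG": hG,
        "log_probs": log_probs,
        "loss_classification": cls,
        "loss_total": total,
    }


@pytest.fixture
def fixture_graph():
    graph, params, expected = worked_fixture()
    return graph, params, expected
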