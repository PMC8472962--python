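"""Training losses: classification, link prediction and assignment entropy.

The classification head is trained with negative log-likelihood under
log-softmax outputs.  Two auxiliary losses regularise the soft cluster
assignments at every pooling level:

* link prediction, ``|| A - S S^T ||_F`` — connected nodes should share
  cluster assignments;
* entropy, the mean per-row entropy of S — assignments should approach
  one-hot.

Auxiliary terms are averaged over pooling levels before the weighted
combination so the loss weights mean the same thing at any depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .pooling import AssignmentMatrix

__all__ = [
    "LossBreakdown",
    "link_prediction_loss",
    "entropy_loss",
    "classification_loss",
    "total_loss",
]


@dataclass
class LossBreakdown:
    """Scalar loss components of one forward pass.

    ``total_tensor`` keeps the differentiable combined loss for backprop;
    the float fields are its detached components for logging.
    """

    classification: float
    link_prediction: float
    entropy: float
    total: float
    weights: tuple[float, float]
    total_tensor: Tensor | None = field(default=None, repr=False, compare=False)


def _assignment_tensor(assignment) -> Tensor:
    if isinstance(assignment, AssignmentMatrix):
        return assignment.tensor
    return as_tensor(assignment)


def link_prediction_loss(adjacency, assignment, *, normalize: bool = False) -> Tensor:
    """Frobenius norm of ``A - S S^T`` (optionally divided by n^2)."""
    A = as_tensor(adjacency)
    S = _assignment_tensor(assignment)
    if A.shape[0] != S.shape[0] or A.shape[0] != A.shape[1]:
        raise ValueError(
            f"adjacency {A.shape} and assignment {S.shape} are not conformable"
        )
    diff = A - S @ S.T
    norm = ad.sqrt((diff * diff).sum())
    if normalize:
        norm = norm / float(A.shape[0] ** 2)
    return norm


def entropy_loss(assignment) -> Tensor:
    """Mean per-row entropy (natural log) of a row-stochastic matrix."""
    S = _assignment_tensor(assignment)
    n = S.shape[0]
    return -ad.xlogx(S).sum() / float(n)


def classification_loss(log_probabilities, labels) -> Tensor:
    """Mean negative log-likelihood of the true classes.

    ``log_probabilities`` is a batch x n_classes matrix of log-softmax
    outputs; ``labels`` the integer class per row.
    """
    logp = as_tensor(log_probabilities)
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    batch, n_classes = logp.shape
    if labels.shape[0] != batch:
        raise ValueError(f"{labels.shape[0]} labels for a batch of {batch}")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"label outside [0, {n_classes})")
    onehot = np.zeros((batch, n_classes))
    onehot[np.arange(batch), labels] = 1.0
    return -(logp * onehot).sum() / float(batch)


def total_loss(
    level_inputs: Sequence[tuple[object, object]],
    log_probabilities,
    labels,
    lp_weight: float = 1.0,
    ent_weight: float = 1.0,
    *,
    normalize_lp: bool = False,
) -> LossBreakdown:
    """Combine the three losses over all pooling levels.

    ``level_inputs`` holds one ``(adjacency, assignment)`` pair per pooling
    level — the adjacency is the one the assignment was computed from.
    Link-prediction and entropy terms are averaged over levels, then
    combined as ``classification + lp_weight * L_LP + ent_weight * L_E``.
    """
    cls = classification_loss(log_probabilities, labels)
    if level_inputs:
        n_levels = float(len(level_inputs))
        lp = None
        ent = None
        for A, S in level_inputs:
            term_lp = link_prediction_loss(A, S, normalize=normalize_lp)
            term_ent = entropy_loss(S)
            lp = term_lp if lp is None else lp + term_lp
            ent = term_ent if ent is None else ent + term_ent
        lp = lp / n_levels
        ent = ent / n_levels
    else:
        lp = Tensor(0.0)
        ent = Tensor(0.0)
    total = cls + lp_weight * lp + ent_weight * ent
    return LossBreakdown(
        classification=float(cls),
        link_prediction=float(lp),
        entropy=float(ent),
        total=float(total),
        weights=(float(lp_weight), float(ent_weight)),
        total_tensor=total,
    )
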