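"""Training and evaluation protocol for whole-graph classification.

The benchmark protocol: stratified 8:1:1 train/validation/test splits,
mini-batch gradient training with per-graph forward passes and gradient
accumulation (graphs have varying node counts, so there is no padding),
best-on-validation model selection, exact-match accuracy, and repeated
runs summarised as mean +/- population standard deviation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .graph_io import GraphDataset, standardize_dataset
from .losses import total_loss
from .model import ModelConfig, forward, forward_tensors, init_parameters

__all__ = [
    "SplitIndices",
    "TrainResult",
    "EvalSummary",
    "split_811",
    "accuracy",
    "select_best_epoch",
    "predict",
    "evaluate",
    "train",
    "repeated_evaluation",
]


@dataclass
class SplitIndices:
    """Disjoint train/validation/test indices into a dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def validate(self, n: int) -> None:
        parts = [self.train, self.validation, self.test]
        combined = np.concatenate(parts)
        if len(set(combined.tolist())) != len(combined) or len(combined) != n:
            raise ValueError("splits must be disjoint and cover the dataset")


@dataclass
class TrainResult:
    """Per-epoch traces and the selected best-on-validation parameters."""

    params: dict[str, Tensor]
    best_epoch: int
    best_val_accuracy: float
    train_accuracy: list[float]
    val_accuracy: list[float]
    loss_trace: list[dict[str, float]]


@dataclass
class EvalSummary:
    """Per-repeat test accuracies with their mean and population std."""

    per_repeat_accuracy: list[float]
    mean: float
    std: float
    n_repeats: int


# ---------------------------------------------------------------------
# splitting


def split_811(dataset: GraphDataset, seed: int) -> SplitIndices:
    """Stratified 8:1:1 split, deterministic given (dataset, seed).

    Validation and test each receive floor(n/10) graphs, allocated to
    classes by largest remainder so every class is represented in
    proportion; the remainder stays in train.  A class with fewer than 3
    graphs is kept whole in train with a warning.
    """
    labels = dataset.labels
    n = len(dataset)
    if n < 10:
        raise ValueError("split_811 needs at least 10 graphs")
    rng = np.random.default_rng(seed)

    by_class: dict[int, np.ndarray] = {}
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        by_class[c] = rng.permutation(idx)

    eligible = {}
    for c, idx in by_class.items():
        if len(idx) < 3:
            warnings.warn(
                f"class {c} has only {len(idx)} graph(s); kept whole in train"
            )
        else:
            eligible[c] = idx

    def allocate(total: int) -> dict[int, int]:
        ideals = {c: len(idx) / 10.0 for c, idx in eligible.items()}
        base = {c: int(np.floor(v)) for c, v in ideals.items()}
        short = total - sum(base.values())
        remainders = sorted(
            eligible, key=lambda c: (-(ideals[c] - base[c]), c)
        )
        for c in remainders[:short]:
            base[c] += 1
        return base

    n_eligible = sum(len(idx) for idx in eligible.values())
    target = n_eligible // 10
    test_alloc = allocate(target)
    val_alloc = allocate(target)

    train_parts, val_parts, test_parts = [], [], []
    for c, idx in by_class.items():
        if c not in eligible:
            train_parts.append(idx)
            continue
        nt, nv = test_alloc[c], val_alloc[c]
        test_parts.append(idx[:nt])
        val_parts.append(idx[nt : nt + nv])
        train_parts.append(idx[nt + nv :])

    split = SplitIndices(
        train=np.sort(np.concatenate(train_parts)).astype(int),
        validation=np.sort(np.concatenate(val_parts)).astype(int)
        if val_parts
        else np.array([], dtype=int),
        test=np.sort(np.concatenate(test_parts)).astype(int)
        if test_parts
        else np.array([], dtype=int),
        seed=seed,
    )
    split.validate(n)
    return split


# ---------------------------------------------------------------------
# metrics


def accuracy(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if predicted.size == 0:
        raise ValueError("accuracy of an empty set is undefined")
    return float(np.mean(predicted == truth))


def select_best_epoch(val_accuracies: Sequence[float]) -> int:
    """Index of the highest validation accuracy (earliest epoch on ties)."""
    return int(np.argmax(np.asarray(val_accuracies)))


def predict(
    dataset: GraphDataset,
    indices: Sequence[int],
    params: dict[str, Tensor],
    config: ModelConfig,
) -> np.ndarray:
    preds = np.empty(len(indices), dtype=int)
    for j, i in enumerate(indices):
        log_probs, _ = forward(dataset.graphs[i], params, config)
        preds[j] = int(np.argmax(log_probs))
    return preds


def evaluate(
    dataset: GraphDataset,
    indices: Sequence[int],
    params: dict[str, Tensor],
    config: ModelConfig,
) -> float:
    preds = predict(dataset, indices, params, config)
    truth = dataset.labels[np.asarray(indices, dtype=int)]
    return accuracy(preds, truth)


# ---------------------------------------------------------------------
# training


def train(
    config: ModelConfig,
    splits: SplitIndices,
    dataset: GraphDataset,
    epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 20,
) -> TrainResult:
    """Gradient training with best-on-validation model selection.

    Each epoch shuffles the training graphs, accumulates per-graph
    gradients over mini-batches of ``batch_size`` and takes one Adam step
    per batch.  After every epoch the validation accuracy is measured;
    the returned parameters belong to the epoch with the highest
    validation accuracy (earliest on ties).  Training accuracy is
    tracked from the in-epoch forward passes.  Fully deterministic given
    the config seed.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    params = init_parameters(config)
    optimizer = Adam(params, lr=lr)
    batch_rng = np.random.default_rng([config.seed, 1])
    train_idx = np.asarray(splits.train, dtype=int)
    labels = dataset.labels

    train_trace: list[float] = []
    val_trace: list[float] = []
    loss_trace: list[dict[str, float]] = []
    best_val = -np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] = {}

    for epoch in range(epochs):
        order = batch_rng.permutation(train_idx)
        correct = 0
        sums = {"classification": 0.0, "link_prediction": 0.0, "entropy": 0.0, "total": 0.0}
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            optimizer.zero_grad()
            for i in batch:
                g = dataset.graphs[i]
                out = forward_tensors(g.adjacency, g.features, params, config)
                breakdown = total_loss(
                    out["level_inputs"],
                    out["log_probs"],
                    [g.label],
                    lp_weight=config.lp_weight,
                    ent_weight=config.ent_weight,
                    normalize_lp=config.normalize_lp,
                )
                for key in sums:
                    value = getattr(breakdown, key)
                    if not np.isfinite(value):
                        raise RuntimeError(
                            f"non-finite {key} loss at epoch {epoch + 1}, graph {i}"
                        )
                    sums[key] += value
                (breakdown.total_tensor / float(len(batch))).backward()
                correct += int(np.argmax(out["log_probs"].data) == labels[i])
            optimizer.step()
        # training accuracy from the in-epoch forward passes (no extra sweep)
        train_acc = correct / max(len(order), 1)
        val_acc = (
            evaluate(dataset, splits.validation, params, config)
            if len(splits.validation)
            else train_acc
        )
        train_trace.append(train_acc)
        val_trace.append(val_acc)
        n_train = max(len(order), 1)
        loss_trace.append({k: v / n_train for k, v in sums.items()})
        if val_acc > best_val:
            best_val = val_acc
            best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in params.items()}

    selected = {
        k: Tensor(v, requires_grad=True) for k, v in best_params.items()
    }
    return TrainResult(
        params=selected,
        best_epoch=best_epoch,
        best_val_accuracy=float(best_val),
        train_accuracy=train_trace,
        val_accuracy=val_trace,
        loss_trace=loss_trace,
    )


def repeated_evaluation(
    config: ModelConfig,
    dataset: GraphDataset,
    n_repeats: int = 10,
    base_seed: int = 0,
    epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 20,
    normalize: str = "full",
) -> EvalSummary:
    """Repeat the split/train/select/test protocol and summarise.

    Repeat r uses seed ``base_seed + r`` for both the split and the
    parameter initialisation.  ``normalize`` controls feature
    standardisation: ``"full"`` fits the normalizer on the whole dataset
    once (the default protocol), ``"train"`` refits per repeat on that
    repeat's training split only, ``"none"`` leaves features untouched.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if normalize not in ("full", "train", "none"):
        raise ValueError("normalize must be 'full', 'train' or 'none'")

    full_ds = standardize_dataset(dataset)[0] if normalize == "full" else dataset
    accs = []
    for r in range(n_repeats):
        seed = base_seed + r
        splits = split_811(dataset, seed)
        ds = (
            standardize_dataset(dataset, fit_indices=splits.train)[0]
            if normalize == "train"
            else full_ds
        )
        cfg = dataclasses.replace(config, seed=seed)
        result = train(cfg, splits, ds, epochs=epochs, lr=lr, batch_size=batch_size)
        accs.append(evaluate(ds, splits.test, result.params, cfg))
    accs_arr = np.asarray(accs)
    return EvalSummary(
        per_repeat_accuracy=[float(a) for a in accs],
        mean=float(accs_arr.mean()),
        std=float(accs_arr.std()),
        n_repeats=n_repeats,
    )
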