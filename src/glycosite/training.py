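"""Weighted binary cross-entropy training with Adam.

The loss is the mean over residues and output classes of

    -[ w * y * log(p) + (1 - y) * log(1 - p) ]

with the weight ``w`` (default 0.9) multiplying only the positive term, to
counter the strong class imbalance of interface residues.  Probabilities
are clamped at 1e-7 for numerical safety.  Optimization is plain Adam at a
1e-4 learning rate: no schedule, no early stopping beyond retaining the
best-validation parameters.

Includes the tiny-overfit harness: a desk-scale model trained on a handful
of generated toy complexes until it memorizes their interfaces, which
exercises every part of the learning machinery end to end.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np

from .autograd import Adam, Tensor
from .dataset import CLASSES, InterfaceLabels, contact_labels
from .geomnet import InterfaceModel, ModelConfig
from .metrics import confusion_rates, summary_metrics
from .structio import AtomicStructure, SubunitPartition
from .synthetic import ToyComplexConfig, make_toy_complex

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainExample",
    "weighted_bce",
    "train",
    "tiny_overfit",
]

PROB_CLAMP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    positive_weight: float = 0.9
    batch_size: int = 1          # structures per optimizer step
    epochs: int = 10
    seed: int = 0
    device: str = "cpu"          # abstract compute target; only cpu is built
    checkpoint_every: int = 0    # epochs between checkpoints; 0 = best-val only

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 < self.positive_weight <= 1:
            raise ValueError("positive_weight must be in (0, 1]")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_bacc: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)


@dataclass
class TrainExample:
    """One training structure with its partition and interface labels."""

    structure: AtomicStructure
    partition: SubunitPartition
    labels: InterfaceLabels


def _label_matrix(labels: InterfaceLabels, keys: list) -> np.ndarray:
    """Align an InterfaceLabels object to the model's residue order."""
    if labels.residue_keys != list(keys):
        index = {k: r for r, k in enumerate(labels.residue_keys)}
        try:
            rows = [index[k] for k in keys]
        except KeyError as exc:
            raise ValueError(f"labels missing residue {exc}") from exc
    else:
        rows = list(range(len(keys)))
    return np.stack([labels.y[c][rows] for c in CLASSES], axis=1).astype(float)


def weighted_bce(probs, labels, positive_weight: float = 0.9):
    """Class-weighted BCE, mean over residues and classes.

    ``probs`` may be an autograd Tensor (for training) or a plain array;
    the return type matches (Tensor vs float).
    """
    tensor_in = isinstance(probs, Tensor)
    p = probs if tensor_in else Tensor(np.asarray(probs, dtype=float))
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    p = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    loss = -(positive_weight * y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
    return loss if tensor_in else float(loss.data)


def _dataset_loss_and_probs(model, examples):
    total, n = 0.0, 0
    per_class_probs = {c: [] for c in CLASSES}
    per_class_labels = {c: [] for c in CLASSES}
    for ex in examples:
        probs, keys, _ = model.forward_tensor(ex.structure, ex.partition)
        y = _label_matrix(ex.labels, keys)
        total += float(weighted_bce(probs, y).data) * y.size
        n += y.size
        for j, c in enumerate(CLASSES):
            per_class_probs[c].append(probs.data[:, j])
            per_class_labels[c].append(y[:, j])
    pooled = {
        c: (np.concatenate(per_class_probs[c]), np.concatenate(per_class_labels[c]))
        for c in CLASSES
    }
    return total / n, pooled


def dataset_bacc(model: InterfaceModel, examples: list[TrainExample]) -> float:
    """Balanced accuracy pooled over all residues, averaged over the output
    classes that have at least one positive label."""
    _, pooled = _dataset_loss_and_probs(model, examples)
    baccs = []
    for c in CLASSES:
        probs, y = pooled[c]
        if y.sum() == 0:
            continue
        baccs.append(summary_metrics(confusion_rates(probs, y)).BACC)
    if not baccs:
        return float("nan")
    return float(np.mean(baccs))


def train(
    model: InterfaceModel,
    train_examples: list[TrainExample],
    config: TrainConfig,
    val_examples: list[TrainExample] | None = None,
    log=None,
) -> tuple[InterfaceModel, TrainHistory]:
    """Train in place; returns the model with its best-validation parameters
    restored, plus the per-epoch history."""
    if not train_examples:
        raise ValueError("empty training split")
    val_examples = val_examples or []
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best = (np.inf, None)
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_examples))
        epoch_loss, n_res = 0.0, 0
        opt.zero_grad()
        since_step = 0
        for i in order:
            ex = train_examples[i]
            probs, keys, _ = model.forward_tensor(ex.structure, ex.partition)
            y = _label_matrix(ex.labels, keys)
            loss = weighted_bce(probs, y, config.positive_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, structure "
                    f"{ex.structure.source_id!r}: {loss.data}"
                )
            loss.backward()
            epoch_loss += float(loss.data) * y.size
            n_res += y.size
            since_step += 1
            if since_step >= config.batch_size:
                opt.step()
                opt.zero_grad()
                since_step = 0
        if since_step:
            opt.step()
            opt.zero_grad()
        history.train_loss.append(epoch_loss / n_res)
        if val_examples:
            val_loss, _ = _dataset_loss_and_probs(model, val_examples)
            vb = dataset_bacc(model, val_examples)
        else:
            val_loss, vb = history.train_loss[-1], float("nan")
        history.val_loss.append(val_loss)
        history.val_bacc.append(vb)
        history.wall_time.append(time.perf_counter() - t0)
        if val_loss < best[0]:
            best = (val_loss, {k: v.data.copy() for k, v in model.params.items()})
        if log is not None:
            log(
                f"epoch={epoch} train_loss={history.train_loss[-1]:.6f} "
                f"val_loss={val_loss:.6f} val_bacc={vb:.4f} "
                f"wall={history.wall_time[-1]:.2f}s"
            )
    if best[1] is not None:
        for k, data in best[1].items():
            model.params[k].data = data
    return model, history


def make_overfit_examples(seed: int = 7, n_complexes: int = 5) -> list[TrainExample]:
    """Toy complexes for the overfit harness: a mix of carbohydrate- and
    cyclodextrin-bound chains so both output heads see positives."""
    examples = []
    for i in range(n_complexes):
        resname = "GLC" if i % 2 == 0 else "BCD"
        cfg = ToyComplexConfig(
            n_residues=10,
            contact_residues=frozenset({(2 + i) % 8, (3 + i) % 8}),
            seed=seed * 1000 + i,
            ligand_resname=resname,
        )
        structure, partition, _ = make_toy_complex(cfg)
        labels = contact_labels(structure, partition)
        examples.append(TrainExample(structure, partition, labels))
    return examples


def tiny_overfit(
    seed: int = 7,
    epochs: int = 300,
    n_complexes: int = 5,
    data_seed: int = 7,
    log=None,
) -> dict:
    """Train a scaled-down model (4 layers, scalar size 16) to memorize a
    handful of toy complexes.  Returns the final pooled train-set BACC and
    the fractional loss reduction.  ``data_seed`` fixes the generated
    complexes (the study conditions); ``seed`` drives parameter
    initialization and shuffling."""
    examples = make_overfit_examples(data_seed, n_complexes)
    model = InterfaceModel(ModelConfig.scaled_down(scalar_size=16, n_layers=4), seed=seed)
    config = TrainConfig(epochs=epochs, seed=seed)
    model, history = train(model, examples, config, log=log)
    final_bacc = dataset_bacc(model, examples)
    reduction = 1.0 - history.train_loss[-1] / history.train_loss[0]
    return {
        "model": model,
        "history": history,
        "final_bacc": final_bacc,
        "loss_reduction": reduction,
    }
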