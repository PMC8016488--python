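"""Dataset preparation and the optimization loop.

Preparation mirrors how large orthology databases are made trainable: groups
below a minimum population are dropped entirely (singletons cannot even be
split), and the remainder is split 81/9/10 into train/validation/test,
stratified per group with largest-remainder rounding so that every group is
represented in every partition.

Optimization is Adam on the softmax cross-entropy, learning rate 0.01 decayed
by 25% after each epoch, batch size 64, with the best-on-validation epoch's
weights returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import architecture
from .alphabet_io import (
    EncodedSequence,
    GroupLabelMap,
    ProteinRecord,
    SequenceTooLongError,
    build_extended_alphabet,
    encode_pseudo_onehot,
    encode_sequence,
    pad_and_batch,
)
from .architecture import ModelState, initialize_self_normalizing  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

MAX_FILTER_PAD = 36


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    lr_decay_per_epoch: float = 0.75
    batch_size: int = 64
    max_epochs: int = 15
    seed: int = 0
    selection_metric: str = "validation_accuracy"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValueError("lr_decay_per_epoch must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.81
    validation: float = 0.09
    test: float = 0.10

    def __post_init__(self):
        parts = (self.train, self.validation, self.test)
        if any(p <= 0 for p in parts) or abs(sum(parts) - 1.0) > 1e-9:
            raise ValueError("split ratios must be positive and sum to 1")


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    @property
    def best_epoch(self) -> int:
        accs = [e["validation_accuracy"] for e in self.epochs]
        return int(np.argmax(accs))  # argmax ties -> earliest epoch


def learning_rate_at(config: TrainingConfig, epoch: int) -> float:
    """lr0 * decay^epoch — the published schedule (25% decay per epoch)."""
    return config.learning_rate * config.lr_decay_per_epoch**epoch


def filter_min_population(
    labels: dict[str, str], threshold: int
) -> tuple[list[str], dict]:
    """Drop every group with fewer than ``threshold`` members.

    Returns the retained ids (input order) and a report of removed groups with
    their member counts.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts: dict[str, int] = {}
    for g in labels.values():
        counts[g] = counts.get(g, 0) + 1
    removed = {g: c for g, c in counts.items() if c < threshold}
    retained = [i for i, g in labels.items() if g not in removed]
    if not retained:
        raise ValueError(
            f"minimum population {threshold} removed every group (largest had "
            f"{max(counts.values())} members)"
        )
    report = {
        "threshold": threshold,
        "removed_groups": removed,
        "removed_sequences": sum(removed.values()),
        "retained_groups": len(counts) - len(removed),
        "retained_sequences": len(retained),
    }
    if removed:
        logger.info(
            "min-population %d removed %d group(s), %d sequence(s)",
            threshold, len(removed), report["removed_sequences"],
        )
    return retained, report


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    quotas = [r * n for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for _ in range(n - sum(counts)):
        j = int(np.argmax(remainders))
        counts[j] += 1
        remainders[j] = -1.0
    # every partition gets at least one member, taken from the largest
    for j in range(len(counts)):
        while counts[j] == 0:
            k = int(np.argmax(counts))
            counts[k] -= 1
            counts[j] += 1
    return counts


def stratified_split(
    labels: dict[str, str],
    ratios: SplitRatios = SplitRatios(),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Per-group 81/9/10 split with largest-remainder rounding.

    Members of each group are shuffled under the seed, then allocated to
    train/validation/test; each partition receives at least one member per
    group. Groups with fewer than three members cannot be split — filter them
    out first with :func:`filter_min_population`.
    """
    by_group: dict[str, list[str]] = {}
    for i, g in labels.items():
        by_group.setdefault(g, []).append(i)
    small = {g: len(m) for g, m in by_group.items() if len(m) < 3}
    if small:
        raise ValueError(
            f"group(s) with fewer than 3 members cannot be split: {sorted(small)}; "
            "apply filter_min_population(threshold>=3) first"
        )
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for g in sorted(by_group):
        members = sorted(by_group[g])
        rng.shuffle(members)
        n_tr, n_va, n_te = _largest_remainder(
            len(members), (ratios.train, ratios.validation, ratios.test)
        )
        train.extend(members[:n_tr])
        val.extend(members[n_tr:n_tr + n_va])
        test.extend(members[n_tr + n_va:])
    return train, val, test


class SequenceDataset:
    """Encoded view over records + labels, serving batches for either variant."""

    def __init__(
        self,
        records: list[ProteinRecord],
        labels: dict[str, str],
        label_map: GroupLabelMap,
        variant: str = "deepnog",
        fixed_length: int = 1000,
    ):
        self.variant = variant
        self.fixed_length = fixed_length
        self.label_map = label_map
        self.labels = labels
        alphabet = build_extended_alphabet()
        self._encoded: dict[str, EncodedSequence] = {}
        self._records: dict[str, ProteinRecord] = {}
        self._onehot: dict[str, np.ndarray] = {}
        self.rejected: list[str] = []
        for rec in records:
            if rec.id not in labels:
                continue
            if variant == "deepfam":
                try:
                    self._onehot[rec.id] = encode_pseudo_onehot(rec, fixed_length)
                except SequenceTooLongError:
                    self.rejected.append(rec.id)
                    continue
            self._records[rec.id] = rec
            self._encoded[rec.id] = encode_sequence(rec, alphabet)

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def usable(self, ids: list[str]) -> list[str]:
        return [i for i in ids if i in self._records]

    def batch(self, ids: list[str]):
        """(inputs, y) for one batch, in the given id order."""
        y = np.array([self.label_map.index_of[self.labels[i]] for i in ids], dtype=np.int64)
        if self.variant == "deepnog":
            return pad_and_batch([self._encoded[i] for i in ids], MAX_FILTER_PAD), y
        return np.stack([self._onehot[i] for i in ids]), y


class AdamOptimizer:
    """Adam with the standard moment defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (lr * (self.m[k] / b1c)
                          / (np.sqrt(self.v[k] / b2c) + self.eps)).astype(params[k].dtype)


def evaluate_accuracy(state: ModelState, dataset: SequenceDataset,
                      ids: list[str], batch_size: int = 64) -> float:
    correct = 0
    for start in range(0, len(ids), batch_size):
        chunk = ids[start:start + batch_size]
        inputs, y = dataset.batch(chunk)
        logits = architecture.forward(state, inputs, training=False)
        correct += int((logits.argmax(axis=1) == y).sum())
    return correct / len(ids)


def train(
    state: ModelState,
    train_ids: list[str],
    val_ids: list[str],
    dataset: SequenceDataset,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[ModelState, TrainingHistory]:
    """Optimize cross-entropy with Adam; return the best-on-validation state.

    Each epoch reshuffles the training ids under the run seed, multiplies the
    learning rate by the decay factor afterwards, and records loss/accuracy.
    Ties in validation accuracy resolve to the earliest epoch.
    """
    train_ids = dataset.usable(train_ids)
    val_ids = dataset.usable(val_ids)
    if not val_ids:
        raise ValueError("validation set is empty")
    missing = {dataset.labels[i] for i in train_ids} - set(dataset.label_map.group_ids)
    if missing:
        raise ValueError(f"label map does not cover training group(s) {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    opt = AdamOptimizer(state.params)
    history = TrainingHistory()
    best_state, best_acc = None, -1.0
    order = np.array(train_ids)
    for epoch in range(config.max_epochs):
        lr = learning_rate_at(config, epoch)
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            chunk = list(order[start:start + config.batch_size])
            inputs, y = dataset.batch(chunk)
            loss, grads = architecture.loss_and_grads(state, inputs, y, dropout_rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"{loss} (lr={lr:g})"
                )
            opt.step(state.params, grads, lr)
            losses.append(loss)
        val_acc = evaluate_accuracy(state, dataset, val_ids, config.batch_size)
        history.epochs.append({
            "epoch": epoch,
            "training_loss": float(np.mean(losses)),
            "validation_accuracy": val_acc,
            "learning_rate": lr,
        })
        logger.info("epoch %d: loss %.4f, val acc %.4f, lr %.6f",
                    epoch, np.mean(losses), val_acc, lr)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = state.copy()
    return best_state, history
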