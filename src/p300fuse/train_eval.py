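"""Training with the published hyperparameters and the four evaluation metrics.

Default hyperparameters: Adam, learning rate 0.001, 75 training epochs,
mini-batches of 32, categorical cross-entropy.  Evaluation reduces each test
epoch to a hard argmax decision and tallies a confusion matrix, from which
accuracy, recall, precision, F1 (and balanced accuracy as a diagnostic for
the 1:5 target/non-target imbalance) are computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import nn
from .errors import DomainError
from .fusion import FusedEpochSet, fuse_parallel, fuse_serial
from .model import build_cnn
from .paradigm import partition_subjects
from .preprocess import EpochSet

__all__ = ["TrainConfig", "ConfusionCounts", "train", "evaluate",
           "stratified_split_indices", "run_group_experiment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults mirror the published setup)."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 75
    batch_size: int = 32
    loss: str = "categorical_crossentropy"
    seed: int = 0
    validation_fraction: float = 0.0
    class_weight: "str | dict | None" = None

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise DomainError("only the adam optimizer is supported")
        if self.loss != "categorical_crossentropy":
            raise DomainError("only categorical cross-entropy is supported")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise DomainError("learning_rate > 0, epochs >= 1, batch_size >= 1 "
                              "required")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tally over a test set ('positive' = target epoch)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_xy(epochs: "EpochSet | FusedEpochSet"):
    x = np.asarray(epochs.data, dtype=np.float32)[..., None]  # (N, T, C, 1)
    y = np.asarray(epochs.labels, dtype=np.int64)
    return x, y


def train(network: nn.Network, train_epochs: "EpochSet | FusedEpochSet",
          config: TrainConfig = TrainConfig()) -> tuple[nn.Network, list]:
    """Fit the network in place; returns it with the per-epoch loss history.

    Raises :class:`DomainError` if only one class is present (cross-entropy
    is degenerate); warns if the data was never normalized.
    """
    x, y = _as_xy(train_epochs)
    if len(np.unique(y)) < 2:
        raise DomainError("training set contains a single class; "
                          "cross-entropy training is degenerate")
    if not getattr(train_epochs, "normalized", False):
        warnings.warn("training on non-normalized epochs", stacklevel=2)
    history = network.fit(x, y, epochs=config.epochs,
                          batch_size=config.batch_size,
                          lr=config.learning_rate, seed=config.seed,
                          class_weight=config.class_weight)
    return network, history


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    """Accuracy, recall, precision, F1 (+ balanced accuracy) from a tally.

    Ratios with a zero denominator are reported as 0 with a warning.
    """
    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                          stacklevel=3)
            return 0.0
        return num / den

    acc = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    rec = ratio(counts.tp, counts.tp + counts.fn, "recall")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    f1 = (2 * rec * prec / (rec + prec)) if (rec + prec) > 0 else 0.0
    spec_ = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    return {"accuracy": acc, "recall": rec, "precision": prec, "f1": f1,
            "balanced_accuracy": 0.5 * (rec + spec_)}


def evaluate(network: nn.Network,
             test: "EpochSet | FusedEpochSet") -> tuple[ConfusionCounts, dict]:
    """Argmax-classify every test epoch and tally the confusion matrix."""
    x, y = _as_xy(test)
    if x.shape[0] == 0:
        raise DomainError("empty test set")
    pred = network.predict(x)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))))
    return counts, metrics_from_counts(counts)


def stratified_split_indices(labels: np.ndarray, test_fraction: float = 0.2,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test indices over the *shared* stimulus stream.

    Splitting on event indices (not per-subject) keeps fused epoch sets
    aligned: every subject contributes the same events to train and test.
    """
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=np.asarray(labels, dtype=int))
    return np.sort(train_idx), np.sort(test_idx)


def _subset(epochs: EpochSet, idx: np.ndarray) -> EpochSet:
    return EpochSet(data=epochs.data[idx], labels=epochs.labels[idx],
                    sampling_rate=epochs.sampling_rate,
                    subject_id=epochs.subject_id,
                    channel_labels=list(epochs.channel_labels),
                    normalized=epochs.normalized)


def _fit_and_score(train_set, test_set, config: TrainConfig,
                   first_kernel=(8, 8), model_seed: int = 0) -> dict:
    network, _ = build_cnn(train_set.n_time, train_set.n_channels,
                           first_kernel=first_kernel, seed=model_seed)
    train(network, train_set, config)
    _, metrics = evaluate(network, test_set)
    return metrics


def run_group_experiment(epoch_sets: Sequence[EpochSet],
                         group_size: int = 2,
                         mode: str = "parallel",
                         config: TrainConfig = TrainConfig(),
                         test_fraction: float = 0.2,
                         first_kernel: tuple = (8, 8)) -> pd.DataFrame:
    """Train/evaluate one classifier per group (or per subject) and tabulate.

    Parameters
    ----------
    epoch_sets
        One preprocessed, event-aligned :class:`EpochSet` per subject
        (canonically 8).
    mode
        ``"single"`` trains one model per subject (no fusion);
        ``"parallel"`` / ``"serial"`` fuse each group's epochs first.

    Returns
    -------
    DataFrame with one row per group/subject plus an ``Average`` row;
    columns: group, n_members, mode, accuracy, recall, precision, f1,
    balanced_accuracy.
    """
    if mode not in ("single", "parallel", "serial"):
        raise DomainError(f"unknown mode {mode!r}")
    epoch_sets = list(epoch_sets)
    labels = epoch_sets[0].labels
    tr_idx, te_idx = stratified_split_indices(labels, test_fraction, config.seed)

    rows = []
    if mode == "single":
        units = [(es.subject_id or f"S{i + 1}", [es])
                 for i, es in enumerate(epoch_sets)]
    else:
        by_id = {es.subject_id or f"S{i + 1}": es
                 for i, es in enumerate(epoch_sets)}
        groups = partition_subjects(list(by_id), group_size, seed=config.seed)
        units = [(g.label, [by_id[sid] for sid in g.member_subject_ids])
                 for g in groups]

    fuse = {"parallel": fuse_parallel, "serial": fuse_serial}.get(mode)
    for label, members in units:
        tr_sets = [_subset(es, tr_idx) for es in members]
        te_sets = [_subset(es, te_idx) for es in members]
        if fuse is None:
            tr_set, te_set = tr_sets[0], te_sets[0]
        else:
            tr_set, te_set = fuse(tr_sets), fuse(te_sets)
        logger.info("training %s model for %s (%d members)", mode, label,
                    len(members))
        metrics = _fit_and_score(tr_set, te_set, config,
                                 first_kernel=first_kernel,
                                 model_seed=config.seed)
        rows.append({"group": label, "n_members": len(members), "mode": mode,
                     **metrics})

    table = pd.DataFrame(rows)
    avg = table.drop(columns=["group", "n_members", "mode"]).mean()
    table.loc[len(table)] = {"group": "Average",
                             "n_members": group_size if mode != "single" else 1,
                             "mode": mode, **avg.to_dict()}
    return table
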