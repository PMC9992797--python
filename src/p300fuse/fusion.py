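"""Centralized multi-subject data fusion of event-aligned epochs.

Two lossless operators combine epochs that different subjects produced in
response to the *same* stimulus stream:

parallel
    channel-wise concatenation — k subjects x 8 channels become one
    8k-channel epoch of unchanged duration (spatial-domain augmentation);

serial
    temporal concatenation — k subjects' epochs are appended in time,
    keeping the channel count (time-domain augmentation), first listed
    subject first.

Both require identical shapes, rates and label vectors across subjects and
record the subject order so the fusion can be inverted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DomainError, ShapeError
from .preprocess import EpochSet

__all__ = ["FusedEpochSet", "fuse_parallel", "fuse_serial"]


@dataclass
class FusedEpochSet:
    """Multi-subject fused epochs plus the bookkeeping needed to un-fuse."""

    data: np.ndarray
    labels: np.ndarray
    mode: str
    subject_order: list
    source_channels: int
    source_time: int
    sampling_rate: float
    channel_labels: list = field(default_factory=list)
    normalized: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=bool)
        k = len(self.subject_order)
        if self.mode == "parallel":
            ok = (self.data.shape[2] == k * self.source_channels
                  and self.data.shape[1] == self.source_time)
        elif self.mode == "serial":
            ok = (self.data.shape[1] == k * self.source_time
                  and self.data.shape[2] == self.source_channels)
        else:
            raise DomainError(f"unknown fusion mode {self.mode!r}")
        if not ok:
            raise ShapeError("fused data shape inconsistent with mode and "
                             "subject count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def group_size(self) -> int:
        return len(self.subject_order)

    def split(self) -> list[EpochSet]:
        """Invert the fusion: recover each subject's EpochSet bit-exactly."""
        out = []
        for i, sid in enumerate(self.subject_order):
            if self.mode == "parallel":
                block = self.data[:, :, i * self.source_channels:
                                  (i + 1) * self.source_channels]
            else:
                block = self.data[:, i * self.source_time:
                                  (i + 1) * self.source_time, :]
            out.append(EpochSet(data=block, labels=self.labels.copy(),
                                sampling_rate=self.sampling_rate,
                                subject_id=str(sid),
                                channel_labels=list(self.channel_labels),
                                normalized=self.normalized))
        return out


def _check_aligned(epoch_sets: Sequence[EpochSet]) -> None:
    if len(epoch_sets) == 0:
        raise DomainError("need at least one epoch set to fuse")
    ref = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.data.shape != ref.data.shape:
            raise ShapeError(f"epoch set shapes differ: {es.data.shape} "
                             f"vs {ref.data.shape}")
        if es.sampling_rate != ref.sampling_rate:
            raise ShapeError("sampling rates differ between epoch sets")
        mismatch = np.nonzero(es.labels != ref.labels)[0]
        if mismatch.size:
            raise AlignmentError(
                f"label vectors differ at epoch {int(mismatch[0])}: the sets "
                "are not aligned on a shared stimulus stream")


def _fuse(epoch_sets: Sequence[EpochSet], mode: str, axis: int) -> FusedEpochSet:
    _check_aligned(epoch_sets)
    ref = epoch_sets[0]
    data = (ref.data.copy() if len(epoch_sets) == 1
            else np.concatenate([es.data for es in epoch_sets], axis=axis))
    return FusedEpochSet(
        data=data, labels=ref.labels.copy(), mode=mode,
        subject_order=[es.subject_id for es in epoch_sets],
        source_channels=ref.n_channels, source_time=ref.n_time,
        sampling_rate=ref.sampling_rate,
        channel_labels=list(ref.channel_labels),
        normalized=all(es.normalized for es in epoch_sets))


def fuse_parallel(epoch_sets: Sequence[EpochSet]) -> FusedEpochSet:
    """Channel-stack aligned epochs: shape (E, T, C) x k -> (E, T, k*C)."""
    return _fuse(epoch_sets, "parallel", axis=2)


def fuse_serial(epoch_sets: Sequence[EpochSet]) -> FusedEpochSet:
    """Time-concatenate aligned epochs: shape (E, T, C) x k -> (E, k*T, C)."""
    return _fuse(epoch_sets, "serial", axis=1)
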