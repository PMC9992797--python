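"""The 6x6 row/column speller oddball paradigm.

A speller session presents a 6x6 character matrix whose 6 rows and 6 columns
flash one at a time in random order.  One *repetition* (round) flashes each of
the 12 rows/columns exactly once; the row and the column containing the
attended character are the two rare *target* flashes that evoke a P300.  This
module models the paradigm geometry and timing, generates reproducible
stimulus event streams, and partitions a subject roster into the fusion
groups used by the collaborative experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "SPELLER_MATRIX",
    "SpellerParadigm",
    "StimulusEvent",
    "SubjectGroup",
    "DATASET_I",
    "DATASET_II",
    "DEFAULT_CHANNELS",
    "char_to_cell",
    "target_codes",
    "default_characters",
    "build_event_stream",
    "partition_subjects",
]

#: Row-major layout of the standard 6x6 alphanumeric speller matrix.
SPELLER_MATRIX: tuple[str, ...] = (
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
)

#: 8-channel 10-20 montage used by the source recordings.
DEFAULT_CHANNELS: tuple[str, ...] = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "PO8", "Oz")


@dataclass(frozen=True)
class SpellerParadigm:
    """Geometry and timing of one speller session.

    Parameters
    ----------
    n_characters : int
        Characters spelled per session (each gets its own block of rounds).
    n_repetitions : int
        Full row+column rounds per character.
    flash_duration : float
        Seconds a row/column stays intensified.
    inter_stimulus_interval : float
        Gap in seconds between the end of one flash and the next onset.
        Stimulus-onset asynchrony is ``flash_duration + inter_stimulus_interval``.
    sampling_rate : float
        EEG sampling rate in Hz.
    inter_character_gap : float
        Pause in seconds between character blocks (target cueing time).
    """

    n_characters: int
    n_repetitions: int
    flash_duration: float = 0.100
    inter_stimulus_interval: float = 0.025
    sampling_rate: float = 240.0
    inter_character_gap: float = 2.0
    matrix_rows: int = 6
    matrix_cols: int = 6

    def __post_init__(self) -> None:
        if self.matrix_rows != 6 or self.matrix_cols != 6:
            raise DomainError("only the standard 6x6 speller matrix is supported")
        if self.n_characters < 1 or self.n_repetitions < 1:
            raise DomainError("n_characters and n_repetitions must be >= 1")
        for name in ("flash_duration", "inter_stimulus_interval", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")

    @property
    def flashes_per_repetition(self) -> int:
        return self.matrix_rows + self.matrix_cols  # 12

    @property
    def targets_per_repetition(self) -> int:
        return 2  # one row + one column contain the attended character

    @property
    def soa_seconds(self) -> float:
        """Stimulus-onset asynchrony: flash plus gap."""
        return self.flash_duration + self.inter_stimulus_interval

    @property
    def soa_samples(self) -> int:
        return int(round(self.soa_seconds * self.sampling_rate))

    @property
    def n_flashes(self) -> int:
        """Total flashes in a session."""
        return self.n_characters * self.n_repetitions * self.flashes_per_repetition


# 35 alphanumeric characters, 10 rounds each, 125 ms onset asynchrony at 240 Hz.
DATASET_I = SpellerParadigm(n_characters=35, n_repetitions=10,
                            flash_duration=0.100, inter_stimulus_interval=0.025,
                            sampling_rate=240.0)

# One character block of 15 rounds; 100 ms flash + 75 ms gap at 240 Hz.
DATASET_II = SpellerParadigm(n_characters=1, n_repetitions=15,
                             flash_duration=0.100, inter_stimulus_interval=0.075,
                             sampling_rate=240.0)

PARADIGM_PRESETS: dict[str, SpellerParadigm] = {
    "dataset1": DATASET_I,
    "dataset2": DATASET_II,
}


@dataclass(frozen=True)
class StimulusEvent:
    """One row/column flash in the continuous recording.

    ``code`` identifies which row or column flashed: by default columns carry
    codes 1-6 (left to right) and rows carry codes 7-12 (top to bottom).
    """

    onset_sample: int
    code: int
    is_target: bool
    character_index: int
    repetition_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.code <= 12:
            raise DomainError(f"stimulus code {self.code} outside 1..12")
        if self.onset_sample < 0:
            raise DomainError("onset_sample must be non-negative")


@dataclass(frozen=True)
class SubjectGroup:
    """An ordered fusion group; member order fixes channel/time order."""

    label: str
    member_subject_ids: tuple

    def __post_init__(self) -> None:
        if len(self.member_subject_ids) not in (2, 3, 4):
            raise DomainError("group size must be 2, 3 or 4")

    @property
    def group_size(self) -> int:
        return len(self.member_subject_ids)


def char_to_cell(character: "str | int") -> tuple[int, int]:
    """Map a matrix character (or flat 0-based index) to (row, col).

    Raises
    ------
    DomainError
        If the character is not in the matrix or the index is out of range.
    """
    if isinstance(character, (int, np.integer)):
        idx = int(character)
        if not 0 <= idx < 36:
            raise DomainError(f"character index {idx} outside the 6x6 matrix (0..35)")
        return divmod(idx, 6)
    ch = str(character).upper()
    for r, row in enumerate(SPELLER_MATRIX):
        c = row.find(ch)
        if c >= 0:
            return r, c
    raise DomainError(f"character {character!r} is not in the 6x6 speller matrix")


def target_codes(character: "str | int",
                 column_code_base: int = 1,
                 row_code_base: int = 7) -> tuple[int, int]:
    """Return the (column_code, row_code) pair that are targets for a character."""
    r, c = char_to_cell(character)
    return column_code_base + c, row_code_base + r


def default_characters(n: int) -> str:
    """Default spelled text: cycle the matrix characters row-major."""
    flat = "".join(SPELLER_MATRIX)
    return "".join(flat[i % len(flat)] for i in range(n))


def build_event_stream(paradigm: SpellerParadigm,
                       target_characters: "Sequence | str | None" = None,
                       seed: int = 0,
                       column_code_base: int = 1,
                       row_code_base: int = 7) -> list[StimulusEvent]:
    """Generate the full flash sequence of one speller session.

    Within every repetition the 12 codes appear exactly once in a seeded
    random order; the two codes addressing the attended character are marked
    as targets.  Onsets advance by the paradigm's stimulus-onset asynchrony,
    with an ``inter_character_gap`` pause between character blocks.

    Parameters
    ----------
    target_characters
        One entry per character block: matrix characters (string or sequence)
        or flat 0-based indices.  Defaults to cycling the matrix alphabet.
    seed
        Seeds the per-repetition shuffles; the stream is a pure function of
        (paradigm, characters, seed).

    Returns
    -------
    list of StimulusEvent
        ``n_characters * n_repetitions * 12`` events with strictly increasing
        onsets and exactly 2 targets per repetition.
    """
    if target_characters is None:
        target_characters = default_characters(paradigm.n_characters)
    if len(target_characters) != paradigm.n_characters:
        raise DomainError(
            f"expected {paradigm.n_characters} target characters, "
            f"got {len(target_characters)}")

    rng = np.random.default_rng(seed)
    soa = paradigm.soa_samples
    gap = int(round(paradigm.inter_character_gap * paradigm.sampling_rate))
    codes = np.arange(1, 13)

    events: list[StimulusEvent] = []
    onset = gap  # cue pause before the first character too
    for ci, ch in enumerate(target_characters):
        col_code, row_code = target_codes(ch, column_code_base, row_code_base)
        for ri in range(paradigm.n_repetitions):
            for code in rng.permutation(codes):
                events.append(StimulusEvent(
                    onset_sample=onset,
                    code=int(code),
                    is_target=bool(code == col_code or code == row_code),
                    character_index=ci,
                    repetition_index=ri,
                ))
                onset += soa
        onset += gap
    return events


def partition_subjects(subject_ids: Sequence,
                       group_size: int,
                       seed: int = 0) -> list[SubjectGroup]:
    """Partition a subject roster into ordered fusion groups C1, C2, ...

    For the canonical 8-subject roster: size 2 gives four disjoint pairs
    (C1-C4), size 4 gives two disjoint quadruples, and size 3 gives three
    triples where the last triple is completed by a seeded random pick from
    the subjects already assigned to full groups.  The same leftover-filling
    rule generalizes to other roster sizes.

    Raises
    ------
    DomainError
        If ``group_size`` is not 2, 3 or 4, subject ids repeat, or the
        leftover cannot be completed from already-grouped subjects.
    """
    if group_size not in (2, 3, 4):
        raise DomainError(f"group_size must be 2, 3 or 4, got {group_size}")
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise DomainError("subject ids must be distinct")
    if len(ids) < group_size:
        raise DomainError("fewer subjects than the requested group size")

    rng = np.random.default_rng(seed)
    n_full = len(ids) // group_size
    groups = [tuple(ids[i * group_size:(i + 1) * group_size]) for i in range(n_full)]
    leftover = ids[n_full * group_size:]
    if leftover:
        pool = [s for s in ids[: n_full * group_size]]
        n_fill = group_size - len(leftover)
        if n_fill > len(pool):
            raise DomainError("cannot complete the last group from fused subjects")
        picks = rng.choice(len(pool), size=n_fill, replace=False)
        groups.append(tuple(leftover) + tuple(pool[int(i)] for i in picks))
    return [SubjectGroup(label=f"C{i + 1}", member_subject_ids=g)
            for i, g in enumerate(groups)]
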