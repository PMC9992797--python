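"""Reading and writing speller sessions.

Two dialects are supported:

``"array+json"``
    The package's native container: a flat little-endian float32 binary of
    shape ``[samples x channels]`` (``<base>.dat``) plus a JSON sidecar
    (``<base>.json``) with ``sampling_rate``, ``channel_labels``,
    ``n_samples``, ``n_channels`` and the event list.

``"mat_bciciii"``
    A MATLAB v5 file laid out like the BCI Competition III P300 sessions:
    ``Signal`` ``[samples x channels]``, and per-sample vectors ``Flashing``
    (1 while a row/column is intensified), ``StimulusCode`` (1-12 during a
    flash, 0 otherwise) and ``StimulusType`` (1 during target flashes).
    Events are reconstructed from the rising edges of ``Flashing``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io

from .errors import FormatError, ValidationError
from .paradigm import DEFAULT_CHANNELS, StimulusEvent

__all__ = ["write_session", "read_session"]


def _base_path(path: "str | Path") -> Path:
    p = Path(path)
    if p.suffix in (".json", ".dat"):
        p = p.with_suffix("")
    return p


def write_session(path: "str | Path",
                  signal: np.ndarray,
                  events: Sequence[StimulusEvent],
                  channel_labels: Sequence[str] | None = None,
                  sampling_rate: float = 240.0) -> tuple[Path, Path]:
    """Write a session in the "array+json" dialect.

    Returns the (binary, sidecar) paths actually written.
    """
    signal = np.asarray(signal, dtype=np.float32)
    if signal.ndim != 2:
        raise FormatError("signal must be 2-D [samples x channels]")
    base = _base_path(path)
    dat, sidecar = base.with_suffix(".dat"), base.with_suffix(".json")
    signal.astype("<f4").tofile(dat)
    meta = {
        "sampling_rate": float(sampling_rate),
        "channel_labels": list(channel_labels) if channel_labels is not None
                          else list(DEFAULT_CHANNELS[: signal.shape[1]]),
        "n_samples": int(signal.shape[0]),
        "n_channels": int(signal.shape[1]),
        "events": [
            {"onset_sample": int(e.onset_sample), "code": int(e.code),
             "is_target": bool(e.is_target),
             "character_index": int(e.character_index),
             "repetition_index": int(e.repetition_index)}
            for e in events
        ],
    }
    sidecar.write_text(json.dumps(meta))
    return dat, sidecar


def read_session(path: "str | Path", dialect: str = "array+json"):
    """Read a session file.

    Returns
    -------
    (signal, events, channel_labels, sampling_rate)
        ``signal`` is float32 ``[samples x channels]``; ``events`` a list of
        :class:`StimulusEvent` with onsets validated against the signal
        length; missing channel labels default to the 8-channel 10-20 montage.
    """
    if dialect == "array+json":
        return _read_array_json(path)
    if dialect == "mat_bciciii":
        return _read_mat_bciciii(path)
    raise FormatError(f"unknown session dialect {dialect!r}")


def _read_array_json(path):
    base = _base_path(path)
    dat, sidecar = base.with_suffix(".dat"), base.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    if not dat.exists():
        raise FormatError(f"missing binary array {dat}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar} is not valid JSON: {exc}") from exc

    for key in ("sampling_rate", "n_samples", "n_channels", "events"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    n_samples, n_channels = int(meta["n_samples"]), int(meta["n_channels"])
    raw = np.fromfile(dat, dtype="<f4")
    if raw.size != n_samples * n_channels:
        raise FormatError(
            f"binary array has {raw.size} values, sidecar declares "
            f"{n_samples}x{n_channels}")
    signal = raw.reshape(n_samples, n_channels)

    labels = meta.get("channel_labels") or list(DEFAULT_CHANNELS[:n_channels])
    events = []
    for i, ev in enumerate(meta["events"]):
        try:
            events.append(StimulusEvent(
                onset_sample=int(ev["onset_sample"]), code=int(ev["code"]),
                is_target=bool(ev["is_target"]),
                character_index=int(ev["character_index"]),
                repetition_index=int(ev["repetition_index"])))
        except KeyError as exc:
            raise FormatError(f"event {i} missing field {exc}") from exc
    _validate_events(events, n_samples)
    return signal, events, labels, float(meta["sampling_rate"])


def _read_mat_bciciii(path):
    try:
        mat = scipy.io.loadmat(str(path), squeeze_me=False)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read MAT file {path}: {exc}") from exc
    for key in ("Signal", "Flashing", "StimulusCode"):
        if key not in mat:
            raise FormatError(f"MAT file missing field {key!r}")

    signal = np.asarray(mat["Signal"], dtype=np.float32)
    if signal.ndim == 3:  # [epochs x samples x channels] -> concatenate runs
        signal = signal.reshape(-1, signal.shape[-1])
    flashing = np.asarray(mat["Flashing"]).ravel().astype(int)
    code = np.asarray(mat["StimulusCode"]).ravel().astype(int)
    stype = (np.asarray(mat["StimulusType"]).ravel().astype(int)
             if "StimulusType" in mat else np.zeros_like(flashing))

    rising = np.flatnonzero(np.diff(np.concatenate([[0], flashing])) == 1)
    events = []
    for k, onset in enumerate(rising):
        events.append(StimulusEvent(
            onset_sample=int(onset), code=int(code[onset]),
            is_target=bool(stype[onset] == 1),
            character_index=0, repetition_index=k // 12))
    _validate_events(events, signal.shape[0])
    return signal, events, list(DEFAULT_CHANNELS[: signal.shape[1]]), 240.0


def _validate_events(events, n_samples: int) -> None:
    last = -1
    for i, ev in enumerate(events):
        if ev.onset_sample >= n_samples:
            raise ValidationError(
                f"event {i} onset {ev.onset_sample} beyond signal "
                f"end ({n_samples} samples)")
        if ev.onset_sample <= last:
            raise ValidationError(f"event onsets not strictly increasing at {i}")
        last = ev.onset_sample
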