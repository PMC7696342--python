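"""Canonical data model and file I/O for labeled multi-channel sEMG recordings.

A recording is one subject holding one static hand gesture while an
8-electrode forearm armband streams raw EMG at 200 Hz.  Samples are signed
8-bit integers (the native output range of consumer armbands such as the
Myo), zero-centered by construction of the hardware.  No filtering or
rescaling happens anywhere in this package: the classifier consumes the raw
integer signal.

Two on-disk formats are supported:

* a single CSV file with columns
  ``subject_id, gesture, recording_ordinal, sample_index, ch1..ch8``
  (UTF-8, header row required, sample_index 0-based);
* a column-binary container: a directory with a ``manifest.json`` sidecar
  and one raw int8 file per recording, channel-major (all of channel 1,
  then all of channel 2, ...).

Loaders are fail-fast: out-of-range or non-integer values, wrong channel
counts and unknown gesture names raise :class:`FormatError` naming the file
and offending row rather than being silently clipped or coerced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("semgrec")

#: sampling rate of the armband stream, Hz
DEFAULT_RATE_HZ = 200.0
#: number of EMG electrodes on the armband ring
N_CHANNELS = 8
#: inclusive int8 sample range
SAMPLE_MIN, SAMPLE_MAX = -128, 127

CSV_CHANNEL_COLUMNS = [f"ch{i + 1}" for i in range(N_CHANNELS)]
CSV_COLUMNS = ["subject_id", "gesture", "recording_ordinal", "sample_index", *CSV_CHANNEL_COLUMNS]


class Gesture(IntEnum):
    """The seven static hand gestures, with a fixed index <-> name bijection.

    The integer value is the class index used everywhere downstream
    (label vectors, confusion-matrix rows, protocol messages).
    """

    OPEN_HAND = 0
    CLOSED_HAND = 1
    VICTORY_SIGN = 2
    TAP = 3
    WRIST_FLEXION = 4
    WRIST_EXTENSION = 5
    NEUTRAL = 6

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Gesture":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown gesture name {label!r}; expected one of "
                f"{[g.label for g in cls]}"
            ) from None


N_CLASSES = len(Gesture)


class FormatError(ValueError):
    """A file does not conform to the canonical dataset formats."""


@dataclass
class Recording:
    """One labeled multi-channel sEMG time series from one subject.

    Parameters
    ----------
    subject_id:
        Opaque subject identifier (e.g. ``"s03"``).
    gesture:
        The static gesture held throughout the recording.
    samples:
        ``T x 8`` integer array in ``[-128, 127]``; stored as int8.
    rate_hz:
        Sampling rate; 200 Hz for the armband this package models.
    ordinal:
        Distinguishes repeated recordings of the same (subject, gesture).
    """

    subject_id: str
    gesture: Gesture
    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    ordinal: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim != 2 or arr.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be T x {N_CHANNELS}, got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("sample values must be integers")
        if arr.min() < SAMPLE_MIN or arr.max() > SAMPLE_MAX:
            raise ValueError(
                f"sample values outside int8 range [{SAMPLE_MIN}, {SAMPLE_MAX}]: "
                f"min {arr.min()}, max {arr.max()}"
            )
        self.samples = arr.astype(np.int8)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.gesture = Gesture(self.gesture)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, int(self.gesture), self.ordinal)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.key == other.key
            and self.rate_hz == other.rate_hz
            and self.samples.shape == other.samples.shape
            and bool(np.array_equal(self.samples, other.samples))
        )


@dataclass
class Dataset:
    """An ordered collection of recordings; keys must be unique."""

    recordings: list[Recording] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.recordings]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate recording key {dup}")

    @property
    def subjects(self) -> set[str]:
        return {r.subject_id for r in self.recordings}

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        a = sorted(self.recordings, key=lambda r: r.key)
        b = sorted(other.recordings, key=lambda r: r.key)
        return a == b

    def subset(self, subjects: Iterable[str]) -> "Dataset":
        wanted = set(subjects)
        return Dataset([r for r in self.recordings if r.subject_id in wanted])

    def concat(self, other: "Dataset") -> "Dataset":
        return Dataset(self.recordings + other.recordings)


# ---------------------------------------------------------------------------
# CSV format
# ---------------------------------------------------------------------------

def _csv_error(path: Path, row: int | None, msg: str) -> FormatError:
    loc = f"{path}" if row is None else f"{path}, data row {row} (file line {row + 2})"
    return FormatError(f"{loc}: {msg}")


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    frames = []
    for rec in dataset:
        t = rec.n_samples
        frame = pd.DataFrame(rec.samples, columns=CSV_CHANNEL_COLUMNS)
        frame.insert(0, "sample_index", np.arange(t, dtype=np.int64))
        frame.insert(0, "recording_ordinal", rec.ordinal)
        frame.insert(0, "gesture", rec.gesture.label)
        frame.insert(0, "subject_id", rec.subject_id)
        frames.append(frame)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=CSV_COLUMNS)
    table.to_csv(path, index=False)


def read_dataset_csv(path: str | Path, rate_hz: float = DEFAULT_RATE_HZ) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.ParserError as exc:
        # ragged rows (e.g. a row with 7 channel values) land here
        raise _csv_error(path, None, f"malformed CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise _csv_error(path, None, f"missing columns {missing}")
    recordings: list[Recording] = []
    if len(table) == 0:
        return Dataset([])
    for col in CSV_CHANNEL_COLUMNS:
        vals = table[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals.index[~np.isfinite(vals) | (np.mod(vals, 1) != 0)]
            row = int(bad[0]) if len(bad) else int(vals.index[0])
            raise _csv_error(path, row, f"non-integer value in column {col}")
        out = (vals < SAMPLE_MIN) | (vals > SAMPLE_MAX)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise _csv_error(
                path, row, f"value {vals.iloc[row]} in column {col} outside int8 range"
            )
    for (subject, gesture_name, ordinal), grp in table.groupby(
        ["subject_id", "gesture", "recording_ordinal"], sort=True
    ):
        try:
            gesture = Gesture.from_label(str(gesture_name))
        except ValueError as exc:
            raise _csv_error(path, int(grp.index[0]), str(exc)) from exc
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise _csv_error(
                path, int(grp.index[0]),
                f"sample_index for ({subject}, {gesture_name}, {ordinal}) is not 0..T-1",
            )
        samples = grp[CSV_CHANNEL_COLUMNS].to_numpy()
        recordings.append(
            Recording(str(subject), gesture, samples, rate_hz=rate_hz, ordinal=int(ordinal))
        )
    return Dataset(recordings)


# ---------------------------------------------------------------------------
# Column-binary container
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def write_dataset_binary(dataset: Dataset, path: str | Path) -> None:
    """Write a directory of channel-major int8 files plus a JSON manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in dataset:
        fname = f"{rec.subject_id}__{rec.gesture.label}__{rec.ordinal}.i8"
        # channel-major: column c occupies bytes [c*T, (c+1)*T)
        rec.samples.T.astype(np.int8).tofile(root / fname)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "gesture": rec.gesture.label,
                "ordinal": rec.ordinal,
                "rate_hz": rec.rate_hz,
                "n_samples": rec.n_samples,
                "n_channels": N_CHANNELS,
                "file": fname,
            }
        )
    (root / MANIFEST_NAME).write_text(json.dumps({"recordings": entries}, indent=2))


def read_dataset_binary(path: str | Path) -> Dataset:
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"{root}: missing {MANIFEST_NAME}")
    manifest = json.loads(manifest_path.read_text())
    recordings = []
    for entry in manifest.get("recordings", []):
        fpath = root / entry["file"]
        if not fpath.exists():
            raise FormatError(f"{manifest_path}: listed file {entry['file']} not found")
        n, c = int(entry["n_samples"]), int(entry.get("n_channels", N_CHANNELS))
        if c != N_CHANNELS:
            raise FormatError(f"{fpath}: channel count {c} != {N_CHANNELS}")
        raw = np.fromfile(fpath, dtype=np.int8)
        if raw.size != n * c:
            raise FormatError(
                f"{fpath}: expected {n * c} bytes ({n} samples x {c} channels), got {raw.size}"
            )
        samples = raw.reshape(c, n).T
        recordings.append(
            Recording(
                str(entry["subject_id"]),
                Gesture.from_label(entry["gesture"]),
                samples,
                rate_hz=float(entry.get("rate_hz", DEFAULT_RATE_HZ)),
                ordinal=int(entry.get("ordinal", 0)),
            )
        )
    return Dataset(recordings)


# ---------------------------------------------------------------------------
# Public façade
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path: str | Path, format: str = "csv") -> None:
    """Write a dataset in the canonical ``csv`` or ``binary`` format."""
    if format == "csv":
        write_dataset_csv(dataset, path)
    elif format == "binary":
        write_dataset_binary(dataset, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'binary'")


def read_dataset(path: str | Path, format: str = "csv") -> Dataset:
    """Read a dataset written by :func:`write_dataset` (bit-exact samples)."""
    if format == "csv":
        return read_dataset_csv(path)
    if format == "binary":
        return read_dataset_binary(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'binary'")


def read_authors_dataset(path: str | Path) -> Dataset:
    """Adapter for the originally published recordings (unimplemented stub).

    The published archive's file layout is undocumented; convert it to the
    canonical CSV format externally and use :func:`read_dataset` instead.
    """
    raise NotImplementedError(
        "the layout of the externally hosted dataset is undocumented; "
        "convert it to the canonical CSV format and use read_dataset()"
    )


def summarize(dataset: Dataset) -> pd.DataFrame:
    """Per (subject, gesture) recording counts, sample totals and durations.

    Returns a DataFrame with columns ``subject_id, gesture, n_recordings,
    total_samples, duration_s`` (one row per subject x gesture present).
    """
    rows = []
    for rec in dataset:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "gesture": rec.gesture.label,
                "n_recordings": 1,
                "total_samples": rec.n_samples,
                "duration_s": rec.duration_s,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "gesture", "n_recordings", "total_samples", "duration_s"]
        )
    table = pd.DataFrame(rows)
    out = (
        table.groupby(["subject_id", "gesture"], sort=True, as_index=False)
        .sum(numeric_only=True)
    )
    return out
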