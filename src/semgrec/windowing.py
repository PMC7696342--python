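"""Sliding-window augmentation and target-vector encoding.

Recordings are cut into fixed-length overlapping windows — 188 samples of
look-back advanced by an offset of 20 samples (0.94 s windows every 0.1 s
at 200 Hz).  Windowing is the only data augmentation used; windows carry
the raw integer samples untouched (no filtering, scaling or centering),
and never cross a recording boundary, so no window mixes subjects or
gestures.

Class targets are encoded either one-hot or with label smoothing: each of
the K-1 incorrect classes receives a small probability ``epsilon`` (0.01
by default) and the correct class ``1 - (K-1)*epsilon``, so every target
is an exact probability distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .dataset import Dataset, Gesture, N_CLASSES, Recording

logger = logging.getLogger("semgrec")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: window length and stride, in samples."""

    look_back: int = 188
    offset: int = 20

    def __post_init__(self) -> None:
        if self.look_back < 1:
            raise ValueError("look_back must be >= 1")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")

    def n_windows(self, n_samples: int) -> int:
        """Number of complete windows in a recording of ``n_samples``."""
        if n_samples < self.look_back:
            return 0
        return (n_samples - self.look_back) // self.offset + 1


@dataclass(frozen=True)
class Window:
    """A fixed-length slice of one recording: the classifier's input unit."""

    values: np.ndarray  # look_back x 8, raw integer samples
    label: Gesture
    subject_id: str
    start_index: int  # 0-based inclusive start within the source recording


@dataclass(frozen=True)
class LabelScheme:
    """One-hot or smoothed encoding of the 7-class target."""

    mode: Literal["one_hot", "smoothed"] = "one_hot"
    epsilon: float = 0.01
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.mode not in ("one_hot", "smoothed"):
            raise ValueError(f"unknown label mode {self.mode!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.mode == "smoothed":
            if not 0.0 <= self.epsilon:
                raise ValueError("epsilon must be non-negative")
            if self.epsilon * (self.n_classes - 1) >= 1.0:
                raise ValueError(
                    f"epsilon {self.epsilon} too large: "
                    f"(K-1)*epsilon must be < 1 for K={self.n_classes}"
                )


def make_windows(recording: Recording, config: WindowConfig = WindowConfig()) -> list[Window]:
    """Cut a recording into overlapping windows starting at 0, offset, 2*offset, ...

    Returns an empty list (with a warning) when the recording is shorter
    than the look-back; the trailing segment shorter than a full window is
    discarded.
    """
    t = recording.n_samples
    n = config.n_windows(t)
    if n == 0:
        logger.warning(
            "recording %s/%s/%d has %d samples < look_back %d: no windows",
            recording.subject_id, recording.gesture.label, recording.ordinal,
            t, config.look_back,
        )
        return []
    windows = []
    for i in range(n):
        start = i * config.offset
        windows.append(
            Window(
                values=recording.samples[start : start + config.look_back],
                label=recording.gesture,
                subject_id=recording.subject_id,
                start_index=start,
            )
        )
    return windows


def encode_label(gesture: Gesture, scheme: LabelScheme) -> np.ndarray:
    """Length-K probability vector for a gesture under the given scheme.

    One-hot places mass 1 on the correct class; smoothing places ``epsilon``
    on each incorrect class and ``1 - (K-1)*epsilon`` on the correct one,
    so the vector sums to 1 exactly.
    """
    k = scheme.n_classes
    idx = int(gesture)
    if not 0 <= idx < k:
        raise ValueError(f"class index {idx} out of range for K={k}")
    if scheme.mode == "one_hot":
        vec = np.zeros(k)
        vec[idx] = 1.0
    else:
        vec = np.full(k, scheme.epsilon)
        vec[idx] = 1.0 - (k - 1) * scheme.epsilon
    return vec


class WindowSet(NamedTuple):
    """Aligned window tensor, target matrix and per-window provenance.

    ``X`` is ``N x look_back x 8`` float32 (raw integer samples cast,
    unmodified), ``y`` is ``N x K``.  ``subject_ids``, ``recording_ids``
    and ``start_indices`` align each window row to its origin, enabling
    subject-group splits and the temporal train/validation split.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    recording_ids: np.ndarray
    start_indices: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        """Integer class index per window (argmax of the target row)."""
        return np.argmax(self.y, axis=1)


def build_training_arrays(
    dataset: Dataset,
    window_config: WindowConfig = WindowConfig(),
    scheme: LabelScheme = LabelScheme(),
) -> WindowSet:
    """Window every recording and stack the results into training arrays.

    One row per window, in recording order then start-index order.  Raises
    on an empty dataset or when no recording is long enough to yield a
    window.
    """
    if len(dataset) == 0:
        raise ValueError("cannot build training arrays from an empty dataset")
    xs, ys, subs, recs, starts = [], [], [], [], []
    for rec_id, recording in enumerate(dataset):
        target = encode_label(recording.gesture, scheme)
        for win in make_windows(recording, window_config):
            xs.append(win.values)
            ys.append(target)
            subs.append(win.subject_id)
            recs.append(rec_id)
            starts.append(win.start_index)
    if not xs:
        raise ValueError(
            f"no recording is long enough for look_back={window_config.look_back}"
        )
    return WindowSet(
        X=np.asarray(xs, dtype=np.float32),
        y=np.asarray(ys, dtype=np.float64),
        subject_ids=np.asarray(subs, dtype=object),
        recording_ids=np.asarray(recs, dtype=np.int64),
        start_indices=np.asarray(starts, dtype=np.int64),
    )


def temporal_split(
    window_set: WindowSet, validation_fraction: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Within-recording temporal split: early windows train, late validate.

    For each source recording, the first ``1 - validation_fraction`` of its
    windows (by start index) go to training and the rest to validation, so
    validation windows come from the same subjects but later moments.
    Returns (train_indices, val_indices) into the window set.
    """
    if not 0.0 <= validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in [0, 1)")
    train_idx, val_idx = [], []
    for rec_id in np.unique(window_set.recording_ids):
        rows = np.flatnonzero(window_set.recording_ids == rec_id)
        rows = rows[np.argsort(window_set.start_indices[rows], kind="stable")]
        n_train = int(round(len(rows) * (1.0 - validation_fraction)))
        n_train = min(max(n_train, 1), len(rows))
        train_idx.extend(rows[:n_train])
        val_idx.extend(rows[n_train:])
    return np.asarray(train_idx, dtype=np.int64), np.asarray(val_idx, dtype=np.int64)
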