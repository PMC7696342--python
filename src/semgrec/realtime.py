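"""Streaming classification, debounce, and the TCP command protocol.

The live path mirrors the offline pipeline: incoming 8-channel samples
fill a circular buffer of the window length (188 samples); once the
buffer is full the classifier may run on its contents, and a gesture
command is emitted at most once per debounce interval (1 s by default) so
the downstream game has time to complete each action.  The debounce
clock is stream time (sample timestamps), which makes replayed streams
deterministic; live sources simply supply wall-clock timestamps.

Commands travel over a one-way TCP line protocol, newline-delimited
UTF-8:

    EVENT <timestamp_s> <class_index> <class_name> <action> <confidence>

Only gestures present in the action map are transmitted; others are
logged and dropped.
"""

from __future__ import annotations

import logging
import socket
import socketserver
import threading
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np

from .dataset import Gesture, N_CHANNELS
from .model import ConvGRUClassifier, TrainedModel, softmax
from .windowing import WindowConfig

logger = logging.getLogger("semgrec")

#: minimum spacing between emitted gesture commands, seconds
DEFAULT_DEBOUNCE_S = 1.0

#: game actions available to the sphere-control game
ACTIONS = ("accelerate", "backward", "jump", "grow", "shrink")

#: default gesture -> action assignment over the five control gestures
DEFAULT_ACTION_MAP: dict[Gesture, str] = {
    Gesture.CLOSED_HAND: "grow",
    Gesture.TAP: "shrink",
    Gesture.WRIST_FLEXION: "backward",
    Gesture.WRIST_EXTENSION: "accelerate",
    Gesture.NEUTRAL: "jump",
}


def validate_action_map(action_map: dict[Gesture, str]) -> dict[Gesture, str]:
    """Ensure the map is injective and uses known actions."""
    for gesture, action in action_map.items():
        Gesture(gesture)
        if action not in ACTIONS:
            raise ValueError(f"unknown action {action!r}; expected one of {ACTIONS}")
    if len(set(action_map.values())) != len(action_map):
        raise ValueError("action map must be injective (one action per gesture)")
    return dict(action_map)


@dataclass(frozen=True)
class GestureEvent:
    """A debounced, timestamped classified gesture."""

    timestamp_s: float
    gesture: Gesture
    confidence: float  # max softmax probability

    def serialize(self, action: str = "none") -> str:
        return (
            f"EVENT {self.timestamp_s:.6f} {int(self.gesture)} "
            f"{self.gesture.label} {action} {self.confidence:.6f}"
        )


class ProtocolError(ValueError):
    """A line does not conform to the command protocol."""


def parse_event_line(line: str) -> tuple[GestureEvent, str]:
    """Inverse of :meth:`GestureEvent.serialize`; returns (event, action)."""
    parts = line.strip().split(" ")
    if len(parts) != 6 or parts[0] != "EVENT":
        raise ProtocolError(f"malformed event line: {line!r}")
    _, ts, idx, name, action, conf = parts
    try:
        timestamp = float(ts)
        index = int(idx)
        confidence = float(conf)
    except ValueError as exc:
        raise ProtocolError(f"malformed numeric field in: {line!r}") from exc
    gesture = Gesture(index) if 0 <= index < len(Gesture) else None
    if gesture is None or gesture.label != name:
        raise ProtocolError(f"class index/name mismatch in: {line!r}")
    if not 0.0 <= confidence <= 1.0:
        raise ProtocolError(f"confidence out of [0, 1] in: {line!r}")
    return GestureEvent(timestamp, gesture, confidence), action


class StreamBuffer:
    """Circular buffer of the most recent ``look_back`` samples x 8 channels."""

    def __init__(self, look_back: int) -> None:
        self.look_back = look_back
        self._buf = np.zeros((look_back, N_CHANNELS), dtype=np.float32)
        self._count = 0
        self._pos = 0

    def push(self, values: np.ndarray) -> None:
        values = np.asarray(values)
        if values.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} channel values, got shape {values.shape}")
        self._buf[self._pos] = values
        self._pos = (self._pos + 1) % self.look_back
        self._count += 1

    @property
    def full(self) -> bool:
        return self._count >= self.look_back

    def window(self) -> np.ndarray:
        """Buffer contents in arrival order (oldest first)."""
        if not self.full:
            raise RuntimeError("buffer not yet full")
        return np.roll(self._buf, -self._pos, axis=0)


def classify_stream(
    samples: Iterable,
    model: TrainedModel | ConvGRUClassifier,
    window_config: WindowConfig = WindowConfig(),
    debounce_s: float = DEFAULT_DEBOUNCE_S,
    min_confidence: float | None = None,
) -> Iterator[GestureEvent]:
    """Classify a timed sample stream into debounced gesture events.

    ``samples`` yields objects with ``timestamp_s`` and ``values`` (length-8)
    attributes, e.g. :class:`~semgrec.synth.StreamSample`.  The first event
    may fire as soon as the buffer fills; thereafter events are spaced at
    least ``debounce_s`` apart in stream time.  The classifier runs only at
    emission opportunities (the debounce suppresses, not queues, predictions
    in between), and each event's gesture is the model argmax on the buffer
    contents at that moment.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    if net.input_length != window_config.look_back:
        raise ValueError(
            f"model input length {net.input_length} != look_back {window_config.look_back}"
        )
    buffer = StreamBuffer(window_config.look_back)
    last_emit: float | None = None
    for sample in samples:
        buffer.push(sample.values)
        if not buffer.full:
            continue
        now = sample.timestamp_s
        if last_emit is not None and now - last_emit < debounce_s:
            continue
        probs = softmax(net.logits(buffer.window()[None, :, :]))[0]
        confidence = float(probs.max())
        if min_confidence is not None and confidence < min_confidence:
            continue
        last_emit = now
        yield GestureEvent(now, Gesture(int(probs.argmax())), confidence)


# ---------------------------------------------------------------------------
# TCP service
# ---------------------------------------------------------------------------

@dataclass
class ServeStats:
    """Counters for one serve() run."""

    events: int = 0
    sent: int = 0
    dropped_unmapped: int = 0
    lines: list[str] = field(default_factory=list)


def serve(
    model: TrainedModel | ConvGRUClassifier,
    samples: Iterable,
    host: str = "127.0.0.1",
    port: int = 0,
    action_map: dict[Gesture, str] | None = None,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
    window_config: WindowConfig = WindowConfig(),
    ready: "threading.Event | None" = None,
    bound_port: list | None = None,
) -> ServeStats:
    """Serve classified gesture commands to one TCP client.

    Listens on ``host:port`` (port 0 picks a free port, reported via
    ``bound_port``), waits for a single client, then streams one protocol
    line per debounced event whose gesture is in the action map; unmapped
    gestures are logged and dropped.  Returns when the sample stream is
    exhausted or the client disconnects.  ``ready`` is set once the socket
    is listening (for test orchestration).
    """
    action_map = validate_action_map(
        DEFAULT_ACTION_MAP if action_map is None else action_map
    )
    stats = ServeStats()
    with socket.socket(socket.AF_INET, socket.SOCK_STREAM) as server:
        server.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        server.bind((host, port))
        server.listen(1)
        if bound_port is not None:
            bound_port.append(server.getsockname()[1])
        if ready is not None:
            ready.set()
        conn, addr = server.accept()
        logger.info("client connected from %s", addr)
        with conn:
            for event in classify_stream(samples, model, window_config, debounce_s):
                stats.events += 1
                action = action_map.get(event.gesture)
                if action is None:
                    stats.dropped_unmapped += 1
                    logger.info("unmapped gesture %s suppressed", event.gesture.label)
                    continue
                line = event.serialize(action)
                stats.lines.append(line)
                try:
                    conn.sendall((line + "\n").encode("utf-8"))
                    stats.sent += 1
                except (BrokenPipeError, ConnectionResetError):
                    logger.warning("client disconnected; stopping stream")
                    break
    return stats


def read_event_lines(sock: socket.socket) -> Iterator[str]:
    """Yield complete protocol lines from a connected client socket."""
    buffer = b""
    while True:
        chunk = sock.recv(4096)
        if not chunk:
            break
        buffer += chunk
        while b"\n" in buffer:
            line, buffer = buffer.split(b"\n", 1)
            yield line.decode("utf-8")
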