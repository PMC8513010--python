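"""Stream segmentation: split-point detection and keyframe extraction.

A continuous inertial stream is buffered through three windows: a
first-layer sliding queue of length ``L``; a short detection window at
its tail that watches the wrist (node 0) synthetic acceleration
``|a| = sqrt(ax^2 + ay^2 + az^2)`` for stroke onsets; and, once a split
point fires, a fixed-length action window that captures the stroke.

Onset detection is threshold-based: the rest baseline (mean ``mu0`` and
standard deviation ``sigma0`` of the wrist synthetic acceleration) is
estimated from the head of the stream, and a split point fires when
every frame of the detection window exceeds ``mu0 + k * sigma0``.  The
split point reported is the first frame at/after which the magnitude
stayed above threshold.  While an action window is being filled the
detector is refractory, so one stroke yields one split point.

From each action window the canonical keyframe excerpt is cut: the
hitting moment is the wrist synthetic-acceleration argmax (earliest row
on ties), and the 36-frame window places 18 frames strictly before it
and 18 from it on (local peak index 18), edge-replicating rows when the
peak sits too close to a window boundary.  Strokes last roughly 1-2 s
(30-60 frames at 30 Hz); the fixed 36-frame core around the hitting
moment keeps the informative part of every stroke at a shape a fixed
network input can consume.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .datamodel import ActionMatrix, EmptyInputError

logger = logging.getLogger(__name__)

KEYFRAME_LENGTH = 36
PEAK_INDEX = 18  # frames strictly before the hitting moment


class InsufficientDataError(ValueError):
    """Stream too short to estimate the rest baseline."""


class TruncatedWindowError(ValueError):
    """The stream ended before a full action window accumulated."""


@dataclass
class SegmenterConfig:
    """Window geometry and trigger rule of the segmenter."""

    sliding_length: int = 90       # first-layer queue L (frames)
    detection_length: int = 10     # second-layer tail window (frames)
    action_length: int = 60        # captured action window W (frames)
    keyframe_length: int = KEYFRAME_LENGTH
    baseline_length: int = 30      # frames used to estimate (mu0, sigma0)
    k_trigger: float = 3.0         # threshold = mu0 + k_trigger * sigma0
    refractory: bool = True

    def __post_init__(self) -> None:
        if self.detection_length > self.sliding_length:
            raise ValueError("detection window cannot exceed the sliding window")
        if self.action_length < KEYFRAME_LENGTH:
            raise ValueError(f"action window must hold >= {KEYFRAME_LENGTH} frames")
        if self.keyframe_length != KEYFRAME_LENGTH:
            raise ValueError(f"keyframe length is fixed at {KEYFRAME_LENGTH}")
        if self.baseline_length < 2:
            raise ValueError("need >= 2 frames to estimate the baseline")


@dataclass
class KeyframeWindow:
    """The canonical 36 x 9d excerpt of one stroke."""

    data: np.ndarray
    peak_index: int
    split_point: int | None = None     # global frame index of the source onset
    hitting_moment: int | None = None  # global frame index of the peak
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != KEYFRAME_LENGTH:
            raise ValueError(
                f"keyframe window must have exactly {KEYFRAME_LENGTH} rows, "
                f"got {self.data.shape}"
            )
        if self.peak_index != PEAK_INDEX:
            raise ValueError(
                f"hitting moment must sit at local index {PEAK_INDEX}"
            )


def synthetic_acceleration(acc: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of 3-axis acceleration.

    Accepts a single 3-vector or a ``T x 3`` array; returns a scalar or a
    length-``T`` vector.
    """
    acc = np.asarray(acc, dtype=float)
    return np.sqrt(np.sum(acc * acc, axis=-1))


def _wrist_magnitude(stream: np.ndarray) -> np.ndarray:
    """Node-0 synthetic acceleration for every frame of a ``T x 9d`` stream."""
    return synthetic_acceleration(stream[:, 0:3])


def estimate_baseline(stream: np.ndarray, config: SegmenterConfig) -> tuple[float, float]:
    """(mu0, sigma0) of the wrist synthetic acceleration at rest."""
    if stream.shape[0] < config.baseline_length:
        raise InsufficientDataError(
            f"need {config.baseline_length} frames to estimate the baseline, "
            f"stream has {stream.shape[0]}"
        )
    head = _wrist_magnitude(stream[: config.baseline_length])
    return float(np.mean(head)), float(np.std(head))


def detect_split_point(
    magnitude: np.ndarray,
    start: int,
    baseline: tuple[float, float],
    config: SegmenterConfig,
) -> int | None:
    """First stroke onset at/after ``start``, or ``None``.

    ``magnitude`` is the wrist synthetic acceleration of the whole
    stream.  A split point fires at the earliest frame ``s >= start``
    such that all ``detection_length`` frames ``s .. s+detection_length``
    exceed the trigger threshold; ``s`` is returned.
    """
    mu0, sigma0 = baseline
    thr = mu0 + config.k_trigger * sigma0
    above = magnitude > thr
    n, w = above.size, config.detection_length
    if n - start < w:
        return None
    # run-length scan: first index s with above[s:s+w] all True
    run = np.convolve(above[start:].astype(int), np.ones(w, dtype=int), "valid")
    hits = np.nonzero(run == w)[0]
    if hits.size == 0:
        return None
    return start + int(hits[0])


def capture_action_window(
    stream: np.ndarray, split_point: int, config: SegmenterConfig, d: int,
    label: int | None = None,
) -> ActionMatrix:
    """The ``W x 9d`` action window starting at the split point."""
    w = config.action_length
    if split_point + w > stream.shape[0]:
        raise TruncatedWindowError(
            f"stream ends at {stream.shape[0]} before the {w}-frame window "
            f"starting at {split_point} completes"
        )
    return ActionMatrix(data=stream[split_point : split_point + w], d=d, label=label)


def extract_keyframes(window: ActionMatrix, split_point: int | None = None) -> KeyframeWindow:
    """Cut the 36-frame keyframe excerpt centred on the hitting moment.

    The hitting moment ``p`` is the wrist synthetic-acceleration argmax
    over the window rows (earliest on ties); rows ``[p-18, p+18)`` are
    returned, edge-replicating the first/last row when the peak sits
    within 18 frames of a boundary, so the output always has exactly 36
    rows with the hitting moment at local index 18.
    """
    if window.T < 1:
        raise EmptyInputError("empty action window")
    mag = _wrist_magnitude(window.data)
    p = int(np.argmax(mag))
    idx = np.clip(np.arange(p - PEAK_INDEX, p + PEAK_INDEX), 0, window.T - 1)
    return KeyframeWindow(
        data=window.data[idx],
        peak_index=PEAK_INDEX,
        split_point=split_point,
        hitting_moment=None if split_point is None else split_point + p,
        label=window.label,
    )


def segment_stream(
    stream: np.ndarray, config: SegmenterConfig, d: int
) -> list[KeyframeWindow]:
    """Run the full three-window machinery over a ``T x 9d`` stream.

    Baseline statistics come from the stream head; detection then scans
    forward, capturing one action window per split point and skipping
    ahead (refractory) while each window fills.  Windows the stream ends
    inside are discarded with a log message.
    """
    stream = np.asarray(stream, dtype=float)
    if stream.ndim != 2:
        raise ValueError("stream must be a T x 9d array")
    baseline = estimate_baseline(stream, config)
    magnitude = _wrist_magnitude(stream)
    keyframes: list[KeyframeWindow] = []
    pos = config.baseline_length
    while True:
        split = detect_split_point(magnitude, pos, baseline, config)
        if split is None:
            break
        try:
            window = capture_action_window(stream, split, config, d)
        except TruncatedWindowError:
            logger.info("discarding truncated window at split point %d", split)
            break
        keyframes.append(extract_keyframes(window, split_point=split))
        logger.info("split point %d -> keyframe window %d", split, len(keyframes))
        if config.refractory:
            pos = split + config.action_length
        else:
            pos = split + 1
    return keyframes
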