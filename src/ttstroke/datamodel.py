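"""Core data containers for multi-node 9-axis inertial action data.

A wearable setup consists of ``d`` inertial nodes, each reporting nine
scalar channels per frame: 3-axis acceleration ``a``, 3-axis angular
velocity ``w`` and 3-axis magnetic field ``h``, in the fixed order
``(ax, ay, az, wx, wy, wz, hx, hy, hz)``.  One synchronized time step of
all ``d`` nodes concatenates into a length ``9*d`` observation vector;
``T`` consecutive observation vectors stack into a ``T x 9d`` action
matrix; labelled action matrices form a dataset split into
train / val / major_test / amateur_test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CHANNELS_PER_NODE = 9
CHANNEL_NAMES = ("ax", "ay", "az", "wx", "wy", "wz", "hx", "hy", "hz")

#: Default node count and placements.  The wrist node must be node 0: it
#: carries the most explosive signal of a stroke and drives segmentation.
DEFAULT_NODE_COUNT = 5
DEFAULT_PLACEMENTS = (
    "right_wrist",
    "right_upper_arm",
    "chest",
    "right_thigh",
    "right_calf",
)

#: Default sampling rate of the inertial stream, frames per second.
DEFAULT_FS = 30.0

SPLITS = ("train", "val", "major_test", "amateur_test")


class StructuralError(ValueError):
    """Shape/ordering contract of a container is violated."""


class SynchronizationError(ValueError):
    """Frames that should share a time index do not."""


class EmptyInputError(ValueError):
    """An operation received no data."""


@dataclass(frozen=True)
class NodeFrame:
    """One time step of one inertial node (9 scalar channels)."""

    node_id: int
    t: int
    a: np.ndarray  # 3-vector acceleration
    w: np.ndarray  # 3-vector angular velocity
    h: np.ndarray  # 3-vector magnetic field

    def __post_init__(self) -> None:
        for name in ("a", "w", "h"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise StructuralError(f"{name} must be a 3-vector, got {v.shape}")
            object.__setattr__(self, name, v)

    @property
    def values(self) -> np.ndarray:
        """The 9 channels in canonical order (ax..az, wx..wz, hx..hz)."""
        return np.concatenate([self.a, self.w, self.h])


@dataclass(frozen=True)
class ObservationVector:
    """Concatenation of all node channels at one time step (length 9d)."""

    values: np.ndarray
    d: int
    t: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != CHANNELS_PER_NODE * self.d:
            raise StructuralError(
                f"observation vector must have length 9*d={9 * self.d}, got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    def node_block(self, node_id: int) -> np.ndarray:
        """Channels of one node (a 9-vector view)."""
        if not 0 <= node_id < self.d:
            raise StructuralError(f"node_id {node_id} outside [0, {self.d})")
        k = node_id * CHANNELS_PER_NODE
        return self.values[k : k + CHANNELS_PER_NODE]


@dataclass
class ActionMatrix:
    """A ``T x 9d`` stroke matrix; row r is the observation vector at step r."""

    data: np.ndarray
    d: int
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise StructuralError("action matrix must be 2-D")
        if self.data.shape[1] % self.d != 0:
            raise StructuralError(
                f"column count {self.data.shape[1]} not divisible by d={self.d}"
            )

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def channels_per_node(self) -> int:
        return self.data.shape[1] // self.d

    def node_columns(self, node_id: int) -> np.ndarray:
        """The ``T x c`` column block belonging to one node."""
        c = self.channels_per_node
        return self.data[:, node_id * c : (node_id + 1) * c]


@dataclass
class LabeledDataset:
    """Labelled actions with split tags (the sets A per class, A* overall)."""

    actions: list[ActionMatrix]
    class_count: int
    splits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.splits) != len(self.actions):
            raise StructuralError("one split tag per action required")
        for m in self.actions:
            if m.label is None or not 0 <= m.label < self.class_count:
                raise StructuralError(
                    f"label {m.label} outside [0, {self.class_count})"
                )
        for s in self.splits:
            if s not in SPLITS:
                raise StructuralError(f"unknown split tag {s!r}")

    def subset(self, split: str) -> "LabeledDataset":
        if split not in SPLITS:
            raise StructuralError(f"unknown split tag {split!r}")
        idx = [i for i, s in enumerate(self.splits) if s == split]
        return LabeledDataset(
            actions=[self.actions[i] for i in idx],
            class_count=self.class_count,
            splits=[split] * len(idx),
        )

    def by_class(self, label: int, split: str | None = None) -> list[ActionMatrix]:
        return [
            m
            for m, s in zip(self.actions, self.splits)
            if m.label == label and (split is None or s == split)
        ]

    def __len__(self) -> int:
        return len(self.actions)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_observation_vector(frames: Sequence[NodeFrame]) -> ObservationVector:
    """Concatenate one frame per node, in ascending node order.

    Raises ``StructuralError`` on missing/duplicate node ids and
    ``SynchronizationError`` if the frames disagree on the time index.
    """
    if not frames:
        raise EmptyInputError("no frames given")
    d = len(frames)
    by_id = {f.node_id: f for f in frames}
    if sorted(by_id) != list(range(d)):
        raise StructuralError(
            f"need exactly one frame per node_id 0..{d - 1}, got ids "
            f"{sorted(f.node_id for f in frames)}"
        )
    t0 = frames[0].t
    if any(f.t != t0 for f in frames):
        raise SynchronizationError(
            f"frames disagree on t: {sorted({f.t for f in frames})}"
        )
    values = np.concatenate([by_id[k].values for k in range(d)])
    return ObservationVector(values=values, d=d, t=t0)


def assemble_action_matrix(
    vectors: Iterable[ObservationVector], label: int | None = None
) -> ActionMatrix:
    """Stack time-ordered observation vectors into a ``T x 9d`` matrix."""
    vectors = list(vectors)
    if not vectors:
        raise EmptyInputError("no observation vectors given")
    d = vectors[0].d
    if any(v.d != d for v in vectors):
        raise StructuralError("observation vectors disagree on node count d")
    ts = [v.t for v in vectors]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise StructuralError("time indices must be strictly increasing")
    data = np.stack([v.values for v in vectors])
    return ActionMatrix(data=data, d=d, label=label)


def axis_column_index(d: int, mode: str) -> np.ndarray:
    """Column indices a full 9-axis layout keeps under an axis mode."""
    if mode == "nine_axis":
        return np.arange(CHANNELS_PER_NODE * d)
    if mode == "six_axis":
        return np.concatenate([np.arange(k * 9, k * 9 + 6) for k in range(d)])
    raise ValueError(f"unknown axis mode {mode!r}")


def select_axes(m: ActionMatrix, mode: str) -> ActionMatrix:
    """Restrict an action matrix to an axis subset.

    ``nine_axis`` keeps all channels; ``six_axis`` drops the magnetometer
    channels of every node, yielding a ``T x 6d`` matrix.  Requires the
    full 9 channels per node, so a second ``six_axis`` application errors.
    """
    if mode not in ("six_axis", "nine_axis"):
        raise ValueError(f"unknown axis mode {mode!r}")
    if m.channels_per_node != CHANNELS_PER_NODE:
        raise StructuralError(
            f"expected 9 channels per node, got {m.channels_per_node}"
        )
    if mode == "nine_axis":
        return m
    keep = axis_column_index(m.d, mode)
    return ActionMatrix(data=m.data[:, keep], d=m.d, label=m.label)
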