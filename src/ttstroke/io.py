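"""File formats, configuration, and the end-to-end pipeline runner.

On-disk artifacts:

* stream files — tab-separated text, one row per frame per node, columns
  ``(t, node_id, ax, ay, az, wx, wy, wz, hx, hy, hz)``;
* a dataset manifest (JSON) listing stream files with class labels and
  split tags;
* a keyframe store (``keyframes.npz``: data ``(N, 36, C)``, labels,
  split tags, split points, plus a schema version) with a JSON sidecar;
* model checkpoints (``.npz``, see :mod:`ttstroke.models`);
* standard action models (JSON: centroids, mapping, purity);
* reports as tab-separated text plus confusion-matrix / training-curve /
  embedding plots.

Every artifact carries a schema version; a mismatch is always an error,
never a silent reinterpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CHANNEL_NAMES, CHANNELS_PER_NODE, EmptyInputError, SPLITS
from .segmentation import KeyframeWindow, SegmenterConfig
from .synth import GeneratorConfig, GroundTruth
from .models import ModelConfig, TrainConfig
from .assessment import StandardActionModel

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ("t", "node_id") + CHANNEL_NAMES
SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """An artifact does not match its expected schema/version."""


# ---------------------------------------------------------------------------
# Stream files
# ---------------------------------------------------------------------------

def write_stream(path: str | Path, stream: np.ndarray, d: int) -> None:
    """Write a ``T x 9d`` stream as one row per (frame, node)."""
    stream = np.asarray(stream)
    t_count = stream.shape[0]
    rows = []
    for node in range(d):
        block = stream[:, node * CHANNELS_PER_NODE : (node + 1) * CHANNELS_PER_NODE]
        frame = pd.DataFrame(block, columns=list(CHANNEL_NAMES))
        frame.insert(0, "node_id", node)
        frame.insert(0, "t", np.arange(t_count))
        rows.append(frame)
    # 17 significant digits: float64 values round-trip bit-exactly
    table = pd.concat(rows).sort_values(["t", "node_id"], kind="stable")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stream(path: str | Path) -> dict[int, np.ndarray]:
    """Per-node frame sequences ``{node_id: (T, 9) array}``, ordered by t."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed stream file {path}: {exc}") from None
    missing = [c for c in STREAM_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path} lacks required columns {missing}")
    if len(table) == 0:
        raise EmptyInputError(f"{path} contains a header but no frames")
    bad = table[list(CHANNEL_NAMES)].isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise SchemaError(f"{path}: missing channel value at line {line}")
    out: dict[int, np.ndarray] = {}
    for node, group in table.groupby("node_id"):
        group = group.sort_values("t", kind="stable")
        out[int(node)] = group[list(CHANNEL_NAMES)].to_numpy(dtype=float)
    return out


def stream_to_matrix(per_node: dict[int, np.ndarray]) -> np.ndarray:
    """Recombine per-node sequences into the ``T x 9d`` stream matrix."""
    d = len(per_node)
    if sorted(per_node) != list(range(d)):
        raise SchemaError(f"node ids must be 0..{d - 1}, got {sorted(per_node)}")
    lengths = {v.shape[0] for v in per_node.values()}
    if len(lengths) != 1:
        raise SchemaError(f"nodes disagree on frame count: {sorted(lengths)}")
    return np.concatenate([per_node[k] for k in range(d)], axis=1)


# ---------------------------------------------------------------------------
# Manifest + ground truth
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, entries: list[dict]) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "streams": entries}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"manifest schema {payload.get('schema_version')} != {SCHEMA_VERSION}"
        )
    return payload["streams"]


def write_ground_truth(path: str | Path, truths: list[GroundTruth],
                       stream_files: list[str]) -> None:
    rows = [
        {
            "stream": f, "class_id": gt.class_id, "split_point": gt.split_point,
            "hitting_moment": gt.hitting_moment, "end": gt.end, "onset": gt.onset,
            "corrupted_nodes": ",".join(map(str, gt.corrupted_nodes)),
        }
        for f, gt in zip(stream_files, truths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# Keyframe store
# ---------------------------------------------------------------------------

def write_keyframes(path: str | Path, windows: list[KeyframeWindow],
                    splits: list[str], d: int) -> None:
    if len(windows) != len(splits):
        raise ValueError("one split tag per window required")
    data = np.stack([w.data for w in windows]) if windows else np.zeros((0, 36, 0))
    labels = np.array([-1 if w.label is None else w.label for w in windows], dtype=int)
    split_idx = np.array([SPLITS.index(s) for s in splits], dtype=int)
    split_points = np.array(
        [-1 if w.split_point is None else w.split_point for w in windows], dtype=int
    )
    np.savez(path, schema_version=SCHEMA_VERSION, data=data, labels=labels,
             split_idx=split_idx, split_points=split_points, d=d)


def read_keyframes(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Returns (data (N, 36, C), labels, split tags as strings, d)."""
    with np.load(path, allow_pickle=False) as archive:
        if int(archive["schema_version"]) != SCHEMA_VERSION:
            raise SchemaError(
                f"keyframe schema {archive['schema_version']} != {SCHEMA_VERSION}"
            )
        splits = np.array([SPLITS[i] for i in archive["split_idx"]])
        return archive["data"], archive["labels"], splits, int(archive["d"])


# ---------------------------------------------------------------------------
# Standard-model files
# ---------------------------------------------------------------------------

def write_standard_models(path: str | Path,
                          models: dict[int, StandardActionModel]) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "models": [
            {
                "class_id": m.class_id,
                "d": m.d,
                "purity": m.purity,
                "cluster_to_node": {str(k): v for k, v in m.cluster_to_node.items()},
                "member_counts": {str(k): v for k, v in m.member_counts.items()},
                "centroids": {str(k): v.tolist() for k, v in m.centroids.items()},
            }
            for m in models.values()
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_standard_models(path: str | Path) -> dict[int, StandardActionModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"standard-model schema {payload.get('schema_version')} != {SCHEMA_VERSION}"
        )
    out = {}
    for m in payload["models"]:
        out[m["class_id"]] = StandardActionModel(
            class_id=m["class_id"],
            d=m["d"],
            centroids={int(k): np.array(v) for k, v in m["centroids"].items()},
            member_counts={int(k): v for k, v in m["member_counts"].items()},
            cluster_to_node={int(k): v for k, v in m["cluster_to_node"].items()},
            purity=m["purity"],
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class AssessmentConfig:
    threshold: float = 0.8
    perplexity: float = 30.0


@dataclass
class PipelineConfig:
    """Nested configuration of every pipeline stage; YAML-serializable."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    assessment: AssessmentConfig = field(default_factory=AssessmentConfig)
    variant: str = "mdff"
    axis_mode: str = "nine_axis"
    seed: int = 0
    model_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # one global seed drives every stage
        self.generator.seed = self.seed
        self.train.seed = self.seed

    def model_config(self, input_cols: int) -> ModelConfig:
        return ModelConfig(
            input_cols=input_cols,
            class_count=self.generator.j,
            seed=self.seed,
            channels_per_node=6 if self.axis_mode == "six_axis" else 9,
            **self.model_overrides,
        )


def _from_dict(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        value = payload[f.name]
        if f.name in ("gap_range", "duration_range", "branch_1d", "branch_3x3"):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """PipelineConfig from a YAML file; unknown keys are rejected."""
    import yaml

    payload = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {"generator", "segmenter", "train", "assessment", "variant",
             "axis_mode", "seed", "model"}
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"unknown config sections: {sorted(unknown)}")
    cfg = PipelineConfig(
        generator=_from_dict(GeneratorConfig, payload.get("generator", {})),
        segmenter=_from_dict(SegmenterConfig, payload.get("segmenter", {})),
        train=_from_dict(TrainConfig, payload.get("train", {})),
        assessment=_from_dict(AssessmentConfig, payload.get("assessment", {})),
        variant=payload.get("variant", "mdff"),
        axis_mode=payload.get("axis_mode", "nine_axis"),
        seed=payload.get("seed", 0),
        model_overrides=payload.get("model", {}),
    )
    if seed is not None:
        cfg.seed = seed
        cfg.__post_init__()
    return cfg


# ---------------------------------------------------------------------------
# Plot helpers (Agg backend; never require a display)
# ---------------------------------------------------------------------------

def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_confusion(matrix: np.ndarray, path: str | Path, title: str = "") -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(matrix, cmap="Blues")
    for (i, j), v in np.ndenumerate(matrix):
        ax.text(j, i, str(int(v)), ha="center", va="center", fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_history(history: dict[str, list[float]], path: str | Path) -> None:
    plt = _pyplot()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3))
    ax1.plot(history["train_loss"], label="train loss")
    if history.get("val_loss"):
        ax1.plot(history["val_loss"], label="val loss")
    ax1.set_xlabel("epoch")
    ax1.legend()
    if history.get("val_accuracy"):
        ax2.plot(history["val_accuracy"])
        ax2.set_xlabel("epoch")
        ax2.set_ylabel("val accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_embedding(coords: np.ndarray, node_ids: np.ndarray, path: str | Path) -> None:
    plt = _pyplot()
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    for node in np.unique(node_ids):
        pts = coords[node_ids == node]
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=6, label=f"node {node}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_node_scores(report, path: str | Path) -> None:
    plt = _pyplot()
    nodes = sorted(report.node_similarity)
    scores = [report.node_similarity[n] for n in nodes]
    colors = ["tab:red" if n in report.flagged_nodes else "tab:blue" for n in nodes]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.bar([str(n) for n in nodes], scores, color=colors)
    ax.axhline(report.threshold, ls="--", c="gray", lw=1)
    ax.set_xlabel("node")
    ax.set_ylabel("cosine similarity")
    ax.set_ylim(min(0.0, min(scores)) if scores else 0.0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
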