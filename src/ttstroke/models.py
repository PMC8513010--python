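"""Stroke classifiers: the multi-dimensional feature-fusion CNN and its
two comparators.

The MDFF network treats a 36 x C keyframe window (C = 9d or 6d channels
across all nodes) as a single-channel image and runs it through an
Inception-style block with four parallel branches: a 1x1 convolution; a
1x1 reduction followed by a 1-D temporal convolution (5x1 along the
36-frame axis); a 1x1 reduction followed by a 3x3 convolution; and a
3x3 max-pool (stride 1) followed by a 1x1 convolution.  All branches
preserve the 36 x C extent and concatenate along channels; a trailing
3x3 convolution then reduces the channel count so the cascade stays
small.  The block output doubles as the action's high-level abstract
feature map for assessment: summing its channels element-wise yields a
single 36 x C map whose column blocks still correspond to the worn
nodes.

Two comparators share the same trunk and head: a plain three-layer
conv/pool CNN, and a single naive Inception block (1x1 / 3x3 / 5x5
convolutions plus a passthrough 3x3 max-pool, no 1x1 reductions, no 1-D
branch).

Training follows a fixed protocol: mini-batches of 64, Adam, initial
learning rate 0.01 decayed by x0.1 every 20 epochs, 60 epochs, softmax
cross-entropy; weights are only updated on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from . import nn
from .nn import DTYPE
from .segmentation import KEYFRAME_LENGTH, KeyframeWindow

VARIANTS = ("mdff", "plain_cnn", "naive_inception")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (filter counts are free choices)."""

    input_cols: int                 # C = 9d (or 6d in six-axis mode)
    class_count: int
    input_rows: int = KEYFRAME_LENGTH
    branch_1x1: int = 6
    branch_1d: tuple[int, int] = (3, 6)   # 1x1 reduction -> 5x1 temporal conv
    branch_3x3: tuple[int, int] = (3, 6)  # 1x1 reduction -> 3x3 conv
    branch_pool: int = 6                  # 1x1 conv after the 3x3 max-pool
    reduction: int = 8                    # trailing 3x3 channel reduction
    trunk: int = 32
    temporal_kernel: int = 5
    channels_per_node: int = 9            # 9 full, 6 without magnetometer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_rows != KEYFRAME_LENGTH:
            raise ValueError(f"input rows fixed at {KEYFRAME_LENGTH}")
        counts = (self.branch_1x1, *self.branch_1d, *self.branch_3x3,
                  self.branch_pool, self.reduction, self.trunk)
        if any(c <= 0 for c in counts):
            raise ValueError("all filter counts must be positive")


@dataclass
class TrainConfig:
    """The training protocol; defaults are the reference recipe."""

    batch_size: int = 64
    epochs: int = 60
    lr: float = 0.01
    lr_decay: float = 0.1
    decay_every: int = 20
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_decay ** (epoch // self.decay_every)


def build_mdff_block(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    """The four-branch fusion block plus the trailing 3x3 reduction.

    Output: ``reduction`` channels at the full 36 x C extent.  Needs
    C >= 3 so the 3x3 kernels fit the padded width.
    """
    if cfg.input_cols < 3:
        raise ValueError("need at least 3 input columns for 3x3 kernels")
    r1d, f1d = cfg.branch_1d
    r33, f33 = cfg.branch_3x3
    branches = nn.Branches(
        nn.Sequential(nn.Conv2d(1, cfg.branch_1x1, 1, 1, rng), nn.ReLU()),
        nn.Sequential(
            nn.Conv2d(1, r1d, 1, 1, rng), nn.ReLU(),
            nn.Conv2d(r1d, f1d, cfg.temporal_kernel, 1, rng), nn.ReLU(),
        ),
        nn.Sequential(
            nn.Conv2d(1, r33, 1, 1, rng), nn.ReLU(),
            nn.Conv2d(r33, f33, 3, 3, rng), nn.ReLU(),
        ),
        nn.Sequential(nn.MaxPool2d(3, 1, same=True),
                      nn.Conv2d(1, cfg.branch_pool, 1, 1, rng), nn.ReLU()),
    )
    concat = cfg.branch_1x1 + f1d + f33 + cfg.branch_pool
    return nn.Sequential(
        branches,
        nn.Conv2d(concat, cfg.reduction, 3, 3, rng), nn.ReLU(),
    )


def _build_naive_inception_block(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    """Naive Inception: 1x1, 3x3 and 5x5 convolutions plus a passthrough
    3x3 max-pool, concatenated; no reductions anywhere."""
    _, f1d = cfg.branch_1d
    _, f33 = cfg.branch_3x3
    return nn.Sequential(nn.Branches(
        nn.Sequential(nn.Conv2d(1, cfg.branch_1x1, 1, 1, rng), nn.ReLU()),
        nn.Sequential(nn.Conv2d(1, f33, 3, 3, rng), nn.ReLU()),
        nn.Sequential(nn.Conv2d(1, f1d, 5, 5, rng), nn.ReLU()),
        nn.MaxPool2d(3, 1, same=True),
    ))


def _head(in_ch: int, cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    """Shared trunk and classification head: 3x3 conv, ReLU, batch norm,
    2x2 max-pool, global average pooling, final fully connected layer."""
    return nn.Sequential(
        nn.Conv2d(in_ch, cfg.trunk, 3, 3, rng), nn.ReLU(),
        nn.BatchNorm2d(cfg.trunk),
        nn.MaxPool2d(2, 2),
        nn.GlobalAvgPool(),
        nn.Linear(cfg.trunk, cfg.class_count, rng),
    )


class StrokeClassifier:
    """A trainable stroke classifier with an abstract-feature tap.

    ``predict_proba`` returns a probability vector (softmax of the
    logits).  For the ``mdff`` variant, ``abstract_map`` exposes the
    fusion-block output summed over channels — the 36 x C high-level
    abstract feature used by the assessment stage.
    """

    def __init__(self, cfg: ModelConfig, variant: str):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        rng = np.random.default_rng(cfg.seed)
        if variant == "mdff":
            self.block = build_mdff_block(cfg, rng)
            self.net = nn.Sequential(self.block, _head(cfg.reduction, cfg, rng))
        elif variant == "naive_inception":
            self.block = _build_naive_inception_block(cfg, rng)
            concat = cfg.branch_1x1 + cfg.branch_3x3[1] + cfg.branch_1d[1] + 1
            self.net = nn.Sequential(self.block, _head(concat, cfg, rng))
        else:  # plain three-layer conv/pool CNN
            self.block = None
            self.net = nn.Sequential(
                nn.Conv2d(1, 8, 3, 3, rng), nn.ReLU(), nn.BatchNorm2d(8),
                nn.MaxPool2d(2, 2),
                nn.Conv2d(8, 16, 3, 3, rng), nn.ReLU(), nn.BatchNorm2d(16),
                nn.MaxPool2d(2, 2),
                nn.Conv2d(16, cfg.trunk, 3, 3, rng), nn.ReLU(),
                nn.BatchNorm2d(cfg.trunk), nn.MaxPool2d(2, 2),
                nn.GlobalAvgPool(),
                nn.Linear(cfg.trunk, cfg.class_count, rng),
            )
        self.sd = np.ones(cfg.input_cols, dtype=DTYPE)
        self.history: dict[str, list[float]] = {
            "train_loss": [], "val_loss": [], "val_accuracy": [], "lr": []
        }

    # -- input plumbing ---------------------------------------------------

    @staticmethod
    def _centre(windows: np.ndarray) -> np.ndarray:
        """Regularize each keyframe window: subtract its per-column mean.

        This removes the static part of every channel — gravity, the
        earth-field baseline, and whatever constant offset the sensor's
        mounting on this particular body adds — leaving the stroke
        dynamics the classifier should care about.
        """
        return windows - windows.mean(axis=1, keepdims=True)

    def fit_scaler(self, windows: np.ndarray) -> None:
        """Fit the input scale on the (per-window centred) training set.

        One shared standard deviation per sensor *type* — accelerometer,
        gyroscope, magnetometer — equalizes the very different physical
        units without erasing the relative burst energy across nodes,
        which is both class- and node-informative.
        """
        centred = self._centre(np.asarray(windows, dtype=float))
        flat = centred.reshape(-1, centred.shape[-1])
        cols = centred.shape[-1]
        cpn = self.cfg.channels_per_node
        sd = flat.std(axis=0)
        if cols % cpn == 0:
            type_of = (np.arange(cols) % cpn) // 3
            for t in np.unique(type_of):
                sd[type_of == t] = flat[:, type_of == t].std()
        self.sd = np.where(sd > 0, sd, 1.0).astype(DTYPE)

    def _prepare(self, windows: np.ndarray) -> np.ndarray:
        w = np.asarray(windows, dtype=DTYPE)
        if w.ndim == 2:
            w = w[None]
        if w.shape[1:] != (self.cfg.input_rows, self.cfg.input_cols):
            raise ValueError(
                f"expected windows of shape {(self.cfg.input_rows, self.cfg.input_cols)}, "
                f"got {w.shape[1:]}"
            )
        return (self._centre(w) / self.sd)[..., None]  # (B, 36, C, 1)

    # -- inference --------------------------------------------------------

    def logits(self, windows: np.ndarray, train: bool = False,
               chunk: int = 128) -> np.ndarray:
        """Network logits; inference runs in chunks to bound memory."""
        x = self._prepare(windows)
        if train or x.shape[0] <= chunk:
            return self.net.forward(x, train)
        return np.concatenate(
            [self.net.forward(x[i : i + chunk], False)
             for i in range(0, x.shape[0], chunk)]
        )

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(windows).astype(np.float64))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(windows), axis=-1)

    def abstract_map(self, window: np.ndarray) -> np.ndarray:
        """Channel-wise sum of the fusion-block output: a 36 x C map."""
        if self.variant != "mdff":
            raise NotImplementedError(
                "abstract features are defined for the mdff variant only"
            )
        x = self._prepare(window)
        out = self.block.forward(x, train=False)  # (B, 36, C, reduction)
        maps = out.sum(axis=-1)
        return maps[0] if np.asarray(window).ndim == 2 else maps

    def n_params(self) -> int:
        return nn.count_params(self.net)


def build_model(cfg: ModelConfig, variant: str = "mdff") -> StrokeClassifier:
    return StrokeClassifier(cfg, variant)


def stack_keyframes(kfs: list[KeyframeWindow]) -> tuple[np.ndarray, np.ndarray]:
    """(N, 36, C) data tensor and length-N label vector."""
    data = np.stack([kf.data for kf in kfs])
    labels = np.array([-1 if kf.label is None else kf.label for kf in kfs])
    return data, labels


def train(
    model: StrokeClassifier,
    train_windows: np.ndarray, train_labels: np.ndarray,
    val_windows: np.ndarray | None = None, val_labels: np.ndarray | None = None,
    tc: TrainConfig | None = None,
) -> StrokeClassifier:
    """Train in place per the reference protocol; returns the model.

    Per-epoch history (train loss, validation loss/accuracy, learning
    rate) is recorded on ``model.history``.  Validation never updates
    weights.  Fully deterministic given the model and train seeds.
    """
    if tc is None:
        tc = TrainConfig()
    if train_windows.shape[0] == 0:
        raise ValueError("empty training set")
    if np.any((train_labels < 0) | (train_labels >= model.cfg.class_count)):
        raise ValueError("train labels outside [0, class_count)")
    model.fit_scaler(train_windows)
    x = model._prepare(train_windows)
    opt = nn.Adam(model.net.params(), lr=tc.lr)
    rng = np.random.default_rng(tc.seed)
    n = x.shape[0]
    for epoch in range(tc.epochs):
        opt.lr = tc.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            logits = model.net.forward(x[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, train_labels[idx])
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        model.history["train_loss"].append(float(np.mean(losses)))
        model.history["lr"].append(opt.lr)
        if val_windows is not None and val_windows.shape[0] > 0:
            vlogits = model.logits(val_windows)
            vloss, _ = nn.cross_entropy(vlogits, val_labels)
            vacc = float(np.mean(np.argmax(vlogits, axis=-1) == val_labels))
            model.history["val_loss"].append(vloss)
            model.history["val_accuracy"].append(vacc)
    return model


def evaluate(
    model: StrokeClassifier, windows: np.ndarray, labels: np.ndarray
) -> dict:
    """Macro-averaged F1 and the j x j confusion matrix (rows = truth)."""
    from sklearn.metrics import confusion_matrix, f1_score

    pred = model.predict(windows)
    j = model.cfg.class_count
    return {
        "macro_f1": float(f1_score(labels, pred, average="macro",
                                   labels=np.arange(j), zero_division=0)),
        "confusion": confusion_matrix(labels, pred, labels=np.arange(j)),
        "accuracy": float(np.mean(pred == labels)),
    }


def extract_abstract_features(model: StrokeClassifier, kf: KeyframeWindow | np.ndarray) -> np.ndarray:
    """36 x C abstract feature map of one keyframe window (mdff only)."""
    data = kf.data if isinstance(kf, KeyframeWindow) else np.asarray(kf)
    return model.abstract_map(data)


# -- serialization ---------------------------------------------------------

def save_model(model: StrokeClassifier, path: str) -> None:
    """Checkpoint: config/variant/history as JSON inside an .npz archive."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.params())}
    bns = [l for l in _walk(model.net) if isinstance(l, nn.BatchNorm2d)]
    for i, bn in enumerate(bns):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    arrays["sd"] = model.sd
    meta = {"variant": model.variant, "config": asdict(model.cfg),
            "history": model.history, "schema_version": 1}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> StrokeClassifier:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"].tobytes()).decode())
        if meta.get("schema_version") != 1:
            raise ValueError(f"unsupported checkpoint schema: {meta.get('schema_version')}")
        cfg_dict = meta["config"]
        cfg_dict["branch_1d"] = tuple(cfg_dict["branch_1d"])
        cfg_dict["branch_3x3"] = tuple(cfg_dict["branch_3x3"])
        model = StrokeClassifier(ModelConfig(**cfg_dict), meta["variant"])
        for i, p in enumerate(model.net.params()):
            p.value = archive[f"param_{i}"].astype(DTYPE)
        bns = [l for l in _walk(model.net) if isinstance(l, nn.BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = archive[f"bn_mean_{i}"].astype(DTYPE)
            bn.running_var = archive[f"bn_var_{i}"].astype(DTYPE)
        model.sd = archive["sd"].astype(DTYPE)
        model.history = meta["history"]
    return model


def _walk(layer: nn.Layer):
    yield layer
    for attr in ("layers", "branches"):
        for child in getattr(layer, attr, []):
            yield from _walk(child)
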