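"""Action quality assessment: overall and per-node (fine-grained).

Overall assessment reads the classifier's softmax output: the argmax
label is the recognized stroke and the maximum probability itself is
the similarity of the whole action to that stroke's standard form.

Fine-grained assessment builds, per stroke class, a *standard action
model*: every training keyframe window is pushed through the trained
fusion network, the channel-summed abstract map (36 x C) is split into
per-node column blocks, the resulting node feature vectors are embedded
to 3-D with t-SNE and clustered with K-means using K = the number of
worn nodes.  Clusters are matched to true node identities by
maximum-agreement bijective assignment, and the per-node centroid is
the mean of the matched cluster's members in the ORIGINAL feature space
(t-SNE cannot embed unseen points, so scoring happens in the original
space while the embedding serves clustering and visualization).

A new action is then scored per node by cosine similarity between its
node feature vector and the class centroid for that node; the two
lowest-scoring nodes, plus any node under a threshold, are flagged as
the weak spots a trainee should work on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import StructuralError
from .models import StrokeClassifier
from .segmentation import KeyframeWindow


class UndefinedSimilarityError(ValueError):
    """Cosine similarity of two zero vectors is undefined."""


@dataclass(frozen=True)
class OverallScore:
    """Recognized class and the max softmax probability as similarity."""

    predicted_class: int
    score: float


@dataclass
class NodeFeature:
    """Flattened abstract-map column block of one node (36 x c values)."""

    node_id: int
    vector: np.ndarray
    coords: np.ndarray | None = None  # 3-D embedding, when computed


@dataclass
class StandardActionModel:
    """Per-class, per-node centroid features in the original space."""

    class_id: int
    d: int
    centroids: dict[int, np.ndarray]
    member_counts: dict[int, int]
    cluster_to_node: dict[int, int]
    purity: float

    def __post_init__(self) -> None:
        if sorted(self.centroids) != list(range(self.d)):
            raise StructuralError("need exactly one centroid per node id")
        if sorted(self.cluster_to_node.values()) != list(range(self.d)):
            raise StructuralError("cluster->node mapping must be a bijection")


@dataclass
class AssessmentReport:
    overall: OverallScore
    node_similarity: dict[int, float]
    flagged_nodes: tuple[int, ...]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.node_similarity) >= 2 and len(self.flagged_nodes) < 2:
            raise StructuralError("at least the two lowest nodes must be flagged")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def overall_score(probs: np.ndarray) -> OverallScore:
    """(argmax class, max probability); earliest index on exact ties."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a single probability vector")
    if abs(p.sum() - 1.0) > 1e-3:
        raise ValueError(f"not a probability distribution (sum={p.sum():.4f})")
    k = int(np.argmax(p))
    return OverallScore(predicted_class=k, score=float(p[k]))


def split_node_features(abstract_map: np.ndarray, d: int) -> list[NodeFeature]:
    """Cut a 36 x C map into d column blocks, flattened row-major."""
    m = np.asarray(abstract_map)
    if m.ndim != 2:
        raise StructuralError("abstract map must be 2-D")
    rows, c = m.shape
    if c % d != 0:
        raise StructuralError(f"column count {c} not divisible by d={d}")
    w = c // d
    return [
        NodeFeature(node_id=k, vector=m[:, k * w : (k + 1) * w].reshape(-1).copy())
        for k in range(d)
    ]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), in [-1, 1]; undefined when both vectors are zero."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 and nv == 0.0:
        raise UndefinedSimilarityError("both vectors are zero")
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def embed_3d(
    vectors: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """Seeded t-SNE embedding of feature vectors to 3 dimensions.

    The perplexity is capped at (n_samples - 1) / 3 so small fixture
    sets remain embeddable.
    """
    from sklearn.manifold import TSNE

    x = np.asarray(vectors, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples to embed, got {n}")
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(n_components=3, perplexity=perplexity, init="pca",
                random_state=seed, max_iter=500)
    return tsne.fit_transform(x)


def attach_embedding(features: list[NodeFeature], seed: int = 0,
                     perplexity: float = 30.0) -> list[NodeFeature]:
    coords = embed_3d(np.stack([f.vector for f in features]), seed, perplexity)
    for f, xyz in zip(features, coords):
        f.coords = xyz
    return features


def cluster_purity(cluster_labels: np.ndarray, true_ids: np.ndarray) -> float:
    """Fraction of points whose cluster's majority true id matches theirs."""
    total = 0
    for k in np.unique(cluster_labels):
        ids, counts = np.unique(true_ids[cluster_labels == k], return_counts=True)
        total += counts.max()
    return total / len(cluster_labels)


def match_clusters(cluster_labels: np.ndarray, true_ids: np.ndarray, d: int) -> dict[int, int]:
    """Maximum-agreement bijection cluster -> node id (Hungarian on the
    contingency table)."""
    table = np.zeros((d, d))
    for c, t in zip(cluster_labels, true_ids):
        table[c, t] += 1
    rows, cols = linear_sum_assignment(-table)
    return {int(r): int(c) for r, c in zip(rows, cols)}


# ---------------------------------------------------------------------------
# Standard-model construction and assessment
# ---------------------------------------------------------------------------

def collect_node_features(
    windows: np.ndarray, d: int, model: StrokeClassifier | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-node feature vectors and their true node ids.

    With a trained fusion model the features are abstract-map column
    blocks; without one they are the raw keyframe column blocks (the
    degraded comparison the learned features are judged against).
    """
    windows = np.asarray(windows)
    if model is not None:
        maps = np.concatenate(
            [model.abstract_map(windows[i : i + 128])
             for i in range(0, windows.shape[0], 128)]
        )
    else:
        maps = windows
    feats, ids = [], []
    for m in maps:
        for f in split_node_features(m, d):
            feats.append(f.vector)
            ids.append(f.node_id)
    return np.stack(feats), np.array(ids)


def build_standard_model(
    windows: np.ndarray,
    model: StrokeClassifier | None,
    d: int,
    class_id: int,
    seed: int = 0,
    perplexity: float = 30.0,
    max_retries: int = 5,
) -> StandardActionModel:
    """Standard action model of one class from its training keyframes.

    Pipeline: abstract features -> per-node split -> 3-D t-SNE ->
    K-means (K = d) -> maximum-agreement cluster/node matching ->
    per-node centroid in the original feature space.
    """
    from sklearn.cluster import KMeans

    windows = np.asarray(windows)
    if windows.shape[0] < 10:
        raise ValueError("need at least 10 actions to build a standard model")
    vectors, true_ids = collect_node_features(windows, d, model)
    coords = embed_3d(vectors, seed=seed, perplexity=perplexity)
    labels = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=d, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) == d:
            break
    else:
        raise RuntimeError(f"K-means produced empty clusters {max_retries} times")
    mapping = match_clusters(labels, true_ids, d)
    centroids: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for cluster, node in mapping.items():
        members = vectors[labels == cluster]
        centroids[node] = members.mean(axis=0)
        counts[node] = int(members.shape[0])
    return StandardActionModel(
        class_id=class_id,
        d=d,
        centroids=centroids,
        member_counts=counts,
        cluster_to_node=mapping,
        purity=cluster_purity(labels, true_ids),
    )


def assess(
    kf: KeyframeWindow | np.ndarray,
    model: StrokeClassifier,
    standard_models: dict[int, StandardActionModel],
    threshold: float = 0.8,
) -> AssessmentReport:
    """Overall + per-node scores of one action against the standard models.

    Flags the two lowest-similarity nodes plus every node whose
    similarity falls below the threshold.
    """
    data = kf.data if isinstance(kf, KeyframeWindow) else np.asarray(kf)
    probs = model.predict_proba(data)[0]
    overall = overall_score(probs)
    std = standard_models.get(overall.predicted_class)
    if std is None:
        raise KeyError(
            f"no standard model for predicted class {overall.predicted_class}; "
            "build one from training data first"
        )
    node_sim: dict[int, float] = {}
    for f in split_node_features(model.abstract_map(data), std.d):
        node_sim[f.node_id] = cosine_similarity(f.vector, std.centroids[f.node_id])
    order = sorted(node_sim, key=lambda n: (node_sim[n], n))
    flags = set(order[: min(2, len(order))])
    flags |= {n for n, s in node_sim.items() if s < threshold}
    return AssessmentReport(
        overall=overall,
        node_similarity=node_sim,
        flagged_nodes=tuple(sorted(flags)),
        threshold=threshold,
    )
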