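"""Handcrafted-feature baseline: time/frequency descriptors, PCA, and
four classical classifiers (KNN, SVM, Gaussian naive Bayes, random
forest).

Each 36-frame keyframe channel contributes eight time-domain
descriptors (mean, standard deviation, min, max, RMS, skewness,
kurtosis, zero-crossing count) and three frequency-domain descriptors
computed from the magnitude spectrum of the 36-sample signal
(dominant non-DC frequency bin, total spectral energy, spectral
entropy).  Features are standardized on the training split, reduced by
PCA to the smallest component count reaching a cumulative explained
variance of 0.9, and fed to the classifiers.  This is the comparison
arm against which the learned CNN features are judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import CHANNEL_NAMES, StructuralError
from .segmentation import KEYFRAME_LENGTH, KeyframeWindow

TIME_DESCRIPTORS = ("mean", "std", "min", "max", "rms", "skewness",
                    "kurtosis", "zero_crossings")
FREQ_DESCRIPTORS = ("dominant_bin", "spectral_energy", "spectral_entropy")
DESCRIPTORS = TIME_DESCRIPTORS + FREQ_DESCRIPTORS


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise StructuralError("one name per feature value required")


def feature_names(columns: int, channels_per_node: int = 9) -> tuple[str, ...]:
    names = []
    for col in range(columns):
        node, ch = divmod(col, channels_per_node)
        ch_name = CHANNEL_NAMES[ch] if channels_per_node == 9 else f"c{ch}"
        names.extend(f"n{node}_{ch_name}_{d}" for d in DESCRIPTORS)
    return tuple(names)


def _channel_features(x: np.ndarray) -> np.ndarray:
    """The 11 descriptors of one 36-sample channel."""
    mean = x.mean()
    std = x.std()
    rms = np.sqrt(np.mean(x * x))
    skew = stats.skew(x) if std > 0 else 0.0
    kurt = stats.kurtosis(x) if std > 0 else 0.0
    zc = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    spectrum = np.abs(np.fft.rfft(x))
    power = spectrum**2
    energy = float(power.sum())
    ac = power[1:]  # non-DC bins
    if ac.sum() > 0:
        dominant = 1 + int(np.argmax(ac))
        p = ac / ac.sum()
        entropy = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
    else:
        dominant = 0
        entropy = 0.0
    return np.array([mean, std, x.min(), x.max(), rms, skew, kurt, zc,
                     dominant, energy, entropy])


def extract_features(kf: KeyframeWindow | np.ndarray) -> FeatureVector:
    """Per-channel descriptor vector of a 36 x C keyframe window."""
    data = kf.data if isinstance(kf, KeyframeWindow) else np.asarray(kf, dtype=float)
    if data.ndim != 2 or data.shape[0] != KEYFRAME_LENGTH:
        raise StructuralError(
            f"expected a {KEYFRAME_LENGTH}-row window, got shape {data.shape}"
        )
    values = np.concatenate([_channel_features(data[:, c]) for c in range(data.shape[1])])
    return FeatureVector(values=values, names=feature_names(data.shape[1]))


def extract_feature_matrix(windows: np.ndarray) -> np.ndarray:
    """(N, C*11) feature matrix for a stack of keyframe windows."""
    return np.stack([extract_features(w).values for w in windows])


@dataclass
class PcaProjection:
    """Standardization + principal-component projection fitted on train."""

    mu: np.ndarray
    sd: np.ndarray
    components: np.ndarray          # (k, p)
    center: np.ndarray              # PCA mean in standardized space
    explained_variance_ratio: np.ndarray
    target: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.mu) / self.sd
        return (z - self.center) @ self.components.T


def fit_pca(train_features: np.ndarray, target: float = 0.9) -> PcaProjection:
    """Smallest component count whose cumulative explained variance
    reaches ``target``, after per-feature standardization."""
    from sklearn.decomposition import PCA

    x = np.asarray(train_features, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a projection")
    sd = x.std(axis=0)
    if not np.any(sd > 0):
        raise ValueError("degenerate feature set: every feature has zero variance")
    mu = x.mean(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(z)
    ratios = pca.explained_variance_ratio_
    nonzero = int(np.sum(pca.explained_variance_ > 1e-12))
    if target >= 1.0:
        k = nonzero
    else:
        k = int(np.searchsorted(np.cumsum(ratios), target) + 1)
        k = min(k, nonzero)
    return PcaProjection(
        mu=mu, sd=sd,
        components=pca.components_[:k],
        center=pca.mean_,
        explained_variance_ratio=ratios[:k],
        target=target,
    )


def make_baseline_classifiers(seed: int = 0, knn_k: int = 5, rf_trees: int = 100) -> dict:
    """The four classical classifiers with their default hyperparameters."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    return {
        "KNN": KNeighborsClassifier(n_neighbors=knn_k),
        "SVM": SVC(kernel="rbf", random_state=seed),
        "GaussianNB": GaussianNB(),
        "RandomForest": RandomForestClassifier(n_estimators=rf_trees, random_state=seed),
    }


def train_and_evaluate_baselines(
    train_windows: np.ndarray, train_labels: np.ndarray,
    test_windows: np.ndarray, test_labels: np.ndarray,
    class_count: int, pca_target: float = 0.9, seed: int = 0,
) -> dict[str, dict]:
    """Feature extraction -> PCA -> four classifiers -> macro-F1 + confusion.

    The feature scaler and the projection are fitted on the training
    split only and applied unchanged to the test split.
    """
    from sklearn.metrics import confusion_matrix, f1_score

    present = np.unique(train_labels)
    if set(range(class_count)) - set(present.tolist()):
        raise ValueError("every class must appear in the training split")
    f_train = extract_feature_matrix(train_windows)
    f_test = extract_feature_matrix(test_windows)
    proj = fit_pca(f_train, target=pca_target)
    z_train, z_test = proj.transform(f_train), proj.transform(f_test)
    results: dict[str, dict] = {}
    for name, clf in make_baseline_classifiers(seed=seed).items():
        clf.fit(z_train, train_labels)
        pred = clf.predict(z_test)
        results[name] = {
            "macro_f1": float(f1_score(test_labels, pred, average="macro",
                                       labels=np.arange(class_count),
                                       zero_division=0)),
            "confusion": confusion_matrix(test_labels, pred,
                                          labels=np.arange(class_count)),
            "n_components": proj.n_components,
        }
    return results
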