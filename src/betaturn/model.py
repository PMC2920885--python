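"""Six class-weighted RBF-kernel classifiers and chain-level cross-validation.

One soft-margin support vector classifier per output channel — the
turn/non-turn locator and the five type channels (I, II, IV, VIII, NS)
— each with kernel exp(-gamma ||xi - xj||^2), penalty C, and the
positive (minority) class penalised by C*w.  The per-channel defaults
are the tuned values

    channel   C     gamma   w
    turn      1     0.04     2
    I         1     0.01     7
    II        0.5   0.03    20
    IV        1     0.01     7.5
    VIII      0.5   0.01    20
    NS        4     0.06    36

Predictions are thresholded at zero on the signed decision score;
channels are independent (a residue may be positive in several type
channels, reflecting overlapping turns).  Cross-validation partitions
chains, never residues, so no chain contributes to both the training
and the held-out side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.svm import SVC

from .annotation import CHANNELS
from .evaluation import ConfusionCounts, auc, confusion, metrics_report, roc_curve
from .features import N_FEATURES, encode_chain, scale_pssm
from .filtering import filter_channel

__all__ = [
    "ClassifierConfig",
    "DEFAULT_CONFIGS",
    "ClassifierBundle",
    "ENCODER_LAYOUT_VERSION",
    "train_channel",
    "train_bundle",
    "predict_scores",
    "predict_binary",
    "cross_validate",
    "encode_corpus",
    "save_bundle",
    "load_bundle",
]

#: Identifier of the frozen 230-attribute layout; persisted with models
#: and checked at prediction time so a bundle is never applied to
#: vectors encoded under a different layout.
ENCODER_LAYOUT_VERSION = "pssm9-ss5-cluster5/v1"


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of one binary channel classifier."""

    channel: str
    c: float
    gamma: float
    w: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.c <= 0 or self.gamma <= 0 or self.w < 1:
            raise ValueError("require C > 0, gamma > 0, w >= 1")


#: Tuned per-channel hyperparameters (see module docstring).
DEFAULT_CONFIGS: dict[str, ClassifierConfig] = {
    "turn": ClassifierConfig("turn", c=1.0, gamma=0.04, w=2.0),
    "I": ClassifierConfig("I", c=1.0, gamma=0.01, w=7.0),
    "II": ClassifierConfig("II", c=0.5, gamma=0.03, w=20.0),
    "IV": ClassifierConfig("IV", c=1.0, gamma=0.01, w=7.5),
    "VIII": ClassifierConfig("VIII", c=0.5, gamma=0.01, w=20.0),
    "NS": ClassifierConfig("NS", c=4.0, gamma=0.06, w=36.0),
}


class TrainingError(ValueError):
    """Raised when a channel cannot be trained (e.g. single-class labels)."""


class LayoutMismatchError(ValueError):
    """Raised when a bundle meets vectors from a different encoder layout."""


@dataclass
class ClassifierBundle:
    """Trained classifiers keyed by channel, plus provenance metadata."""

    classifiers: dict[str, SVC] = field(default_factory=dict)
    configs: dict[str, ClassifierConfig] = field(default_factory=dict)
    layout_version: str = ENCODER_LAYOUT_VERSION
    metadata: dict = field(default_factory=dict)

    def require_complete(self) -> None:
        missing = [ch for ch in CHANNELS if ch not in self.classifiers]
        if missing:
            raise ValueError(f"bundle is missing channels: {missing}")


def train_channel(X, y, config: ClassifierConfig, seed: int = 0) -> SVC:
    """Fit one RBF-kernel classifier with positive-class penalty C*w."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y) or len(X) < 2:
        raise TrainingError("need at least two instances with matching labels")
    if len(np.unique(y)) < 2:
        raise TrainingError(
            f"channel {config.channel!r}: training labels contain a single class")
    clf = SVC(kernel="rbf", C=config.c, gamma=config.gamma,
              class_weight={1: config.w}, random_state=seed)
    clf.fit(X, y)
    return clf


def train_bundle(X, labels_by_channel: dict[str, np.ndarray],
                 configs: dict[str, ClassifierConfig] | None = None,
                 seed: int = 0,
                 channels=CHANNELS) -> ClassifierBundle:
    """Train the requested channels on one feature matrix."""
    configs = configs or DEFAULT_CONFIGS
    bundle = ClassifierBundle(metadata={"seed": seed, "n_train": len(X)})
    for ch in channels:
        bundle.configs[ch] = configs[ch]
        bundle.classifiers[ch] = train_channel(X, labels_by_channel[ch],
                                               configs[ch], seed=seed)
    return bundle


def _check_layout(bundle: ClassifierBundle, X: np.ndarray) -> None:
    if bundle.layout_version != ENCODER_LAYOUT_VERSION:
        raise LayoutMismatchError(
            f"bundle layout {bundle.layout_version!r} != "
            f"runtime layout {ENCODER_LAYOUT_VERSION!r}")
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise LayoutMismatchError(
            f"feature matrix has {X.shape[-1]} attributes, expected {N_FEATURES}")


def predict_scores(bundle: ClassifierBundle, X) -> dict[str, np.ndarray]:
    """Signed decision score per instance per trained channel (positive = hit)."""
    X = np.asarray(X, dtype=float)
    _check_layout(bundle, X)
    return {ch: clf.decision_function(X)
            for ch, clf in bundle.classifiers.items()}


def predict_binary(bundle: ClassifierBundle, X) -> dict[str, np.ndarray]:
    """Binary channel predictions: 1 iff the decision score is positive."""
    return {ch: (s > 0).astype(np.uint8)
            for ch, s in predict_scores(bundle, X).items()}


def apply_filter(binary: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Run the state-flipping filter on each channel of one chain."""
    out = {}
    for ch, arr in binary.items():
        s = "".join("t" if v else "n" for v in arr)
        out[ch] = np.array([1 if c == "t" else 0 for c in filter_channel(s)],
                           dtype=np.uint8)
    return out


def encode_corpus(corpus) -> list[tuple[np.ndarray, dict[str, np.ndarray]]]:
    """Encode every corpus chain: (L x 230 matrix, per-channel labels)."""
    out = []
    for ch in corpus.chains:
        X = encode_chain(scale_pssm(ch.profile), ch.upstream)
        y = {name: np.asarray(ch.labels[name], dtype=int) for name in CHANNELS}
        out.append((X, y))
    return out


@dataclass
class CrossValResult:
    """Per-fold and pooled evaluation of chain-level cross-validation."""

    fold_counts: dict[str, list[ConfusionCounts]]
    pooled_counts: dict[str, ConfusionCounts]
    reports: dict[str, object]
    fold_assignment: np.ndarray


def cross_validate(encoded_chains, folds: int = 7, seed: int = 0,
                   configs: dict[str, ClassifierConfig] | None = None,
                   channels=("turn",),
                   filter_predictions: bool = True) -> CrossValResult:
    """Chain-level k-fold cross-validation with pooled confusion counts.

    ``encoded_chains`` is the output of :func:`encode_corpus`.  Chains
    are shuffled with the seed and dealt into ``folds`` groups; each
    fold's chains are predicted by classifiers trained on all other
    folds, filtered per chain (unless disabled), and tallied.  Pooled
    metrics come from the summed counts over folds (residue pooling);
    the ROC AUC per channel is computed from the pooled raw decision
    scores, before filtering.
    """
    n = len(encoded_chains)
    if n < folds:
        raise ValueError(f"need at least {folds} chains for {folds}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.arange(n) % folds

    fold_counts: dict[str, list[ConfusionCounts]] = {ch: [] for ch in channels}
    scores_pool: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}
    truth_pool: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}

    for f in range(folds):
        train_idx = [i for i in range(n) if assignment[i] != f]
        test_idx = [i for i in range(n) if assignment[i] == f]
        X_train = np.vstack([encoded_chains[i][0] for i in train_idx])
        y_train = {ch: np.concatenate([encoded_chains[i][1][ch] for i in train_idx])
                   for ch in channels}
        bundle = train_bundle(X_train, y_train, configs=configs, seed=seed,
                              channels=channels)
        counts = {ch: ConfusionCounts(0, 0, 0, 0) for ch in channels}
        for i in test_idx:
            X, y = encoded_chains[i]
            scores = predict_scores(bundle, X)
            binary = {ch: (scores[ch] > 0).astype(np.uint8) for ch in channels}
            if filter_predictions:
                binary = apply_filter(binary)
            for ch in channels:
                counts[ch] = counts[ch] + confusion(binary[ch], y[ch])
                scores_pool[ch].append(scores[ch])
                truth_pool[ch].append(y[ch])
        for ch in channels:
            fold_counts[ch].append(counts[ch])

    pooled = {ch: sum(fold_counts[ch][1:], fold_counts[ch][0]) for ch in channels}
    reports = {}
    for ch in channels:
        truth = np.concatenate(truth_pool[ch])
        roc_auc = None
        if truth.min() != truth.max():
            roc_auc = auc(roc_curve(np.concatenate(scores_pool[ch]), truth))
        reports[ch] = metrics_report(pooled[ch], roc_auc=roc_auc)
    return CrossValResult(fold_counts=fold_counts, pooled_counts=pooled,
                          reports=reports, fold_assignment=assignment)


_BUNDLE_FORMAT_VERSION = 1


def save_bundle(bundle: ClassifierBundle, path) -> None:
    """Persist a bundle as a versioned joblib archive."""
    joblib.dump({
        "format_version": _BUNDLE_FORMAT_VERSION,
        "layout_version": bundle.layout_version,
        "configs": bundle.configs,
        "classifiers": bundle.classifiers,
        "metadata": bundle.metadata,
    }, path)


def load_bundle(path) -> ClassifierBundle:
    payload = joblib.load(path)
    if payload.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version in {path}")
    return ClassifierBundle(classifiers=payload["classifiers"],
                            configs=payload["configs"],
                            layout_version=payload["layout_version"],
                            metadata=payload["metadata"])
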