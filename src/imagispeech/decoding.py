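"""Representation-guided binary decoding and chance thresholds.

Speech items are merged into two classes by complete-linkage hierarchical
clustering of their representation distance matrix, choosing the dendrogram
cut that minimizes class imbalance.  Decoding is a linear-kernel SVM with
recursive feature elimination: outer stratified 10-fold cross-validation,
with the retained feature count chosen inside each training fold by nested
stratified 5-fold cross-validation on balanced accuracy.  Significance uses
the inverse binomial threshold: the smallest accuracy whose probability
under a fair-coin null falls below alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import RFECV
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import FeatureTable

logger = logging.getLogger("imagispeech")


@dataclass
class BinarySplit:
    """A dendrogram-consistent two-class grouping of the lexicon."""

    class_a: frozenset
    class_b: frozenset
    imbalance: int
    inter_distance: float
    representation: str | None = None

    def label_of(self, item: str) -> int:
        if item in self.class_a:
            return 0
        if item in self.class_b:
            return 1
        raise KeyError(f"item {item!r} not in either class")


@dataclass
class DecodingResult:
    balanced_accuracy: float
    fold_accuracies: list = field(default_factory=list)
    n_trials: int = 0
    selected_feature_counts: list = field(default_factory=list)
    threshold: float = 1.0
    significant: bool = False


def _cluster_members(z: np.ndarray, n: int) -> list[set]:
    """Member sets of every node (leaves and merges) of a linkage tree."""
    members = [{i} for i in range(n)]
    for row in z:
        members.append(members[int(row[0])] | members[int(row[1])])
    return members


def build_binary_classes(
    distance: pd.DataFrame, representation: str | None = None
) -> BinarySplit:
    """Two classes from complete-linkage clustering of an item distance matrix.

    Every partition obtained by separating one dendrogram cluster from the
    rest is evaluated; the minimal-imbalance one wins, with ties broken by
    the larger maximum between-class distance (then deterministically by
    item names).
    """
    items = list(distance.index)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items")
    mat = distance.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T) or np.any(np.diag(mat) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    off = mat[~np.eye(n, dtype=bool)]
    if np.all(off == 0):
        raise ValueError("degenerate representation: all pairwise distances are zero")
    condensed = scipy.spatial.distance.squareform(mat, checks=False)
    z = scipy.cluster.hierarchy.linkage(condensed, method="complete")
    best = None
    for members in _cluster_members(z, n):
        if not 1 <= len(members) < n:
            continue
        rest = set(range(n)) - members
        imbalance = abs(len(members) - len(rest))
        inter = mat[np.ix_(sorted(members), sorted(rest))].max()
        a = frozenset(items[i] for i in members)
        b = frozenset(items[i] for i in rest)
        if tuple(sorted(a)) > tuple(sorted(b)):
            a, b = b, a
        key = (imbalance, -inter, tuple(sorted(a)))
        if best is None or key < best[0]:
            best = (key, BinarySplit(class_a=a, class_b=b, imbalance=imbalance,
                                     inter_distance=float(inter), representation=representation))
    return best[1]


def binomial_significance_threshold(
    n_trials: int, alpha: float = 0.05, chance: float = 0.5
) -> float:
    """Smallest accuracy k/n with a fair-coin tail probability below alpha.

    For very small n no accuracy reaches significance (even n correct out of
    n has tail probability >= alpha); the threshold is then 1.0, i.e. the
    best achievable accuracy, which still does not certify significance.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    tails = scipy.stats.binom.sf(np.arange(n_trials + 1) - 1, n_trials, chance)
    hits = np.nonzero(tails < alpha)[0]
    if len(hits) == 0:
        return 1.0
    return float(hits[0]) / n_trials


def svm_rfe_decode(
    features: FeatureTable,
    split: BinarySplit,
    folds: int = 10,
    inner_folds: int = 5,
    c: float = 1.0,
    rfe_step: float = 0.1,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Linear-SVM decoding with per-fold recursive feature elimination.

    Feature standardization and RFE are fit inside each training fold only.
    Classes with fewer trials than folds reduce the fold count with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    items = features.trials["item"].to_numpy()
    in_split = np.array([it in split.class_a or it in split.class_b for it in items])
    x = features.values[in_split]
    y = np.array([split.label_of(it) for it in items[in_split]])
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < 2:
        raise ValueError("each class needs at least 2 trials")
    if class_counts.min() < folds:
        logger.warning(
            "smallest class has %d trials; reducing folds from %d", class_counts.min(), folds
        )
        folds = int(class_counts.min())
    outer = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    fold_acc, n_selected = [], []
    for train, test in outer.split(x, y):
        scaler = StandardScaler().fit(x[train])
        xtr = scaler.transform(x[train])
        xte = scaler.transform(x[test])
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        selector = RFECV(
            estimator=SVC(kernel="linear", C=c),
            step=rfe_step,
            min_features_to_select=1,
            cv=inner,
            scoring="balanced_accuracy",
        )
        selector.fit(xtr, y[train])
        fold_acc.append(balanced_accuracy_score(y[test], selector.predict(xte)))
        n_selected.append(int(selector.n_features_))
    mean_acc = float(np.mean(fold_acc))
    threshold = binomial_significance_threshold(len(y), alpha=alpha)
    return DecodingResult(
        balanced_accuracy=mean_acc,
        fold_accuracies=[float(a) for a in fold_acc],
        n_trials=len(y),
        selected_feature_counts=n_selected,
        threshold=threshold,
        significant=mean_acc >= threshold,
    )


def task_discrimination(
    feature_sets: dict,
    labels: np.ndarray,
    folds: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """LDA task classification (e.g. listen vs overt vs imagined) per feature set.

    Stratified k-fold accuracy for each named feature matrix.  Shrinkage
    (Ledoit-Wolf) is used whenever the within-class covariance would be
    singular (more features than trials), and logged.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 classes")
    rows = []
    for name, x in feature_sets.items():
        x = np.asarray(x, dtype=float)
        if x.shape[1] >= x.shape[0]:
            logger.info("feature set %s: shrinkage LDA (p=%d >= n=%d)", name, x.shape[1], x.shape[0])
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            clf = LinearDiscriminantAnalysis()
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for fold, (train, test) in enumerate(skf.split(x, labels)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(x[train], labels[train])
                acc = accuracy_score(labels[test], clf.predict(x[test]))
            rows.append({"feature_set": name, "fold": fold, "accuracy": float(acc)})
    return pd.DataFrame(rows)
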