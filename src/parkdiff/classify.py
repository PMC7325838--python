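"""FDR-ranked incremental SVM classification with leave-two-out CV.

Features are ranked by the Fisher Discriminant Ratio

    FDR = (mu_1 - mu_2)^2 / (sigma_1^2 + sigma_2^2)

computed per feature from the two training classes (sample variances). A
soft-margin SVM (linear kernel, C = 1 by default) is then trained on the
top-k features for k = 1..K, giving accuracy as a function of the number of
features.

Two evaluation schemes: leave-two-out paired cross-validation, where each
fold holds out one subject from each class and the FDR ranking (and, in
leakage-safe mode, z-scoring and the PCA basis) is refit on the remaining
training subjects; and independent validation, where ranking, normalization
and models are fit once on the full training cohort and applied to unseen
subjects. Paper mode fits normalization/PCA on all subjects jointly
(reproducing a common but optimistic practice) while still re-ranking per
fold; the accuracy gap between the two modes on null data measures the
selection-leakage optimism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._streams import stream
from .features import FeatureMatrix, fit_pca, normalize_features, pca_project

__all__ = ["ClassStats", "RankedFeatureList", "AccuracyCurve", "SVMConfig",
           "CVConfig", "fisher_discriminant_ratio", "class_stats",
           "rank_features", "incremental_svm_accuracy", "leave_two_out_cv",
           "independent_validation", "pair_label"]

log = logging.getLogger(__name__)

# clinical ordering used to pick the positive class of a pair
_GROUP_ORDER = ("Control", "PD", "PSP-RS", "CBS")


def pair_label(g1: str, g2: str) -> tuple[str, str, str]:
    """Canonical "A vs B" label; B (the later group in clinical order,
    i.e. the patient or rarer disorder) is the positive class."""
    order = {g: i for i, g in enumerate(_GROUP_ORDER)}
    a, b = sorted((g1, g2), key=lambda g: order.get(g, len(order)))
    return f"{a} vs {b}", a, b


@dataclass
class ClassStats:
    """Per-feature mean and variance of the two classes."""

    features: list[str]
    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray


@dataclass
class RankedFeatureList:
    """Features in descending FDR order with their scores."""

    features: list[str]
    scores: list[float]
    training_ids: list[str]

    def __post_init__(self) -> None:
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")


@dataclass
class AccuracyCurve:
    """Accuracy/sensitivity/specificity as a function of feature count."""

    label: str
    ks: list[int]
    accuracy: list[float]
    sensitivity: list[float]
    specificity: list[float]
    n_folds: int
    positive_class: str
    balanced_accuracy: list[float] | None = None
    weights: dict[int, pd.Series] | None = None   # per-k linear SVM weights

    def as_frame(self) -> pd.DataFrame:
        d = {"k": self.ks, "accuracy": self.accuracy,
             "sensitivity": self.sensitivity, "specificity": self.specificity}
        if self.balanced_accuracy is not None:
            d["balanced_accuracy"] = self.balanced_accuracy
        return pd.DataFrame(d)


@dataclass
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0


@dataclass
class CVConfig:
    """Pipeline settings shared by CV and independent validation."""

    method: str = "roi"            # roi (features as given) | pca (voxel vectors)
    mode: str = "safe"             # safe | paper
    k_max: int | None = None
    svm: SVMConfig = field(default_factory=SVMConfig)
    folds: str | int = "exhaustive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("safe", "paper"):
            raise ValueError("mode must be 'safe' or 'paper'")
        if self.method not in ("roi", "pca"):
            raise ValueError("method must be 'roi' or 'pca'")


def fisher_discriminant_ratio(class1, class2) -> float:
    """(mu1 - mu2)^2 / (s1^2 + s2^2) with sample variances.

    Symmetric in class order and invariant to a common affine rescaling of
    both classes. A zero denominator yields +inf when the means differ
    (perfect separation of two constants) and 0 when they coincide.
    """
    a = np.asarray(class1, dtype=float)
    b = np.asarray(class2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 values")
    num = (a.mean() - b.mean()) ** 2
    den = a.var(ddof=1) + b.var(ddof=1)
    if den == 0:
        if num == 0:
            return 0.0
        log.warning("zero within-class variance with distinct means: FDR=+inf")
        return float("inf")
    return float(num / den)


def class_stats(fm: FeatureMatrix, labels: pd.Series) -> ClassStats:
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly 2 classes required")
    x1 = fm.data.loc[labels[labels == classes[0]].index]
    x2 = fm.data.loc[labels[labels == classes[1]].index]
    return ClassStats(fm.feature_names,
                      x1.mean().to_numpy(), x2.mean().to_numpy(),
                      x1.var(ddof=1).to_numpy(), x2.var(ddof=1).to_numpy())


def rank_features(train: FeatureMatrix, labels: pd.Series) -> RankedFeatureList:
    """Descending-FDR feature ranking from training rows only.

    Ties are broken by feature name (lexicographic) for determinism.
    """
    labels = labels.loc[train.subject_ids]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("training set must contain exactly 2 classes")
    g1 = train.data.loc[labels[labels == classes[0]].index].to_numpy(dtype=float)
    g2 = train.data.loc[labels[labels == classes[1]].index].to_numpy(dtype=float)
    num = (g1.mean(axis=0) - g2.mean(axis=0)) ** 2
    den = g1.var(axis=0, ddof=1) + g2.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    names = np.array(train.feature_names)
    # sort by (-score, name); np.lexsort keys are applied last-first
    order = np.lexsort((names, -scores))
    return RankedFeatureList([str(n) for n in names[order]],
                             [float(s) for s in scores[order]],
                             list(train.subject_ids))


def incremental_svm_accuracy(train: FeatureMatrix, test: FeatureMatrix,
                             train_labels: pd.Series, ranking: RankedFeatureList,
                             k_max: int | None = None,
                             svm: SVMConfig | None = None,
                             keep_weights: bool = False
                             ) -> tuple[pd.DataFrame, dict[int, pd.Series]]:
    """Predictions for each feature-count k = 1..k_max.

    For each k, an SVM is trained on the top-k ranked features of the
    training matrix and the test rows are predicted. Returns a (k, test
    subject) prediction table and, optionally, per-k linear weight vectors.
    """
    svm = svm or SVMConfig()
    avail = len(ranking.features)
    if k_max is None:
        k_max = avail
    if k_max > avail:
        log.warning("k_max=%d exceeds %d available features; clipping", k_max, avail)
        k_max = avail
    y = train_labels.loc[train.subject_ids].to_numpy()
    preds = {}
    weights: dict[int, pd.Series] = {}
    for k in range(1, k_max + 1):
        cols = ranking.features[:k]
        clf = SVC(kernel=svm.kernel, C=svm.C)
        clf.fit(train.data[cols].to_numpy(dtype=float), y)
        preds[k] = clf.predict(test.data[cols].to_numpy(dtype=float))
        if keep_weights and svm.kernel == "linear":
            weights[k] = pd.Series(clf.coef_[0], index=cols)
    table = pd.DataFrame(preds, index=test.subject_ids).T
    table.index.name = "k"
    return table, weights


def _enumerate_folds(ids_a: list[str], ids_b: list[str],
                     folds: str | int, seed: int) -> list[tuple[str, str]]:
    all_pairs = list(product(ids_a, ids_b))
    if folds == "exhaustive":
        return all_pairs
    n = int(folds)
    if n >= len(all_pairs):
        return all_pairs
    rng = stream(seed, "cv-folds")
    idx = rng.choice(len(all_pairs), size=n, replace=False)
    return [all_pairs[i] for i in sorted(idx)]


def _prepare_fold(features, train_ids, test_ids, config: CVConfig):
    """Per-fold feature preparation honoring the leakage mode."""
    if config.method == "roi":
        fm: FeatureMatrix = features
        if config.mode == "safe":
            (tr, te), _ = normalize_features(fm.rows(train_ids), fm.rows(test_ids))
        else:
            (all_z,), _ = normalize_features(fm)
            tr, te = all_z.rows(train_ids), all_z.rows(test_ids)
        return tr, te
    # pca: features is a per-subject voxel DataFrame
    vox: pd.DataFrame = features
    if config.mode == "safe":
        basis = fit_pca(vox.loc[list(train_ids)])
        tr_s = pca_project(basis, vox.loc[list(train_ids)])
        te_s = pca_project(basis, vox.loc[list(test_ids)])
        (tr, te), _ = normalize_features(tr_s, te_s)
    else:
        basis = fit_pca(vox)
        scores = pca_project(basis, vox)
        (all_z,), _ = normalize_features(scores)
        tr, te = all_z.rows(train_ids), all_z.rows(test_ids)
    return tr, te


def _curve_from_counts(label, ks, n_folds, correct, pos_total, neg_total,
                       pos_correct, neg_correct, positive, weights=None,
                       balanced=False):
    accuracy = [correct[k] / (pos_total + neg_total) for k in ks]
    sens = [pos_correct[k] / pos_total if pos_total else 0.0 for k in ks]
    spec = [neg_correct[k] / neg_total if neg_total else 0.0 for k in ks]
    bal = [(s + p) / 2 for s, p in zip(sens, spec)] if balanced else None
    return AccuracyCurve(label, list(ks), accuracy, sens, spec, n_folds,
                         positive, balanced_accuracy=bal, weights=weights)


def leave_two_out_cv(features, labels: pd.Series, config: CVConfig | None = None,
                     label: str | None = None) -> AccuracyCurve:
    """Leave-two-out paired cross-validation.

    Folds hold out one subject from each class — exhaustively (N_A x N_B
    folds) or a seeded subsample. Within each fold, normalization (and the
    PCA basis, for the pca method) are fit on the 2N-2 training subjects in
    safe mode, the FDR ranking is recomputed on training rows, and the
    incremental SVM is scored on the held-out pair.

    ``features`` is a FeatureMatrix for the roi method or a per-subject
    voxel DataFrame for the pca method.
    """
    config = config or CVConfig()
    ids = list(features.subject_ids if isinstance(features, FeatureMatrix)
               else features.index)
    labels = labels.loc[ids]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly 2 classes required")
    lab, neg_class, pos_class = pair_label(classes[0], classes[1])
    if label is None:
        label = lab
    ids_a = [i for i in ids if labels[i] == neg_class]
    ids_b = [i for i in ids if labels[i] == pos_class]
    if min(len(ids_a), len(ids_b)) < 3:
        raise ValueError("need at least 3 subjects per class")
    folds = _enumerate_folds(ids_a, ids_b, config.folds, config.seed)

    # fixed k grid: smallest feature count any fold can provide
    if config.method == "roi":
        avail = features.data.shape[1]
    else:
        avail = len(ids) - 3  # 2N-2 training subjects -> at most 2N-3 components
    k_max = min(config.k_max or avail, avail)

    ks = range(1, k_max + 1)
    correct = {k: 0.0 for k in ks}
    pos_correct = {k: 0.0 for k in ks}
    neg_correct = {k: 0.0 for k in ks}
    for a_id, b_id in folds:
        test_ids = [a_id, b_id]
        train_ids = [i for i in ids if i not in test_ids]
        tr, te = _prepare_fold(features, train_ids, test_ids, config)
        ranking = rank_features(tr, labels)
        preds, _ = incremental_svm_accuracy(tr, te, labels, ranking,
                                            k_max=k_max, svm=config.svm)
        for k in ks:
            row = preds.loc[k]
            neg_correct[k] += float(row[a_id] == neg_class)
            pos_correct[k] += float(row[b_id] == pos_class)
            correct[k] += float(row[a_id] == neg_class) + float(row[b_id] == pos_class)
    n = len(folds)
    return _curve_from_counts(label, list(ks), n, correct, n, n,
                              pos_correct, neg_correct, pos_class)


def independent_validation(train_features, val_features, labels: pd.Series,
                           config: CVConfig | None = None,
                           label: str | None = None) -> AccuracyCurve:
    """Frozen-ranking validation on unseen subjects.

    Ranking, normalization (and the PCA basis) are fit once on the full
    training cohort; incremental SVMs trained on the training cohort are
    applied to the validation subjects. Validation groups may be unequal, so
    balanced accuracy is reported alongside the raw fraction. Weights of
    each per-k model are retained for spatial localization.
    """
    config = config or CVConfig()
    is_fm = isinstance(train_features, FeatureMatrix)
    train_ids = list(train_features.subject_ids if is_fm else train_features.index)
    val_ids = list(val_features.subject_ids if is_fm else val_features.index)
    overlap = set(train_ids) & set(val_ids)
    if overlap:
        raise ValueError(f"subjects appear in both cohorts: {sorted(overlap)[:5]}")
    classes = sorted(labels.loc[train_ids].unique())
    if len(classes) != 2:
        raise ValueError("exactly 2 classes required")
    lab, neg_class, pos_class = pair_label(classes[0], classes[1])
    if label is None:
        label = lab

    if config.method == "roi":
        if config.mode == "safe":
            (tr, te), _ = normalize_features(train_features, val_features)
        else:
            joint = FeatureMatrix(pd.concat([train_features.data, val_features.data]))
            (all_z,), _ = normalize_features(joint)
            tr, te = all_z.rows(train_ids), all_z.rows(val_ids)
    else:
        if config.mode == "safe":
            basis = fit_pca(train_features)
            (tr, te), _ = normalize_features(pca_project(basis, train_features),
                                             pca_project(basis, val_features))
        else:
            joint = pd.concat([train_features, val_features])
            basis = fit_pca(joint)
            scores = pca_project(basis, joint)
            (all_z,), _ = normalize_features(scores)
            tr, te = all_z.rows(train_ids), all_z.rows(val_ids)

    ranking = rank_features(tr, labels)
    k_max = min(config.k_max or len(ranking.features), len(ranking.features))
    preds, weights = incremental_svm_accuracy(
        tr, te, labels, ranking, k_max=k_max, svm=config.svm, keep_weights=True)

    val_labels = labels.loc[val_ids]
    pos_ids = [i for i in val_ids if val_labels[i] == pos_class]
    neg_ids = [i for i in val_ids if val_labels[i] == neg_class]
    ks = range(1, k_max + 1)
    correct = {k: float((preds.loc[k] == val_labels).sum()) for k in ks}
    pos_correct = {k: float((preds.loc[k, pos_ids] == pos_class).sum()) for k in ks}
    neg_correct = {k: float((preds.loc[k, neg_ids] == neg_class).sum()) for k in ks}
    return _curve_from_counts(label, list(ks), 1, correct, len(pos_ids),
                              len(neg_ids), pos_correct, neg_correct, pos_class,
                              weights=weights, balanced=True)
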