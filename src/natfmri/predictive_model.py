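"""Linear-SVM predictive model: leave-one-subject-out evaluation and
significant-feature identification.

The classifier is a linear SVM (C = 1 by default, no cross-voxel scaling)
trained on whole-mask activation feature vectors. Evaluation is
leave-one-subject-out: all runs of one subject are held out per fold.
Significant spatial features are identified two ways: bootstrap stability tests
on the SVM weight vector, and recursive feature elimination (RFE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_curve
from sklearn.svm import SVC
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _linear_svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C)


@dataclass
class CVResult:
    """Pooled leave-one-subject-out predictions."""

    decision_values: np.ndarray  # signed distances, positive class = classes[1]
    y_pred: np.ndarray
    y_true: np.ndarray
    fold_ids: np.ndarray  # held-out subject id per sample
    fold_weights: dict[int, np.ndarray]  # subject id -> weight vector
    classes: tuple


@dataclass
class ConfusionMetrics:
    TP: int
    FN: int
    FP: int
    TN: int
    S_N: float
    S_P: float
    accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class SignificanceMap:
    """Per-feature selection flags with signs and provenance.

    ``sign`` is +1 where the underlying weight favors the positive class
    (classes[1]), -1 where it favors the negative class, 0 for unselected /
    zero-weight features.
    """

    statistic: np.ndarray
    selected: np.ndarray  # bool
    sign: np.ndarray  # int8 in {-1, 0, +1}
    method: str
    classes: tuple


def fit_svm_loso(
    features: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    C: float = 1.0,
) -> CVResult:
    """Leave-one-subject-out linear SVM.

    Each subject's runs in turn form the test set; the SVM is refit on the
    remaining subjects. Decision values, predictions, and per-fold weight
    vectors are pooled over folds. Deterministic given the inputs.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if len(subjects) < 2:
        raise ValueError("at least 2 subjects required for leave-one-subject-out")
    classes = tuple(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("binary classification requires exactly 2 classes")

    n = len(labels)
    decision = np.empty(n)
    y_pred = np.empty(n, dtype=labels.dtype)
    fold_ids = np.empty(n, dtype=subject_ids.dtype)
    fold_weights: dict = {}
    for subj in subjects:
        test = subject_ids == subj
        train = ~test
        train_classes = set(np.unique(labels[train]))
        if train_classes != set(classes):
            raise ValueError(
                f"training fold for held-out subject {subj!r} is missing a class"
            )
        clf = _linear_svm(C).fit(features[train], labels[train])
        decision[test] = clf.decision_function(features[test])
        y_pred[test] = clf.predict(features[test])
        fold_ids[test] = subj
        fold_weights[subj] = clf.coef_.ravel().copy()
    return CVResult(
        decision_values=decision,
        y_pred=y_pred,
        y_true=labels.copy(),
        fold_ids=fold_ids,
        fold_weights=fold_weights,
        classes=classes,
    )


def confusion_and_roc(cv: CVResult) -> ConfusionMetrics:
    """Confusion counts at decision threshold 0, sensitivity/specificity, and
    the pooled ROC curve with trapezoid AUC.

    S_N = TP / (TP + FN), S_P = TN / (TN + FP); the positive class is
    ``cv.classes[1]`` (the class on the positive side of the decision axis).
    """
    pos = cv.classes[1]
    is_pos = cv.y_true == pos
    pred_pos = cv.decision_values > 0
    TP = int(np.sum(is_pos & pred_pos))
    FN = int(np.sum(is_pos & ~pred_pos))
    FP = int(np.sum(~is_pos & pred_pos))
    TN = int(np.sum(~is_pos & ~pred_pos))
    if TP + FN == 0 or TN + FP == 0:
        raise ValueError("both classes must be present to form S_N and S_P")
    fpr, tpr, _ = roc_curve(is_pos.astype(int), cv.decision_values)
    auc = float(np.trapezoid(tpr, fpr))
    return ConfusionMetrics(
        TP=TP,
        FN=FN,
        FP=FP,
        TN=TN,
        S_N=TP / (TP + FN),
        S_P=TN / (TN + FP),
        accuracy=(TP + TN) / (TP + FN + FP + TN),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
    )


def bootstrap_feature_test(
    features: np.ndarray,
    labels: np.ndarray,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    C: float = 1.0,
) -> SignificanceMap:
    """Bootstrap stability test on SVM weights.

    ``B`` class-stratified resamples (with replacement) of the samples; the SVM
    is refit on each and the weight vectors collected. Per feature,
    z = mean(w) / sd(w) over resamples, two-sided normal p-values, and
    Benjamini-Hochberg FDR control at ``alpha``. Selected features carry the
    sign of their mean weight.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable weight s.d.")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("binary classification requires exactly 2 classes")
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(labels == c) for c in classes]

    W = np.empty((B, features.shape[1]))
    for b in range(B):
        idx = np.concatenate(
            [rng.choice(ci, size=len(ci), replace=True) for ci in class_idx]
        )
        clf = _linear_svm(C).fit(features[idx], labels[idx])
        W[b] = clf.coef_.ravel()

    mean_w = W.mean(axis=0)
    sd_w = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean_w / sd_w
    # zero-variance weights: infinitely stable if nonzero, null if zero
    z[(sd_w == 0) & (mean_w != 0)] = np.inf * np.sign(mean_w[(sd_w == 0) & (mean_w != 0)])
    z[(sd_w == 0) & (mean_w == 0)] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(z))
    selected = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    sign = np.sign(mean_w).astype(np.int8)
    sign[~selected] = 0
    return SignificanceMap(
        statistic=z, selected=selected, sign=sign, method="bootstrap", classes=classes
    )


def rfe_select(
    features: np.ndarray,
    labels: np.ndarray,
    step_fraction: float = 0.1,
    n_keep: int | None = None,
    C: float = 1.0,
) -> SignificanceMap:
    """Recursive feature elimination down to ``n_keep`` surviving features.

    Each iteration drops the ``step_fraction`` of surviving features with the
    smallest |w| (the final step truncated to land exactly on ``n_keep``).
    Survivor signs come from an SVM refit on the survivors alone.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n_features = features.shape[1]
    if n_keep is None:
        n_keep = max(1, n_features // 100)
    if not 1 <= n_keep <= n_features:
        raise ValueError(f"n_keep must be in [1, {n_features}]")
    classes = tuple(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("binary classification requires exactly 2 classes")

    rfe = RFE(
        estimator=_linear_svm(C),
        n_features_to_select=n_keep,
        step=step_fraction,
    ).fit(features, labels)
    selected = rfe.support_.copy()

    final = _linear_svm(C).fit(features[:, selected], labels)
    w = final.coef_.ravel()
    sign = np.zeros(n_features, dtype=np.int8)
    sign[selected] = np.sign(w).astype(np.int8)
    statistic = np.zeros(n_features)
    statistic[selected] = np.abs(w)
    return SignificanceMap(
        statistic=statistic, selected=selected, sign=sign, method="RFE", classes=classes
    )
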