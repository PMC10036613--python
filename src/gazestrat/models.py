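"""Classifiers and evaluation protocol for the two prediction tasks.

CT1 is binary (equilibrium choice or not), CT2 is three-class (exact
strategy).  Data are split 70-20-10 at the *participant* level so every
evaluation concerns people the model never saw; CT1 is balanced by
undersampling the majority class.  The image classifier is an RBF-kernel
SVM on downscaled scanpath rasters; the baseline is a (multinomial)
logistic regression on the own/other/intracell transition proportions.
Metrics follow the study protocol: accuracy, AUC (weighted one-vs-rest
for CT2), F1 (weighted for CT2) and the confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as skm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .features import BASELINE_COLUMNS

CT1, CT2 = "CT1", "CT2"

#: the study's stated SVM hyperparameters: kernel coefficient (gamma) and
#: regularisation penalty (C)
SVM_GAMMA = 1e-4
SVM_C = 10.0

#: downscaled image edge used to vectorise rasters for the SVM
SVM_IMAGE_EDGE = 64


@dataclass(frozen=True)
class SplitAssignment:
    """Participant-level train/val/test partition."""

    assignment: dict[str, str]  # participant_id -> "train" | "val" | "test"
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, subset: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == subset]

    def subset_of(self, records, subset: str):
        keep = set(self.ids(subset))
        return [r for r in records if r.participant_id in keep]


def split_participants(
    ids,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Random participant partition honouring the fractions.

    Subset sizes follow largest-remainder rounding of ``n * fraction``
    (e.g. 243 participants at 0.7/0.2/0.1 gives 170/49/24); the permutation
    is deterministic per seed.
    """
    ids = list(dict.fromkeys(ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 participants to split")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative and sum to 1")
    n = len(ids)
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = sorted(range(3), key=lambda i: quotas[i] - sizes[i], reverse=True)
    for i in range(n - sum(sizes)):
        sizes[remainders[i % 3]] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    pos = 0
    for name, size in zip(names, sizes):
        for k in perm[pos : pos + size]:
            assignment[ids[k]] = name
        pos += size
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def balance_binary(records, key, seed: int = 0):
    """Balance a binary-labelled record list by undersampling the majority.

    ``key(record)`` must return a boolean/binary label.  Removes exactly
    ``majority - minority`` randomly chosen majority records; the order of
    the survivors is preserved.
    """
    labels = [bool(key(r)) for r in records]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("balance_binary requires both classes present")
    majority = n_pos > n_neg
    excess = abs(n_pos - n_neg)
    rng = np.random.default_rng(seed)
    maj_idx = [i for i, l in enumerate(labels) if l == majority]
    drop = set(rng.choice(maj_idx, size=excess, replace=False).tolist())
    return [r for i, r in enumerate(records) if i not in drop]


def images_to_vectors(images: np.ndarray, edge: int = SVM_IMAGE_EDGE) -> np.ndarray:
    """Downscale (N, H, W, 3) uint8 rasters to flat [0, 1] vectors.

    Block-averages to ``edge x edge`` (exact when H and W are multiples of
    ``edge``, else via nearest-index sampling grid).
    """
    images = np.asarray(images)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got {images.shape}")
    n, h, w, _ = images.shape
    if h % edge == 0 and w % edge == 0:
        small = images.reshape(n, edge, h // edge, edge, w // edge, 3).mean(axis=(2, 4))
    else:
        yi = (np.arange(edge) * h / edge).astype(int)
        xi = (np.arange(edge) * w / edge).astype(int)
        small = images[:, yi][:, :, xi].astype(float)
    return small.reshape(n, -1) / 255.0


def train_svm_image(
    images: np.ndarray,
    labels,
    task: str = CT1,
    cv_config: dict | None = None,
    seed: int = 0,
    edge: int = SVM_IMAGE_EDGE,
):
    """Fit the RBF-kernel SVM image classifier.

    With ``cv_config=None`` the stated hyperparameters (gamma 1e-4, C 10)
    are used directly; passing e.g. ``{"C": [1, 10], "gamma": [1e-4, 1e-3]}``
    runs a 5-fold cross-validated exhaustive grid search (deterministic per
    seed).  CT2 uses class weights inversely proportional to class
    frequencies.  Returns a fitted estimator exposing ``predict`` and
    ``predict_proba`` on vectorised images.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    X = images_to_vectors(images, edge=edge)
    if X.shape[0] != len(labels):
        raise ValueError("images and labels are misaligned")
    class_weight = "balanced" if task == CT2 else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(
            kernel="rbf",
            gamma=SVM_GAMMA,
            C=SVM_C,
            class_weight=class_weight,
            probability=True,
            random_state=seed,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        if cv_config:
            cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
            search = GridSearchCV(svc, param_grid=cv_config, cv=cv, n_jobs=1)
            search.fit(X, labels)
            model = search.best_estimator_
            model._cv_results = {k: v for k, v in search.best_params_.items()}
        else:
            model = svc.fit(X, labels)
    model._image_edge = edge
    return model


def train_logit(features: np.ndarray, labels, task: str = CT1):
    """Maximum-likelihood (multinomial) logistic regression baseline.

    ``features`` are the own/other/intracell transition proportions.  On
    (quasi-)perfect separation the unpenalised fit diverges; this is
    reported as a warning and an L2-regularised fit is returned instead.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=2000).fit(X, labels)
    # a fit that classifies its own training set perfectly implies linear
    # separability, under which the unpenalised MLE does not exist
    separated = bool(np.all(model.predict(X) == labels))
    if separated or not np.all(np.isfinite(model.coef_)) or np.abs(model.coef_).max() > 1e4:
        warnings.warn(
            "possible perfect separation in logistic fit; falling back to L2 regularisation",
            stacklevel=2,
        )
        model = LogisticRegression(C=1.0, max_iter=2000).fit(X, labels)
    return model


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    auc: float
    f1: float
    confusion: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def compute_metrics(y_true, y_pred, scores=None, task: str = CT1, classes=None) -> Metrics:
    """Accuracy, AUC, F1 and confusion matrix under the task's protocol.

    CT1: binary AUC from the positive-class score, plain F1.  CT2:
    one-vs-rest AUC averaged with class-frequency weights (wAUC) and
    class-frequency-weighted F1.  ``scores`` are class-probability columns
    aligned with ``classes`` (CT2) or the positive-class score (CT1); AUC
    is NaN when scores are absent or only one class appears.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label/prediction length mismatch")
    uniq = np.unique(y_true) if classes is None else np.asarray(classes)
    conf = skm.confusion_matrix(y_true, y_pred, labels=uniq)
    acc = float(np.trace(conf)) / len(y_true)
    auc = float("nan")
    if scores is not None and len(np.unique(y_true)) > 1:
        scores = np.asarray(scores)
        if task == CT1:
            pos = scores if scores.ndim == 1 else scores[:, -1]
            auc = float(skm.roc_auc_score(y_true, pos))
        else:
            auc = float(
                skm.roc_auc_score(y_true, scores, multi_class="ovr",
                                  average="weighted", labels=uniq)
            )
    if task == CT1:
        f1 = float(skm.f1_score(y_true, y_pred, pos_label=uniq[-1]))
    else:
        f1 = float(skm.f1_score(y_true, y_pred, average="weighted", labels=uniq))
    return Metrics(accuracy=acc, auc=auc, f1=f1, confusion=conf, n=len(y_true))


def evaluate(model, X, y_true, task: str = CT1, vectorize_images: bool = False) -> Metrics:
    """Evaluate a fitted classifier on held-out inputs.

    Set ``vectorize_images=True`` to pass raw (N, H, W, 3) rasters to an
    image model trained by :func:`train_svm_image`.
    """
    if vectorize_images:
        X = images_to_vectors(np.asarray(X), edge=getattr(model, "_image_edge", SVM_IMAGE_EDGE))
    y_pred = model.predict(X)
    scores = model.predict_proba(X) if hasattr(model, "predict_proba") else None
    if scores is not None and task == CT1:
        scores = scores[:, -1]
    return compute_metrics(y_true, y_pred, scores=scores, task=task, classes=model.classes_)


def confidence_scores(model, X, vectorize_images: bool = False) -> np.ndarray:
    """Per-sample confidence: the probability of the predicted class."""
    if not hasattr(model, "predict_proba"):
        raise TypeError("classifier does not expose class probabilities")
    if vectorize_images:
        X = images_to_vectors(np.asarray(X), edge=getattr(model, "_image_edge", SVM_IMAGE_EDGE))
    return model.predict_proba(X).max(axis=1)


def correlate_confidence(conf, feature_column) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between confidence and a feature."""
    conf = np.asarray(conf, dtype=float)
    feat = np.asarray(feature_column, dtype=float)
    if conf.shape != feat.shape or conf.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(conf) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(conf) == 0 or np.std(feat) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(conf, feat)
    return float(r), float(p)
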