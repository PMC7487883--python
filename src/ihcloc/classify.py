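"""RBF-SVM training, cross-validation under per-image / per-protein partitions,
and protein-level voting.

The classifier is a radial-basis-function SVM (one-vs-one with pairwise-
coupled probability estimates, the LIBSVM behavior) over min-max scaled
features; the kernel parameters (c, g) are chosen by an inner 5-fold grid
search.  Two outer cross-validation partitions are supported:

* **per_image** — stratified k-fold over images; images of one protein may
  appear in both train and test folds, so accuracy is optimistic when
  proteins have identifiable appearance.
* **per_protein** — grouped k-fold over proteins; no protein ever spans
  train and test, measuring generalization to unseen proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .core_io import DatasetManifest, LABEL_TO_INT
from .engineered_features import FeatureMatrix

logger = logging.getLogger(__name__)

#: standard coarse RBF grid: c = 2^-5..2^15, g = 2^-15..2^3, steps of 2^2
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_G_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))
#: reduced grid for desk-scale runs
SMALL_C_GRID = (2.0 ** -1, 2.0 ** 3, 2.0 ** 7)
SMALL_G_GRID = (2.0 ** -7, 2.0 ** -3, 2.0 ** 1)

CLASS_ORDER = (0, 1, 2)  # i, ii, iii


@dataclass
class TrainedModel:
    """A fitted RBF-SVM with its scaling statistics and column contract."""

    svc: SVC
    c: float
    g: float
    column_names: list[str]
    feat_min: np.ndarray
    feat_max: np.ndarray
    classes: np.ndarray

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = self.feat_max - self.feat_min
        span[span == 0] = 1.0
        return np.clip((X - self.feat_min) / span, -1.0, 2.0)


@dataclass
class EvalReport:
    """Aggregated held-out evaluation of one cross-validation run."""

    confusion: np.ndarray
    accuracy: float
    macro_recall: float
    macro_precision: float
    macro_f1: float
    partition_mode: str
    per_fold_accuracy: list[float] = field(default_factory=list)


def _inner_cv_accuracy(X, y, c, g, seed, k=5) -> float:
    k = min(k, int(np.bincount(y).min()))
    if k < 2:
        return float("nan")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        m = SVC(C=c, gamma=g, kernel="rbf")
        m.fit(X[tr], y[tr])
        correct += int((m.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def train_svm(X: np.ndarray, y, grid: tuple = (DEFAULT_C_GRID, DEFAULT_G_GRID),
              seed: int = 0, column_names: list[str] | None = None) -> TrainedModel:
    """Grid-searched RBF-SVM with probability outputs.

    Features are min-max scaled to [0, 1] with statistics from the training
    data; (c, g) maximize inner 5-fold CV accuracy with ties broken to the
    smaller c then smaller g; the final model refits on all data.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    c_grid, g_grid = grid
    if len(c_grid) == 0 or len(g_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    span = fmax - fmin
    span_safe = np.where(span == 0, 1.0, span)
    Xs = (X - fmin) / span_safe
    best = None
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            acc = _inner_cv_accuracy(Xs, y, c, g, seed)
            if np.isnan(acc):
                acc = -1.0
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, g)
    _, c, g = best
    import warnings

    with warnings.catch_warnings():
        # SVC(probability=True) is the pairwise-coupled LIBSVM behavior we
        # want; silence the deprecation notice newer sklearn emits for it
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(C=c, gamma=g, kernel="rbf", probability=True, random_state=seed)
        svc.fit(Xs, y)
    return TrainedModel(svc=svc, c=c, g=g,
                        column_names=list(column_names or []),
                        feat_min=fmin, feat_max=fmax, classes=svc.classes_)


def predict_scores(model: TrainedModel, X: np.ndarray,
                   column_names: list[str] | None = None) -> np.ndarray:
    """Rows x 3 probability-like score matrix over classes (i, ii, iii).

    Classes absent from training get zero columns so every model emits the
    same 3-wide contract; argmax of a row is the predicted class index.
    """
    if column_names is not None and model.column_names:
        if list(column_names) != model.column_names:
            missing = sorted(set(model.column_names) - set(column_names))
            raise ValueError(f"feature columns do not match training; missing: {missing}")
    X = np.asarray(X, dtype=np.float64)
    prob = model.svc.predict_proba(model.scale(X))
    out = np.zeros((X.shape[0], len(CLASS_ORDER)))
    for j, cls in enumerate(model.classes):
        out[:, int(cls)] = prob[:, j]
    return out


def compute_metrics(confusion: np.ndarray) -> tuple[float, float, float, float]:
    """(accuracy, macro recall, macro precision, macro F1) from a 3x3 confusion.

    Macro averages are unweighted over classes that actually occur (empty
    rows/columns are excluded with a warning); F1 is the harmonic mean of
    macro precision and macro recall.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm) / total)
    recalls, precisions = [], []
    for k in range(cm.shape[0]):
        if cm[k, :].sum() > 0:
            recalls.append(cm[k, k] / cm[k, :].sum())
        else:
            logger.warning("class %d absent from evaluation; excluded from macro recall", k)
        if cm[:, k].sum() > 0:
            precisions.append(cm[k, k] / cm[:, k].sum())
    macro_recall = float(np.mean(recalls))
    macro_precision = float(np.mean(precisions))
    if macro_precision + macro_recall > 0:
        f1 = 2 * macro_precision * macro_recall / (macro_precision + macro_recall)
    else:
        f1 = 0.0
    return accuracy, macro_recall, macro_precision, float(f1)


def crossval(manifest: DatasetManifest, features: FeatureMatrix,
             mode: str = "per_image", k: int = 10, seed: int = 0,
             grid: tuple = (SMALL_C_GRID, SMALL_G_GRID)) -> EvalReport:
    """k-fold cross-validation of the SVM under one partition mode.

    Feature rows must align with manifest records (row i <-> record i) and
    labels must be known.  Every image is held out exactly once; the
    confusion matrix aggregates all held-out predictions.
    """
    if mode not in ("per_image", "per_protein"):
        raise ValueError("mode must be per_image or per_protein")
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([LABEL_TO_INT.get(r.label, -1) for r in manifest.records])
    if (y < 0).any():
        raise ValueError("cross-validation requires known labels on every record")
    X = features.values
    if X.shape[0] != len(manifest):
        raise ValueError("feature rows do not align with manifest records")
    groups = np.array([r.protein_id for r in manifest.records])
    if mode == "per_protein":
        if len(np.unique(groups)) < k:
            raise ValueError(f"per_protein needs >= {k} proteins")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups)
    else:
        if len(y) < k:
            raise ValueError(f"per_image needs >= {k} images")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    cm = np.zeros((3, 3), dtype=np.int64)
    fold_acc = []
    seen = np.zeros(len(y), dtype=bool)
    for fold, (tr, te) in enumerate(split):
        model = train_svm(X[tr], y[tr], grid=grid, seed=seed + fold)
        scores = predict_scores(model, X[te])
        pred = scores.argmax(axis=1)
        for t, p in zip(y[te], pred):
            cm[t, p] += 1
        fold_acc.append(float((pred == y[te]).mean()))
        seen[te] = True
    assert seen.all(), "some images were never held out"
    acc, rec, prec, f1 = compute_metrics(cm)
    return EvalReport(confusion=cm, accuracy=acc, macro_recall=rec,
                      macro_precision=prec, macro_f1=f1, partition_mode=mode,
                      per_fold_accuracy=fold_acc)


def protein_vote(image_predictions: list[tuple[int, np.ndarray]]) -> int:
    """Protein-level location by majority vote over image predictions.

    ``image_predictions`` holds (label, score-vector) pairs; ties break to
    the class with the largest mean score across the images.
    """
    if not image_predictions:
        raise ValueError("need at least one image prediction")
    labels = np.array([int(lb) for lb, _ in image_predictions])
    counts = np.bincount(labels, minlength=3)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return int(tied[0])
    mean_scores = np.mean([s for _, s in image_predictions], axis=0)
    masked = np.full(3, -np.inf)
    masked[tied] = mean_scores[tied]
    return int(np.argmax(masked))
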