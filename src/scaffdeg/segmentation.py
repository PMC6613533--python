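"""Random-forest pixel segmentation of micrographs into four tissue
classes, a grayscale-thresholding baseline, and validation metrics.

A pixel classifier is trained on a balanced sample of labelled pixels
described by the texture feature stack, and applied to whole images to
produce per-class probability maps (the fraction of tree votes per class)
and argmax label masks.  Validation follows the usual multiclass
one-vs-rest accounting: a 4x4 confusion matrix (rows = real class,
columns = predicted) with per-class TP rate, FP rate, precision,
F-measure and Matthews correlation, plus support-weighted averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from ._utils import (
    CLASS_NAMES,
    N_CLASSES,
    ValidationError,
    check,
    rng_from_seed,
    to_grayscale_u8,
)
from .texture import FeatureStack

__all__ = [
    "TrainingSet",
    "sample_training_pixels",
    "RandomForestPixelSegmenter",
    "train_classifier",
    "predict_probability_maps",
    "classify",
    "threshold_segment",
    "ClassMetrics",
    "confusion_and_metrics",
    "crossvalidate",
    "misclassification_error",
]


@dataclass(frozen=True)
class TrainingSet:
    """Labelled pixel sample: features, labels and pixel provenance."""

    X: np.ndarray                      # (n_pixels, F)
    y: np.ndarray                      # (n_pixels,), labels 0..3
    feature_names: tuple[str, ...]
    coords: np.ndarray                 # (n_pixels, 2) row, col
    seed: int | None = None

    def __post_init__(self):
        check(self.X.ndim == 2 and self.y.ndim == 1, "X must be 2-D, y 1-D")
        check(self.X.shape[0] == self.y.shape[0], "X rows must align with y")
        check(self.X.shape[1] == len(self.feature_names),
              "feature_names must match X columns")


def sample_training_pixels(stack: FeatureStack, mask, n_per_class: int,
                           seed: int | None = None,
                           strict: bool = True) -> TrainingSet:
    """Draw a balanced, seeded, without-replacement pixel sample per class.

    Classes with fewer than ``n_per_class`` labelled pixels contribute all
    they have.  With ``strict=True`` (default), a class absent from the
    mask raises; otherwise absent classes are skipped.
    """
    mask = np.asarray(mask)
    check(mask.shape == stack.data.shape[:2],
          "mask and feature stack must share dimensions")
    check(n_per_class >= 1, "n_per_class must be >= 1")
    missing = [CLASS_NAMES[c] for c in range(N_CLASSES)
               if not np.any(mask == c)]
    if missing and strict:
        raise ValidationError(f"classes missing from mask: {missing}")
    rng = rng_from_seed(seed)
    flat = stack.to_matrix()
    rows_all, labels = [], []
    for c in range(N_CLASSES):
        idx = np.flatnonzero(mask.ravel() == c)
        if idx.size == 0:
            continue
        take = min(n_per_class, idx.size)
        if take < n_per_class:
            import logging
            logging.getLogger(__name__).warning(
                "class %s has only %d labelled pixels (< %d requested)",
                CLASS_NAMES[c], idx.size, n_per_class)
        chosen = rng.choice(idx, size=take, replace=False)
        rows_all.append(chosen)
        labels.append(np.full(take, c, dtype=np.uint8))
    rows = np.concatenate(rows_all)
    coords = np.column_stack(np.unravel_index(rows, mask.shape))
    return TrainingSet(X=flat[rows], y=np.concatenate(labels),
                       feature_names=stack.feature_names,
                       coords=coords, seed=seed)


class RandomForestPixelSegmenter(ClassifierMixin, BaseEstimator):
    """Random-forest pixel classifier over texture feature stacks.

    Defaults (200 trees, sqrt(F) features per split, unbounded depth) are
    standard for a 24-feature stack; all are configurable.  The model
    records the feature-name order it was trained on and refuses stacks
    whose order differs.
    """

    def __init__(self, n_trees: int = 200, max_features="sqrt",
                 max_depth: int | None = None,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y=None, feature_names=None):
        """Fit on an (n_pixels, F) matrix, or pass a TrainingSet as X."""
        if isinstance(X, TrainingSet):
            feature_names = X.feature_names
            X, y = X.X, X.y
        X = np.asarray(X)
        y = np.asarray(y)
        check(self.n_trees >= 1, "n_trees must be >= 1")
        if np.unique(y).size < 2:
            raise ValidationError("training set contains a single class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features=self.max_features,
            max_depth=self.max_depth, random_state=self.random_state)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_names_ = tuple(feature_names) if feature_names else None
        self.n_features_in_ = X.shape[1]
        return self

    def _check_stack(self, stack: FeatureStack):
        if self.feature_names_ is not None and \
                tuple(stack.feature_names) != self.feature_names_:
            raise ValidationError(
                "feature stack does not match the model's training features: "
                f"{stack.feature_names} vs {self.feature_names_}")

    def predict(self, X):
        return self.forest_.predict(np.asarray(X))

    def predict_proba(self, X):
        return self.forest_.predict_proba(np.asarray(X))

    def predict_probability_maps(self, stack: FeatureStack) -> np.ndarray:
        """Per-pixel class membership probabilities, shape (H, W, 4).

        Probabilities are the averaged tree votes and sum to 1 per pixel.
        Classes absent from training get an all-zero plane.
        """
        self._check_stack(stack)
        h, w, _ = stack.data.shape
        proba = self.forest_.predict_proba(stack.to_matrix())
        maps = np.zeros((h * w, N_CLASSES), dtype=np.float64)
        maps[:, self.classes_.astype(int)] = proba
        return maps.reshape(h, w, N_CLASSES)

    def segment(self, stack: FeatureStack) -> np.ndarray:
        """Probability maps followed by argmax classification."""
        return classify(self.predict_probability_maps(stack))

    # -- persistence ---------------------------------------------------
    def save(self, path):
        """Persist to ``path`` (joblib binary) + a JSON sidecar manifest."""
        import joblib

        joblib.dump(self, path)
        manifest = {
            "format_version": 1,
            "estimator": type(self).__name__,
            "params": {k: v for k, v in self.get_params().items()},
            "feature_names": list(self.feature_names_ or []),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @staticmethod
    def load(path) -> "RandomForestPixelSegmenter":
        import joblib

        return joblib.load(path)


def train_classifier(train: TrainingSet, n_trees: int = 200,
                     max_features="sqrt", max_depth=None,
                     seed: int | None = None) -> RandomForestPixelSegmenter:
    """Convenience wrapper: fit a seeded forest on a training set."""
    return RandomForestPixelSegmenter(
        n_trees=n_trees, max_features=max_features, max_depth=max_depth,
        random_state=seed).fit(train)


def predict_probability_maps(model: RandomForestPixelSegmenter,
                             stack: FeatureStack) -> np.ndarray:
    return model.predict_probability_maps(stack)


def classify(maps) -> np.ndarray:
    """Argmax label mask from probability maps; exact ties break toward
    the lowest label index."""
    maps = np.asarray(maps)
    check(maps.ndim == 3 and maps.shape[2] == N_CLASSES,
          "maps must be (H, W, 4)")
    return np.argmax(maps, axis=2).astype(np.uint8)


def threshold_segment(image, thresholds, band_labels=None) -> np.ndarray:
    """Grayscale-thresholding baseline segmentation.

    The image is converted to 8-bit luma and banded by 1–3 strictly
    increasing cut points in [0, 255]; ``band_labels`` maps each band
    (dark to bright) to a class label (identity by default).  Pixels with
    luma strictly above the i-th cut fall in band i+1.
    """
    cuts = np.asarray(thresholds, dtype=float).reshape(-1)
    check(1 <= cuts.size <= 3, "need 1-3 thresholds")
    check(np.all(np.diff(cuts) > 0), "thresholds must be strictly increasing")
    check(np.all((cuts >= 0) & (cuts <= 255)), "thresholds must lie in [0, 255]")
    gray = to_grayscale_u8(image)
    bands = np.searchsorted(cuts, gray, side="left").astype(np.uint8)
    if band_labels is not None:
        band_labels = np.asarray(band_labels, dtype=np.uint8)
        check(band_labels.size == cuts.size + 1,
              "band_labels must have one entry per band")
        bands = band_labels[bands]
    return bands


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest validation metrics plus weighted averages.

    ``per_class`` rows are indexed by class name with columns tp_rate,
    fp_rate, precision, recall, f_measure, mcc and support; ``weighted``
    averages each column by real-class support.  Metric cells with a 0/0
    denominator are reported as 0 and flagged in ``undefined``.
    """

    confusion: np.ndarray
    per_class: pd.DataFrame
    weighted: pd.Series
    accuracy: float
    undefined: pd.DataFrame


def _safe_div(num, den):
    return (num / den if den > 0 else 0.0), den == 0


def confusion_and_metrics(truth, pred) -> tuple[np.ndarray, ClassMetrics]:
    """Confusion matrix (real x predicted) and the full metric suite.

    Accepts label masks of any shape, or a precomputed 4x4 count matrix
    passed as ``truth`` with ``pred=None``.
    """
    if pred is None:
        counts = np.asarray(truth, dtype=np.int64)
        check(counts.shape == (N_CLASSES, N_CLASSES),
              "precomputed confusion matrix must be 4x4")
        check(np.all(counts >= 0), "counts must be nonnegative")
    else:
        t = np.asarray(truth).ravel()
        p = np.asarray(pred).ravel()
        check(t.shape == p.shape, "truth and prediction shapes differ")
        check(np.all((t >= 0) & (t < N_CLASSES)), "labels must be in 0..3")
        check(np.all((p >= 0) & (p < N_CLASSES)), "labels must be in 0..3")
        counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        np.add.at(counts, (t.astype(int), p.astype(int)), 1)

    total = int(counts.sum())
    check(total > 0, "empty confusion matrix")
    rows, flags = [], []
    for c in range(N_CLASSES):
        tp = int(counts[c, c])
        fn = int(counts[c].sum() - tp)
        fp = int(counts[:, c].sum() - tp)
        tn = total - tp - fn - fp
        tp_rate, u1 = _safe_div(tp, tp + fn)
        fp_rate, u2 = _safe_div(fp, fp + tn)
        precision, u3 = _safe_div(tp, tp + fp)
        f_measure, u4 = _safe_div(2 * precision * tp_rate, precision + tp_rate)
        mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
        rows.append({"tp_rate": tp_rate, "fp_rate": fp_rate,
                     "precision": precision, "recall": tp_rate,
                     "f_measure": f_measure, "mcc": mcc,
                     "support": tp + fn})
        flags.append({"tp_rate": u1, "fp_rate": u2, "precision": u3,
                      "f_measure": u4, "mcc": mcc_den == 0})
    per_class = pd.DataFrame(rows, index=list(CLASS_NAMES))
    undefined = pd.DataFrame(flags, index=list(CLASS_NAMES))
    support = per_class["support"].to_numpy(dtype=float)
    weights = support / support.sum()
    metric_cols = ["tp_rate", "fp_rate", "precision", "recall",
                   "f_measure", "mcc"]
    weighted = pd.Series(
        {m: float(per_class[m].to_numpy() @ weights) for m in metric_cols})
    accuracy = float(np.trace(counts)) / total
    metrics = ClassMetrics(confusion=counts, per_class=per_class,
                           weighted=weighted, accuracy=accuracy,
                           undefined=undefined)
    return counts, metrics


def crossvalidate(train: TrainingSet, k: int = 10, seed: int | None = None,
                  **forest_params) -> ClassMetrics:
    """Stratified k-fold cross-validation with a pooled out-of-fold
    confusion matrix (a single Table-style matrix, not fold averages).

    Falls back to plain k-fold with a warning when some class has fewer
    than ``k`` members.
    """
    n = train.y.size
    check(n >= k >= 2, "need 2 <= k <= n")
    _, class_counts = np.unique(train.y, return_counts=True)
    if class_counts.min() < k:
        import logging
        logging.getLogger(__name__).warning(
            "smallest class has %d < k=%d members; using unstratified folds",
            class_counts.min(), k)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for tr_idx, te_idx in splitter.split(train.X, train.y):
        model = RandomForestPixelSegmenter(
            random_state=seed, **forest_params).fit(
            train.X[tr_idx], train.y[tr_idx],
            feature_names=train.feature_names)
        pred = model.predict(train.X[te_idx])
        np.add.at(pooled, (train.y[te_idx].astype(int), pred.astype(int)), 1)
    _, metrics = confusion_and_metrics(pooled, None)
    return metrics


def misclassification_error(truth, pred, roi_class: int) -> float:
    """Square root of the number of pixels whose one-vs-rest membership
    in ``roi_class`` disagrees between the two masks."""
    t = np.asarray(truth) == roi_class
    p = np.asarray(pred) == roi_class
    check(t.shape == p.shape, "masks must share shape")
    return float(np.sqrt(np.count_nonzero(t != p)))
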