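"""The Statistical-Risk arm: encoding, SMOTE-NC augmentation, bagged trees.

The classifier consumes every descriptor of the cohort schema *except* the
expert-assigned BI-RADS category (kept out deliberately, so the statistical
prediction is independent of the index later used for the correction stage).
Age, the single numeric feature, is Min-Max normalized with bounds taken
from the training data:  t' = (t - min) / (max - min).

Class imbalance is addressed with SMOTE-NC, the mixed numeric/categorical
variant of synthetic minority over-sampling: both classes are grown to a
common target (200 cases each by default) by interpolating numeric features
between a seed point and one of its k = 5 nearest same-class neighbours and
setting categorical features by majority vote among those neighbours.  In
the neighbour metric a categorical mismatch contributes the median of the
standard deviations of the class's numeric features, as in the original
SMOTE-NC formulation.

The classifier is a bootstrap-aggregated (bagged) decision-tree ensemble;
performance is estimated with stratified k-fold cross-validation (k = 5)
and a rank-based ROC AUC.  Augmentation is applied inside each training
fold only — held-out rows are always original patients — so the
cross-validated AUC is free of resampling leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .datamodel import COLUMNS, VOCABULARIES, Cohort, PatientRecord

__all__ = [
    "NormalizationParams",
    "FeatureTable",
    "ClassifierModel",
    "FeatureSchemaError",
    "FEATURE_COLUMNS",
    "normalize_age",
    "encode_features",
    "encode_record",
    "augment_smote_nc",
    "train_classifier",
    "predict_statistical_risk",
]


class FeatureSchemaError(ValueError):
    """A record or table does not match the expected feature schema."""


@dataclass(frozen=True)
class NormalizationParams:
    """Min-Max age bounds learned from training data."""

    min_t: float
    max_t: float

    def __post_init__(self) -> None:
        if not self.max_t > self.min_t:
            raise FeatureSchemaError(
                f"degenerate age range: max_t ({self.max_t}) must exceed min_t ({self.min_t})"
            )


def normalize_age(age: float, params: NormalizationParams, clip: bool = True) -> float:
    """t' = (t - min)/(max - min); scoring-time ages outside the training
    range are clipped to [0, 1] with a warning."""
    t = (age - params.min_t) / (params.max_t - params.min_t)
    if clip and not 0.0 <= t <= 1.0:
        warnings.warn(
            f"age {age} outside training range [{params.min_t}, {params.max_t}]; clipped",
            stacklevel=2,
        )
        t = min(max(t, 0.0), 1.0)
    return t


#: deterministic feature-column order: normalized age then every categorical
#: descriptor of the record schema except patient_id, birads and label.
_CATEGORICAL_FEATURES = tuple(
    c for c in COLUMNS if c not in ("patient_id", "age", "birads", "label")
)
FEATURE_COLUMNS = ("age_norm",) + _CATEGORICAL_FEATURES

#: category -> integer code maps (flags are booleans coded 0/1)
_FLAG_VOCAB = ("false", "true")
ENCODING_MAP: dict[str, tuple[str, ...]] = {
    c: (_FLAG_VOCAB if c.endswith("_present") else VOCABULARIES[c])
    for c in _CATEGORICAL_FEATURES
}


@dataclass
class FeatureTable:
    """Encoded design matrix (one row per patient) plus label vector.

    ``X`` holds ``age_norm`` (float) and integer-coded categorical columns;
    ``categorical_cols`` marks the columns SMOTE-NC must treat as nominal.
    """

    X: pd.DataFrame
    y: pd.Series
    params: NormalizationParams
    categorical_cols: tuple[str, ...] = _CATEGORICAL_FEATURES

    def __post_init__(self) -> None:
        if "birads" in self.X.columns:
            raise FeatureSchemaError("BI-RADS must never enter the feature table")
        if tuple(self.X.columns) != FEATURE_COLUMNS:
            raise FeatureSchemaError(
                f"unexpected feature columns: {tuple(self.X.columns)}"
            )
        if len(self.X) != len(self.y):
            raise FeatureSchemaError("X and y length mismatch")

    def class_counts(self) -> dict[str, int]:
        return self.y.value_counts().to_dict()


def _encode_value(column: str, record: PatientRecord) -> int:
    if column.endswith("_present"):
        return int(getattr(record, column))
    vocab = ENCODING_MAP[column]
    return vocab.index(getattr(record, column))


def encode_record(record: PatientRecord, params: NormalizationParams) -> np.ndarray:
    """Encode one record into the model's feature vector (no label needed)."""
    row = [normalize_age(record.age, params)]
    row += [_encode_value(c, record) for c in _CATEGORICAL_FEATURES]
    return np.asarray(row, dtype=float)


def encode_features(cohort: Cohort, params: Optional[NormalizationParams] = None) -> FeatureTable:
    """Encode a fully labeled cohort; age bounds default to the cohort's
    observed min/max (training behaviour)."""
    unlabeled = [r.patient_id for r in cohort if r.label is None]
    if unlabeled:
        raise FeatureSchemaError(f"unlabeled record(s): {unlabeled}")
    if params is None:
        ages = [r.age for r in cohort]
        params = NormalizationParams(min(ages), max(ages))
    rows = [encode_record(r, params) for r in cohort]
    X = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    y = pd.Series([r.label for r in cohort], name="label")
    return FeatureTable(X=X, y=y, params=params)


def decode_features(table: FeatureTable) -> pd.DataFrame:
    """Inverse of the categorical encoding (age stays normalized); used to
    check injectivity and to inspect synthetic rows."""
    out = pd.DataFrame({"age_norm": table.X["age_norm"]})
    for c in _CATEGORICAL_FEATURES:
        vocab = ENCODING_MAP[c]
        out[c] = [vocab[int(v)] for v in table.X[c]]
    return out


def _smote_nc_class(
    X: np.ndarray,
    num_idx: Sequence[int],
    cat_idx: Sequence[int],
    n_new: int,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``n_new`` synthetic rows within one class (SMOTE-NC rule)."""
    n = len(X)
    stds = np.std(X[:, num_idx], axis=0, ddof=1) if len(num_idx) else np.array([0.0])
    penalty = float(np.median(stds)) ** 2  # per-mismatch squared contribution
    # pairwise distances: numeric Euclidean + categorical mismatch penalty
    d2 = np.zeros((n, n))
    for j in num_idx:
        d2 += (X[:, j][:, None] - X[:, j][None, :]) ** 2
    for j in cat_idx:
        d2 += penalty * (X[:, j][:, None] != X[:, j][None, :])
    np.fill_diagonal(d2, np.inf)
    neighbours = np.argsort(d2, axis=1, kind="stable")[:, :k]

    seeds = rng.integers(0, n, size=n_new)
    picks = rng.integers(0, k, size=n_new)
    gaps = rng.random(size=n_new)
    out = np.empty((n_new, X.shape[1]))
    for row, (i, p, u) in enumerate(zip(seeds, picks, gaps)):
        nn = neighbours[i, p]
        new = X[i].copy()
        for j in num_idx:
            new[j] = X[i, j] + u * (X[nn, j] - X[i, j])
        for j in cat_idx:
            values = X[neighbours[i], j].astype(int)
            counts = np.bincount(values)
            new[j] = np.argmax(counts)  # majority vote, ties -> lowest code
        out[row] = new
    return out


def augment_smote_nc(
    table: FeatureTable,
    target_per_class: int = 200,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> FeatureTable:
    """Grow each class to exactly ``target_per_class`` rows with SMOTE-NC.

    Original rows are preserved unchanged (and first, in order).  A class
    already at or above the target is left untouched (with a warning if it
    exceeds it); a class smaller than ``k_neighbors + 1`` is an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    num_idx = [table.X.columns.get_loc("age_norm")]
    cat_idx = [table.X.columns.get_loc(c) for c in table.categorical_cols]

    frames = [table.X]
    labels = [table.y]
    for cls in sorted(table.y.unique()):
        mask = (table.y == cls).to_numpy()
        n_cls = int(mask.sum())
        if n_cls > target_per_class:
            warnings.warn(
                f"class {cls!r} has {n_cls} > target {target_per_class}: left as-is",
                stacklevel=2,
            )
            continue
        if n_cls == target_per_class:
            continue
        if n_cls < k_neighbors + 1:
            raise FeatureSchemaError(
                f"class {cls!r} has {n_cls} rows; needs > {k_neighbors} for SMOTE-NC"
            )
        new = _smote_nc_class(
            table.X.to_numpy(dtype=float)[mask],
            num_idx,
            cat_idx,
            target_per_class - n_cls,
            k_neighbors,
            rng,
        )
        frames.append(pd.DataFrame(new, columns=table.X.columns))
        labels.append(pd.Series([cls] * len(new), name="label"))

    X = pd.concat(frames, ignore_index=True)
    y = pd.concat(labels, ignore_index=True)
    return FeatureTable(X=X, y=y, params=table.params)


@dataclass
class ClassifierModel:
    """Trained bagged-trees ensemble plus everything needed to score a record."""

    estimator: BaggingClassifier
    params: NormalizationParams
    encoding: dict[str, tuple[str, ...]]
    cv_auc: float
    roc_points: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, ClassifierModel):
            raise FeatureSchemaError(f"{path} is not a ClassifierModel archive")
        return model


def _make_bagger(trees: int, seed: int) -> BaggingClassifier:
    return BaggingClassifier(
        estimator=DecisionTreeClassifier(criterion="gini", random_state=seed),
        n_estimators=trees,
        random_state=seed,
    )


def train_classifier(
    table: FeatureTable,
    folds: int = 5,
    trees: int = 100,
    seed: int = 0,
    augment: bool = True,
    target_per_class: int = 200,
    k_neighbors: int = 5,
) -> ClassifierModel:
    """Train the bagged-trees ensemble with stratified k-fold CV ROC/AUC.

    Cross-validation operates on the rows given (normally the *original*
    cohort); when ``augment`` is set, SMOTE-NC runs inside each training
    fold, and once more on the full table for the final fit.  The returned
    model carries the fold-out AUC, the pooled ROC curve, the normalization
    bounds and the feature-encoding map.
    """
    from .evaluation import auc as rank_auc  # local import: avoids module cycle

    classes = sorted(table.y.unique())
    if len(classes) < 2:
        raise FeatureSchemaError(f"need both classes to train, got {classes}")

    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    rng = np.random.default_rng(seed)
    for train_idx, test_idx in skf.split(X, y):
        fold = FeatureTable(
            X=table.X.iloc[train_idx].reset_index(drop=True),
            y=table.y.iloc[train_idx].reset_index(drop=True),
            params=table.params,
        )
        if augment:
            fold = augment_smote_nc(fold, target_per_class, k_neighbors, rng)
        clf = _make_bagger(trees, seed)
        clf.fit(fold.X.to_numpy(dtype=float), fold.y.to_numpy())
        cancer_col = list(clf.classes_).index("cancer")
        scores[test_idx] = clf.predict_proba(X[test_idx])[:, cancer_col]

    truth = (y == "cancer").astype(int)
    cv_auc = rank_auc(scores, truth)
    fpr, tpr, thresholds = roc_curve(truth, scores)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})

    final_table = table
    if augment:
        final_table = augment_smote_nc(table, target_per_class, k_neighbors, rng)
    estimator = _make_bagger(trees, seed)
    estimator.fit(final_table.X.to_numpy(dtype=float), final_table.y.to_numpy())

    return ClassifierModel(
        estimator=estimator,
        params=table.params,
        encoding=dict(ENCODING_MAP),
        cv_auc=float(cv_auc),
        roc_points=roc_points,
        metadata={
            "seed": seed,
            "folds": folds,
            "trees": trees,
            "augment": augment,
            "target_per_class": target_per_class,
            "k_neighbors": k_neighbors,
            "n_train": len(y),
            "class_counts": table.class_counts(),
        },
    )


def predict_statistical_risk(model: ClassifierModel, record: PatientRecord) -> float:
    """Rs = ensemble cancer-class probability x 100, in [0, 100]."""
    if model.encoding != ENCODING_MAP:
        raise FeatureSchemaError("model encoding map does not match the current schema")
    x = encode_record(record, model.params).reshape(1, -1)
    cancer_col = list(model.estimator.classes_).index("cancer")
    return float(model.estimator.predict_proba(x)[0, cancer_col] * 100.0)
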