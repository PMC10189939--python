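"""Classifier heads for expressibility prediction.

Two heads are used throughout: a random forest (300 trees, otherwise
library defaults) on pooled embeddings or flattened per-residue tensors,
and an L2-regularized logistic regression on random-convolution features
(standardized, since ppv and max features live on different scales).
Knottin and non-knottin partitions get fully independent model instances;
there is no parameter sharing between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix, Provenance

DEFAULT_N_TREES = 300


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier head.

    ``regularization_c`` is the inverse regularization strength of the
    logistic head (library convention; larger = weaker penalty), default
    1.0.  ``cv_grid`` enables an internal cross-validated search over
    10^-3..10^3 instead of the fixed value.  ``standardize`` controls
    per-column centring/scaling for the logistic head (training-set
    statistics are stored in the fitted model; zero-variance columns are
    scaled by 1).  Forests consume raw features: split points are
    invariant to monotone rescaling.
    """

    head: Literal["random_forest", "l2_logreg"]
    n_trees: int = DEFAULT_N_TREES
    regularization_c: float = 1.0
    cv_grid: bool = False
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head not in ("random_forest", "l2_logreg"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.regularization_c <= 0:
            raise ValueError("regularization_c must be positive")


@dataclass
class FittedModel:
    """A fitted head plus the provenance of its training columns."""

    spec: ClassifierSpec
    estimator: object
    scaler: StandardScaler | None
    provenance: Provenance | None

    def predict_scores(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict_scores(self, X)


def _as_values(X: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, Provenance | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.provenance
    return np.asarray(X, dtype=np.float64), None


def fit(spec: ClassifierSpec, X: FeatureMatrix | np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit a classifier head.  Deterministic under ``spec.seed``.

    Raises on NaN features or single-class labels.
    """
    values, provenance = _as_values(X)
    y = np.asarray(y).astype(int)
    if values.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if np.isnan(values).any():
        raise ValueError("feature matrix contains NaN")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training labels contain a single class ({classes.tolist()})")

    scaler: StandardScaler | None = None
    if spec.head == "random_forest":
        estimator = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed
        )
        estimator.fit(values, y)
    else:
        if spec.standardize:
            scaler = StandardScaler()
            values = scaler.fit_transform(values)
        if spec.cv_grid:
            estimator = GridSearchCV(
                LogisticRegression(max_iter=2000, random_state=spec.seed),
                {"C": np.logspace(-3, 3, 7)},
                scoring="roc_auc",
                cv=5,
            )
        else:
            estimator = LogisticRegression(
                C=spec.regularization_c,
                max_iter=2000,
                random_state=spec.seed,
            )
        estimator.fit(values, y)
    return FittedModel(spec=spec, estimator=estimator, scaler=scaler, provenance=provenance)


def predict_scores(model: FittedModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Probability of the positive ("expressed") class per sample.

    Forest score is the across-tree average of leaf class probabilities;
    logistic score is the sigmoid of the linear predictor after the stored
    standardization.  Scoring a matrix whose column provenance differs
    from training is an error.
    """
    values, provenance = _as_values(X)
    if (
        model.provenance is not None
        and provenance is not None
        and provenance != model.provenance
    ):
        raise ValueError("feature provenance does not match the training features")
    if model.scaler is not None:
        values = model.scaler.transform(values)
    proba = model.estimator.predict_proba(values)
    pos_col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    return proba[:, pos_col]


def save_model(model: FittedModel, path: str | Path) -> None:
    """Serialize a fitted model to a single file."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> FittedModel:
    """Load a fitted model; predictions are bit-identical to pre-save."""
    return joblib.load(path)


@dataclass(frozen=True)
class PartitionedModel:
    """Independent knottin / non-knottin heads behind one scoring surface."""

    knottin: FittedModel
    non_knottin: FittedModel

    def score(self, X: FeatureMatrix | np.ndarray, is_knottin: np.ndarray) -> np.ndarray:
        values, _ = _as_values(X)
        is_knottin = np.asarray(is_knottin, dtype=bool)
        out = np.empty(values.shape[0], dtype=np.float64)
        if is_knottin.any():
            out[is_knottin] = predict_scores(self.knottin, values[is_knottin])
        if (~is_knottin).any():
            out[~is_knottin] = predict_scores(self.non_knottin, values[~is_knottin])
        return out
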