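"""Cluster prediction for external cohorts.

A two-layer validation harness compares six classifiers on the five-score
matrix — CART (decision tree), logistic regression, linear discriminant
analysis, k-nearest neighbours, Gaussian naive Bayes, and an RBF-kernel SVM:
stratified 80/20 split, stratified five-fold cross-validation on the training
split (the inner layer), then a single holdout evaluation on the 20%
validation split (the outer layer). The SVM is then fitted on all labeled
samples and shipped with the training standardization and a fingerprint of
the signature scheme, so external score matrices are checked for scheme
compatibility and rescaled with the *training* parameters, never refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def _algorithms(seed: int) -> dict:
    return {
        "CART": DecisionTreeClassifier(random_state=seed),
        "LR": LogisticRegression(max_iter=2000),
        "LDA": LinearDiscriminantAnalysis(),
        "KNN": KNeighborsClassifier(),
        "NB": GaussianNB(),
        "SVM": SVC(kernel="rbf", C=1.0, class_weight="balanced", random_state=seed),
    }


@dataclass
class ValidationReport:
    """Cross-validated and holdout accuracies of the six algorithms."""

    cv_accuracy: dict[str, float]
    holdout_accuracy: dict[str, float]
    split_seed: int
    chosen: str
    n_train: int
    n_holdout: int

    def to_dict(self) -> dict:
        return {
            "cv_accuracy": self.cv_accuracy,
            "holdout_accuracy": self.holdout_accuracy,
            "split_seed": self.split_seed,
            "chosen": self.chosen,
            "n_train": self.n_train,
            "n_holdout": self.n_holdout,
        }


@dataclass
class ClusterModel:
    """A fitted multiclass SVM plus everything needed to apply it elsewhere."""

    scheme_fingerprint: Optional[str]
    scaler: StandardScaler
    predictor: SVC
    classes: tuple
    config: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ClusterModel":
        model = joblib.load(path)
        if not isinstance(model, ClusterModel):
            raise ValueError(f"{path} does not contain a ClusterModel")
        return model


def two_layer_validate(
    scores: ScoreMatrix, labels: pd.Series | np.ndarray, seed: int = 0
) -> ValidationReport:
    """Stratified 80/20 split; five-fold CV of six algorithms on the training
    split; holdout accuracy on the validation split. ``chosen`` is the
    holdout argmax (ties broken by CV accuracy)."""
    X = scores.values()
    y = np.asarray(labels)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y
    )
    if len(np.unique(y_tr)) != len(np.unique(y)):
        raise ValueError("a class is absent from the training split")

    scaler = StandardScaler().fit(X_tr)
    Xs_tr, Xs_ho = scaler.transform(X_tr), scaler.transform(X_ho)

    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    cv_acc: dict[str, float] = {}
    ho_acc: dict[str, float] = {}
    for name, est in _algorithms(seed).items():
        cv_acc[name] = float(np.mean(cross_val_score(est, Xs_tr, y_tr, cv=cv, scoring="accuracy")))
        est.fit(Xs_tr, y_tr)
        ho_acc[name] = float(np.mean(est.predict(Xs_ho) == y_ho))
    chosen = max(ho_acc, key=lambda n: (ho_acc[n], cv_acc[n]))
    logger.info("two-layer validation: holdout accuracies %s; chose %s", ho_acc, chosen)
    return ValidationReport(
        cv_accuracy=cv_acc,
        holdout_accuracy=ho_acc,
        split_seed=seed,
        chosen=chosen,
        n_train=len(y_tr),
        n_holdout=len(y_ho),
    )


def train_predictor(
    scores: ScoreMatrix,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
    C: float = 1.0,
) -> ClusterModel:
    """Fit the shipping SVM on all labeled samples with recorded scaling."""
    y = np.asarray(labels)
    classes = tuple(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    X = scores.values()
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel="rbf", C=C, class_weight="balanced", random_state=seed)
    svm.fit(scaler.transform(X), y)
    return ClusterModel(
        scheme_fingerprint=scores.scheme_fingerprint,
        scaler=scaler,
        predictor=svm,
        classes=classes,
        config={"kernel": "rbf", "C": C, "class_weight": "balanced", "seed": seed},
    )


def predict_clusters(
    model: ClusterModel, external_scores: ScoreMatrix
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign a cluster to every external sample.

    The external matrix must carry the same scheme fingerprint the model was
    trained under; the training standardization is re-applied (never refit).
    Returns the assignments and the per-class decision values.
    """
    if model.scheme_fingerprint is not None and (
        external_scores.scheme_fingerprint != model.scheme_fingerprint
    ):
        raise ValueError(
            "scheme fingerprint mismatch: the external score matrix was not "
            "computed under the model's signature scheme; refusing to rescale"
        )
    Xs = model.scaler.transform(external_scores.values())
    pred = pd.Series(
        model.predictor.predict(Xs), index=external_scores.samples, name="cluster"
    )
    dec = model.predictor.decision_function(Xs)
    if dec.ndim == 1:  # binary model
        dec = np.column_stack([-dec, dec])
    cols = [f"df_{i}" for i in range(dec.shape[1])]
    decisions = pd.DataFrame(dec, index=external_scores.samples, columns=cols)
    counts = pred.value_counts().to_dict()
    logger.info("predicted cluster distribution: %s", counts)
    return pred, decisions
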