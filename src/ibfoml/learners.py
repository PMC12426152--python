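"""The four base learners behind a uniform fit/predict-proba contract.

Logistic regression (LR), RBF-kernel support vector machine (SVM), a
single-hidden-layer backpropagation neural network (BPNN) and gradient
boosted trees (XGBoost), all wrapped so the optimization loop can treat them
interchangeably.  LR and SVM assume standardized inputs (the cohort pipeline
z-scores continuous columns); the BPNN uses a rectified-linear hidden layer
trained with Adam for at most 500 epochs and no early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import MetricReport, compute_metrics

__all__ = ["LEARNER_IDS", "LearnerSpec", "FittedModel", "fit", "cross_validate"]

LEARNER_IDS = ("LR", "SVM", "BPNN", "XGBoost")

#: trees per boosted ensemble; not part of the tuned search space
XGB_N_ESTIMATORS = 100


@dataclass
class LearnerSpec:
    """A learner identity plus a concrete (decoded) hyperparameter assignment."""

    learner_id: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner_id not in LEARNER_IDS:
            raise ValueError(f"unknown learner_id {self.learner_id!r}; expected one of {LEARNER_IDS}")


@dataclass
class FittedModel:
    spec: LearnerSpec
    estimator: object
    n_features: int

    def predict_proba(self, features) -> np.ndarray:
        """Probability of the positive (poor-recovery) class."""
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature count mismatch: model trained on {self.n_features} columns, got {X.shape[1]}"
            )
        return self.estimator.predict_proba(X)[:, 1]


def _build_estimator(spec: LearnerSpec):
    hp = dict(spec.hyperparameters)
    lid = spec.learner_id
    if lid == "LR":
        penalty = str(hp.get("penalty", "L2")).upper()
        return LogisticRegression(
            C=float(hp.get("C", 1.0)),
            l1_ratio=1.0 if penalty == "L1" else 0.0,
            solver="liblinear",
            max_iter=2000,
            intercept_scaling=100.0,  # liblinear penalizes the intercept otherwise
            random_state=spec.seed,
        )
    if lid == "SVM":
        return SVC(
            C=float(hp.get("C", 1.0)),
            gamma=float(hp.get("gamma", "scale") if "gamma" in hp else 1.0),
            kernel="rbf",
            probability=True,
            random_state=spec.seed,
        )
    if lid == "BPNN":
        return MLPClassifier(
            hidden_layer_sizes=(int(hp.get("hidden", 32)),),
            learning_rate_init=float(hp.get("learning_rate", 0.01)),
            activation="relu",
            solver="adam",
            max_iter=int(hp.get("epochs", 500)),
            early_stopping=False,
            random_state=spec.seed,
        )
    if lid == "XGBoost":
        return XGBClassifier(
            max_depth=int(hp.get("max_depth", 6)),
            learning_rate=float(hp.get("learning_rate", 0.3)),
            colsample_bytree=float(hp.get("colsample_bytree", 1.0)),
            n_estimators=int(hp.get("n_estimators", XGB_N_ESTIMATORS)),
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=spec.seed,
            verbosity=0,
        )
    raise ValueError(lid)


def fit(spec: LearnerSpec, features, labels) -> FittedModel:
    """Fit one base learner; deterministic given ``spec.seed``."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be an (n_samples, n_features) matrix matching labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    est = _build_estimator(spec)
    import warnings

    with warnings.catch_warnings():
        # BPNN routinely exhausts its fixed epoch cap on hard folds
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
        warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
        est.fit(X, y)
    return FittedModel(spec, est, X.shape[1])


def cross_validate(
    spec: LearnerSpec, features, labels, folds: int = 10, seed: int = 0, threshold: float = 0.5
) -> tuple[list[MetricReport], float]:
    """Seeded stratified k-fold CV.

    Returns per-fold metric reports and the pooled F1 computed on the
    concatenated out-of-fold predictions (one prediction per sample).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n_minority = int(np.bincount(y, minlength=2).min())
    if folds > y.size:
        raise ValueError("more folds than samples")
    if n_minority < 1:
        raise ValueError("both classes required")
    if folds == y.size:
        # leave-one-out: stratification is vacuous with singleton test folds
        from sklearn.model_selection import KFold

        skf = KFold(n_splits=folds)
    elif folds > n_minority:
        raise ValueError("folds exceed the minority-class count; folds=n gives leave-one-out")
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(y.size)
    reports = []
    for train_idx, test_idx in skf.split(X, y):
        model = fit(spec, X[train_idx], y[train_idx])
        p = model.predict_proba(X[test_idx])
        oof[test_idx] = p
        if np.unique(y[test_idx]).size == 2:
            reports.append(compute_metrics(y[test_idx], p, threshold))
    pooled = compute_metrics(y, oof, threshold)
    return reports, float(pooled.F1)
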