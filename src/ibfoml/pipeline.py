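"""Cohort table schema, preprocessing, outcome labeling, LASSO selection, splitting.

One row per patient undergoing general anesthesia (ASA physical status I-II).
The composite outcome is *poor postoperative recovery*: the patient
experienced at least one of hypothermia on PACU admission, delayed PACU
discharge (> 120 min) or delayed awakening (> 30 min).

Preprocessing follows a fit-on-train / apply-anywhere contract.  Continuous
columns are screened for outliers with Tukey fences (Q1 - 1.5 IQR,
Q3 + 1.5 IQR), corrected by winsorizing at the 1st/99th percentiles, and
z-scored with training-set mean and standard deviation.  Unordered
categoricals expand to one-hot indicator blocks, the ordinal ASA grade maps
to consecutive integers, and binary flags map to 0/1.  The fitted model is
frozen: applying it to a test table reuses the training statistics, so no
information leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CONTINUOUS_COLUMNS",
    "BINARY_COLUMNS",
    "EVENT_COLUMNS",
    "DISEASE_TYPES",
    "COHORT_COLUMNS",
    "OUTCOME_COLUMN",
    "validate_cohort",
    "label_outcome",
    "PreprocessModel",
    "fit_preprocess",
    "apply_preprocess",
    "lasso_select",
    "stratified_split",
]

CONTINUOUS_COLUMNS = [
    "age",
    "bmi",
    "alt",
    "creatinine",
    "crp",
    "nlr",
    "anesthesia_duration",
    "surgery_duration",
    "mean_hr",
    "mean_bp",
    "mean_rr",
]

#: flags stored as 0/1 (gender: 1 = male; surgery_type handled separately)
BINARY_COLUMNS = [
    "gender",
    "heart_disease",
    "diabetes",
    "hypertension",
    "emergency",
    "drug_allergy",
    "transfusion",
]

#: the three adverse events defining the composite outcome — never features
EVENT_COLUMNS = ["hypothermia", "delayed_discharge", "delayed_awakening"]

DISEASE_TYPES = ["benign_tumor", "malignant_tumor", "orthopedic", "cardiovascular", "other"]
SURGERY_TYPES = ["minimally_invasive", "open"]
ASA_LEVELS = {"I": 1, "II": 2}

COHORT_COLUMNS = (
    CONTINUOUS_COLUMNS
    + BINARY_COLUMNS
    + ["asa_class", "disease_type", "surgery_type"]
    + EVENT_COLUMNS
)

OUTCOME_COLUMN = "poor_recovery"


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Schema and range checks; missing values are rejected, not imputed."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    sub = table[COHORT_COLUMNS]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values present (no imputation performed): {bad}")
    for c in BINARY_COLUMNS + EVENT_COLUMNS:
        if not set(pd.unique(table[c])) <= {0, 1}:
            raise ValueError(f"column {c!r} must be binary 0/1")
    if not set(pd.unique(table["asa_class"])) <= set(ASA_LEVELS):
        raise ValueError("asa_class must be 'I' or 'II'")
    if (table["surgery_duration"] <= 0).any() or (table["anesthesia_duration"] <= 0).any():
        raise ValueError("durations must be positive")
    if (table["anesthesia_duration"] < table["surgery_duration"]).any():
        raise ValueError("anesthesia duration must cover surgery duration")
    return table


def label_outcome(table: pd.DataFrame) -> pd.Series:
    """Composite outcome: 1 (poor recovery) iff at least one adverse event.

    Accepts a full cohort table or any frame holding the three event flags.
    """
    for c in EVENT_COLUMNS:
        if c not in table.columns:
            raise ValueError(f"missing event flag {c!r}")
        if not set(pd.unique(table[c])) <= {0, 1}:
            raise ValueError(f"event flag {c!r} must be binary")
    return (table[EVENT_COLUMNS].sum(axis=1) > 0).astype(int).rename(OUTCOME_COLUMN)


@dataclass
class PreprocessModel:
    """Frozen training-set statistics and encodings."""

    winsor_bounds: dict[str, tuple[float, float]]
    tukey_fences: dict[str, tuple[float, float]]
    means: dict[str, float]
    sds: dict[str, float]
    disease_levels: list[str]
    surgery_levels: list[str]
    asa_levels: dict[str, int]
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "winsor_bounds": {k: list(v) for k, v in self.winsor_bounds.items()},
            "tukey_fences": {k: list(v) for k, v in self.tukey_fences.items()},
            "means": self.means,
            "sds": self.sds,
            "disease_levels": self.disease_levels,
            "surgery_levels": self.surgery_levels,
            "asa_levels": self.asa_levels,
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessModel":
        return cls(
            winsor_bounds={k: tuple(v) for k, v in d["winsor_bounds"].items()},
            tukey_fences={k: tuple(v) for k, v in d["tukey_fences"].items()},
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            disease_levels=list(d["disease_levels"]),
            surgery_levels=list(d["surgery_levels"]),
            asa_levels={k: int(v) for k, v in d["asa_levels"].items()},
            feature_names=list(d["feature_names"]),
        )


def fit_preprocess(train_table: pd.DataFrame) -> PreprocessModel:
    """Learn winsor bounds, Tukey fences, z-score statistics and encodings.

    Quantiles use the linear-interpolation convention (numpy default).  The
    z-score statistics are computed on the winsorized training values, so the
    transformed training matrix has column mean 0 and sd 1.
    """
    table = validate_cohort(train_table)
    if len(table) == 0:
        raise ValueError("empty training table")
    winsor, fences, means, sds = {}, {}, {}, {}
    for c in CONTINUOUS_COLUMNS:
        x = table[c].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(f"continuous column {c!r} is constant on the training set")
        lo, hi = np.quantile(x, [0.01, 0.99])
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        fences[c] = (float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr))
        winsor[c] = (float(lo), float(hi))
        xw = np.clip(x, lo, hi)
        mu = float(xw.mean())
        sd = float(xw.std(ddof=0))
        if sd <= 0:
            raise ValueError(f"zero variance after winsorization in column {c!r}")
        means[c], sds[c] = mu, sd
    disease_levels = [l for l in DISEASE_TYPES if l in set(table["disease_type"])]
    extra = set(table["disease_type"]) - set(DISEASE_TYPES)
    if extra:
        disease_levels = disease_levels + sorted(extra)
    model = PreprocessModel(
        winsor_bounds=winsor,
        tukey_fences=fences,
        means=means,
        sds=sds,
        disease_levels=disease_levels,
        surgery_levels=list(SURGERY_TYPES),
        asa_levels=dict(ASA_LEVELS),
    )
    model.feature_names = list(apply_preprocess(model, table.head(1)).columns)
    return model


def apply_preprocess(model: PreprocessModel, table: pd.DataFrame) -> pd.DataFrame:
    """Transform any cohort table with the *training* statistics."""
    table = validate_cohort(table)
    out = {}
    for c in CONTINUOUS_COLUMNS:
        lo, hi = model.winsor_bounds[c]
        x = np.clip(table[c].to_numpy(dtype=float), lo, hi)
        out[c] = (x - model.means[c]) / model.sds[c]
    for c in BINARY_COLUMNS:
        out[c] = table[c].to_numpy(dtype=float)
    out["asa_class"] = table["asa_class"].map(model.asa_levels).to_numpy(dtype=float)
    unseen = set(table["disease_type"]) - set(model.disease_levels)
    if unseen:
        raise ValueError(f"unseen disease_type categories at apply time: {sorted(unseen)}")
    for level in model.disease_levels:
        out[f"disease_{level}"] = (table["disease_type"] == level).to_numpy(dtype=float)
    unseen = set(table["surgery_type"]) - set(model.surgery_levels)
    if unseen:
        raise ValueError(f"unseen surgery_type categories at apply time: {sorted(unseen)}")
    out["surgery_open"] = (table["surgery_type"] == "open").to_numpy(dtype=float)
    return pd.DataFrame(out, index=table.index)


def tukey_outlier_report(model: PreprocessModel, table: pd.DataFrame) -> pd.DataFrame:
    """Count of values outside the Tukey fences per continuous column."""
    rows = []
    for c in CONTINUOUS_COLUMNS:
        lo, hi = model.tukey_fences[c]
        x = table[c].to_numpy(dtype=float)
        rows.append({"column": c, "below": int((x < lo).sum()), "above": int((x > hi).sum())})
    return pd.DataFrame(rows)


def _cv_loss(y_true: np.ndarray, p: np.ndarray, loss: str) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    if loss == "deviance":
        return float(-2.0 * np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))
    if loss == "mse":
        return float(np.mean((y_true - p) ** 2))
    raise ValueError(f"unknown loss {loss!r}")


def lasso_select(
    train_matrix,
    labels,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_decades: float = 4.0,
    loss: str = "deviance",
    return_path: bool = False,
):
    """L1-penalized logistic feature selection at the one-standard-error penalty.

    The penalty path is log-spaced downward from the smallest lambda that
    zeroes every coefficient.  Each lambda is scored by seeded stratified
    k-fold cross-validated loss (binomial deviance by default; squared error
    available); lambda_1SE is the largest lambda whose mean CV loss is within
    one standard error of the minimum.  Features with nonzero coefficients in
    the full-data refit at lambda_1SE are returned.  An empty selection is
    legal (pure-noise labels should produce one).
    """
    if isinstance(train_matrix, pd.DataFrame):
        names = list(train_matrix.columns)
        X = train_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(train_matrix, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    n = y.size

    # smallest penalty killing all coefficients (KKT at the intercept-only fit)
    p0 = y.mean()
    lambda_max = np.max(np.abs(X.T @ (y - p0))) / n
    lambdas = np.logspace(np.log10(lambda_max), np.log10(lambda_max) - lambda_decades, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_losses = np.zeros((folds, n_lambdas))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        for j, lam in enumerate(lambdas):
            est = _l1_logistic(lam, n_train=tr.size, seed=seed)
            est.fit(X[tr], y[tr])
            p = est.predict_proba(X[va])[:, 1]
            fold_losses[f, j] = _cv_loss(y[va], p, loss)
    mean_loss = fold_losses.mean(axis=0)
    se_loss = fold_losses.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(mean_loss))
    cutoff = mean_loss[j_min] + se_loss[j_min]
    j_1se = int(np.flatnonzero(mean_loss <= cutoff)[0])  # lambdas descend: first = largest

    est = _l1_logistic(lambdas[j_1se], n_train=n, seed=seed)
    est.fit(X, y)
    coefs = est.coef_.ravel()
    selected = [names[i] for i in np.flatnonzero(np.abs(coefs) > 1e-8)]
    if return_path:
        path = {
            "lambdas": lambdas,
            "mean_loss": mean_loss,
            "se_loss": se_loss,
            "lambda_min": float(lambdas[j_min]),
            "lambda_1se": float(lambdas[j_1se]),
            "coefficients": dict(zip(names, coefs)),
        }
        return selected, path
    return selected


def _l1_logistic(lam: float, n_train: int, seed: int) -> LogisticRegression:
    # liblinear objective: C * sum(loss_i) + |beta|_1  <=>  mean loss + lam*|beta|_1.
    # liblinear penalizes the intercept; a large intercept_scaling makes it effectively
    # free, otherwise near-constant columns get selected as intercept surrogates.
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (lam * n_train),
        solver="liblinear",
        max_iter=2000,
        intercept_scaling=100.0,
        random_state=seed,
    )


def stratified_split(
    table: pd.DataFrame,
    labels: Optional[pd.Series] = None,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome-stratified train/test split with per-class round-half-up sizes.

    Per-class training counts are ``floor(f * n_class + 0.5)``, then adjusted
    by +/-1 on the largest class so the total equals ``floor(f * n + 0.5)``.
    The split is disjoint and exhaustive.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = label_outcome(table) if labels is None else pd.Series(labels, index=table.index)
    classes, counts = np.unique(y.to_numpy(), return_counts=True)
    if (counts < 2).any():
        raise ValueError("each class needs at least two members")
    n_total_train = int(np.floor(train_fraction * len(table) + 0.5))
    per_class = {c: int(np.floor(train_fraction * k + 0.5)) for c, k in zip(classes, counts)}
    drift = n_total_train - sum(per_class.values())
    if drift != 0:
        largest = classes[int(np.argmax(counts))]
        per_class[largest] += drift
    rng = np.random.default_rng(seed)
    train_idx = []
    for c in classes:
        members = table.index[y == c].to_numpy()
        rng.shuffle(members)
        train_idx.extend(members[: per_class[c]])
    train_mask = table.index.isin(train_idx)
    return table.loc[train_mask], table.loc[~train_mask]
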