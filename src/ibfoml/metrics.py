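"""Binary-classification evaluation metrics.

The report bundles the seven quantities used to judge the clinical risk
models: precision (PRE), sensitivity (SEN), specificity (SPE), accuracy
(ACC), F1, ROC-AUC and PR-AUC, plus the confusion counts behind them.

ROC-AUC is computed by the rank (Mann-Whitney) formulation with ties given
half credit; PR-AUC by step integration of the precision-recall curve
(precision held constant over each recall increment).  Both are written out
explicitly here because they are part of the package's numeric contract and
are cross-checked against brute-force pair counting in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["MetricReport", "compute_metrics", "roc_auc", "pr_auc"]

#: column order used when serializing reports
METRIC_COLUMNS = ["PRE", "SEN", "SPE", "ACC", "F1", "ROC_AUC", "PR_AUC"]


@dataclass
class MetricReport:
    PRE: float
    SEN: float
    SPE: float
    ACC: float
    F1: float
    ROC_AUC: float
    PR_AUC: float
    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float = 0.5

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})

    def to_row(self) -> pd.DataFrame:
        """Single-row table in the canonical PRE..PR-AUC column order."""
        return pd.DataFrame([[getattr(self, c) for c in METRIC_COLUMNS]], columns=METRIC_COLUMNS)


def _validate(labels, probabilities):
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and probabilities must be equal-length vectors")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y, p


def roc_auc(labels, probabilities) -> float:
    """ROC-AUC via the Mann-Whitney rank statistic, ties counted half."""
    y, p = _validate(labels, probabilities)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined: only one class present")
    ranks = rankdata(p)  # average ranks give ties half credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(labels, probabilities) -> float:
    """Area under the precision-recall curve by step integration.

    Thresholds sweep the distinct scores in decreasing order; the curve is
    integrated as sum(precision_k * (recall_k - recall_{k-1})), i.e. precision
    held constant over each recall increment.
    """
    y, p = _validate(labels, probabilities)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("PR-AUC undefined: only one class present")
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tp = np.cumsum(y_sorted)
    predicted_pos = np.arange(1, y.size + 1)
    # evaluate only at the last index of each tied score block
    block_end = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    precision = tp[block_end] / predicted_pos[block_end]
    recall = tp[block_end] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - prev_recall)))


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricReport:
    """Confusion-matrix metrics at ``threshold`` plus ROC-AUC and PR-AUC.

    Raises if only one class is present (the AUC terms are undefined there).
    """
    y, p = _validate(labels, probabilities)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    pre = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / y.size
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return MetricReport(
        PRE=pre,
        SEN=sen,
        SPE=spe,
        ACC=acc,
        F1=f1,
        ROC_AUC=roc_auc(y, p),
        PR_AUC=pr_auc(y, p),
        TP=tp,
        FP=fp,
        TN=tn,
        FN=fn,
        threshold=threshold,
    )
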