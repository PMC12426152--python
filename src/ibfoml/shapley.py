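"""Shapley-value attribution for fitted tabular models.

Attributions use the interventional (marginal) value function: the value of a
coalition S for a sample x is the mean model output over background rows with
the features in S replaced by x's values.  Exact attribution enumerates all
2^k coalitions (feasible for the clinical seven-feature models; capped at
k = 15); a permutation-sampling estimator covers larger feature counts and is
unbiased for the exact value.

The exact computation satisfies the classical axioms on which the test suite
relies: efficiency (base value plus attributions equals the model output),
symmetry (interchangeable features receive equal credit) and null player
(an ignored feature receives exactly zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ShapExplanation",
    "exact_shapley",
    "sampled_shapley",
    "explain",
    "summarize",
    "dependence_data",
]

EXACT_FEATURE_CAP = 15


@dataclass
class ShapExplanation:
    attributions: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_values: np.ndarray
    feature_names: list[str]
    output_space: str = "probability"

    def __post_init__(self) -> None:
        if self.attributions.shape != self.feature_values.shape:
            raise ValueError("attributions and feature_values must share a shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attributions, columns=self.feature_names)


class _CoalitionValues:
    """Caches the interventional value v(S) per coalition bitmask."""

    def __init__(self, predict: Callable, x: np.ndarray, background: np.ndarray):
        self.predict = predict
        self.x = np.asarray(x, dtype=float).ravel()
        self.background = np.asarray(background, dtype=float)
        if self.background.ndim != 2 or self.background.shape[1] != self.x.size:
            raise ValueError("background must be (n_rows, n_features) matching the sample")
        self.k = self.x.size
        self._cache: dict[int, float] = {}

    def value(self, mask: int) -> float:
        if mask not in self._cache:
            self._cache[mask] = self.values([mask])[0]
        return self._cache[mask]

    def values(self, masks: Sequence[int]) -> np.ndarray:
        missing = [m for m in masks if m not in self._cache]
        if missing:
            nb = self.background.shape[0]
            rows = np.repeat(self.background[None, :, :], len(missing), axis=0)
            for j, m in enumerate(missing):
                on = [i for i in range(self.k) if (m >> i) & 1]
                rows[j, :, on] = self.x[on][:, None]
            out = np.asarray(self.predict(rows.reshape(-1, self.k)), dtype=float)
            out = out.reshape(len(missing), nb).mean(axis=1)
            for m, v in zip(missing, out):
                self._cache[m] = float(v)
        return np.array([self._cache[m] for m in masks])


def exact_shapley(
    predict: Callable,
    sample: np.ndarray,
    background: np.ndarray,
    chunk: int = 2048,
) -> tuple[np.ndarray, float]:
    """Exact Shapley attributions by full coalition enumeration.

    ``predict`` maps an (n, k) matrix to n scalar outputs.  Returns the
    attribution vector and the base value (mean output over the background).
    Raises for k above the enumeration cap; use :func:`sampled_shapley` there.
    """
    cv = _CoalitionValues(predict, sample, background)
    k = cv.k
    if k > EXACT_FEATURE_CAP:
        raise ValueError(f"{k} features exceeds the exact-enumeration cap of {EXACT_FEATURE_CAP}")
    all_masks = np.arange(2**k)
    for start in range(0, all_masks.size, chunk):
        cv.values(all_masks[start : start + chunk].tolist())
    v = np.array([cv._cache[m] for m in range(2**k)])

    sizes = np.array([bin(m).count("1") for m in range(2**k)])
    fact = np.array([math.factorial(i) for i in range(k + 1)], dtype=float)
    phi = np.zeros(k)
    for i in range(k):
        without = all_masks[(all_masks >> i) & 1 == 0]
        w = fact[sizes[without]] * fact[k - sizes[without] - 1] / fact[k]
        phi[i] = np.sum(w * (v[without | (1 << i)] - v[without]))
    return phi, float(v[0])


def sampled_shapley(
    predict: Callable,
    sample: np.ndarray,
    background: np.ndarray,
    permutations: int | Iterable[Sequence[int]] = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimator (unbiased for the exact value).

    ``permutations`` is either a count of random permutations to draw from the
    seeded generator, or an explicit iterable of feature orderings; passing
    all k! distinct orderings reproduces the exact attribution.
    """
    cv = _CoalitionValues(predict, sample, background)
    k = cv.k
    if isinstance(permutations, int):
        if permutations < 1:
            raise ValueError("need at least one permutation")
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(k)) for _ in range(permutations)]
    else:
        perms = [tuple(p) for p in permutations]
        if not perms:
            raise ValueError("need at least one permutation")
    phi = np.zeros(k)
    for perm in perms:
        mask = 0
        prev = cv.value(0)
        for i in perm:
            mask |= 1 << int(i)
            cur = cv.value(mask)
            phi[int(i)] += cur - prev
            prev = cur
    return phi / len(perms), cv.value(0)


def explain(
    predict: Callable,
    samples,
    background,
    feature_names: Optional[Sequence[str]] = None,
    mode: str = "auto",
    permutations: int = 200,
    seed: int = 0,
    output_space: str = "probability",
) -> ShapExplanation:
    """Attribute each sample row; exact when the feature count permits.

    ``mode`` is 'exact', 'sampled' or 'auto' (exact up to the enumeration cap).
    """
    if isinstance(samples, pd.DataFrame):
        feature_names = feature_names or list(samples.columns)
        X = samples.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(samples, dtype=float))
    if isinstance(background, pd.DataFrame):
        background = background.to_numpy(dtype=float)
    background = np.asarray(background, dtype=float)
    k = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(k)]
    if mode == "auto":
        mode = "exact" if k <= EXACT_FEATURE_CAP else "sampled"
    attributions = np.zeros_like(X)
    base = 0.0
    for r in range(X.shape[0]):
        if mode == "exact":
            attributions[r], base = exact_shapley(predict, X[r], background)
        elif mode == "sampled":
            attributions[r], base = sampled_shapley(
                predict, X[r], background, permutations=permutations, seed=seed + r
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return ShapExplanation(attributions, base, X, list(feature_names), output_space)


def summarize(explanation: ShapExplanation) -> pd.DataFrame:
    """Importance ranking: mean |attribution| per feature, descending.

    Ties break lexicographically on the feature name so the ranking is a
    strict, reproducible order.
    """
    if explanation.attributions.size == 0:
        raise ValueError("empty explanation")
    mean_abs = np.abs(explanation.attributions).mean(axis=0)
    df = pd.DataFrame({"feature": explanation.feature_names, "mean_abs_shap": mean_abs})
    df = df.sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def summary_plot_data(explanation: ShapExplanation) -> pd.DataFrame:
    """Long-form (feature, feature value, attribution) records for summary plots."""
    records = []
    for j, name in enumerate(explanation.feature_names):
        for i in range(explanation.attributions.shape[0]):
            records.append(
                {
                    "feature": name,
                    "value": explanation.feature_values[i, j],
                    "shap": explanation.attributions[i, j],
                }
            )
    return pd.DataFrame(records)


def dependence_data(explanation: ShapExplanation, feature: str) -> pd.DataFrame:
    """(feature value, attribution) pairs for one feature, with their Spearman rho."""
    try:
        j = explanation.feature_names.index(feature)
    except ValueError:
        raise KeyError(f"unknown feature {feature!r}") from None
    df = pd.DataFrame(
        {
            "value": explanation.feature_values[:, j],
            "shap": explanation.attributions[:, j],
        }
    )
    rho = spearmanr(df["value"], df["shap"]).statistic if len(df) > 2 else np.nan
    df.attrs["spearman_rho"] = float(rho)
    return df
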