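"""Joint feature selection and hyperparameter tuning with a hybrid chromosome.

A candidate solution carries a binary feature-inclusion mask (one bit per
column of the training matrix) and a block of real genes on [0, 1] that decode
into the learner's hyperparameters.  The population evolves by genetic
operators — roulette selection, single-point/arithmetic crossover, bit-flip
and Gaussian mutation — and the real block additionally receives the
bitterling-fish attraction move plus the Gaussian random walk of the improved
optimizer, so feature weights and hyperparameter values are updated
synchronously each generation.

Fitness rewards cross-validated predictive performance (pooled F1) plus a
small sparsity bonus:

    score = w_perf * F1_cv + w_sparse * 1/k,   k = number of enabled features

``1/k`` is the reciprocal of the enabled-feature proportion normalized by the
total feature count, bounded in (0, 1] so performance dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .learners import LEARNER_IDS, LearnerSpec, cross_validate
from .optimizer import OptimizerConfig, gaussian_walk, sine_chaotic_init

__all__ = [
    "ParamSpec",
    "SearchSpace",
    "DEFAULT_SEARCH_SPACES",
    "GaConfig",
    "HybridChromosome",
    "decode",
    "fitness",
    "roulette_select",
    "crossover",
    "mutate",
    "optimize_model",
    "WrapperResult",
]


@dataclass(frozen=True)
class ParamSpec:
    """One tunable hyperparameter: name, scale and range (or categories)."""

    name: str
    scale: str  # 'log' | 'linear' | 'integer' | 'categorical'
    low: float = 0.0
    high: float = 1.0
    choices: tuple = ()

    def decode_gene(self, g: float) -> object:
        g = min(max(float(g), 0.0), 1.0)
        if self.scale == "log":
            lo, hi = np.log10(self.low), np.log10(self.high)
            return float(10.0 ** (lo + g * (hi - lo)))
        if self.scale == "linear":
            return float(self.low + g * (self.high - self.low))
        if self.scale == "integer":
            return int(round(self.low + g * (self.high - self.low)))
        if self.scale == "categorical":
            # equal-width buckets on [0, 1); g = 1 falls in the last bucket
            idx = min(int(g * len(self.choices)), len(self.choices) - 1)
            return self.choices[idx]
        raise ValueError(f"unknown scale {self.scale!r}")


@dataclass(frozen=True)
class SearchSpace:
    learner_id: str
    params: tuple[ParamSpec, ...]
    fixed: dict = field(default_factory=dict)  # e.g. the BPNN's 500-epoch cap

    @property
    def n_genes(self) -> int:
        return len(self.params)

    def decode_genes(self, genes: Sequence[float]) -> dict:
        if len(genes) != self.n_genes:
            raise ValueError("gene count does not match search space")
        hp = {p.name: p.decode_gene(g) for p, g in zip(self.params, genes)}
        hp.update(self.fixed)
        return hp


DEFAULT_SEARCH_SPACES: dict[str, SearchSpace] = {
    "LR": SearchSpace(
        "LR",
        (
            ParamSpec("C", "log", 1e-3, 100.0),
            ParamSpec("penalty", "categorical", choices=("L1", "L2")),
        ),
    ),
    "SVM": SearchSpace(
        "SVM",
        (
            ParamSpec("gamma", "log", 1e-4, 10.0),
            ParamSpec("C", "linear", 0.1, 1000.0),
        ),
    ),
    "BPNN": SearchSpace(
        "BPNN",
        (
            ParamSpec("hidden", "categorical", choices=(16, 32, 64)),
            ParamSpec("learning_rate", "linear", 0.001, 0.1),
        ),
        fixed={"epochs": 500},
    ),
    "XGBoost": SearchSpace(
        "XGBoost",
        (
            ParamSpec("max_depth", "integer", 3, 10),
            ParamSpec("learning_rate", "linear", 0.01, 0.3),
            ParamSpec("colsample_bytree", "linear", 0.5, 0.9),
        ),
    ),
}


@dataclass
class GaConfig:
    crossover_prob_binary: float = 0.8
    mutation_prob_bit: float = 0.02
    mutation_sigma_real: float = 0.1
    w_perf: float = 1.0
    w_sparse: float = 0.05
    cv_folds: int = 10

    def __post_init__(self) -> None:
        for p in (self.crossover_prob_binary, self.mutation_prob_bit):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.w_perf <= 0 or self.w_sparse < 0:
            raise ValueError("w_perf must be positive and w_sparse nonnegative")


@dataclass(eq=False)
class HybridChromosome:
    mask: np.ndarray  # bool, one bit per feature
    real_genes: np.ndarray  # floats in [0, 1]
    learner_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.real_genes = np.clip(np.asarray(self.real_genes, dtype=float), 0.0, 1.0)
        if self.learner_id not in LEARNER_IDS:
            raise ValueError(f"unknown learner_id {self.learner_id!r}")

    def copy(self) -> "HybridChromosome":
        return HybridChromosome(self.mask.copy(), self.real_genes.copy(), self.learner_id)

    def cache_key(self) -> tuple:
        return (self.mask.tobytes(), tuple(np.round(self.real_genes, 9)), self.learner_id)


def repair(chromosome: HybridChromosome, rng: np.random.Generator) -> HybridChromosome:
    """Enforce the at-least-one-feature invariant by setting a random bit."""
    if not chromosome.mask.any():
        chromosome.mask[rng.integers(chromosome.mask.size)] = True
    return chromosome


def decode(
    chromosome: HybridChromosome, search_space: SearchSpace
) -> tuple[dict, np.ndarray]:
    """Concrete hyperparameter assignment plus enabled feature indices."""
    hp = search_space.decode_genes(chromosome.real_genes)
    return hp, np.flatnonzero(chromosome.mask)


def fitness(
    chromosome: HybridChromosome,
    features,
    labels,
    search_space: SearchSpace,
    ga_config: GaConfig,
    seed: int = 0,
) -> float:
    """Weighted CV-F1 + sparsity score; higher is better; seeded and deterministic."""
    X = np.asarray(features, dtype=float)
    hp, cols = decode(chromosome, search_space)
    if cols.size == 0:
        raise ValueError("empty mask reached fitness(); repair first")
    spec = LearnerSpec(chromosome.learner_id, hp, seed=seed)
    _, pooled_f1 = cross_validate(spec, X[:, cols], labels, folds=ga_config.cv_folds, seed=seed)
    sparsity = 1.0 / cols.size  # (n/k)/n, bounded in (0, 1]
    return ga_config.w_perf * pooled_f1 + ga_config.w_sparse * sparsity


def roulette_select(
    population: Sequence[HybridChromosome], scores, rng: np.random.Generator
) -> tuple[HybridChromosome, HybridChromosome]:
    """Fitness-proportional parent pair (maximization; min-shifted to nonnegative)."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two individuals")
    w = s.copy()
    if w.min() < 0.0:
        w = w - w.min() + 1e-12
    total = w.sum()
    p = np.full(s.size, 1.0 / s.size) if total <= 0 else w / total
    i, j = rng.choice(s.size, size=2, p=p)
    return population[int(i)], population[int(j)]


def crossover(
    parent_a: HybridChromosome,
    parent_b: HybridChromosome,
    ga_config: GaConfig,
    rng: np.random.Generator,
) -> tuple[HybridChromosome, HybridChromosome]:
    """Single-point mask crossover + arithmetic real crossover, one 0.8-probability event."""
    if parent_a.learner_id != parent_b.learner_id:
        raise ValueError("parents must share a learner")
    if parent_a.mask.size != parent_b.mask.size or parent_a.real_genes.size != parent_b.real_genes.size:
        raise ValueError("parents must have equal chromosome lengths")
    a, b = parent_a.copy(), parent_b.copy()
    if rng.random() < ga_config.crossover_prob_binary:
        n = a.mask.size
        if n > 1:
            cut = int(rng.integers(1, n))
            a.mask[cut:], b.mask[cut:] = parent_b.mask[cut:].copy(), parent_a.mask[cut:].copy()
        lam = rng.random()
        ga, gb = parent_a.real_genes, parent_b.real_genes
        a.real_genes = lam * ga + (1.0 - lam) * gb
        b.real_genes = (1.0 - lam) * ga + lam * gb
    return a, b


def mutate(
    chromosome: HybridChromosome, ga_config: GaConfig, rng: np.random.Generator
) -> HybridChromosome:
    """Bit-flip mask mutation and clipped Gaussian real-gene perturbation."""
    c = chromosome.copy()
    if ga_config.mutation_prob_bit > 0:
        flips = rng.random(c.mask.size) < ga_config.mutation_prob_bit
        c.mask = c.mask ^ flips
    if ga_config.mutation_sigma_real > 0:
        noise = rng.normal(0.0, ga_config.mutation_sigma_real, size=c.real_genes.size)
        c.real_genes = np.clip(c.real_genes + noise, 0.0, 1.0)
    return repair(c, rng)


@dataclass
class WrapperResult:
    best_chromosome: HybridChromosome
    best_score: float
    hyperparameters: dict
    selected_indices: np.ndarray
    selected_features: list[str]
    history: np.ndarray  # best score after each generation (non-decreasing)
    evaluations: int


def optimize_model(
    features,
    labels,
    learner_id: str,
    search_space: Optional[SearchSpace] = None,
    ga_config: Optional[GaConfig] = None,
    optimizer_config: Optional[OptimizerConfig] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> WrapperResult:
    """Evolve hybrid chromosomes to jointly pick features and hyperparameters.

    Each generation applies GA operators (roulette selection, crossover,
    mutation), then the improved-optimizer move on the real block (attraction
    toward the incumbent best and a mate, plus the decaying Gaussian walk),
    and finally greedy one-to-one survival against the parent population.
    Returns the highest-scoring chromosome ever evaluated.
    """
    import pandas as pd

    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns) if feature_names is None else list(feature_names)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n_features = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(n_features)]
    space = search_space or DEFAULT_SEARCH_SPACES[learner_id]
    ga = ga_config or GaConfig()
    opt = optimizer_config or OptimizerConfig(population_size=16, max_iterations=12, seed=seed)
    if opt.max_iterations < 1:
        raise ValueError("budget below one generation")
    rng = np.random.default_rng(opt.seed)
    pop_n = opt.population_size
    m = space.n_genes

    unit = (np.zeros(m), np.ones(m))
    if opt.chaotic_init and m > 0:
        genes0 = sine_chaotic_init(pop_n, m, unit, rng)
    else:
        genes0 = rng.random((pop_n, m))
    population = []
    for i in range(pop_n):
        mask = rng.random(n_features) < 0.5
        population.append(
            repair(HybridChromosome(mask, genes0[i] if m else np.empty(0), learner_id), rng)
        )

    cache: dict[tuple, float] = {}
    evaluations = 0

    def score_of(chrom: HybridChromosome) -> float:
        nonlocal evaluations
        key = chrom.cache_key()
        if key not in cache:
            cache[key] = fitness(chrom, X, y, space, ga, seed=opt.seed)
            evaluations += 1
        return cache[key]

    scores = np.array([score_of(c) for c in population])
    best_idx = int(np.argmax(scores))
    best = population[best_idx].copy()
    best_score = float(scores[best_idx])
    history = []

    for t in range(opt.max_iterations):
        sigma_t = opt.walk_sigma0 * (1.0 - t / max(opt.max_iterations, 1))
        offspring = []
        while len(offspring) < pop_n:
            pa, pb = roulette_select(population, scores, rng)
            ca, cb = crossover(pa, pb, ga, rng)
            offspring.extend([mutate(ca, ga, rng), mutate(cb, ga, rng)])
        offspring = offspring[:pop_n]

        # improved-optimizer move on the real block
        if m > 0:
            probs = None
            s = scores - scores.min() + 1e-12
            probs = s / s.sum()
            for child in offspring:
                mate = population[int(rng.choice(pop_n, p=probs))]
                r1 = rng.random(m)
                r2 = rng.random(m)
                g = child.real_genes
                g = g + r1 * (best.real_genes - g) + r2 * (mate.real_genes - g)
                child.real_genes = np.clip(g, 0.0, 1.0)
                if opt.walk_probability > 0 and rng.random() < opt.walk_probability:
                    child.real_genes = gaussian_walk(child.real_genes, sigma_t, unit, rng)

        # greedy one-to-one survival
        for i, child in enumerate(offspring):
            child_score = score_of(child)
            if child_score >= scores[i]:
                population[i] = child
                scores[i] = child_score
            if child_score > best_score:
                best_score = float(child_score)
                best = child.copy()
        history.append(best_score)

    hp, cols = decode(best, space)
    return WrapperResult(
        best_chromosome=best,
        best_score=best_score,
        hyperparameters=hp,
        selected_indices=cols,
        selected_features=[feature_names[i] for i in cols],
        history=np.array(history),
        evaluations=evaluations,
    )
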