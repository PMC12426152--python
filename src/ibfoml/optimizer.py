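"""Bitterling fish optimization (BFO) and its improved variant (IBFO).

BFO is a population metaheuristic modeled on the mating behavior of
bitterling fish: females deposit eggs in mussels and seek stronger males, so
each candidate solution is attracted both toward the population's best member
and toward a fitness-proportionally chosen mate.  The improved variant (IBFO)
adds two ingredients:

* **sine-chaotic initialization** — initial positions come from iterating the
  chaotic map ``c_{k+1} = sin(pi * c_k)`` on (0, 1), which spreads the initial
  population more ergodically than i.i.d. uniform draws;
* **Gaussian random-walk mutation** — after each move an individual may take a
  random walk with a linearly decaying step scale, increasing exploration
  early while preserving exploitation late.

The movement rule used here is the standard attraction template

    x' = x + r1 * (best - x) + r2 * (mate - x)

with ``r1, r2`` elementwise uniform on [0, 1], a roulette-chosen mate, greedy
acceptance, and clamping to the box bounds.  All randomness flows from a
single seeded :class:`numpy.random.Generator`, so identical configurations
reproduce bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "OptimizerConfig",
    "OptimizeResult",
    "sine_chaotic_init",
    "gaussian_walk",
    "roulette_probabilities",
    "optimize",
    "make_benchmark_optimizer",
]

Bounds = tuple[np.ndarray, np.ndarray]


@dataclass
class OptimizerConfig:
    """Settings for one BFO/IBFO run.

    ``walk_probability`` and ``chaotic_init`` default per variant: the
    original BFO uses uniform initialization and no random walk; IBFO uses
    the sine-chaotic map and ``walk_probability = 0.2``.  Setting
    ``walk_probability = 0`` and ``chaotic_init = False`` on the ibfo variant
    makes it bit-identical to original_bfo for the same seed.
    """

    population_size: int = 30
    max_iterations: int = 100
    variant: str = "ibfo"
    walk_probability: Optional[float] = None
    walk_sigma0: float = 0.1
    chaotic_init: Optional[bool] = None
    seed: int = 0
    max_evaluations: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in ("original_bfo", "ibfo"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.walk_sigma0 <= 0:
            raise ValueError("walk_sigma0 must be positive")
        if self.walk_probability is None:
            self.walk_probability = 0.2 if self.variant == "ibfo" else 0.0
        if not 0.0 <= self.walk_probability <= 1.0:
            raise ValueError("walk_probability must lie in [0, 1]")
        if self.chaotic_init is None:
            self.chaotic_init = self.variant == "ibfo"


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_value: float
    trajectory: np.ndarray  # best-so-far value after init and each iteration
    evaluations: int


def _check_bounds(bounds: Bounds) -> Bounds:
    lb = np.asarray(bounds[0], dtype=float)
    ub = np.asarray(bounds[1], dtype=float)
    if lb.shape != ub.shape:
        raise ValueError("bound arrays must have equal shape")
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("bounds must be finite")
    if np.any(lb >= ub):
        raise ValueError("degenerate bounds: lower must be strictly below upper")
    return lb, ub


def sine_chaotic_init(
    population_size: int,
    dim: int,
    bounds: Bounds,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Initial positions from the sine chaotic map, affinely mapped into bounds.

    Each coordinate is produced by iterating ``c <- sin(pi * c)`` from a
    seeded starting value in (0, 1) and mapping ``c`` to ``lb + c*(ub - lb)``.
    If the orbit collapses to 0 (an absorbing state reachable in floating
    point, e.g. 0.5 -> 1 -> 0) a fresh starting value is drawn.
    """
    lb, ub = _check_bounds(bounds)
    if population_size * dim <= 0:
        raise ValueError("population_size and dim must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = rng.uniform(1e-6, 1.0 - 1e-6)
    vals = np.empty(population_size * dim)
    for k in range(vals.size):
        c = np.sin(np.pi * c)
        if c <= 0.0 or c >= 1.0:  # absorbing orbit guard
            c = rng.uniform(1e-6, 1.0 - 1e-6)
            c = np.sin(np.pi * c)
        vals[k] = c
    pos = vals.reshape(population_size, dim)
    return lb + pos * (ub - lb)


def gaussian_walk(
    x: np.ndarray, sigma: float, bounds: Bounds, rng: np.random.Generator
) -> np.ndarray:
    """One Gaussian random-walk step with per-dimension scale ``sigma*(ub-lb)``."""
    lb, ub = _check_bounds(bounds)
    if sigma == 0.0:
        return np.array(x, dtype=float, copy=True)
    step = rng.normal(0.0, sigma * (ub - lb), size=np.shape(x))
    return np.clip(np.asarray(x, dtype=float) + step, lb, ub)


def roulette_probabilities(fitnesses: np.ndarray) -> np.ndarray:
    """Selection probabilities for a *minimization* fitness vector.

    Fitnesses are inverted (max-shifted) so lower values receive higher
    probability; an all-equal vector yields the uniform distribution.
    """
    f = np.asarray(fitnesses, dtype=float)
    finite = np.isfinite(f)
    if not finite.any():
        return np.full(f.size, 1.0 / f.size)
    w = np.zeros(f.size)
    w[finite] = np.max(f[finite]) - f[finite]  # failed (inf) candidates get zero weight
    total = w.sum()
    if total <= 0.0:
        return np.full(f.size, 1.0 / f.size)
    return w / total


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: OptimizerConfig,
) -> OptimizeResult:
    """Run the BFO/IBFO loop and return the global best with its trajectory.

    Non-finite objective values are treated as failed candidates: they are
    assigned ``+inf`` fitness and can never be accepted.  The trajectory has
    one entry after initialization plus one per completed iteration and is
    monotone non-increasing (elitism).
    """
    lb, ub = _check_bounds(bounds)
    dim = lb.size
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    budget = config.max_evaluations if config.max_evaluations is not None else np.inf
    evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        v = objective(x)
        return float(v) if np.isfinite(v) else np.inf

    if config.chaotic_init:
        positions = sine_chaotic_init(n, dim, (lb, ub), rng)
    else:
        positions = rng.uniform(lb, ub, size=(n, dim))
    if budget < n:
        raise ValueError("evaluation budget smaller than one population")
    fitnesses = np.array([evaluate(x) for x in positions])

    ibest = int(np.argmin(fitnesses))
    best_position = positions[ibest].copy()
    best_value = float(fitnesses[ibest])
    trajectory = [best_value]

    for t in range(config.max_iterations):
        if evals + 1 > budget:
            break
        sigma_t = config.walk_sigma0 * (1.0 - t / max(config.max_iterations, 1))
        probs = roulette_probabilities(fitnesses)
        for i in range(n):
            if evals + 1 > budget:
                break
            mate = int(rng.choice(n, p=probs))
            r1 = rng.random(dim)
            r2 = rng.random(dim)
            proposal = positions[i] + r1 * (best_position - positions[i]) + r2 * (
                positions[mate] - positions[i]
            )
            proposal = np.clip(proposal, lb, ub)
            value = evaluate(proposal)
            if value < fitnesses[i]:  # greedy acceptance
                positions[i] = proposal
                fitnesses[i] = value
            if config.walk_probability > 0.0 and evals + 1 <= budget:
                if rng.random() < config.walk_probability:
                    walked = gaussian_walk(positions[i], sigma_t, (lb, ub), rng)
                    wvalue = evaluate(walked)
                    if wvalue < fitnesses[i]:
                        positions[i] = walked
                        fitnesses[i] = wvalue
            if fitnesses[i] < best_value:
                best_value = float(fitnesses[i])
                best_position = positions[i].copy()
        trajectory.append(best_value)

    return OptimizeResult(best_position, best_value, np.array(trajectory), evals)


def make_benchmark_optimizer(variant: str = "ibfo", population_size: int = 30, **kwargs):
    """Adapter giving :func:`ibfoml.benchmarks.run_benchmark` its optimizer handle."""

    def handle(objective, bounds, seed, budget):
        probe = OptimizerConfig(population_size=population_size, variant=variant, **kwargs)
        # expected evaluations per generation: one move plus walk_probability walks each
        per_gen = population_size * (1.0 + probe.walk_probability)
        config = OptimizerConfig(
            population_size=population_size,
            max_iterations=max(1, int(budget / per_gen)),  # sigma decays over the whole budget
            variant=variant,
            seed=seed,
            max_evaluations=budget,
            **kwargs,
        )
        return optimize(objective, bounds, config).best_value

    handle.name = variant
    return handle
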