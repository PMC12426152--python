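"""The 23 classic benchmark test functions and a seeded optimizer-comparison harness.

The suite is the canonical unimodal (F1-F7), multimodal (F8-F13) and
fixed-dimension multimodal (F14-F23) collection used throughout the
nature-inspired-optimization literature.  Each function carries its standard
bounds, default dimensionality and, where one is tabulated, the global minimum
and an exactly known minimizer.

F7 (quartic with noise) is the only stochastic member; its additive uniform
noise is drawn from an explicit :class:`numpy.random.Generator` so benchmark
runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BenchmarkFunction",
    "BenchmarkResult",
    "FUNCTIONS",
    "get_function",
    "evaluate_function",
    "run_benchmark",
    "results_table",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """One member of the 23-function suite."""

    id: int
    name: str
    dimension: int
    lower: float
    upper: float
    func: Callable[[np.ndarray], float]
    known_minimum: Optional[float] = None
    #: exactly known minimizer (None when only approximate locations are tabulated)
    minimizer: Optional[np.ndarray] = None
    stochastic: bool = False

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.full(self.dimension, self.lower, dtype=float)
        ub = np.full(self.dimension, self.upper, dtype=float)
        return lb, ub

    @property
    def scalable(self) -> bool:
        """F1-F13 accept any dimension; F14-F23 are fixed-dimension."""
        return self.id <= 13

    def __call__(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size == 0 or (not self.scalable and x.shape != (self.dimension,)):
            raise ValueError(
                f"F{self.id} ({self.name}) expects dimension {self.dimension}, "
                f"got shape {x.shape}"
            )
        if self.stochastic:
            if rng is None:
                rng = np.random.default_rng()
            return float(self.func(x) + rng.random())
        return float(self.func(x))


@dataclass
class BenchmarkResult:
    """Best objective value per seed for one optimizer on one function."""

    function_id: int
    optimizer_name: str
    seeds: list[int]
    best_values: list[float]
    evaluations_budget: int
    dimension: int = 0

    def __post_init__(self) -> None:
        if len(self.best_values) != len(self.seeds):
            raise ValueError("one best value per seed required")

    @property
    def median_best(self) -> float:
        return float(np.median(self.best_values))


def _sphere(x):  # F1
    return np.sum(x * x)


def _schwefel_2_22(x):  # F2
    a = np.abs(x)
    return np.sum(a) + np.prod(a)


def _schwefel_1_2(x):  # F3
    return np.sum(np.cumsum(x) ** 2)


def _schwefel_2_21(x):  # F4
    return np.max(np.abs(x))


def _rosenbrock(x):  # F5
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _step(x):  # F6
    return np.sum(np.floor(x + 0.5) ** 2)


def _quartic(x):  # F7 (noise added by the harness)
    i = np.arange(1, x.size + 1)
    return np.sum(i * x**4)


def _schwefel_2_26(x):  # F8
    return -np.sum(x * np.sin(np.sqrt(np.abs(x))))


def _rastrigin(x):  # F9
    return np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0)


def _ackley(x):  # F10
    n = x.size
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _griewank(x):  # F11
    i = np.arange(1, x.size + 1)
    return np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0


def _u_penalty(x, a, k, m):
    out = np.zeros_like(x)
    hi = x > a
    lo = x < -a
    out[hi] = k * (x[hi] - a) ** m
    out[lo] = k * (-x[lo] - a) ** m
    return np.sum(out)


def _penalized_1(x):  # F12
    n = x.size
    y = 1.0 + (x + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return np.pi / n * term + _u_penalty(x, 10.0, 100.0, 4)


def _penalized_2(x):  # F13
    term = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return 0.1 * term + _u_penalty(x, 5.0, 100.0, 4)


_FOXHOLE_A = np.array(
    [
        [-32, -16, 0, 16, 32] * 5,
        [-32] * 5 + [-16] * 5 + [0] * 5 + [16] * 5 + [32] * 5,
    ],
    dtype=float,
)


def _foxholes(x):  # F14
    d = x[:, None] - _FOXHOLE_A
    j = np.arange(1, 26)
    return 1.0 / (1.0 / 500.0 + np.sum(1.0 / (j + np.sum(d**6, axis=0))))


_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def _kowalik(x):  # F15
    b = _KOWALIK_B
    model = x[0] * (b**2 + b * x[1]) / (b**2 + b * x[2] + x[3])
    return np.sum((_KOWALIK_A - model) ** 2)


def _six_hump_camel(x):  # F16
    x1, x2 = x
    return (
        4.0 * x1**2
        - 2.1 * x1**4
        + x1**6 / 3.0
        + x1 * x2
        - 4.0 * x2**2
        + 4.0 * x2**4
    )


def _branin(x):  # F17
    x1, x2 = x
    return (
        (x2 - 5.1 / (4.0 * np.pi**2) * x1**2 + 5.0 / np.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8.0 * np.pi)) * np.cos(x1)
        + 10.0
    )


def _goldstein_price(x):  # F18
    x1, x2 = x
    a = 1.0 + (x1 + x2 + 1.0) ** 2 * (
        19.0 - 14.0 * x1 + 3.0 * x1**2 - 14.0 * x2 + 6.0 * x1 * x2 + 3.0 * x2**2
    )
    b = 30.0 + (2.0 * x1 - 3.0 * x2) ** 2 * (
        18.0 - 32.0 * x1 + 12.0 * x1**2 + 48.0 * x2 - 36.0 * x1 * x2 + 27.0 * x2**2
    )
    return a * b


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3, 10, 30], [0.1, 10, 35], [3, 10, 30], [0.1, 10, 35]], dtype=float)
_H3_P = np.array(
    [
        [0.3689, 0.1170, 0.2673],
        [0.4699, 0.4387, 0.7470],
        [0.1091, 0.8732, 0.5547],
        [0.0381, 0.5743, 0.8828],
    ]
)


def _hartman_3(x):  # F19
    inner = np.sum(_H3_A * (x - _H3_P) ** 2, axis=1)
    return -np.sum(_H3_ALPHA * np.exp(-inner))


_H6_A = np.array(
    [
        [10, 3, 17, 3.5, 1.7, 8],
        [0.05, 10, 17, 0.1, 8, 14],
        [3, 3.5, 1.7, 10, 17, 8],
        [17, 8, 0.05, 10, 0.1, 14],
    ],
    dtype=float,
)
_H6_P = np.array(
    [
        [0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
        [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
        [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
        [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381],
    ]
)


def _hartman_6(x):  # F20
    inner = np.sum(_H6_A * (x - _H6_P) ** 2, axis=1)
    return -np.sum(_H3_ALPHA * np.exp(-inner))


_SHEKEL_A = np.array(
    [
        [4, 4, 4, 4],
        [1, 1, 1, 1],
        [8, 8, 8, 8],
        [6, 6, 6, 6],
        [3, 7, 3, 7],
        [2, 9, 2, 9],
        [5, 5, 3, 3],
        [8, 1, 8, 1],
        [6, 2, 6, 2],
        [7, 3.6, 7, 3.6],
    ],
    dtype=float,
)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(m):
    def f(x):
        d = np.sum((x - _SHEKEL_A[:m]) ** 2, axis=1)
        return -np.sum(1.0 / (d + _SHEKEL_C[:m]))

    return f


def _make_suite() -> dict[int, BenchmarkFunction]:
    zeros30 = np.zeros(30)
    suite = [
        BenchmarkFunction(1, "sphere", 30, -100, 100, _sphere, 0.0, zeros30),
        BenchmarkFunction(2, "schwefel_2.22", 30, -10, 10, _schwefel_2_22, 0.0, zeros30),
        BenchmarkFunction(3, "schwefel_1.2", 30, -100, 100, _schwefel_1_2, 0.0, zeros30),
        BenchmarkFunction(4, "schwefel_2.21", 30, -100, 100, _schwefel_2_21, 0.0, zeros30),
        BenchmarkFunction(5, "rosenbrock", 30, -30, 30, _rosenbrock, 0.0, np.ones(30)),
        BenchmarkFunction(6, "step", 30, -100, 100, _step, 0.0, zeros30),
        BenchmarkFunction(7, "quartic_noise", 30, -1.28, 1.28, _quartic, 0.0, None, stochastic=True),
        # -418.98288727... per dimension at x_i ~ 420.9687; the minimizer is
        # only tabulated approximately, so the stored minimum is conservative.
        BenchmarkFunction(8, "schwefel_2.26", 30, -500, 500, _schwefel_2_26, -12569.5, None),
        BenchmarkFunction(9, "rastrigin", 30, -5.12, 5.12, _rastrigin, 0.0, zeros30),
        BenchmarkFunction(10, "ackley", 30, -32, 32, _ackley, 0.0, zeros30),
        BenchmarkFunction(11, "griewank", 30, -600, 600, _griewank, 0.0, zeros30),
        BenchmarkFunction(12, "penalized_1", 30, -50, 50, _penalized_1, 0.0, -np.ones(30)),
        BenchmarkFunction(13, "penalized_2", 30, -50, 50, _penalized_2, 0.0, np.ones(30)),
        BenchmarkFunction(14, "foxholes", 2, -65.536, 65.536, _foxholes, 0.998, None),
        BenchmarkFunction(15, "kowalik", 4, -5, 5, _kowalik, 0.0003, None),
        BenchmarkFunction(16, "six_hump_camel", 2, -5, 5, _six_hump_camel, -1.03163, None),
        BenchmarkFunction(17, "branin", 2, -5, 15, _branin, 0.39788, None),
        BenchmarkFunction(18, "goldstein_price", 2, -2, 2, _goldstein_price, 3.0, np.array([0.0, -1.0])),
        BenchmarkFunction(19, "hartman_3", 3, 0, 1, _hartman_3, -3.8628, None),
        BenchmarkFunction(20, "hartman_6", 6, 0, 1, _hartman_6, -3.3224, None),
        BenchmarkFunction(21, "shekel_5", 4, 0, 10, _shekel(5), -10.1532, None),
        BenchmarkFunction(22, "shekel_7", 4, 0, 10, _shekel(7), -10.4029, None),
        BenchmarkFunction(23, "shekel_10", 4, 0, 10, _shekel(10), -10.5364, None),
    ]
    return {f.id: f for f in suite}


FUNCTIONS: dict[int, BenchmarkFunction] = _make_suite()


def get_function(id: int) -> BenchmarkFunction:
    try:
        return FUNCTIONS[int(id)]
    except KeyError:
        raise KeyError(f"unknown benchmark function id {id}; valid ids are 1-23") from None


def evaluate_function(
    id: int, x: Sequence[float], rng: Optional[np.random.Generator] = None
) -> float:
    """Evaluate benchmark function ``id`` at ``x``.

    Deterministic for all functions except the quartic-with-noise (F7), whose
    additive uniform noise is drawn from ``rng``.
    """
    return get_function(id)(np.asarray(x, dtype=float), rng=rng)


def run_benchmark(
    optimizer,
    id: int,
    dim: Optional[int] = None,
    budget: int = 10_000,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    optimizer_name: Optional[str] = None,
) -> BenchmarkResult:
    """Run ``optimizer`` on one benchmark function once per seed.

    ``optimizer`` is a callable ``(objective, bounds, seed, budget) -> best value``
    (see :func:`ibfoml.optimizer.make_benchmark_optimizer`).  Identical seeds
    reproduce identical best values for deterministic functions.
    """
    fn = get_function(id)
    if dim is None:
        dim = fn.dimension
    elif not fn.scalable and dim != fn.dimension:
        raise ValueError(f"F{fn.id} has fixed dimension {fn.dimension}")
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed required")
    lb = np.full(dim, fn.lower, dtype=float)
    ub = np.full(dim, fn.upper, dtype=float)
    best_values = []
    for seed in seeds:
        noise_rng = np.random.default_rng(seed + 982_451_653 % (2**31))
        if fn.stochastic:
            objective = lambda x: fn(x, rng=noise_rng)  # noqa: E731
        else:
            objective = fn
        best = optimizer(objective, (lb, ub), seed, budget)
        best_values.append(float(best))
    name = optimizer_name or getattr(optimizer, "name", type(optimizer).__name__)
    return BenchmarkResult(fn.id, name, seeds, best_values, budget, dim)


def results_table(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Long-format table (function, optimizer, seed, best, budget) for export."""
    rows = []
    for r in results:
        fn = get_function(r.function_id)
        for seed, best in zip(r.seeds, r.best_values):
            rows.append(
                {
                    "function": f"F{r.function_id}",
                    "name": fn.name,
                    "optimizer": r.optimizer_name,
                    "seed": seed,
                    "best": best,
                    "budget": r.evaluations_budget,
                    "dimension": r.dimension,
                }
            )
    return pd.DataFrame(rows)
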