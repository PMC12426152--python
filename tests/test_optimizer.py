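"""BFO/IBFO core: chaotic initialization, random walk, loop contracts."""

import numpy as np
import pytest

from ibfoml.optimizer import (
    OptimizerConfig,
    gaussian_walk,
    optimize,
    roulette_probabilities,
    sine_chaotic_init,
)

BOUNDS_2D = (np.full(2, -5.0), np.full(2, 5.0))


def sphere(x):
    return float(np.sum(x * x))


def test_sine_map_step_matches_direct_evaluation():
    # one iteration of the map from c = 0.25
    assert np.sin(np.pi * 0.25) == pytest.approx(0.70711, abs=5e-6)


def test_chaotic_init_within_bounds_and_seeded():
    lb, ub = np.array([-5.0, 0.0, 2.0]), np.array([5.0, 1.0, 8.0])
    a = sine_chaotic_init(40, 3, (lb, ub), seed=3)
    b = sine_chaotic_init(40, 3, (lb, ub), seed=3)
    assert a.shape == (40, 3)
    assert np.array_equal(a, b)
    assert np.all(a >= lb) and np.all(a <= ub)
    # chaotic value 0.5 maps to the affine midpoint
    assert -5.0 + 0.5 * 10.0 == 0.0


def test_chaotic_init_rejects_degenerate_bounds():
    with pytest.raises(ValueError):
        sine_chaotic_init(5, 2, (np.ones(2), np.ones(2)), seed=0)


def test_gaussian_walk_zero_sigma_is_identity_and_clamps():
    rng = np.random.default_rng(0)
    x = np.array([4.9, -4.9])
    assert np.array_equal(gaussian_walk(x, 0.0, BOUNDS_2D, rng), x)
    for _ in range(50):
        out = gaussian_walk(x, 0.5, BOUNDS_2D, rng)
        assert np.all(out >= -5.0) and np.all(out <= 5.0)


def test_gaussian_walk_displacement_centred_at_zero():
    rng = np.random.default_rng(1)
    sigma, n = 0.05, 10_000
    x = np.zeros(1)
    draws = np.array([gaussian_walk(x, sigma, (np.array([-50.0]), np.array([50.0])), rng)[0]
                      for _ in range(n)])
    se = sigma * 100.0 / np.sqrt(n)
    assert abs(draws.mean()) < 3 * se


def test_constant_objective_returns_constant():
    res = optimize(lambda x: 7.5, BOUNDS_2D, OptimizerConfig(population_size=6, max_iterations=5, seed=0))
    assert res.best_value == 7.5


def test_sphere_2d_converges_within_budget():
    cfg = OptimizerConfig(population_size=20, max_iterations=200, seed=0, max_evaluations=5000)
    res = optimize(sphere, BOUNDS_2D, cfg)
    assert res.best_value < 1e-4
    assert res.evaluations <= 5000


def test_trajectory_monotone_non_increasing():
    for variant in ("ibfo", "original_bfo"):
        res = optimize(sphere, BOUNDS_2D, OptimizerConfig(
            population_size=10, max_iterations=50, variant=variant, seed=2))
        assert np.all(np.diff(res.trajectory) <= 0)


def test_disabled_improvements_reduce_to_original_bfo():
    """With chaos and walk switched off, ibfo and original_bfo are bit-identical."""
    kwargs = dict(population_size=12, max_iterations=30, walk_probability=0.0,
                  chaotic_init=False, seed=9)
    a = optimize(sphere, BOUNDS_2D, OptimizerConfig(variant="ibfo", **kwargs))
    b = optimize(sphere, BOUNDS_2D, OptimizerConfig(variant="original_bfo", **kwargs))
    assert np.array_equal(a.trajectory, b.trajectory)
    assert np.array_equal(a.best_position, b.best_position)


def test_seed_determinism():
    cfg = OptimizerConfig(population_size=10, max_iterations=20, seed=4)
    a = optimize(sphere, BOUNDS_2D, cfg)
    b = optimize(sphere, BOUNDS_2D, OptimizerConfig(population_size=10, max_iterations=20, seed=4))
    assert a.best_value == b.best_value
    assert np.array_equal(a.trajectory, b.trajectory)


def test_non_finite_objective_values_are_rejected():
    calls = {"n": 0}

    def nasty(x):
        calls["n"] += 1
        return np.nan if calls["n"] % 3 == 0 else sphere(x)

    res = optimize(nasty, BOUNDS_2D, OptimizerConfig(population_size=8, max_iterations=20, seed=1))
    assert np.isfinite(res.best_value)


def test_roulette_probabilities_invert_minimization_fitness():
    p = roulette_probabilities(np.array([1.0, 1.0, 1.0]))
    assert np.allclose(p, 1 / 3)
    p = roulette_probabilities(np.array([0.0, 10.0]))
    assert p[0] > p[1]


def test_config_validation():
    with pytest.raises(ValueError):
        OptimizerConfig(population_size=1)
    with pytest.raises(ValueError):
        OptimizerConfig(walk_sigma0=0.0)
    with pytest.raises(ValueError):
        OptimizerConfig(variant="annealing")
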