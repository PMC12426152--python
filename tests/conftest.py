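import numpy as np
import pandas as pd
import pytest

from ibfoml.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded 600-row synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n=600, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the 1,128-row study scale."""
    return generate_cohort(GeneratorConfig(n=1128, seed=7))


@pytest.fixture()
def separable_data():
    """Linearly separable two-class data: feature 0 fully separates classes."""
    rng = np.random.default_rng(42)
    n = 80
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 3))
    X[:, 0] = np.where(y == 1, 3.0, -3.0) + 0.1 * rng.normal(size=n)
    return X, y


def make_planted_classification(n, n_informative, n_noise, seed, beta=1.8):
    """Logistic outcome driven by the first ``n_informative`` columns only."""
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    X = rng.normal(size=(n, p))
    logit = X[:, :n_informative] @ (beta * np.linspace(1.0, 0.6, n_informative))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return X, y
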