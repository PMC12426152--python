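"""Generator structure: marginal constraints, calibration, parameter recovery."""

import numpy as np
import pytest

from ibfoml.pipeline import label_outcome
from ibfoml.simulate import (
    DEFAULT_EFFECTS,
    GeneratorConfig,
    INFORMATIVE_FEATURES,
    REFERENCE_SCALE,
    calibrate_intercepts,
    generate_cohort,
)


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(GeneratorConfig(n=20_000, seed=123))


def test_anesthesia_covers_surgery(small_cohort):
    t = small_cohort.table
    assert (t.anesthesia_duration >= t.surgery_duration).all()
    assert (t.surgery_duration > 0).all()


def test_composite_prevalence_near_target(big_cohort):
    rate = label_outcome(big_cohort.table).mean()
    assert rate == pytest.approx(0.4238, abs=0.02)


def test_truth_probabilities_match_drawn_events(big_cohort):
    # drawn composite rate agrees with the stored ground-truth probabilities
    assert label_outcome(big_cohort.table).mean() == pytest.approx(
        big_cohort.truth["composite"].mean(), abs=0.02
    )


def test_noise_features_uncorrelated_with_outcome(big_cohort):
    y = label_outcome(big_cohort.table).to_numpy()
    t = big_cohort.table
    for col in ("alt", "mean_hr", "mean_bp", "mean_rr", "gender", "diabetes"):
        r = np.corrcoef(t[col].to_numpy(dtype=float), y)[0, 1]
        assert abs(r) < 0.05, col


def test_calibration_monotone_and_hits_target():
    base = GeneratorConfig(n=1000, seed=0, calibration_n=8000)
    lo = calibrate_intercepts(base)
    higher = GeneratorConfig(n=1000, seed=0, calibration_n=8000, target_prevalence=0.6)
    hi = calibrate_intercepts(higher)
    assert hi > lo  # raising the target prevalence raises the intercept
    fresh = generate_cohort(GeneratorConfig(n=20_000, seed=77, calibration_n=8000,
                                            target_prevalence=0.6))
    assert label_outcome(fresh.table).mean() == pytest.approx(0.6, abs=0.02)


def test_zero_effect_model_calibrates_to_half():
    effects = {f: b * 1e-9 for f, b in DEFAULT_EFFECTS.items()}
    cfg = GeneratorConfig(n=1000, seed=0, effects=effects, target_prevalence=0.5,
                          surgery_threshold_bonus=0.0, nlr_threshold_bonus=0.0,
                          calibration_n=8000)
    shift = calibrate_intercepts(cfg)
    c = generate_cohort(cfg)
    assert c.truth["composite"].mean() == pytest.approx(0.5, abs=0.005)
    assert np.isfinite(shift)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n=10)
    with pytest.raises(ValueError):
        GeneratorConfig(target_prevalence=1.5)
    bad = dict(DEFAULT_EFFECTS)
    bad["age"] = 2.0  # breaks the descending-importance ordering
    with pytest.raises(ValueError):
        GeneratorConfig(effects=bad)


def test_seed_determinism():
    a = generate_cohort(GeneratorConfig(n=200, seed=5))
    b = generate_cohort(GeneratorConfig(n=200, seed=5))
    assert a.table.equals(b.table)
    assert not a.table.equals(generate_cohort(GeneratorConfig(n=200, seed=6)).table)


def test_logistic_fit_recovers_planted_structure():
    """Signs of all seven drivers and the top-2 ordering reappear in a plain fit."""
    from sklearn.linear_model import LogisticRegression

    sign_hits, order_hits = 0, 0
    for seed in range(5):
        c = generate_cohort(GeneratorConfig(n=20_000, seed=seed))
        t, y = c.table, label_outcome(c.table)
        Z = np.column_stack([
            (t[f].to_numpy() - REFERENCE_SCALE[f][0]) / REFERENCE_SCALE[f][1]
            for f in INFORMATIVE_FEATURES
        ])
        est = LogisticRegression(C=1e6, max_iter=3000).fit(Z, y)
        coef = est.coef_.ravel()
        sign_hits += bool(np.all(coef > 0))
        order_hits += bool(np.argsort(-np.abs(coef))[0] in (0, 1)
                           and np.argsort(-np.abs(coef))[1] in (0, 1))
    assert sign_hits >= 4
    assert order_hits >= 4
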