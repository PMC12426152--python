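"""Artifact persistence round-trips and the interactive prediction endpoint."""

import numpy as np
import pytest

from ibfoml.artifact import ModelArtifact, load_artifact, save_artifact
from ibfoml.learners import LEARNER_IDS, LearnerSpec, fit
from ibfoml.pipeline import apply_preprocess, fit_preprocess, label_outcome, stratified_split
from ibfoml.simulate import INFORMATIVE_FEATURES


@pytest.fixture(scope="module")
def fitted_setup(small_cohort):
    train, test = stratified_split(small_cohort.table, seed=0)
    pre = fit_preprocess(train)
    X = apply_preprocess(pre, train)
    y = label_outcome(train)
    return train, test, pre, X, y


@pytest.mark.parametrize("learner_id", LEARNER_IDS)
def test_round_trip_identical_predictions(tmp_path, fitted_setup, learner_id):
    train, test, pre, X, y = fitted_setup
    hp = {"epochs": 40} if learner_id == "BPNN" else {}
    model = fit(LearnerSpec(learner_id, hp, seed=0), X[INFORMATIVE_FEATURES].to_numpy(), y)
    art = ModelArtifact(model, pre, list(INFORMATIVE_FEATURES), metadata={"seed": 0})
    save_artifact(art, tmp_path / learner_id)
    loaded = load_artifact(tmp_path / learner_id)
    p0 = art.predict_proba_table(test)
    p1 = loaded.predict_proba_table(test)
    assert np.array_equal(p0, p1)
    assert loaded.selected_features == list(INFORMATIVE_FEATURES)


def test_predict_features_consistent_with_batch_pipeline(tmp_path, fitted_setup):
    train, test, pre, X, y = fitted_setup
    model = fit(LearnerSpec("XGBoost", {}, seed=0), X[INFORMATIVE_FEATURES].to_numpy(), y)
    art = ModelArtifact(model, pre, list(INFORMATIVE_FEATURES))
    row = test.iloc[0]
    batch = art.predict_proba_table(test.iloc[[0]])[0]
    single = art.predict_features({f: row[f] for f in INFORMATIVE_FEATURES},
                                  allow_out_of_range=True)
    assert single["probability_poor"] == pytest.approx(batch, abs=1e-9)
    assert single["predicted_class"] in ("good", "poor")
    assert 0.0 <= single["probability_poor"] <= 1.0


def test_predict_features_validation(fitted_setup):
    train, test, pre, X, y = fitted_setup
    model = fit(LearnerSpec("LR", {}, seed=0), X[INFORMATIVE_FEATURES].to_numpy(), y)
    art = ModelArtifact(model, pre, list(INFORMATIVE_FEATURES))
    good = {f: float(test.iloc[0][f]) for f in INFORMATIVE_FEATURES}
    with pytest.raises(ValueError, match="missing required"):
        art.predict_features({"age": 50.0})
    bad = dict(good)
    bad["age"] = 300.0
    with pytest.raises(ValueError, match="plausible range"):
        art.predict_features(bad)
    out = art.predict_features(bad, allow_out_of_range=True)
    assert out["warnings"]


def test_missing_manifest_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_artifact(tmp_path / "nothing_here")


def test_raising_surgery_duration_does_not_lower_risk(fitted_setup):
    """Planted positive duration effect shows through the fitted model."""
    train, test, pre, X, y = fitted_setup
    hits = 0
    for seed in range(5):
        model = fit(LearnerSpec("XGBoost", {"max_depth": 4, "learning_rate": 0.1}, seed=seed),
                    X[INFORMATIVE_FEATURES].to_numpy(), y)
        art = ModelArtifact(model, pre, list(INFORMATIVE_FEATURES))
        med = {f: float(train[f].median()) for f in INFORMATIVE_FEATURES}
        short = dict(med, surgery_duration=60.0)
        longer = dict(med, surgery_duration=300.0)
        longer["anesthesia_duration"] = max(longer["anesthesia_duration"], 310.0)
        short_p = art.predict_features(short, allow_out_of_range=True)["probability_poor"]
        long_p = art.predict_features(longer, allow_out_of_range=True)["probability_poor"]
        hits += long_p >= short_p
    assert hits >= 3
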