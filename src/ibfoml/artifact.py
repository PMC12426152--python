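"""Persisted model artifacts and the seven-feature prediction endpoint.

An artifact bundles everything needed to score a new patient: the fitted
base learner, the decoded hyperparameters, the selected feature names and the
frozen preprocessing statistics (normalization coefficients).  It is stored
as a self-describing directory: a plain-text ``manifest.json`` plus a
``model.joblib`` holding the fitted estimator.  Artifacts round-trip —
save, load, and the loaded copy reproduces the original predictions.

``predict_features`` is the interactive endpoint: given raw values for the
model's input features (for the headline model: surgery duration, anesthesia
duration, NLR, CRP, serum creatinine, BMI and age) it applies the stored
normalization and returns the predicted recovery class and probability.
Inputs outside the documented physiologically plausible ranges are refused
unless explicitly overridden.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .learners import FittedModel, LearnerSpec
from .pipeline import CONTINUOUS_COLUMNS, PreprocessModel, apply_preprocess

__all__ = ["PLAUSIBLE_RANGES", "ModelArtifact", "save_artifact", "load_artifact"]

#: physiologically plausible input bounds for interactive prediction
PLAUSIBLE_RANGES = {
    "age": (18.0, 100.0),
    "bmi": (10.0, 60.0),
    "creatinine": (20.0, 400.0),
    "crp": (0.0, 300.0),
    "nlr": (0.1, 30.0),
    "alt": (1.0, 1000.0),
    "surgery_duration": (10.0, 900.0),
    "anesthesia_duration": (15.0, 960.0),
    "mean_hr": (30.0, 180.0),
    "mean_bp": (40.0, 160.0),
    "mean_rr": (6.0, 40.0),
}

MANIFEST_NAME = "manifest.json"
MODEL_NAME = "model.joblib"


@dataclass
class ModelArtifact:
    model: FittedModel
    preprocess: PreprocessModel
    selected_features: list[str]
    metadata: dict = field(default_factory=dict)

    def predict_proba_table(self, cohort_table: pd.DataFrame) -> np.ndarray:
        """Score raw cohort rows through the full stored pipeline."""
        matrix = apply_preprocess(self.preprocess, cohort_table)
        return self.model.predict_proba(matrix[self.selected_features].to_numpy())

    def predict_features(
        self,
        values: Mapping[str, float],
        threshold: float = 0.5,
        allow_out_of_range: bool = False,
    ) -> dict:
        """Score one patient from raw feature values (the interactive endpoint)."""
        missing = [f for f in self.selected_features if f not in values]
        if missing:
            raise ValueError(f"missing required inputs: {missing}")
        row = []
        warnings = []
        for f in self.selected_features:
            v = float(values[f])
            if f in PLAUSIBLE_RANGES:
                lo, hi = PLAUSIBLE_RANGES[f]
                if not lo <= v <= hi:
                    msg = f"{f} = {v} outside plausible range [{lo}, {hi}]"
                    if not allow_out_of_range:
                        raise ValueError(msg + " (pass allow_out_of_range to override)")
                    warnings.append(msg)
            if f in CONTINUOUS_COLUMNS:
                wlo, whi = self.preprocess.winsor_bounds[f]
                v = min(max(v, wlo), whi)
                v = (v - self.preprocess.means[f]) / self.preprocess.sds[f]
            row.append(v)
        prob = float(self.model.predict_proba(np.array(row)[None, :])[0])
        return {
            "probability_poor": prob,
            "predicted_class": "poor" if prob >= threshold else "good",
            "threshold": threshold,
            "warnings": warnings,
        }


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_artifact(artifact: ModelArtifact, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spec = artifact.model.spec
    manifest = {
        "format": "ibfoml-artifact-v1",
        "package_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "learner": {
            "learner_id": spec.learner_id,
            "hyperparameters": {k: v for k, v in spec.hyperparameters.items()},
            "seed": spec.seed,
        },
        "n_features": artifact.model.n_features,
        "selected_features": artifact.selected_features,
        "preprocess": artifact.preprocess.to_dict(),
        "metadata": dict(artifact.metadata),
    }
    manifest["config_digest"] = _digest(
        {k: manifest[k] for k in ("learner", "selected_features", "preprocess")}
    )
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, default=str))
    joblib.dump(artifact.model.estimator, path / MODEL_NAME)
    return path


def load_artifact(path: str | Path) -> ModelArtifact:
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no artifact manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "ibfoml-artifact-v1":
        raise ValueError("unrecognized artifact format")
    estimator = joblib.load(path / MODEL_NAME)
    lm = manifest["learner"]
    spec = LearnerSpec(lm["learner_id"], lm["hyperparameters"], seed=int(lm["seed"]))
    model = FittedModel(spec, estimator, int(manifest["n_features"]))
    return ModelArtifact(
        model=model,
        preprocess=PreprocessModel.from_dict(manifest["preprocess"]),
        selected_features=list(manifest["selected_features"]),
        metadata=dict(manifest.get("metadata", {})),
    )
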