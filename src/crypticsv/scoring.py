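"""Random-forest cluster classification (Score) and training (Train).

A binary random forest separates split-read clusters that mark real SV
junctions (tight position spread, high clip base quality, support tracking
depth) from technical artifacts (scattered low-quality clips, recurrent
clipping sites). The default operating point keeps a cluster when its score is
at least 0.5 AND it has >= 5 supporting split reads; the support floor mirrors
the low-support exclusion applied upstream of the published cohort analyses.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import __version__
from .clustering import FEATURE_NAMES, FeatureVector, SplitReadCluster

log = logging.getLogger(__name__)

LABEL_TRUE = "TRUE_VARIANT"
LABEL_ARTIFACT = "ARTIFACT"


@dataclass
class LabeledExample:
    features: FeatureVector
    label: str
    source_id: str = ""

    def __post_init__(self):
        if self.label not in (LABEL_TRUE, LABEL_ARTIFACT):
            raise ValueError(f"label must be {LABEL_TRUE} or {LABEL_ARTIFACT}")


@dataclass
class ModelArtifact:
    model: RandomForestClassifier
    feature_names: list
    training_seed: int
    version: str
    threshold_default: float
    metrics: dict = field(default_factory=dict)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Probability of the TRUE_VARIANT class per row."""
        idx = list(self.model.classes_).index(1)
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, idx]


def _examples_to_xy(examples):
    X = np.array([ex.features.as_array() for ex in examples], dtype=float)
    y = np.array([1 if ex.label == LABEL_TRUE else 0 for ex in examples], dtype=int)
    return X, y


def train_model(
    examples,
    seed: int,
    n_estimators: int = 500,
    max_features: str = "sqrt",
    max_depth=None,
    class_weight: str = "balanced",
    threshold_default: float = 0.5,
) -> ModelArtifact:
    """Fit a reproducible random forest on labeled cluster features.

    Out-of-bag accuracy is recorded in the artifact metrics and logged;
    training twice with the same (examples, seed, hyperparameters) yields
    identical predictions.
    """
    examples = list(examples)
    if len(examples) < 4:
        raise ValueError("need at least 2 examples of each class")
    X, y = _examples_to_xy(examples)
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("training data must contain >=2 examples of each class")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=max_features,
        max_depth=max_depth,
        class_weight=class_weight,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)
    metrics = {
        "oob_accuracy": float(clf.oob_score_),
        "n_examples": int(len(y)),
        "n_true": int((y == 1).sum()),
        "n_artifact": int((y == 0).sum()),
    }
    log.info("trained random forest: oob_accuracy=%.4f on %d examples", metrics["oob_accuracy"], len(y))
    return ModelArtifact(
        model=clf,
        feature_names=list(FEATURE_NAMES),
        training_seed=int(seed),
        version=__version__,
        threshold_default=float(threshold_default),
        metrics=metrics,
    )


def score_clusters(
    clusters,
    artifact: ModelArtifact,
    threshold: float | None = None,
    min_support: int = 5,
):
    """Score clusters and split into (retained, dropped_count).

    A cluster is retained iff score >= threshold AND support >= min_support.
    Every input cluster keeps its score regardless of retention.
    """
    clusters = list(clusters)
    if artifact.feature_names != list(FEATURE_NAMES):
        raise ValueError("model feature schema does not match FeatureVector contract")
    threshold = artifact.threshold_default if threshold is None else float(threshold)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not clusters:
        return [], 0
    X = np.array([c.features.as_array() for c in clusters], dtype=float)
    scores = artifact.predict_scores(X)
    retained = []
    for c, s in zip(clusters, scores):
        c.score = float(s)
        if s >= threshold and c.support >= min_support:
            retained.append(c)
    dropped = len(clusters) - len(retained)
    log.info("scored %d clusters: retained %d, dropped %d", len(clusters), len(retained), dropped)
    return retained, dropped


def save_model(artifact: ModelArtifact, path) -> None:
    """Persist the classifier plus a JSON sidecar with schema and provenance.

    The model is serialized, reloaded and serialized again before writing:
    one round-trip normalizes pickle's object-sharing memo so that
    save -> load -> save is bit-identical.
    """
    path = Path(path)
    canonical = pickle.loads(pickle.dumps(artifact.model, protocol=4))
    path.write_bytes(pickle.dumps(canonical, protocol=4))
    sidecar = {
        "feature_names": artifact.feature_names,
        "training_seed": artifact.training_seed,
        "version": artifact.version,
        "threshold_default": artifact.threshold_default,
        "metrics": artifact.metrics,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def load_model(path) -> ModelArtifact:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"model sidecar {sidecar_path} missing")
    meta = json.loads(sidecar_path.read_text())
    if meta["feature_names"] != list(FEATURE_NAMES):
        raise ValueError(
            "refusing to load model with mismatched feature schema: "
            f"{meta['feature_names']} != {FEATURE_NAMES}"
        )
    return ModelArtifact(
        model=pickle.loads(Path(path).read_bytes()),
        feature_names=meta["feature_names"],
        training_seed=meta["training_seed"],
        version=meta["version"],
        threshold_default=meta["threshold_default"],
        metrics=meta.get("metrics", {}),
    )
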