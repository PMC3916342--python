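"""Second-stage Random Forest over candidate object features.

The pixel stage is tuned for recall; this stage restores precision by
scoring each segmented candidate with a Random Forest (100 trees grown to
purity) trained on binary true/false synapse labels of candidate objects.
Candidates with score >= threshold (default 0.5) are accepted; raising the
threshold trades recall for precision monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .object_features import OBJECT_FEATURE_NAMES

__all__ = [
    "ObjectClassifier",
    "CandidateScore",
    "train_object_classifier",
    "classify_candidates",
    "save_object_classifier",
    "load_object_classifier",
]


@dataclass
class ObjectClassifier:
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators


@dataclass
class CandidateScore:
    """Score of one candidate: probability of being a true synapse."""

    candidate_id: int
    score: float
    accepted: bool
    touches_boundary: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")


def _as_matrix(features, feature_names) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return features[list(feature_names)].to_numpy(dtype=np.float64)
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError(
            f"feature matrix must have {len(feature_names)} columns, got shape {X.shape}"
        )
    return X


def train_object_classifier(
    features,
    labels,
    n_trees: int = 100,
    seed: int = 0,
    feature_names: tuple[str, ...] = OBJECT_FEATURE_NAMES,
) -> ObjectClassifier:
    """Train the object-level forest on labeled candidates.

    ``labels`` is a boolean array (True = true synapse); both classes must be
    present.  Trees are grown to purity, so the forest memorizes separable
    training sets; deterministic given ``seed``.
    """
    X = _as_matrix(features, feature_names)
    y = np.asarray(labels, dtype=bool)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must match feature rows")
    if y.all() or not y.any():
        raise ValueError("need both true and false candidate labels")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y.astype(int))
    return ObjectClassifier(forest, tuple(feature_names))


def classify_candidates(
    clf: ObjectClassifier,
    features,
    threshold: float = 0.5,
    candidate_ids=None,
    touches_boundary=None,
) -> list[CandidateScore]:
    """Score candidates and accept those with score >= threshold.

    Candidates crossing a volume boundary plane can be flagged via
    ``touches_boundary``; they are scored normally but carry the flag in the
    output (training annotators avoid such objects, so their scores are less
    reliable).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    X = _as_matrix(features, clf.feature_names)
    pos = int(np.where(clf.forest.classes_ == 1)[0][0])
    scores = clf.forest.predict_proba(X)[:, pos]
    if candidate_ids is None:
        candidate_ids = np.arange(len(scores))
    if touches_boundary is None:
        touches_boundary = np.zeros(len(scores), dtype=bool)
    return [
        CandidateScore(int(cid), float(s), bool(s >= threshold), bool(tb))
        for cid, s, tb in zip(candidate_ids, scores, touches_boundary)
    ]


def save_object_classifier(clf: ObjectClassifier, path) -> None:
    joblib.dump({"forest": clf.forest, "feature_names": clf.feature_names}, path)


def load_object_classifier(path) -> ObjectClassifier:
    d = joblib.load(path)
    return ObjectClassifier(d["forest"], tuple(d["feature_names"]))
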