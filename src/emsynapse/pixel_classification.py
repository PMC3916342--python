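"""Sparse-label Random Forest pixel classification.

A three-class Random Forest (synapse / membrane / other) is trained on the
feature vectors of a sparse set of annotated voxels — a fully annotated
subvolume is never required — and applied to every voxel to produce a
probability map.  The out-of-bag error of the forest is recorded as the
standard generalization estimate used to decide when enough labels have been
provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .filters import FeatureStack
from .volume import CLASS_NAMES, ProbabilityMap

__all__ = [
    "SparseLabels",
    "PixelClassifier",
    "train_pixel_classifier",
    "predict_probabilities",
    "save_pixel_classifier",
    "load_pixel_classifier",
]

logger = logging.getLogger(__name__)


@dataclass
class SparseLabels:
    """Sparse voxel annotations: coordinates (z, y, x) and class ids.

    ``class_ids`` index into ``class_names`` (default synapse, membrane,
    other).  Duplicate coordinates with conflicting classes are rejected.
    """

    coordinates: np.ndarray  # (n, 3) int
    class_ids: np.ndarray  # (n,) int
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=np.intp))
        self.class_ids = np.asarray(self.class_ids, dtype=np.intp)
        self.class_names = tuple(self.class_names)
        if self.coordinates.shape != (len(self.class_ids), 3):
            raise ValueError("coordinates must be (n, 3) matching class_ids")
        if len(self.class_ids) and (
            self.class_ids.min() < 0 or self.class_ids.max() >= len(self.class_names)
        ):
            raise ValueError("class_ids out of range")
        # conflicting duplicates are annotation errors, not ties to resolve
        df = pd.DataFrame(self.coordinates, columns=["z", "y", "x"])
        df["c"] = self.class_ids
        nunique = df.groupby(["z", "y", "x"])["c"].nunique()
        if (nunique > 1).any():
            bad = nunique[nunique > 1].index[0]
            raise ValueError(f"conflicting labels at voxel {tuple(bad)}")

    def check_bounds(self, shape: tuple[int, int, int]) -> None:
        if len(self.class_ids) == 0:
            return
        if (self.coordinates < 0).any() or (self.coordinates >= np.asarray(shape)).any():
            raise ValueError("label coordinates outside volume bounds")

    @classmethod
    def from_label_volume(
        cls, labels: np.ndarray, class_names: tuple[str, ...] = CLASS_NAMES
    ) -> "SparseLabels":
        """Build sparse labels from a dense label grid (0 = unlabeled,
        class ids numbered from 1)."""
        labels = np.asarray(labels)
        coords = np.argwhere(labels > 0)
        ids = labels[labels > 0].astype(np.intp) - 1
        return cls(coords, ids, class_names)

    @classmethod
    def from_csv(cls, path, class_names: tuple[str, ...] = CLASS_NAMES) -> "SparseLabels":
        """Read labels from CSV with columns z, y, x, class (name or id)."""
        df = pd.read_csv(path)
        cls_col = df["class"]
        if cls_col.dtype == object:
            ids = cls_col.map({n: i for i, n in enumerate(class_names)})
            if ids.isna().any():
                raise ValueError(f"unknown class name in {path}")
            ids = ids.to_numpy(dtype=np.intp)
        else:
            ids = cls_col.to_numpy(dtype=np.intp)
        return cls(df[["z", "y", "x"]].to_numpy(), ids, class_names)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.coordinates, columns=["z", "y", "x"])
        df["class"] = [self.class_names[i] for i in self.class_ids]
        df.to_csv(path, index=False)


@dataclass
class PixelClassifier:
    """A trained pixel-level forest plus the metadata needed to apply it."""

    forest: RandomForestClassifier
    channel_names: tuple[str, ...]
    class_names: tuple[str, ...]
    oob_error: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.oob_error <= 1.0:
            raise ValueError("oob_error must be in [0, 1]")

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators


def train_pixel_classifier(
    fs: FeatureStack,
    labels: SparseLabels,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifier:
    """Train the three-class forest on the labeled voxels' feature vectors.

    Trees are grown to purity with sqrt(n_features) candidate features per
    split.  Training is deterministic given ``seed``.  Every class must have
    at least one label.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    labels.check_bounds(fs.data.shape[1:])
    counts = np.bincount(labels.class_ids, minlength=len(labels.class_names))
    for name, c in zip(labels.class_names, counts):
        if c == 0:
            raise ValueError(f"class {name!r} has no labels")
    z, y, x = labels.coordinates.T
    X = fs.data[:, z, y, x].T.astype(np.float64)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, labels.class_ids)
    oob_error = float(1.0 - forest.oob_score_)
    logger.info(
        "pixel classifier: %d labels, %d trees, OOB error %.3f", len(X), n_trees, oob_error
    )
    return PixelClassifier(forest, fs.channel_names, labels.class_names, oob_error)


def predict_probabilities(
    clf: PixelClassifier, fs: FeatureStack, voxel_size=(1.0, 1.0, 1.0)
) -> ProbabilityMap:
    """Per-voxel class probabilities from the forest's normalized tree votes."""
    if tuple(fs.channel_names) != tuple(clf.channel_names):
        raise ValueError("feature channels do not match the classifier's training channels")
    X = fs.as_matrix()
    proba = clf.forest.predict_proba(X)
    # map forest class order back to the fixed (synapse, membrane, other) order
    full = np.zeros((X.shape[0], len(clf.class_names)), dtype=np.float32)
    for j, cid in enumerate(clf.forest.classes_):
        full[:, int(cid)] = proba[:, j]
    grid = full.T.reshape((len(clf.class_names),) + fs.data.shape[1:])
    return ProbabilityMap(grid, voxel_size, clf.class_names)


def save_pixel_classifier(clf: PixelClassifier, path) -> None:
    joblib.dump(
        {
            "forest": clf.forest,
            "channel_names": clf.channel_names,
            "class_names": clf.class_names,
            "oob_error": clf.oob_error,
        },
        path,
    )


def load_pixel_classifier(path) -> PixelClassifier:
    d = joblib.load(path)
    return PixelClassifier(d["forest"], tuple(d["channel_names"]), tuple(d["class_names"]), d["oob_error"])
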