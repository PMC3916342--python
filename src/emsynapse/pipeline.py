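"""End-to-end detection pipeline and blockwise processing.

Stages: z-upsample by 2 → 3D filter bank → Random-Forest pixel
probabilities (evaluated at native sections) → threshold/components/size
filter → per-box Ising graph cut → object features → object-level Random
Forest → accepted synapses.  One top-level seed drives every source of
randomness.

Synapses are sparse and spatially limited, so the whole pipeline runs
blockwise: the volume is tiled laterally, each block is processed with a
500 nm halo on every side (enough context for filters, detection boxes and
neighborhoods), and a candidate is owned by the block whose core contains
its centroid.  On volumes whose objects are smaller than the halo the
blockwise result equals the whole-volume run.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import detection
from .detection import detect_candidates
from .filters import FeatureConfig, compute_feature_stack
from .graphcut import calibrate_beta, segment_graphcut
from .object_classification import (
    CandidateScore,
    ObjectClassifier,
    classify_candidates,
    train_object_classifier,
)
from .object_features import (
    OBJECT_FEATURE_NAMES,
    NeighborhoodSpec,
    compute_object_features,
)
from .phantom import (
    PhantomTruth,
    ProbabilityPhantomSpec,
    generate_probability_phantom,
    sample_sparse_labels,
)
from .pixel_classification import (
    PixelClassifier,
    SparseLabels,
    predict_probabilities,
    train_pixel_classifier,
)
from .volume import AnisotropicVolume, ProbabilityMap, upsample_z
from skimage.measure import label as cc_label

__all__ = [
    "PipelineConfig",
    "Candidate",
    "TrainedDetector",
    "PipelineResult",
    "compute_probability_map",
    "segment_candidates",
    "candidate_features",
    "label_candidates_from_truth",
    "train_pipeline",
    "run_pipeline",
    "blockwise_process",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the detection pipeline, serializable to YAML."""

    voxel_size: tuple[float, float, float] = (45.0, 4.5, 4.5)
    upsample_factor: int = 2
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    pixel_n_trees: int = 50
    object_n_trees: int = 100
    label_budget: int = 300
    detection_threshold: float = detection.DEFAULT_THRESHOLD
    connectivity: int = 26
    min_size: int = detection.DEFAULT_MIN_SIZE
    max_size: int = detection.DEFAULT_MAX_SIZE
    halo_nm: float = detection.DEFAULT_HALO_NM
    beta: float | None = None  # None -> calibrated on probability phantoms
    beta_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0)
    object_threshold: float = 0.5
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    seed: int = 0
    version: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in (0, 1)")
        if not 0 <= self.object_threshold <= 1:
            raise ValueError("object_threshold must be in [0, 1]")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.min_size > self.max_size:
            raise ValueError("min_size exceeds max_size")
        if self.halo_nm < 0:
            raise ValueError("halo_nm must be >= 0")

    def to_yaml(self, path) -> None:
        d = {
            "version": self.version,
            "voxel_size": list(self.voxel_size),
            "upsample_factor": self.upsample_factor,
            "feature_sigmas": {k: list(v) for k, v in self.feature_config.sigmas.items()},
            "pixel_n_trees": self.pixel_n_trees,
            "object_n_trees": self.object_n_trees,
            "label_budget": self.label_budget,
            "detection_threshold": self.detection_threshold,
            "connectivity": self.connectivity,
            "min_size": self.min_size,
            "max_size": self.max_size,
            "halo_nm": self.halo_nm,
            "beta": self.beta,
            "beta_grid": list(self.beta_grid),
            "object_threshold": self.object_threshold,
            "neighborhood_radii_xyz": list(self.neighborhood.radii),
            "seed": self.seed,
        }
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        kwargs = dict(
            voxel_size=tuple(d.get("voxel_size", (45.0, 4.5, 4.5))),
            upsample_factor=d.get("upsample_factor", 2),
            pixel_n_trees=d.get("pixel_n_trees", 100),
            object_n_trees=d.get("object_n_trees", 100),
            label_budget=d.get("label_budget", 300),
            detection_threshold=d.get("detection_threshold", 0.5),
            connectivity=d.get("connectivity", 26),
            min_size=d.get("min_size", 100),
            max_size=d.get("max_size", 1_000_000),
            halo_nm=d.get("halo_nm", 500.0),
            beta=d.get("beta"),
            beta_grid=tuple(d.get("beta_grid", (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0))),
            object_threshold=d.get("object_threshold", 0.5),
            seed=d.get("seed", 0),
        )
        if "feature_sigmas" in d:
            kwargs["feature_config"] = FeatureConfig(
                {k: tuple(v) for k, v in d["feature_sigmas"].items()}
            )
        if "neighborhood_radii_xyz" in d:
            kwargs["neighborhood"] = NeighborhoodSpec(tuple(d["neighborhood_radii_xyz"]))
        return cls(**kwargs)


@dataclass
class Candidate:
    """One segmented synapse candidate.

    ``mask`` is a boolean crop located at ``origin`` (z, y, x) in volume
    coordinates; ``component_id`` is the detection component that seeded it.
    """

    candidate_id: int
    component_id: int
    mask: np.ndarray
    origin: tuple[int, int, int]
    centroid: tuple[float, float, float]
    voxel_count: int
    touches_boundary: bool = False

    def global_coords(self) -> np.ndarray:
        return np.argwhere(self.mask) + np.asarray(self.origin)


@dataclass
class TrainedDetector:
    """The pixel and object classifiers plus the calibrated Ising constant."""

    pixel_classifier: PixelClassifier
    object_classifier: ObjectClassifier | None
    beta: float


@dataclass
class PipelineResult:
    probability_map: ProbabilityMap
    candidates: list[Candidate]
    features: pd.DataFrame
    scores: list[CandidateScore]
    stage_log: dict

    @property
    def accepted(self) -> list[Candidate]:
        ok = {s.candidate_id for s in self.scores if s.accepted}
        return [c for c in self.candidates if c.candidate_id in ok]

    def accepted_centroids(self) -> np.ndarray:
        return np.asarray([c.centroid for c in self.accepted]).reshape(-1, 3)


def _native_slice_indices(n_z: int, factor: int) -> np.ndarray:
    return np.arange(n_z) * factor


def native_feature_stack(volume: AnisotropicVolume, cfg: PipelineConfig):
    """Filter bank on the z-upsampled grid, assembled at native sections.

    Filters run on the upsampled grid (so they see the interpolated
    context), but channels are stored only at the slices that survive
    downsampling back to native sections — identical to computing
    everywhere and downsampling, at half the cost.
    """
    up = upsample_z(volume, cfg.upsample_factor)
    native = _native_slice_indices(volume.shape[0], cfg.upsample_factor)
    return compute_feature_stack(up, cfg.feature_config, z_slices=native)


def compute_probability_map(
    volume: AnisotropicVolume,
    pixel_clf: PixelClassifier,
    cfg: PipelineConfig,
) -> ProbabilityMap:
    """Upsample, filter, classify; returns probabilities on the native grid."""
    fs = native_feature_stack(volume, cfg)
    return predict_probabilities(pixel_clf, fs, volume.voxel_size)


def train_pixel_stage(
    volume: AnisotropicVolume,
    labels: SparseLabels,
    cfg: PipelineConfig,
) -> PixelClassifier:
    """Train the pixel classifier from sparse labels on the native grid."""
    fs = native_feature_stack(volume, cfg)
    return train_pixel_classifier(fs, labels, cfg.pixel_n_trees, cfg.seed)


def segment_candidates(
    pmap: ProbabilityMap,
    beta: float,
    cfg: PipelineConfig,
) -> list[Candidate]:
    """Detect components and segment each one by graph cut in its enlarged box.

    The graph-cut mask is restricted to its connected components that
    overlap the seeding detection component; candidates whose restricted
    mask is empty are dropped.
    """
    labeled, table = detect_candidates(
        pmap,
        threshold=cfg.detection_threshold,
        connectivity=cfg.connectivity,
        min_size=cfg.min_size,
        max_size=cfg.max_size,
        halo_nm=cfg.halo_nm,
    )
    p_syn = pmap.class_probability("synapse")
    shape = p_syn.shape
    candidates: list[Candidate] = []
    next_id = 0
    conn = {6: 1, 18: 2, 26: 3}[cfg.connectivity]
    for row in table.itertuples(index=False):
        sl = (
            slice(row.ez0, row.ez1),
            slice(row.ey0, row.ey1),
            slice(row.ex0, row.ex1),
        )
        crop_p = p_syn[sl]
        gc_mask = segment_graphcut(crop_p, beta)
        if not gc_mask.any():
            continue
        seed_mask = labeled[sl] == row.component_id
        pieces = cc_label(gc_mask, connectivity=conn)
        keep = np.unique(pieces[seed_mask & gc_mask])
        keep = keep[keep > 0]
        if keep.size == 0:
            continue
        mask = np.isin(pieces, keep)
        origin = (row.ez0, row.ey0, row.ex0)
        coords = np.argwhere(mask) + np.asarray(origin)
        centroid = tuple(coords.mean(axis=0))
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        touches = bool((lo == 0).any() or (hi == np.asarray(shape)).any())
        candidates.append(
            Candidate(
                candidate_id=next_id,
                component_id=int(row.component_id),
                mask=mask,
                origin=origin,
                centroid=centroid,
                voxel_count=int(mask.sum()),
                touches_boundary=touches,
            )
        )
        next_id += 1
    return candidates


def candidate_features(
    volume: AnisotropicVolume,
    candidates: list[Candidate],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """The 29 object features per candidate, as a DataFrame keyed by id."""
    rows = [
        compute_object_features(volume, c.mask, c.origin, cfg.neighborhood)
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=list(OBJECT_FEATURE_NAMES))
    df.insert(0, "candidate_id", [c.candidate_id for c in candidates])
    return df


def label_candidates_from_truth(
    candidates: list[Candidate], truth: PhantomTruth
) -> np.ndarray:
    """Boolean candidate labels: True iff the mask overlaps a true synapse."""
    out = np.zeros(len(candidates), dtype=bool)
    for i, c in enumerate(candidates):
        sl = tuple(
            slice(o, o + s) for o, s in zip(c.origin, c.mask.shape)
        )
        out[i] = bool((truth.synapse_labels[sl][c.mask] > 0).any())
    return out


def calibrate_beta_on_phantoms(cfg: PipelineConfig, n_phantoms: int = 4) -> float:
    """Default Ising constant: Jaccard grid search on probability phantoms.

    Stands in for the manual segmentation of a handful of synapses: noisy
    probability phantoms are generated and the beta maximizing the mean
    Jaccard index against their truth masks is selected from the grid.
    """
    crops, masks = [], []
    for i in range(n_phantoms):
        pspec = ProbabilityPhantomSpec(noise=0.15, seed=cfg.seed * 1000 + i)
        pmap, truth = generate_probability_phantom(pspec)
        crops.append(pmap.class_probability("synapse"))
        masks.append(truth.synapse_labels > 0)
    return calibrate_beta(crops, masks, list(cfg.beta_grid))


def train_pipeline(
    volume: AnisotropicVolume,
    truth: PhantomTruth,
    cfg: PipelineConfig,
) -> TrainedDetector:
    """Train both classifiers (and calibrate beta) on one annotated volume.

    Sparse pixel labels are sampled from the truth the way an annotator
    would scribble them; candidates segmented on the training volume are
    labeled true/false by overlap with the truth masks and train the object
    stage.
    """
    labels = sample_sparse_labels(truth, cfg.label_budget, seed=cfg.seed + 2)
    t0 = time.time()
    fs = native_feature_stack(volume, cfg)
    pixel_clf = train_pixel_classifier(fs, labels, cfg.pixel_n_trees, cfg.seed)
    logger.info("pixel stage trained in %.1fs (OOB error %.3f)", time.time() - t0, pixel_clf.oob_error)

    beta = cfg.beta if cfg.beta is not None else calibrate_beta_on_phantoms(cfg)
    logger.info("using Ising beta = %.3f", beta)

    pmap = predict_probabilities(pixel_clf, fs, volume.voxel_size)
    del fs
    candidates = segment_candidates(pmap, beta, cfg)
    if not candidates:
        raise RuntimeError("no candidates segmented on the training volume")
    y = label_candidates_from_truth(candidates, truth)
    if y.all() or not y.any():
        raise RuntimeError(
            "training volume produced single-class candidate labels; "
            "add distractors or synapses"
        )
    feats = candidate_features(volume, candidates, cfg)
    object_clf = train_object_classifier(
        feats[list(OBJECT_FEATURE_NAMES)], y, cfg.object_n_trees, cfg.seed + 1
    )
    return TrainedDetector(pixel_clf, object_clf, beta)


def run_pipeline(
    volume: AnisotropicVolume,
    detector: TrainedDetector,
    cfg: PipelineConfig,
) -> PipelineResult:
    """Apply the trained two-stage detector to a volume."""
    log: dict = {"shape": tuple(volume.shape)}
    t0 = time.time()
    pmap = compute_probability_map(volume, detector.pixel_classifier, cfg)
    log["t_pixel"] = time.time() - t0

    t0 = time.time()
    candidates = segment_candidates(pmap, detector.beta, cfg)
    log["t_segment"] = time.time() - t0
    log["n_candidates"] = len(candidates)

    t0 = time.time()
    if candidates:
        feats = candidate_features(volume, candidates, cfg)
        scores = classify_candidates(
            detector.object_classifier,
            feats[list(OBJECT_FEATURE_NAMES)],
            cfg.object_threshold,
            candidate_ids=[c.candidate_id for c in candidates],
            touches_boundary=[c.touches_boundary for c in candidates],
        )
    else:
        feats = pd.DataFrame(columns=["candidate_id", *OBJECT_FEATURE_NAMES])
        scores = []
    log["t_object"] = time.time() - t0
    log["n_accepted"] = sum(s.accepted for s in scores)
    logger.info(
        "pipeline: %d candidates, %d accepted (pixel %.1fs, segment %.1fs, object %.1fs)",
        log["n_candidates"], log["n_accepted"], log["t_pixel"], log["t_segment"], log["t_object"],
    )
    return PipelineResult(pmap, candidates, feats, scores, log)


def blockwise_process(
    volume: AnisotropicVolume,
    detector: TrainedDetector,
    cfg: PipelineConfig,
    block_shape: tuple[int, int],
) -> PipelineResult:
    """Process the volume in lateral blocks with a 500 nm halo per side.

    ``block_shape`` is the (y, x) core size in voxels; blocks span the full
    z extent (a z-split halo of 500 nm would not contain the largest filter
    support, the lateral one comfortably does).  Each block is processed
    independently on core+halo; a candidate is kept iff its centroid lies in
    the block core, so every object is reported exactly once.
    """
    n_z, n_y, n_x = volume.shape
    by, bx = block_shape
    halo_y = math.ceil(cfg.halo_nm / volume.voxel_size[1])
    halo_x = math.ceil(cfg.halo_nm / volume.voxel_size[2])
    if by <= 0 or bx <= 0 or by > n_y or bx > n_x:
        raise ValueError(f"block shape {block_shape} does not fit volume {volume.shape}")
    if halo_y > by or halo_x > bx:
        raise ValueError("halo larger than block core")

    all_cands: list[Candidate] = []
    all_feats: list[pd.DataFrame] = []
    all_scores: list[CandidateScore] = []
    log: dict = {"blocks": [], "shape": tuple(volume.shape)}
    next_id = 0
    for y0 in range(0, n_y, by):
        for x0 in range(0, n_x, bx):
            y1, x1 = min(y0 + by, n_y), min(x0 + bx, n_x)
            ey0, ey1 = max(y0 - halo_y, 0), min(y1 + halo_y, n_y)
            ex0, ex1 = max(x0 - halo_x, 0), min(x1 + halo_x, n_x)
            sub = AnisotropicVolume(
                np.ascontiguousarray(volume.data[:, ey0:ey1, ex0:ex1]),
                volume.voxel_size,
            )
            res = run_pipeline(sub, detector, cfg)
            offset = np.array([0, ey0, ex0])
            kept_ids = []
            for c in res.candidates:
                cz, cy, cx = np.asarray(c.centroid) + offset
                if y0 <= cy < y1 and x0 <= cx < x1:
                    kept_ids.append(c.candidate_id)
            id_map = {}
            for c in res.candidates:
                if c.candidate_id not in kept_ids:
                    continue
                id_map[c.candidate_id] = next_id
                coords = np.asarray(c.centroid) + offset
                all_cands.append(
                    replace(
                        c,
                        candidate_id=next_id,
                        origin=tuple(np.asarray(c.origin) + offset),
                        centroid=tuple(coords),
                    )
                )
                next_id += 1
            f = res.features[res.features["candidate_id"].isin(kept_ids)].copy()
            f["candidate_id"] = f["candidate_id"].map(id_map)
            all_feats.append(f)
            all_scores.extend(
                CandidateScore(id_map[s.candidate_id], s.score, s.accepted, s.touches_boundary)
                for s in res.scores
                if s.candidate_id in id_map
            )
            log["blocks"].append(
                {"core": (y0, x0, y1, x1), "n_candidates": len(res.candidates), "n_kept": len(kept_ids)}
            )
    feats = (
        pd.concat(all_feats, ignore_index=True)
        if all_feats
        else pd.DataFrame(columns=["candidate_id", *OBJECT_FEATURE_NAMES])
    )
    log["n_candidates"] = len(all_cands)
    log["n_accepted"] = sum(s.accepted for s in all_scores)
    # probability map of the last block only is not meaningful globally; omit
    empty_pmap = ProbabilityMap(
        np.zeros((3, 1, 1, 1)), volume.voxel_size
    )
    return PipelineResult(empty_pmap, all_cands, feats, all_scores, log)
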