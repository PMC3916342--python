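"""Detection evaluation and error-analysis morphometrics.

Accepted candidates are matched one-to-one against ground-truth synapse
point annotations (greedy, by increasing anisotropic distance, within a
tolerance); unmatched ground truth counts as false negatives and unmatched
candidates as false positives.  Both error fractions are normalized by the
number of ground-truth synapses.

The morphometrics quantify what makes a synapse hard to detect in
anisotropic stacks: mean cross-section area in xy (averaged over the 5
central slices), continuity in z (number of occupied slices), physical size
estimated from per-slice medial-axis skeletons, and perforation (slices
where the cross-section splits in two) — perforated synapses turn out to be
the easy ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import medial_axis

__all__ = [
    "GroundTruthAnnotation",
    "EvaluationReport",
    "match_detections",
    "mean_xy_area",
    "z_range",
    "skeleton_size",
    "perforation_count",
    "error_rates",
]

DEFAULT_MATCH_TOLERANCE_NM = 250.0


@dataclass
class GroundTruthAnnotation:
    """Ground-truth synapse locations as (z, y, x) voxel points."""

    points: np.ndarray  # (n, 3)
    annotators: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")

    @classmethod
    def from_csv(cls, path) -> "GroundTruthAnnotation":
        df = pd.read_csv(path)
        ann = df["annotator"].tolist() if "annotator" in df.columns else None
        return cls(df[["z", "y", "x"]].to_numpy(), ann)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class EvaluationReport:
    n_gt: int
    n_detected: int
    n_fn: int
    n_fp: int
    matches: dict[int, int | None]  # gt index -> candidate id or None
    morphometrics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        matched = sum(1 for v in self.matches.values() if v is not None)
        if self.n_fn != self.n_gt - matched:
            raise ValueError("inconsistent report: n_fn != n_gt - matched")


def _point_to_mask_distance(
    point: np.ndarray, coords_nm: np.ndarray, voxel_size: np.ndarray
) -> float:
    """Min anisotropic distance (nm) from a GT point to a candidate's voxels."""
    d = coords_nm - point * voxel_size
    return float(np.sqrt((d * d).sum(axis=1).min()))


def match_detections(
    candidates: dict[int, np.ndarray],
    gt: GroundTruthAnnotation,
    voxel_size: tuple[float, float, float],
    tolerance_nm: float = DEFAULT_MATCH_TOLERANCE_NM,
    candidate_origins: dict[int, tuple[int, int, int]] | None = None,
) -> EvaluationReport:
    """Greedy one-to-one matching of candidates to ground-truth points.

    A point matches a candidate if it lies inside the mask (distance 0) or
    within ``tolerance_nm`` of it in anisotropic physical distance.  Pairs
    are matched in order of increasing distance; each candidate and each
    point is used at most once.

    Parameters
    ----------
    candidates
        Mapping candidate_id -> boolean mask (full-volume or crop; crop
        origins go in ``candidate_origins``).
    """
    if tolerance_nm < 0:
        raise ValueError("tolerance_nm must be >= 0")
    vs = np.asarray(voxel_size, dtype=np.float64)
    origins = candidate_origins or {}
    coords_nm = {}
    for cid, mask in candidates.items():
        c = np.argwhere(np.asarray(mask, dtype=bool)).astype(np.float64)
        c += np.asarray(origins.get(cid, (0, 0, 0)), dtype=np.float64)
        coords_nm[cid] = c * vs

    pairs = []  # (distance, gt_index, candidate_id)
    for gi, point in enumerate(gt.points):
        for cid, cnm in coords_nm.items():
            if len(cnm) == 0:
                continue
            d = _point_to_mask_distance(point, cnm, vs)
            if d <= tolerance_nm:
                pairs.append((d, gi, cid))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    matches: dict[int, int | None] = {gi: None for gi in range(len(gt))}
    used_cands: set[int] = set()
    for d, gi, cid in pairs:
        if matches[gi] is None and cid not in used_cands:
            matches[gi] = cid
            used_cands.add(cid)
    n_matched = len(used_cands)
    return EvaluationReport(
        n_gt=len(gt),
        n_detected=len(candidates),
        n_fn=len(gt) - n_matched,
        n_fp=len(candidates) - n_matched,
        matches=matches,
    )


def _occupied_slices(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return np.flatnonzero(mask.any(axis=(1, 2)))


def mean_xy_area(mask: np.ndarray) -> float:
    """Mean in-slice voxel count over the 5 slices centered on the z midpoint.

    The center is the midpoint of the mask's z extent; masks spanning fewer
    than 5 slices use all their slices.  Slices within the selected window
    that happen to be empty contribute zero area.
    """
    mask = np.asarray(mask, dtype=bool)
    occ = _occupied_slices(mask)
    z0, z1 = occ[0], occ[-1]
    mid = (z0 + z1) // 2
    lo = max(mid - 2, z0)
    hi = min(mid + 2, z1)
    counts = mask[lo:hi + 1].sum(axis=(1, 2))
    return float(counts.mean())


def z_range(mask: np.ndarray) -> int:
    """Number of distinct slices containing mask voxels (occupancy, not span)."""
    return int(len(_occupied_slices(mask)))


def skeleton_size(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Synapse size from per-slice medial-axis skeletons, in nm².

    In each slice the 2D medial axis of the cross-section is extracted; its
    length (skeleton voxel count × lateral voxel size) is summed over slices
    and multiplied by the slice thickness.  This estimates the sheet area of
    the synaptic density.  Synapses lying parallel to the cutting plane are
    systematically underestimated (their cross-section is a patch, not a
    ridge).  The lateral size is taken as the mean of the y and x voxel
    sizes.
    """
    mask = np.asarray(mask, dtype=bool)
    occ = _occupied_slices(mask)
    z_nm, y_nm, x_nm = voxel_size
    lateral_nm = 0.5 * (y_nm + x_nm)
    total_length_nm = 0.0
    for z in occ:
        skel = medial_axis(mask[z])
        total_length_nm += float(skel.sum()) * lateral_nm
    return total_length_nm * z_nm


def perforation_count(mask: np.ndarray, *, at_least: bool = False) -> int:
    """Slices in which the 2D cross-section has exactly two components.

    A perforated synapse appears as two independent connected components
    (2D 8-connectivity) in some slices.  ``at_least=True`` counts slices with
    two *or more* components instead of exactly two.
    """
    mask = np.asarray(mask, dtype=bool)
    count = 0
    for z in range(mask.shape[0]):
        if not mask[z].any():
            continue
        n = int(cc_label(mask[z], connectivity=2).max())
        if n == 2 or (at_least and n > 2):
            count += 1
    return count


def error_rates(report: EvaluationReport) -> tuple[float, float]:
    """(FN fraction, FP fraction), both normalized by the ground-truth count."""
    if report.n_gt == 0:
        raise ValueError("error rates undefined for zero ground-truth synapses")
    return (report.n_fn / report.n_gt, report.n_fp / report.n_gt)
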