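"""Synapse candidate detection on probability maps.

The synapse-class probability map is thresholded at 0.5, connected components
are extracted and filtered by size (components below 100 or above 1e6 voxels
are discarded), and each surviving component's bounding box is enlarged by a
500 nm halo so it can be assumed to contain the full extent of the synapse.
Detection exists to limit the more expensive segmentation stage to regions
likely to contain synapses.

Component tables are pandas DataFrames with 0-based, half-open (z, y, x)
box coordinates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label

from .volume import ProbabilityMap

__all__ = [
    "threshold_probability",
    "connected_components",
    "filter_components_by_size",
    "enlarge_bounding_boxes",
    "detect_candidates",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_MAX_SIZE",
    "DEFAULT_HALO_NM",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_SIZE = 100
DEFAULT_MAX_SIZE = 1_000_000
DEFAULT_HALO_NM = 500.0

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}

BOX_COLUMNS = ["z0", "y0", "x0", "z1", "y1", "x1"]
ENLARGED_COLUMNS = ["ez0", "ey0", "ex0", "ez1", "ey1", "ex1"]


def threshold_probability(
    p: ProbabilityMap | np.ndarray, t: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Binary mask where the synapse-class probability strictly exceeds t."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    grid = p.class_probability("synapse") if isinstance(p, ProbabilityMap) else np.asarray(p)
    return grid > t


def connected_components(
    mask: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label connected true-regions and tabulate their size and bounding box.

    Returns the labeled grid (0 = background, components numbered from 1) and
    a table with columns component_id, voxel_count, z0..x1 (half-open).
    Connectivity is 6, 18 or 26; 26 is the default so that tilted synapses
    that touch only diagonally across the anisotropic z step stay connected.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    labeled = cc_label(np.asarray(mask, dtype=bool), connectivity=_CONNECTIVITY[connectivity])
    n = int(labeled.max())
    rows = []
    if n:
        counts = np.bincount(labeled.ravel(), minlength=n + 1)
        objects = ndimage.find_objects(labeled)
        for cid in range(1, n + 1):
            sl = objects[cid - 1]
            rows.append(
                (
                    cid,
                    int(counts[cid]),
                    sl[0].start, sl[1].start, sl[2].start,
                    sl[0].stop, sl[1].stop, sl[2].stop,
                )
            )
    table = pd.DataFrame(rows, columns=["component_id", "voxel_count"] + BOX_COLUMNS)
    return labeled, table


def filter_components_by_size(
    table: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> pd.DataFrame:
    """Keep components with min_size <= voxel_count <= max_size (inclusive).

    Bounds are inclusive: the defaults discard components of *less than* 100
    or *more than* 1e6 voxels.  Sizes refer to voxels of the native
    (non-upsampled) grid and are therefore resolution dependent.
    """
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} exceeds max_size {max_size}")
    keep = (table["voxel_count"] >= min_size) & (table["voxel_count"] <= max_size)
    return table[keep].reset_index(drop=True)


def enlarge_bounding_boxes(
    table: pd.DataFrame,
    halo_nm: float,
    voxel_size: tuple[float, float, float],
    volume_shape: tuple[int, int, int],
) -> pd.DataFrame:
    """Grow each bounding box by ceil(halo_nm / voxel_size) voxels per side.

    The halo (default 500 nm) is chosen so the enlarged box contains the full
    extent of the synapse around the detected core.  Boxes are clipped to the
    volume bounds.  Adds columns ez0..ex1.
    """
    if halo_nm < 0:
        raise ValueError("halo_nm must be >= 0")
    growth = [int(math.ceil(halo_nm / s)) for s in voxel_size]
    out = table.copy()
    for ax, (g, lim) in enumerate(zip(growth, volume_shape)):
        lo = (table[BOX_COLUMNS[ax]] - g).clip(lower=0)
        hi = (table[BOX_COLUMNS[ax + 3]] + g).clip(upper=lim)
        out[ENLARGED_COLUMNS[ax]] = lo
        out[ENLARGED_COLUMNS[ax + 3]] = hi
    return out


def detect_candidates(
    p: ProbabilityMap,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = 26,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    halo_nm: float = DEFAULT_HALO_NM,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold → components → size filter → enlarged boxes, in one call."""
    mask = threshold_probability(p, threshold)
    labeled, table = connected_components(mask, connectivity)
    table = filter_components_by_size(table, min_size, max_size)
    table = enlarge_bounding_boxes(table, halo_nm, p.voxel_size, labeled.shape)
    return labeled, table
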