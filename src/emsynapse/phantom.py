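"""Synthetic phantom volumes with ground truth.

The phantom generator emulates the *appearance statistics* that the
detection pipeline keys on, not EM physics.  A chemical synapse in ssTEM
shows up as a dark, slightly curved sheet (the apposed thickened membranes
and cleft, ~50 nm across, 200-800 nm in extent) with a cloud of dark
vesicle-sized speckles on the presynaptic side.  The phantom plants such
sheets at random orientations — including the hard low-angle-to-cutting-
plane cases — into a textured background, together with two distractor
classes that share the darkness but not the full signature:

* membrane-like sheets: thinner, lighter, no vesicle speckle;
* mitochondrion-like blobs: dark ellipsoids with internal stripe texture.

All geometry is specified in nanometres and voxelized onto the anisotropic
grid; all randomness derives from one seed.  Truth masks are pairwise
disjoint and record exactly the generating geometry.

A second generator produces *probability* phantoms directly — synthetic
synapse-probability maps with optional thin high-probability protrusions
and sub-threshold bridges — to exercise the segmentation stage in
isolation from the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CLASS_NAMES, AnisotropicVolume, ProbabilityMap
from .evaluation import GroundTruthAnnotation
from .pixel_classification import SparseLabels

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ProbabilityPhantomSpec",
    "generate_phantom",
    "generate_probability_phantom",
    "sample_sparse_labels",
    "phantom_gt_points",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for a phantom volume.

    Geometry ranges are in nanometres.  ``flat_fraction`` is the probability
    that a synapse sheet lies at a low angle to the cutting plane (the
    hard-to-detect orientation); other sheets are tilted steeply enough to
    cross several sections.
    """

    shape: tuple[int, int, int] = (30, 512, 512)
    voxel_size: tuple[float, float, float] = (45.0, 4.5, 4.5)
    n_synapses: int = 20
    synapse_extent_nm: tuple[float, float] = (200.0, 800.0)
    synapse_thickness_nm: float = 50.0
    flat_fraction: float = 0.15
    curvature_fraction: float = 0.15
    vesicle_radius_nm: float = 22.0
    n_membranes: int = 8
    membrane_extent_nm: tuple[float, float] = (250.0, 700.0)
    membrane_thickness_nm: float = 35.0
    n_blobs: int = 6
    blob_axis_nm: tuple[float, float] = (150.0, 400.0)
    background_mean: float = 160.0
    background_texture_sd: float = 6.0
    synapse_darkening: float = 90.0
    vesicle_darkening: float = 45.0
    membrane_darkening: float = 80.0
    blob_darkening: float = 60.0
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1 or self.n_synapses < 0:
            raise ValueError("invalid phantom spec")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: per-synapse masks and distractor masks."""

    synapse_labels: np.ndarray  # int grid, 0 = none, synapses numbered from 1
    centroids: np.ndarray  # (n_synapses, 3) voxel coordinates (z, y, x)
    membrane_mask: np.ndarray = field(default=None)
    blob_mask: np.ndarray = field(default=None)
    vesicle_mask: np.ndarray = field(default=None)

    @property
    def n_synapses(self) -> int:
        return len(self.centroids)

    def synapse_mask(self, i: int) -> np.ndarray:
        """Boolean mask of synapse ``i`` (0-based)."""
        return self.synapse_labels == i + 1


def _random_unit_vector(rng: np.random.Generator, polar_range: tuple[float, float]) -> np.ndarray:
    """Unit vector (z, y, x) with polar angle from +z uniform in ``polar_range``."""
    theta = rng.uniform(*polar_range)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)])


def _sheet_mask_local(
    grids_nm: tuple[np.ndarray, np.ndarray, np.ndarray],
    normal: np.ndarray,
    diameter_nm: float,
    thickness_nm: float,
    bow_nm: float,
) -> np.ndarray:
    """Voxel-center membership in a bowed disc: |u - bow*(rho/R)^2| <= t/2, rho <= R."""
    z, y, x = grids_nm
    u = z * normal[0] + y * normal[1] + x * normal[2]
    r2 = z * z + y * y + x * x
    rho2 = np.clip(r2 - u * u, 0.0, None)
    R = diameter_nm / 2.0
    sag = bow_nm * rho2 / (R * R)
    return (np.abs(u - sag) <= thickness_nm / 2.0) & (rho2 <= R * R)


class _Placer:
    """Places objects by rejection sampling against an occupancy grid.

    Sheets are thin, so bounding-sphere exclusion would be hopelessly
    conservative; instead each painted object is recorded in an occupancy
    grid dilated by a small guard (1 slice in z, 3 px laterally) and a new
    object is accepted only if its voxel mask avoids that grid.  This keeps
    all truth masks pairwise disjoint and non-touching.
    """

    _GUARD = np.ones((3, 7, 7), dtype=bool)

    def __init__(self, shape, voxel_size, rng, max_tries: int = 2000):
        self.shape = np.asarray(shape)
        self.voxel_size = np.asarray(voxel_size, dtype=np.float64)
        self.extent_nm = self.shape * self.voxel_size
        self.rng = rng
        self.max_tries = max_tries
        self.occupied = np.zeros(tuple(shape), dtype=bool)

    def place(
        self,
        lat_half_nm: float,
        z_half_nm: float,
        bound_radius_nm: float,
        member_fn,
        kind: str,
    ) -> tuple[np.ndarray, np.ndarray, tuple[slice, ...]]:
        """Sample a center, voxelize ``member_fn`` there, and claim the voxels."""
        margin = np.array([z_half_nm + 50.0, lat_half_nm + 30.0, lat_half_nm + 30.0])
        lo, hi = margin, self.extent_nm - margin
        if (lo >= hi).any():
            raise ValueError(f"{kind} does not fit the volume with margins {margin}")
        for _ in range(self.max_tries):
            center = self.rng.uniform(lo, hi)
            # cheap strided pre-check before the full-resolution paint
            if self._collides_coarse(center, bound_radius_nm, member_fn):
                continue
            local, sl = _paint(self.occupied, center, bound_radius_nm, self.voxel_size, member_fn)
            if local.sum() == 0:
                continue
            if self.occupied[sl][local].any():
                continue
            guarded = ndimage.maximum_filter(local, size=self._GUARD.shape)
            self.occupied[sl] |= guarded
            return center, local, sl
        raise RuntimeError(
            f"could not place {kind} after {self.max_tries} tries; "
            "reduce object counts or sizes"
        )

    def _collides_coarse(self, center_nm, radius_nm, member_fn, stride=(1, 4, 4)) -> bool:
        """Membership test on a decimated grid; True if any hit is occupied."""
        lo = np.maximum(np.floor((center_nm - radius_nm) / self.voxel_size).astype(int), 0)
        hi = np.minimum(
            np.ceil((center_nm + radius_nm) / self.voxel_size).astype(int) + 1, self.shape
        )
        zi = np.arange(lo[0], hi[0], stride[0])
        yi = np.arange(lo[1], hi[1], stride[1])
        xi = np.arange(lo[2], hi[2], stride[2])
        g = (
            (zi * self.voxel_size[0] - center_nm[0])[:, None, None],
            (yi * self.voxel_size[1] - center_nm[1])[None, :, None],
            (xi * self.voxel_size[2] - center_nm[2])[None, None, :],
        )
        local = member_fn(g)
        sub = self.occupied[np.ix_(zi, yi, xi)]
        return bool(sub[local].any())


def _paint(
    grid_mask: np.ndarray,
    center_nm: np.ndarray,
    radius_nm: float,
    voxel_size: np.ndarray,
    member_fn,
) -> tuple[np.ndarray, tuple[slice, ...]]:
    """Evaluate ``member_fn`` on voxel centers within a local bounding box.

    Returns the local boolean mask and the slices locating it in the volume.
    ``member_fn`` receives three broadcastable coordinate grids (z, y, x) in
    nm relative to the center.
    """
    shape = np.asarray(grid_mask.shape)
    lo = np.maximum(np.floor((center_nm - radius_nm) / voxel_size).astype(int), 0)
    hi = np.minimum(np.ceil((center_nm + radius_nm) / voxel_size).astype(int) + 1, shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    z = (np.arange(lo[0], hi[0]) * voxel_size[0] - center_nm[0])[:, None, None]
    y = (np.arange(lo[1], hi[1]) * voxel_size[1] - center_nm[1])[None, :, None]
    x = (np.arange(lo[2], hi[2]) * voxel_size[2] - center_nm[2])[None, None, :]
    local = member_fn((z, y, x))
    return local, sl


def generate_phantom(spec: PhantomSpec) -> tuple[AnisotropicVolume, PhantomTruth]:
    """Generate a phantom EM volume and its ground truth.

    Deterministic given ``spec.seed``.  Raises if the requested objects
    cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    vs = np.asarray(spec.voxel_size, dtype=np.float64)
    shape = spec.shape
    placer = _Placer(shape, vs, rng)

    synapse_labels = np.zeros(shape, dtype=np.int16)
    membrane_mask = np.zeros(shape, dtype=bool)
    blob_mask = np.zeros(shape, dtype=bool)
    vesicle_mask = np.zeros(shape, dtype=bool)

    steep = (np.deg2rad(25.0), np.deg2rad(65.0))
    flat = (0.0, np.deg2rad(15.0))

    # Sample every object's geometry up-front, then place largest-first:
    # big tilted sheets compete for the mid-volume z band and must go in
    # before smaller objects fragment the free space.
    t_syn = spec.synapse_thickness_nm
    t_mem = spec.membrane_thickness_nm
    objects = []  # (bound_radius_nm, kind, index, params)
    syn_count = 0
    for _ in range(spec.n_synapses):
        d = rng.uniform(*spec.synapse_extent_nm)
        normal = _random_unit_vector(rng, flat if rng.random() < spec.flat_fraction else steep)
        bow = spec.curvature_fraction * d / 2.0
        objects.append((d / 2.0 + t_syn + bow, "synapse", syn_count, (d, normal, t_syn, bow)))
        syn_count += 1
    for i in range(spec.n_membranes):
        d = rng.uniform(*spec.membrane_extent_nm)
        normal = _random_unit_vector(rng, steep)
        bow = spec.curvature_fraction * d / 2.0
        objects.append((d / 2.0 + t_mem + bow, "membrane", i, (d, normal, t_mem, bow)))
    for i in range(spec.n_blobs):
        axes = np.sort(rng.uniform(*spec.blob_axis_nm, size=3))[::-1] / 2.0
        normal = _random_unit_vector(rng, steep)
        objects.append((axes[0], "blob", i, (axes, normal)))
    objects.sort(key=lambda o: (-o[0], o[1], o[2]))

    centroids = [None] * spec.n_synapses
    next_label = 1
    for bound, kind, idx, params in objects:
        if kind in ("synapse", "membrane"):
            d, normal, t, bow = params
            R = d / 2.0
            sin_theta = float(np.sqrt(1.0 - normal[0] ** 2))  # tilt of the sheet plane
            z_half = R * sin_theta + t / 2.0 + bow + 30.0
            center, local, sl = placer.place(
                bound, z_half, bound,
                lambda g: _sheet_mask_local(g, normal, d, t, bow),
                f"{kind} {idx}",
            )
            if kind == "membrane":
                membrane_mask[sl] |= local
                continue
            label = next_label
            next_label += 1
            synapse_labels[sl][local] = label
            centroids[label - 1] = np.argwhere(synapse_labels == label).mean(axis=0)
            # one-sided vesicle speckle: dark spheres clustered presynaptically
            n_ves = max(4, int(np.pi * (0.8 * R) ** 2 / 9000.0))
            for _ in range(n_ves):
                rho = R * 0.85 * np.sqrt(rng.random())
                ang = rng.uniform(0, 2 * np.pi)
                e1 = np.zeros(3)
                e1[np.argmin(np.abs(normal))] = 1.0
                e1 -= normal * (e1 @ normal)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(normal, e1)
                off = t / 2.0 + rng.uniform(15.0, 130.0)
                vc = center + normal * off + e1 * rho * np.cos(ang) + e2 * rho * np.sin(ang)
                vr = spec.vesicle_radius_nm
                if ((vc - vr < 0) | (vc + vr > placer.extent_nm)).any():
                    continue
                vloc, vsl = _paint(
                    vesicle_mask, vc, vr, vs,
                    lambda g: g[0] ** 2 + g[1] ** 2 + g[2] ** 2 <= vr * vr,
                )
                # vesicles darken the image but never invade another object's mask
                vloc &= ~(synapse_labels[vsl] > 0)
                vesicle_mask[vsl] |= vloc
        else:
            axes, normal = params
            e1 = np.zeros(3)
            e1[np.argmin(np.abs(normal))] = 1.0
            e1 -= normal * (e1 @ normal)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(normal, e1)
            B = np.stack([normal, e1, e2])  # rows: principal directions

            def _ellipsoid(g, B=B, axes=axes):
                z, y, x = g
                out = None
                for k in range(3):
                    q = (z * B[k, 0] + y * B[k, 1] + x * B[k, 2]) / axes[k]
                    out = q * q if out is None else out + q * q
                return out <= 1.0

            _, local, sl = placer.place(axes[0], axes[0], axes[0], _ellipsoid, f"blob {idx}")
            blob_mask[sl] |= local

    # vesicles are painted before the distractors exist; resolve collisions
    vesicle_mask &= ~(membrane_mask | blob_mask)

    # --- intensity model -------------------------------------------------
    img = np.full(shape, spec.background_mean, dtype=np.float32)
    texture = rng.standard_normal(shape).astype(np.float32)
    texture = ndimage.gaussian_filter(texture, sigma=(0.5, 3.0, 3.0))
    texture *= spec.background_texture_sd / max(texture.std(), 1e-12)
    img += texture

    darkening = np.zeros(shape, dtype=np.float32)
    darkening[synapse_labels > 0] = spec.synapse_darkening
    darkening[membrane_mask] = spec.membrane_darkening
    if blob_mask.any():
        # stripe texture inside blobs (cristae-like)
        zz = np.arange(shape[1], dtype=np.float32)
        stripes = 0.7 + 0.3 * np.sin(2 * np.pi * zz / 12.0)
        dark_blob = spec.blob_darkening * stripes[None, :, None]
        darkening[blob_mask] = np.broadcast_to(dark_blob, shape)[blob_mask]
    darkening[vesicle_mask] = spec.vesicle_darkening
    # soften object edges slightly (sub-voxel partial-volume proxy)
    darkening = ndimage.gaussian_filter(darkening, sigma=(0.3, 0.8, 0.8))
    img -= darkening
    img += rng.standard_normal(shape).astype(np.float32) * spec.noise_sigma
    np.clip(img, 0.0, 255.0, out=img)

    truth = PhantomTruth(
        synapse_labels=synapse_labels,
        centroids=np.asarray(centroids).reshape(-1, 3),
        membrane_mask=membrane_mask,
        blob_mask=blob_mask,
        vesicle_mask=vesicle_mask,
    )
    return AnisotropicVolume(img, spec.voxel_size), truth


def phantom_gt_points(truth: PhantomTruth) -> GroundTruthAnnotation:
    """Ground-truth point annotations (synapse centroids) for evaluation."""
    return GroundTruthAnnotation(truth.centroids)


def sample_sparse_labels(
    truth: PhantomTruth,
    n_per_class: int = 300,
    seed: int = 0,
) -> SparseLabels:
    """Sparse training labels emulating an annotator's scribbles.

    Synapse labels are drawn from the synapse truth masks, membrane labels
    from the membrane distractors, and "other" labels from a mixture of
    plain background, blob interiors and vesicle clouds (annotators label
    vesicle clouds and mitochondria as non-synapse).
    """
    rng = np.random.default_rng(seed)

    def _draw(mask: np.ndarray, k: int) -> np.ndarray:
        coords = np.argwhere(mask)
        if len(coords) == 0:
            raise ValueError("cannot sample labels from an empty class region")
        idx = rng.choice(len(coords), size=min(k, len(coords)), replace=False)
        return coords[idx]

    syn = _draw(truth.synapse_labels > 0, n_per_class)
    mem = _draw(truth.membrane_mask, n_per_class)
    background = ~(
        (truth.synapse_labels > 0)
        | truth.membrane_mask
        | truth.blob_mask
        | truth.vesicle_mask
    )
    n_bg = max(n_per_class // 2, 1)
    n_blob = max(n_per_class // 4, 1)
    n_ves = max(n_per_class - n_bg - n_blob, 1)
    other = [_draw(background, n_bg)]
    if truth.blob_mask.any():
        other.append(_draw(truth.blob_mask, n_blob))
    if truth.vesicle_mask.any():
        other.append(_draw(truth.vesicle_mask & (truth.synapse_labels == 0), n_ves))
    other = np.concatenate(other)

    coords = np.concatenate([syn, mem, other])
    class_ids = np.concatenate(
        [np.zeros(len(syn), int), np.ones(len(mem), int), np.full(len(other), 2)]
    )
    return SparseLabels(coords, class_ids, CLASS_NAMES)


@dataclass(frozen=True)
class ProbabilityPhantomSpec:
    """Conditions for a synthetic synapse-probability map.

    Objects are ellipsoidal high-probability regions (~``p_object``) on a
    low-probability background.  Optional extras construct the fixtures the
    segmentation stage is judged on: a thin high-probability ``protrusion``
    attached to the first object (hysteresis attaches it, graph cut's
    shrinking bias should not) and a sub-threshold ``bridge`` of
    intermediate probability between the first two objects.
    """

    shape: tuple[int, int, int] = (12, 64, 64)
    voxel_size: tuple[float, float, float] = (45.0, 4.5, 4.5)
    n_objects: int = 3
    object_radius_vox: tuple[float, float] = (4.0, 10.0)  # lateral, z scaled down
    p_object: float = 0.9
    p_background: float = 0.05
    noise: float = 0.03
    protrusion: bool = False
    bridge: bool = False
    seed: int = 0


def generate_probability_phantom(
    spec: ProbabilityPhantomSpec,
) -> tuple[ProbabilityMap, PhantomTruth]:
    """Generate a synthetic probability map plus truth masks.

    With no noise and beta = 0 the graph cut recovers the truth exactly
    (threshold limit); the protrusion and bridge fixtures probe the
    qualitative differences between graph cut and hysteresis thresholding.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    labels = np.zeros(shape, dtype=np.int16)
    p = np.full(shape, spec.p_background, dtype=np.float64)

    nz, ny, nx = shape
    centers = []
    for i in range(spec.n_objects):
        for _ in range(200):
            r_lat = rng.uniform(*spec.object_radius_vox)
            r_z = max(1.0, r_lat * spec.voxel_size[1] / spec.voxel_size[0] * 2.5)
            c = np.array(
                [
                    rng.uniform(r_z + 1, nz - r_z - 1),
                    rng.uniform(r_lat + 2, ny - r_lat - 2),
                    rng.uniform(r_lat + 2, nx - r_lat - 2),
                ]
            )
            if all(np.linalg.norm((c - pc) / [1, 1, 1]) > 2.5 * r_lat for pc in centers):
                break
        else:
            raise RuntimeError("could not place probability-phantom object")
        centers.append(c)
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        m = (
            ((zz - c[0]) / r_z) ** 2
            + ((yy - c[1]) / r_lat) ** 2
            + ((xx - c[2]) / r_lat) ** 2
        ) <= 1.0
        labels[m & (labels == 0)] = i + 1
        p[m] = spec.p_object

    if spec.protrusion and spec.n_objects >= 1:
        c = np.round(centers[0]).astype(int)
        z = int(c[0])
        y = int(c[1])
        x0 = int(c[2])
        length = min(nx - x0 - 2, 25)
        p[z, y, x0:x0 + length] = np.maximum(p[z, y, x0:x0 + length], 0.85)

    if spec.bridge and spec.n_objects >= 2:
        a, b = centers[0], centers[1]
        steps = int(np.ceil(np.abs(b - a).max())) * 2 + 1
        for s in np.linspace(0.0, 1.0, steps):
            q = np.round(a + s * (b - a)).astype(int)
            if labels[tuple(q)] == 0:
                p[tuple(q)] = 0.45  # under the 0.5 detection threshold

    if spec.noise > 0:
        p += rng.normal(0.0, spec.noise, size=shape)
    np.clip(p, 0.0, 1.0, out=p)

    data = np.zeros((3,) + shape, dtype=np.float64)
    data[0] = p
    data[2] = 1.0 - p
    pmap = ProbabilityMap(data, spec.voxel_size, CLASS_NAMES)

    coords = [np.argwhere(labels == i + 1).mean(axis=0) for i in range(spec.n_objects)]
    truth = PhantomTruth(
        synapse_labels=labels,
        centroids=np.asarray(coords).reshape(-1, 3),
        membrane_mask=np.zeros(shape, dtype=bool),
        blob_mask=np.zeros(shape, dtype=bool),
        vesicle_mask=np.zeros(shape, dtype=bool),
    )
    return pmap, truth
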