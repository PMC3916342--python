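"""3D filter bank for pixel classification.

The pixel stage discriminates synaptic densities from membranes and cytoplasm
using generic rotation-covariant scale-space features, all computed in 3D on
the z-upsampled grid: Gaussian-smoothed intensity, Hessian eigenvalues,
Laplacian of Gaussian, difference of Gaussians and structure-tensor
eigenvalues, each at several isotropic scales (in pixels of the upsampled
grid).  The default configuration yields 26 channels.

Boundary handling is reflective everywhere, so blockwise processing does not
create artificial edge responses, and all inputs are cast to floating point
before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import AnisotropicVolume

__all__ = [
    "FeatureConfig",
    "FeatureStack",
    "DEFAULT_FEATURE_CONFIG",
    "gaussian_smoothing",
    "hessian_eigenvalues",
    "laplacian_of_gaussian",
    "difference_of_gaussians",
    "structure_tensor_eigenvalues",
    "compute_feature_stack",
]

_MODE = "reflect"

#: ratio of the second (subtracted) Gaussian's sigma in the DoG filter
DOG_SIGMA_RATIO = 0.66
#: ratio of the inner (gradient) scale to the outer scale in the structure tensor
STRUCTURE_TENSOR_INNER_RATIO = 0.5

#: channels produced per filter application
_FILTER_CHANNELS = {
    "gaussian": 1,
    "hessian_eig": 3,
    "log": 1,
    "dog": 1,
    "structure_eig": 3,
}
_FILTER_ORDER = ("gaussian", "hessian_eig", "log", "dog", "structure_eig")


@dataclass(frozen=True)
class FeatureConfig:
    """Per-filter sigma lists (pixels of the grid the filters run on).

    Sigmas are isotropic — the same value in all three dimensions — and must
    be positive and sorted ascending per filter.
    """

    sigmas: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "gaussian": (0.7, 1.0, 1.6, 3.5, 5.0, 10.0),
            "hessian_eig": (1.6, 3.5, 5.0, 10.0),
            "log": (3.5, 5.0, 10.0),
            "dog": (5.0, 10.0),
            "structure_eig": (5.0,),
        }
    )

    def __post_init__(self) -> None:
        if not self.sigmas:
            raise ValueError("feature configuration is empty")
        for name, sig in self.sigmas.items():
            if name not in _FILTER_CHANNELS:
                raise ValueError(f"unknown filter {name!r}")
            sig = tuple(float(s) for s in sig)
            if any(s <= 0 for s in sig):
                raise ValueError(f"{name}: sigmas must be positive, got {sig}")
            if list(sig) != sorted(sig):
                raise ValueError(f"{name}: sigmas must be sorted ascending, got {sig}")
            object.__setattr__(self, "sigmas", {**self.sigmas, name: sig})

    @property
    def channel_names(self) -> tuple[str, ...]:
        names = []
        for fname in _FILTER_ORDER:
            for sigma in self.sigmas.get(fname, ()):
                k = _FILTER_CHANNELS[fname]
                if k == 1:
                    names.append(f"{fname}@{sigma:g}")
                else:
                    names.extend(f"{fname}@{sigma:g}:{i}" for i in range(k))
        return tuple(names)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


DEFAULT_FEATURE_CONFIG = FeatureConfig()


@dataclass
class FeatureStack:
    """Stack of feature channels, shape (n_channels, n_z, n_y, n_x)."""

    data: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError("feature stack must be rank 4 (channel, z, y, x)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Features as an (n_voxels, n_channels) matrix (z, y, x raveled)."""
        return self.data.reshape(self.n_channels, -1).T


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma


def _as_float(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    if not np.issubdtype(v.dtype, np.floating):
        v = v.astype(np.float32)
    return v


def gaussian_smoothing(v: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic 3D Gaussian smoothing (reflective boundary)."""
    sigma = _check_sigma(sigma)
    return ndimage.gaussian_filter(_as_float(v), sigma, mode=_MODE)


def _hessian_elements(v: np.ndarray, sigma: float) -> list[np.ndarray]:
    """Upper-triangle Gaussian second derivatives (zz, zy, zx, yy, yx, xx)."""
    v = _as_float(v)
    orders = [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)]
    return [ndimage.gaussian_filter(v, sigma, order=o, mode=_MODE) for o in orders]


def _eigvalsh_descending(elems: list[np.ndarray]) -> np.ndarray:
    """Eigenvalues of a symmetric 3x3 field, sorted descending.

    ``elems`` holds the 6 upper-triangle components in the order produced by
    :func:`_hessian_elements`; output shape is (3,) + field shape.  Uses the
    closed-form trigonometric solution for symmetric 3x3 matrices (an order
    of magnitude faster than batched LAPACK on volume-sized fields; absolute
    error ~1e-12 on unit-scale inputs, verified against ``np.linalg.eigvalsh``
    in the test suite).
    """
    zz, zy, zx, yy, yx, xx = (np.asarray(e, dtype=np.float64) for e in elems)
    shape = zz.shape
    q = (zz + yy + xx) / 3.0
    off2 = zy * zy + zx * zx + yx * yx
    p2 = (zz - q) ** 2 + (yy - q) ** 2 + (xx - q) ** 2 + 2.0 * off2
    p = np.sqrt(p2 / 6.0)
    safe_p = np.where(p > 0, p, 1.0)
    b00 = (zz - q) / safe_p
    b11 = (yy - q) / safe_p
    b22 = (xx - q) / safe_p
    b01 = zy / safe_p
    b02 = zx / safe_p
    b12 = yx / safe_p
    det_b = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    phi = np.arccos(np.clip(det_b / 2.0, -1.0, 1.0)) / 3.0
    w0 = q + 2.0 * p * np.cos(phi)
    w2 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    w1 = 3.0 * q - w0 - w2
    out = np.empty((3,) + shape, dtype=np.float64)
    out[0], out[1], out[2] = w0, w1, w2
    return out


def hessian_eigenvalues(v: np.ndarray, sigma: float) -> np.ndarray:
    """Eigenvalues of the Gaussian Hessian, sorted descending; 3 channels.

    Synaptic densities are dark sheet-like structures, whose signature is one
    strongly positive eigenvalue (across the sheet) against two near-zero
    ones — the classic plate detector.
    """
    sigma = _check_sigma(sigma)
    return _eigvalsh_descending(_hessian_elements(v, sigma))


def laplacian_of_gaussian(v: np.ndarray, sigma: float) -> np.ndarray:
    """Trace of the Gaussian Hessian (blob detector); constants map to 0."""
    sigma = _check_sigma(sigma)
    v = _as_float(v)
    out = ndimage.gaussian_filter(v, sigma, order=(2, 0, 0), mode=_MODE)
    out += ndimage.gaussian_filter(v, sigma, order=(0, 2, 0), mode=_MODE)
    out += ndimage.gaussian_filter(v, sigma, order=(0, 0, 2), mode=_MODE)
    return out


def difference_of_gaussians(v: np.ndarray, sigma: float) -> np.ndarray:
    """Band-pass filter: smooth(v, sigma) − smooth(v, 0.66·sigma)."""
    sigma = _check_sigma(sigma)
    v = _as_float(v)
    return gaussian_smoothing(v, sigma) - gaussian_smoothing(v, DOG_SIGMA_RATIO * sigma)


def _structure_tensor_elements(v: np.ndarray, sigma: float) -> list[np.ndarray]:
    v = _as_float(v)
    inner = STRUCTURE_TENSOR_INNER_RATIO * sigma
    g = [
        ndimage.gaussian_filter(v, inner, order=o, mode=_MODE)
        for o in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    ]
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    return [ndimage.gaussian_filter(g[i] * g[j], sigma, mode=_MODE) for i, j in pairs]


def structure_tensor_eigenvalues(v: np.ndarray, sigma: float) -> np.ndarray:
    """Eigenvalues (descending, all ≥ 0) of the 3D structure tensor.

    Gradients are taken at inner scale sigma/2 (Gaussian derivatives); their
    outer products are averaged at the outer scale sigma.  Captures the local
    orientation structure: one dominant eigenvalue for sheets/edges, two for
    tubes, three for blobs or noise.
    """
    sigma = _check_sigma(sigma)
    return _eigvalsh_descending(_structure_tensor_elements(v, sigma))


def compute_feature_stack(
    v: AnisotropicVolume | np.ndarray,
    cfg: FeatureConfig = DEFAULT_FEATURE_CONFIG,
    *,
    z_slices: np.ndarray | slice | None = None,
) -> FeatureStack:
    """Compute all configured channels in the fixed documented order.

    Channel order follows ``cfg.channel_names``: filters in the order
    gaussian, hessian_eig, log, dog, structure_eig; sigmas ascending within a
    filter; eigenvalue components descending within a sigma.  With the default
    configuration this yields exactly 26 channels.

    Parameters
    ----------
    v
        Volume (already z-upsampled per pipeline configuration) or raw array.
    cfg
        Which filters at which scales.
    z_slices
        Optionally assemble the stack only at these z indices.  All linear
        filtering still runs on the full grid (so values are identical to a
        full computation); only per-voxel nonlinearities (eigen-decomposition)
        and storage are restricted.  Used by the pipeline to evaluate features
        only at slices that survive z-downsampling.
    """
    data = v.data if isinstance(v, AnisotropicVolume) else np.asarray(v)
    data = _as_float(data)
    sel = slice(None) if z_slices is None else z_slices

    # shared intermediate results (already restricted to the selected slices):
    # smoothings feed both the intensity and DoG channels, Hessian elements
    # feed both the eigenvalue and LoG (= trace) channels
    smooth_cache: dict[float, np.ndarray] = {}
    hessian_cache: dict[float, list[np.ndarray]] = {}

    def smooth(s: float) -> np.ndarray:
        if s not in smooth_cache:
            smooth_cache[s] = gaussian_smoothing(data, s)[sel]
        return smooth_cache[s]

    def hessian_elems(s: float) -> list[np.ndarray]:
        if s not in hessian_cache:
            hessian_cache[s] = [e[sel] for e in _hessian_elements(data, s)]
        return hessian_cache[s]

    channels: list[np.ndarray] = []
    for fname in _FILTER_ORDER:
        for sigma in cfg.sigmas.get(fname, ()):
            if fname == "gaussian":
                channels.append(smooth(sigma))
            elif fname == "log":
                zz, _, _, yy, _, xx = hessian_elems(sigma)
                channels.append(zz + yy + xx)
            elif fname == "dog":
                channels.append(smooth(sigma) - smooth(DOG_SIGMA_RATIO * sigma))
            elif fname == "hessian_eig":
                channels.extend(_eigvalsh_descending(hessian_elems(sigma)))
            elif fname == "structure_eig":
                elems = [e[sel] for e in _structure_tensor_elements(data, sigma)]
                channels.extend(_eigvalsh_descending(elems))
    return FeatureStack(np.stack(channels), cfg.channel_names)
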