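"""Volume containers and axial resampling.

Serial-section TEM stacks are strongly anisotropic: lateral resolution of a
few nanometres per pixel against section thicknesses of tens of nanometres
(the reference acquisition here is 4.5 x 4.5 x 45 nm).  Everything downstream
needs to know the physical voxel size, so the raw data travels together with
it in :class:`AnisotropicVolume`.  Axis order is (z, y, x) throughout the
package; parameters quoted in (x, y, z) order by convention elsewhere are
converted at the API boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

__all__ = [
    "AnisotropicVolume",
    "ProbabilityMap",
    "read_volume",
    "write_volume",
    "upsample_z",
    "downsample_z",
    "CLASS_NAMES",
]

#: Fixed class order of the pixel-classification stage.
CLASS_NAMES = ("synapse", "membrane", "other")


@dataclass
class AnisotropicVolume:
    """A 3D scalar grid with per-axis voxel size in nanometres.

    Parameters
    ----------
    data
        Array of shape (n_z, n_y, n_x).
    voxel_size
        Physical voxel extent (z_nm, y_nm, x_nm); all entries positive.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be rank 3, got rank {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("volume must have at least one voxel per axis")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities on the same grid as a source volume.

    ``data`` has shape (n_classes, n_z, n_y, n_x); probabilities at each voxel
    are in [0, 1] and sum to 1.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"probability map must be rank 4, got rank {self.data.ndim}")
        if self.data.shape[0] != len(self.class_names):
            raise ValueError("first axis must match the number of classes")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        self.class_names = tuple(self.class_names)

    def validate(self, atol: float = 1e-6) -> None:
        """Raise if probabilities leave [0,1] or do not sum to 1 per voxel."""
        if self.data.min() < -atol or self.data.max() > 1 + atol:
            raise ValueError("probabilities outside [0, 1]")
        s = self.data.sum(axis=0)
        if not np.allclose(s, 1.0, atol=atol):
            raise ValueError("per-voxel probabilities do not sum to 1")

    def class_probability(self, name: str) -> np.ndarray:
        """The 3D probability grid of one class."""
        return self.data[self.class_names.index(name)]


def read_volume(path: str | os.PathLike, voxel_size, *, h5_dataset: str | None = None) -> AnisotropicVolume:
    """Read a multi-page TIFF or an HDF5 rank-3 dataset into a volume.

    The voxel size is never guessed from file metadata; it is supplied by the
    caller (typically from the pipeline config).  Integer grayscale data is
    preserved bit-exactly.

    Parameters
    ----------
    path
        ``.tif``/``.tiff`` stack or an HDF5 file.
    voxel_size
        (z_nm, y_nm, x_nm).
    h5_dataset
        Dataset path inside an HDF5 file.  Defaults to the file's single
        rank-3 dataset; ambiguous files require an explicit name.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:  # single page
            data = data[None]
    elif ext in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as f:
            if h5_dataset is None:
                cands = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
                if len(cands) != 1:
                    raise ValueError(
                        f"HDF5 file has {len(cands)} root datasets; pass h5_dataset explicitly"
                    )
                h5_dataset = cands[0]
            data = f[h5_dataset][()]
    else:
        raise ValueError(f"unsupported volume format: {ext!r}")
    if data.ndim != 3:
        raise ValueError(f"expected a rank-3 volume, got rank {data.ndim}")
    return AnisotropicVolume(data, voxel_size)


def write_volume(path: str | os.PathLike, volume: AnisotropicVolume, *, h5_dataset: str = "volume") -> None:
    """Write a volume as multi-page TIFF or HDF5 (by file extension)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.data, photometric="minisblack")
    elif ext in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as f:
            f.create_dataset(h5_dataset, data=volume.data)
    else:
        raise ValueError(f"unsupported volume format: {ext!r}")


def upsample_z(volume: AnisotropicVolume, factor: int) -> AnisotropicVolume:
    """Linearly interpolate a stack along z by an integer factor.

    Section thickness is the limiting resolution in ssTEM; interpolating by a
    factor of two along z gives nonlinear 3D filters the intermediate-slice
    context they need.  Interpolation is edge-aligned: the output has
    ``(n_z - 1) * factor + 1`` slices and reproduces the original slices
    exactly at indices ``0, factor, 2*factor, ...`` — no data is invented
    past the last section.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"upsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return AnisotropicVolume(volume.data.copy(), volume.voxel_size)
    data = np.asarray(volume.data, dtype=np.float32)
    n_z = data.shape[0]
    n_out = (n_z - 1) * factor + 1
    out = np.empty((n_out,) + data.shape[1:], dtype=np.float32)
    out[::factor] = data
    for k in range(1, factor):
        w = k / factor
        out[k::factor] = (1.0 - w) * data[:-1] + w * data[1:]
    z_nm, y_nm, x_nm = volume.voxel_size
    return AnisotropicVolume(out, (z_nm / factor, y_nm, x_nm))


def downsample_z(pmap: ProbabilityMap, factor: int) -> ProbabilityMap:
    """Keep every ``factor``-th slice of a probability map, starting at 0.

    Returns predictions made on an upsampled grid to the native section grid;
    the inverse of :func:`upsample_z` on the original slices.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    z_nm, y_nm, x_nm = pmap.voxel_size
    return ProbabilityMap(
        pmap.data[:, ::factor].copy(), (z_nm * factor, y_nm, x_nm), pmap.class_names
    )
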