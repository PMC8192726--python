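"""3D grayscale volume container and file I/O.

Volumes are single-channel scalar grids with an anisotropic physical voxel
spacing in micrometers.  Axis order is (x, y, z) throughout the package;
TIFF files are stored as page-per-z-slice with (y, x) pages, the usual
microscopy convention, and transposed on read/write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import h5py

_ALLOWED_DTYPES = (np.uint8, np.uint16, np.float32, np.float64)


class VolumeFormatError(ValueError):
    """Raised for unreadable or internally inconsistent volume files."""


@dataclass
class VoxelGrid:
    """A dense scalar volume with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar grid; unsigned 8/16-bit integer or floating point.
    spacing : tuple of float
        Micrometers per voxel along (x, y, z); all strictly positive.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 3 or min(a.shape) < 1:
            raise ValueError(f"expected non-empty 3D grid, got shape {a.shape}")
        if not any(np.issubdtype(a.dtype, t) for t in _ALLOWED_DTYPES):
            raise VolumeFormatError(f"unsupported dtype {a.dtype}")
        if np.issubdtype(a.dtype, np.floating) and not np.all(np.isfinite(a)):
            raise ValueError("intensities must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.intensities = a
        self.spacing = sp

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.intensities.shape)  # type: ignore[return-value]

    def physical_position(self, index) -> np.ndarray:
        """Voxel-centered physical coordinate (micrometers) of an index."""
        return (np.asarray(index, dtype=float) + 0.5) * np.asarray(self.spacing)


def read_volume(path: str | os.PathLike, spacing=(1.0, 1.0, 1.0)) -> VoxelGrid:
    """Read a volume from multi-page TIFF, a TIFF-stack directory, or HDF5.

    ``spacing`` is used for TIFF input; HDF5 containers written by
    :func:`write_volume` carry their own ``spacing_um`` attribute which takes
    precedence.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        pages = sorted(
            f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff"))
        )
        if not pages:
            raise VolumeFormatError(f"no TIFF slices in directory {path}")
        slices = [tifffile.imread(os.path.join(path, f)) for f in pages]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise VolumeFormatError(f"inconsistent slice shapes: {sorted(shapes)}")
        zyx = np.stack(slices, axis=0)
    elif path.lower().endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            if "volume" not in f:
                raise VolumeFormatError(f"{path}: missing 'volume' dataset")
            ds = f["volume"]
            zyx = ds[()]
            if "spacing_um" in ds.attrs:
                spacing = tuple(float(s) for s in ds.attrs["spacing_um"])
    else:
        try:
            zyx = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - normalize into format error
            raise VolumeFormatError(f"cannot read TIFF {path}: {exc}") from exc
        if zyx.ndim == 2:
            zyx = zyx[None]
    if zyx.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {zyx.shape}")
    try:
        return VoxelGrid(np.ascontiguousarray(zyx.transpose(2, 1, 0)), spacing)
    except VolumeFormatError:
        raise
    except ValueError as exc:
        raise VolumeFormatError(str(exc)) from exc


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a volume as multi-page TIFF (.tif) or chunked HDF5 (.h5).

    Lossless: ``read_volume(write_volume(g))`` reproduces intensities, dims
    and (for HDF5) spacing bit-for-bit.
    """
    path = os.fspath(path)
    zyx = grid.intensities.transpose(2, 1, 0)
    if path.lower().endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=zyx, chunks=True)
            ds.attrs["spacing_um"] = np.asarray(grid.spacing, dtype=float)
    elif path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.ascontiguousarray(zyx))
    else:
        raise VolumeFormatError(f"unsupported output format: {path}")
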