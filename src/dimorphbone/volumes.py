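"""Voxel-grid containers for CT stacks and binary masks.

Axis convention: axis 0 is the scan (long-bone) axis; axes 1, 2 are the
in-plane rows/columns. Voxels are isotropic; physical size is carried in
micrometres alongside the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VolumeImage", "BinaryMask", "read_volume", "write_volume"]


@dataclass
class VolumeImage:
    """A 3D grayscale image with isotropic voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity values (integer dtype for 8/16-bit CT data).
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    """

    voxels: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def bit_depth(self) -> int:
        return self.voxels.dtype.itemsize * 8

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3


@dataclass
class BinaryMask:
    """A boolean voxel mask sharing the geometry of its source volume.

    ``label`` records the semantics of True voxels: "bone" (calcified
    tissue), "cortex_solid" (cortical shell with pores filled), or
    "porosity" (intracortical void space).
    """

    voxels: np.ndarray
    voxel_size_um: float
    label: str = "bone"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.voxels.ndim}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_um3(self) -> float:
        return self.count() * self.voxel_volume_um3


def read_volume(path: str | Path, voxel_size_um: float) -> VolumeImage:
    """Read a multi-page TIFF stack (or a directory of per-slice TIFFs)."""
    path = Path(path)
    if path.is_dir():
        slices = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not slices:
            raise FileNotFoundError(f"no .tif slices in {path}")
        data = np.stack([tifffile.imread(p) for p in slices], axis=0)
    else:
        data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VolumeImage(data, voxel_size_um)


def write_volume(image: VolumeImage | BinaryMask, path: str | Path) -> None:
    """Write a stack as multi-page TIFF (masks are written as 0/255 uint8)."""
    data = image.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(Path(path), data)
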