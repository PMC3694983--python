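"""Spatial containers shared across the pipeline.

All grids are isotropic, RAS-oriented, with 0-based voxel indices; mm
coordinates refer to voxel centers. Functional data live as ``time x voxel``
matrices restricted to an analysis mask, so every downstream stage works on
dense 2-D arrays and only I/O touches 3-D/4-D volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["Grid", "VolumeMask", "VolumeSeries", "full_mask"]


@dataclass(frozen=True)
class Grid:
    """Isotropic 3-D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along x, y, z.
    voxel_size : float
        Edge length of a voxel in mm (isotropic).
    origin : tuple of float
        mm coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size**3)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * self.voxel_size + np.asarray(self.origin)

    def mm_to_index(self, xyz) -> tuple[int, int, int]:
        """Nearest voxel index for a mm coordinate."""
        rel = (np.asarray(xyz, float) - np.asarray(self.origin)) / self.voxel_size
        idx = np.rint(rel).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def contains(self, xyz) -> bool:
        """True if a mm coordinate falls inside the grid's bounding box."""
        rel = (np.asarray(xyz, float) - np.asarray(self.origin)) / self.voxel_size
        return bool(np.all(rel >= -0.5) and np.all(rel <= np.asarray(self.shape) - 0.5))

    def all_centers_mm(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates in C (row-major) flat order."""
        ii = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_mm(ii)


@dataclass
class VolumeMask:
    """Boolean analysis mask on a grid."""

    grid: Grid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.inside.shape} != grid shape {self.grid.shape}"
            )
        if self.n_voxels == 0:
            raise ValueError("mask selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    @property
    def fraction(self) -> float:
        return self.n_voxels / self.grid.n_voxels

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.inside.ravel())

    def coords_mm(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of in-mask voxel centers."""
        ijk = np.argwhere(self.inside)
        return self.grid.index_to_mm(ijk)

    def column_lookup(self) -> np.ndarray:
        """Full-grid flat index -> mask column (-1 outside)."""
        lut = np.full(self.grid.n_voxels, -1, dtype=int)
        lut[self.flat_indices] = np.arange(self.n_voxels)
        return lut

    def unmask(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector back onto the 3-D grid."""
        vec = np.asarray(vec)
        if vec.shape[-1] != self.n_voxels:
            raise ValueError("vector length does not match mask voxel count")
        vol = np.full(self.grid.shape, fill, dtype=vec.dtype)
        vol[self.inside] = vec
        return vol

    def apply(self, vol: np.ndarray) -> np.ndarray:
        if vol.shape != self.grid.shape:
            raise ValueError("volume shape does not match grid")
        return vol[self.inside]

    def same_as(self, other: "VolumeMask") -> bool:
        return self.grid == other.grid and bool(np.array_equal(self.inside, other.inside))


def full_mask(grid: Grid) -> VolumeMask:
    """Mask covering every voxel of the grid."""
    return VolumeMask(grid, np.ones(grid.shape, bool))


@dataclass
class VolumeSeries:
    """Masked 4-D functional run as a ``time x voxel`` matrix.

    ``orig_index`` carries the 1-based volume numbers of the original
    acquisition so that segment windows defined on the scanner's numbering
    survive discarding and filtering.
    """

    data: np.ndarray
    mask: VolumeMask
    tr: float
    subject: str = ""
    condition: str = ""
    segment: str = ""
    orig_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x voxel)")
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{self.mask.n_voxels} voxels"
            )
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.orig_index is None:
            self.orig_index = np.arange(1, self.data.shape[0] + 1)
        else:
            self.orig_index = np.asarray(self.orig_index, int)
            if self.orig_index.shape != (self.data.shape[0],):
                raise ValueError("orig_index length must equal number of timepoints")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[1])

    def with_data(self, data: np.ndarray, **meta) -> "VolumeSeries":
        """Copy carrying new data (same mask/provenance unless overridden)."""
        fields = dict(
            data=data, mask=self.mask, tr=self.tr, subject=self.subject,
            condition=self.condition, segment=self.segment,
            orig_index=self.orig_index,
        )
        fields.update(meta)
        if fields["orig_index"] is not None and len(fields["orig_index"]) != len(data):
            if "orig_index" not in meta:
                raise ValueError(
                    "timepoint count changed; pass orig_index explicitly"
                )
        return VolumeSeries(**fields)

    @property
    def run_id(self) -> str:
        parts = [p for p in (self.subject, self.condition, self.segment) if p]
        return "/".join(parts) if parts else "run"
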