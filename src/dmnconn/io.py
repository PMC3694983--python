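"""NIfTI input/output for masked series, maps and masks (via nibabel)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .core import Grid, VolumeMask, VolumeSeries

__all__ = ["save_series", "load_series", "save_map", "load_map", "save_mask", "load_mask"]


def _grid_from_img(img) -> Grid:
    aff = img.affine
    vox = float(aff[0, 0])
    if not np.allclose(np.diag(aff)[:3], vox) or not np.allclose(
        aff[:3, :3], np.diag([vox] * 3)
    ):
        raise ValueError("only axis-aligned isotropic affines are supported")
    return Grid(shape=tuple(img.shape[:3]), voxel_size=vox, origin=tuple(aff[:3, 3]))


def save_mask(mask: VolumeMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.inside.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def load_mask(path: str | Path) -> VolumeMask:
    img = nib.load(str(path))
    return VolumeMask(_grid_from_img(img), np.asarray(img.dataobj) > 0)


def save_map(vec: np.ndarray, mask: VolumeMask, path: str | Path) -> None:
    """Write a masked voxel vector as a 3-D NIfTI (zeros outside the mask)."""
    img = nib.Nifti1Image(mask.unmask(np.asarray(vec, np.float32)), mask.grid.affine())
    nib.save(img, str(path))


def load_map(path: str | Path, mask: VolumeMask) -> np.ndarray:
    img = nib.load(str(path))
    if _grid_from_img(img) != mask.grid:
        raise ValueError(f"grid of {path} does not match mask grid")
    return np.asarray(img.dataobj)[mask.inside]


def save_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a masked time x voxel series as a 4-D NIfTI."""
    mask = series.mask
    vol4 = np.zeros(mask.grid.shape + (series.n_timepoints,), dtype=np.float32)
    vol4[mask.inside, :] = series.data.T
    img = nib.Nifti1Image(vol4, mask.grid.affine())
    img.header.set_zooms((mask.grid.voxel_size,) * 3 + (series.tr,))
    nib.save(img, str(path))


def load_series(
    path: str | Path,
    mask: VolumeMask,
    tr: Optional[float] = None,
    subject: str = "",
    condition: str = "",
) -> VolumeSeries:
    img = nib.load(str(path))
    if _grid_from_img(img) != mask.grid:
        raise ValueError(f"grid of {path} does not match mask grid")
    if img.ndim != 4:
        raise ValueError(f"{path} is not a 4-D series")
    data = np.asarray(img.dataobj)[mask.inside, :].T
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(
        data=data, mask=mask, tr=tr, subject=subject, condition=condition, segment="full"
    )
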