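"""Temporal/spatial preprocessing of functional runs.

The canonical order, applied to the complete post-discard run before any
segment is extracted, is: linear detrend -> high-pass (cycles per time
course) -> 6-mm Gaussian smoothing -> per-voxel temporal normalization.
Segment extraction keys on original volume numbers carried by
``VolumeSeries.orig_index``, so it composes with filtering in either order
and never reorders time.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Grid, VolumeMask, VolumeSeries
from .synthetic import RunLayout

logger = logging.getLogger(__name__)

__all__ = [
    "build_group_mask",
    "drop_initial",
    "discard_and_segment",
    "detrend_linear",
    "highpass_cycles",
    "highpass_cutoff_hz",
    "smooth_gaussian",
    "znormalize_time",
    "preprocess_run",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))  # sigma = FWHM / 2.3548


def build_group_mask(
    anatomies: Sequence[np.ndarray],
    grid: Grid,
    intensity_quantile: float = 0.5,
) -> VolumeMask:
    """Threshold the mean anatomy into an analysis mask.

    The threshold sits at ``intensity_quantile`` of the mean image's
    intensity range (min + q * (max - min)); voxels at or above it are kept.
    """
    if not len(anatomies):
        raise ValueError("need at least one anatomy")
    if not 0.0 <= intensity_quantile <= 1.0:
        raise ValueError("intensity_quantile must be in [0, 1]")
    vols = [np.asarray(a, float) for a in anatomies]
    for v in vols:
        if v.shape != grid.shape:
            raise ValueError(f"anatomy shape {v.shape} does not match grid {grid.shape}")
    mean = np.mean(vols, axis=0)
    lo, hi = float(mean.min()), float(mean.max())
    thr = lo + intensity_quantile * (hi - lo)
    inside = mean >= thr
    if not inside.any():
        raise ValueError("mask is empty at the requested quantile")
    mask = VolumeMask(grid, inside)
    logger.info(
        "group mask: %d voxels (%.1f%% of grid) at threshold %.4g",
        mask.n_voxels, 100.0 * mask.fraction, thr,
    )
    return mask


def drop_initial(series: VolumeSeries, n: int) -> VolumeSeries:
    """Discard leading volumes (scanner saturation), by original number."""
    keep = series.orig_index > n
    return series.with_data(series.data[keep], orig_index=series.orig_index[keep])


def _extract_by_volumes(series: VolumeSeries, volumes: np.ndarray, label: str) -> VolumeSeries:
    pos = {v: i for i, v in enumerate(series.orig_index)}
    missing = [int(v) for v in volumes if v not in pos]
    if missing:
        raise ValueError(
            f"{label}: volumes {missing[:5]}{'...' if len(missing) > 5 else ''} "
            "not present in series"
        )
    idx = np.array([pos[v] for v in volumes], int)
    return series.with_data(
        series.data[idx], orig_index=series.orig_index[idx], segment=label
    )


def discard_and_segment(
    series: VolumeSeries, layout: RunLayout
) -> tuple[VolumeSeries, VolumeSeries]:
    """Discard initial volumes and extract the trimmed resting segments.

    Returns ``(rs1, rs2)``; each carries the original volume numbers of its
    timepoints as provenance. Window overlap or out-of-range windows raise
    at ``RunLayout`` construction or here.
    """
    rs1_vols = layout.rs1_volumes()
    rs2_vols = layout.rs2_volumes()
    if len(rs1_vols) < 1 or len(rs2_vols) < 1:
        raise ValueError("segment window empty after discard and trims")
    rs1 = _extract_by_volumes(series, rs1_vols, "RS1")
    rs2 = _extract_by_volumes(series, rs2_vols, "RS2")
    return rs1, rs2


def detrend_linear(series: VolumeSeries) -> VolumeSeries:
    """Remove the per-voxel least-squares line (intercept + slope)."""
    T = series.n_timepoints
    if T < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    beta, *_ = np.linalg.lstsq(X, np.asarray(series.data, float), rcond=None)
    return series.with_data(np.asarray(series.data, float) - X @ beta)


def highpass_cutoff_hz(n_timepoints: int, tr: float, n_cycles: int) -> float:
    """Cutoff frequency of an ``n_cycles``-per-time-course high-pass."""
    return n_cycles / (n_timepoints * tr)


def highpass_cycles(series: VolumeSeries, n_cycles: int = 5) -> VolumeSeries:
    """High-pass by removing the mean and the first ``n_cycles`` Fourier
    pairs of each voxel's time course (exact projection, no filter roll-off)."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    T = series.n_timepoints
    if T <= 2 * n_cycles:
        raise ValueError(f"need more than {2 * n_cycles} timepoints for {n_cycles} cycles")
    F = np.fft.rfft(np.asarray(series.data, float), axis=0)
    F[: n_cycles + 1] = 0.0
    out = np.fft.irfft(F, n=T, axis=0)
    logger.debug(
        "high-pass: removed <= %d cycles (cutoff %.4g Hz)",
        n_cycles, highpass_cutoff_hz(T, series.tr, n_cycles),
    )
    return series.with_data(out)


def smooth_gaussian(series: VolumeSeries, fwhm_mm: float = 6.0) -> VolumeSeries:
    """Per-timepoint 3-D Gaussian smoothing inside the mask.

    Values outside the mask are treated as zero (zero-padding), an edge
    approximation; ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return series.with_data(series.data.copy())
    mask = series.mask
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / mask.grid.voxel_size
    out = np.empty_like(np.asarray(series.data, float))
    vol = np.zeros(mask.grid.shape)
    for i in range(series.n_timepoints):
        vol[...] = 0.0
        vol[mask.inside] = series.data[i]
        sm = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)
        out[i] = sm[mask.inside]
    return series.with_data(out)


def znormalize_time(series: VolumeSeries) -> VolumeSeries:
    """Scale each voxel time course to mean 0, sd 1.

    Zero-variance voxels are set to 0 and logged (they carry no
    connectivity information)."""
    data = np.asarray(series.data, float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    flat = sd <= 1e-12 * max(1.0, np.abs(mean).max())
    n_flat = int(flat.sum())
    if n_flat:
        logger.warning("znormalize: %d zero-variance voxels set to 0", n_flat)
    sd_safe = np.where(flat, 1.0, sd)
    out = (data - mean) / sd_safe
    out[:, flat] = 0.0
    return series.with_data(out)


def preprocess_run(
    series: VolumeSeries,
    layout: RunLayout,
    n_cycles: int = 5,
    smooth_fwhm_mm: float = 6.0,
) -> VolumeSeries:
    """Standard full-run preprocessing: discard initial volumes, then
    detrend -> high-pass -> smooth (normalization is applied downstream,
    per segment)."""
    run = drop_initial(series, layout.discard_initial)
    run = detrend_linear(run)
    run = highpass_cycles(run, n_cycles=n_cycles)
    run = smooth_gaussian(run, fwhm_mm=smooth_fwhm_mm)
    logger.info(
        "preprocessed %s: %d timepoints, high-pass cutoff %.4g Hz, smoothing %g mm",
        run.run_id, run.n_timepoints,
        highpass_cutoff_hz(run.n_timepoints, run.tr, n_cycles), smooth_fwhm_mm,
    )
    return run
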