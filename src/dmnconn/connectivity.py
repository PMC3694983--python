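"""ROI definition, time-course denoising and pairwise Fisher-Z connectivity.

Regions are face-connected clusters of voxels surviving an FDR-thresholded
one-sample t-map with a Monte-Carlo-calibrated minimum cluster extent. ROI
mean courses are cleaned of non-network mode courses, motion/tissue signals
and all discrete frequencies above 0.1 Hz, then segmented, Z-normalized and
pairwise Pearson-correlated; correlations are mapped to Fisher Z for
parametric inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import VolumeMask, VolumeSeries
from .synthetic import _DMN_CENTERS

logger = logging.getLogger(__name__)

__all__ = [
    "ROI",
    "ConnectivityRecord",
    "define_rois",
    "extract_roi_timeseries",
    "highfreq_regressors",
    "nuisance_regress",
    "pairwise_connectivity",
    "fisher_z",
    "pair_labels",
]

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
R_CLIP = 1.0 - 1e-7


@dataclass
class ROI:
    """A labelled cluster of in-mask voxels.

    ``voxels`` indexes columns of the masked data matrix; ``center`` is the
    cluster's center of mass in mm.
    """

    label: str
    voxels: np.ndarray
    size_mm3: float
    center: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(len(self.voxels))


def define_rois(
    pvals: np.ndarray,
    mask: VolumeMask,
    q: float = 0.05,
    min_cluster_mm3: float = 270.0,
    tvals: Optional[np.ndarray] = None,
    reference_centers: Optional[Mapping[str, tuple[float, float, float]]] = None,
    label_radius_mm: float = 20.0,
) -> list[ROI]:
    """Cluster FDR-surviving voxels into ROIs.

    Voxels passing Benjamini-Hochberg FDR at ``q`` (restricted to positive
    ``tvals`` when given) are grouped by face adjacency; clusters smaller
    than ``min_cluster_mm3`` are dropped. Clusters are labelled by the
    nearest reference center within ``label_radius_mm`` (default: the seven
    canonical DMN coordinates), otherwise by their own coordinates.
    """
    from .stats import bh_fdr

    pvals = np.asarray(pvals, float)
    if pvals.shape[0] != mask.n_voxels:
        raise ValueError("p-value vector must match mask voxel count")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if reference_centers is None:
        reference_centers = _DMN_CENTERS

    reject, _ = bh_fdr(pvals, q)
    if tvals is not None:
        reject = reject & (np.asarray(tvals, float) > 0)
    if not reject.any():
        logger.warning("define_rois: no voxels survive FDR at q=%g", q)
        return []

    sig3d = mask.unmask(reject.astype(np.uint8)).astype(bool)
    labels3d, n_clusters = ndimage.label(sig3d, structure=FACE_STRUCTURE)
    voxvol = mask.grid.voxel_volume_mm3
    min_vox = int(np.ceil(min_cluster_mm3 / voxvol))
    lut = mask.column_lookup()

    rois: list[ROI] = []
    for c in range(1, n_clusters + 1):
        where = labels3d == c
        n_vox = int(where.sum())
        if n_vox < min_vox:
            continue
        flat = np.flatnonzero(where.ravel())
        cols = lut[flat]
        ijk = np.argwhere(where)
        com = tuple(float(x) for x in mask.grid.index_to_mm(ijk.mean(axis=0)))
        rois.append(ROI(label="", voxels=np.sort(cols), size_mm3=n_vox * voxvol, center=com))

    # label by nearest reference center within radius, largest cluster first
    rois.sort(key=lambda r: -r.size_mm3)
    used: dict[str, int] = {}
    for roi in rois:
        best, best_d = None, np.inf
        for name, ctr in reference_centers.items():
            d = float(np.linalg.norm(np.asarray(roi.center) - np.asarray(ctr)))
            if d < best_d:
                best, best_d = name, d
        if best is not None and best_d <= label_radius_mm:
            used[best] = used.get(best, 0) + 1
            roi.label = best if used[best] == 1 else f"{best}-{used[best]}"
        else:
            roi.label = "x{:+.0f}y{:+.0f}z{:+.0f}".format(*roi.center)
    logger.info(
        "defined %d ROIs (>= %d voxels each): %s",
        len(rois), min_vox, [r.label for r in rois],
    )
    return rois


def extract_roi_timeseries(run: VolumeSeries, roi: ROI) -> np.ndarray:
    """Unweighted mean course over the ROI's voxels."""
    if roi.n_voxels == 0:
        raise ValueError(f"ROI {roi.label!r} is empty")
    if roi.voxels.max() >= run.n_voxels:
        raise ValueError(f"ROI {roi.label!r} indexes voxels outside the run's mask")
    return np.asarray(run.data, float)[:, roi.voxels].mean(axis=1)


def highfreq_regressors(n_timepoints: int, tr: float, cutoff_hz: float = 0.1) -> np.ndarray:
    """Sine/cosine pairs at every discrete frequency above the cutoff.

    Frequencies are ``j / (T * tr)`` for integer ``j`` up to Nyquist;
    identically-zero columns (the Nyquist sine) are dropped.
    """
    t = np.arange(n_timepoints)
    cols = []
    for j in range(1, n_timepoints // 2 + 1):
        f = j / (n_timepoints * tr)
        if f <= cutoff_hz:
            continue
        arg = 2.0 * np.pi * j * t / n_timepoints
        cols.extend([np.sin(arg), np.cos(arg)])
    if not cols:
        return np.empty((n_timepoints, 0))
    X = np.column_stack(cols)
    keep = np.abs(X).max(axis=0) > 1e-12
    return X[:, keep]


def nuisance_regress(ts: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residual of a course after regressing out an intercept plus the
    confound columns (least squares; pseudoinverse with a warning when the
    confound matrix is rank-deficient)."""
    ts = np.asarray(ts, float)
    confounds = np.asarray(confounds, float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != ts.shape[0]:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows but course has {ts.shape[0]}"
        )
    X = np.column_stack([np.ones(ts.shape[0]), confounds])
    beta, _, rank, _ = np.linalg.lstsq(X, ts, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "nuisance design rank-deficient (rank %d < %d); pseudoinverse used",
            rank, X.shape[1],
        )
    return ts - X @ beta


def fisher_z(r) -> np.ndarray | float:
    """Fisher Z (atanh) of a correlation, clipped to |r| <= 1 - 1e-7."""
    arr = np.asarray(r, float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("|r| > 1 is not a correlation")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


@dataclass
class ConnectivityRecord:
    """Symmetric Fisher-Z matrix over ROIs for one run segment."""

    z: np.ndarray
    roi_labels: list[str]
    subject: str = ""
    condition: str = ""
    segment: str = ""

    def pair(self, a: str, b: str) -> float:
        i, j = self.roi_labels.index(a), self.roi_labels.index(b)
        return float(self.z[i, j])


def pair_labels(roi_labels: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered ROI pairs in row-major upper-triangle order."""
    labs = list(roi_labels)
    return [(labs[i], labs[j]) for i in range(len(labs)) for j in range(i + 1, len(labs))]


def pairwise_connectivity(
    roi_ts: np.ndarray,
    roi_labels: Sequence[str],
    segments: Optional[Mapping[str, np.ndarray]] = None,
    subject: str = "",
    condition: str = "",
) -> dict[str, ConnectivityRecord]:
    """Pearson-correlate Z-normalized ROI courses pairwise per segment.

    ``roi_ts`` is ``n_roi x T`` (typically nuisance-regressed residuals);
    ``segments`` maps segment label to positional time indices (default: one
    segment spanning the full courses). Zero-variance courses are flagged and
    their pairs set to NaN; correlations are clipped before the Fisher-Z
    transform so identical courses map to a finite Z.
    """
    roi_ts = np.asarray(roi_ts, float)
    n_roi = roi_ts.shape[0]
    if n_roi < 2:
        raise ValueError("need at least two ROIs")
    if len(roi_labels) != n_roi:
        raise ValueError("roi_labels length must match roi_ts rows")
    if segments is None:
        segments = {"full": np.arange(roi_ts.shape[1])}

    out: dict[str, ConnectivityRecord] = {}
    for seg_name, pos in segments.items():
        pos = np.asarray(pos, int)
        if len(pos) < 3:
            raise ValueError(f"segment {seg_name!r} has fewer than 3 timepoints")
        seg = roi_ts[:, pos]
        sd = seg.std(axis=1)
        flat = sd <= 1e-14
        if flat.any():
            logger.warning(
                "segment %s: zero-variance ROI course(s) %s flagged missing",
                seg_name, [roi_labels[i] for i in np.flatnonzero(flat)],
            )
        segz = seg - seg.mean(axis=1, keepdims=True)
        segz[~flat] /= sd[~flat, None]
        r = (segz @ segz.T) / seg.shape[1]
        np.clip(r, -1.0, 1.0, out=r)
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        z[flat, :] = np.nan
        z[:, flat] = np.nan
        np.fill_diagonal(z, np.nan)
        out[seg_name] = ConnectivityRecord(
            z=z, roi_labels=list(roi_labels), subject=subject,
            condition=condition, segment=seg_name,
        )
    return out
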