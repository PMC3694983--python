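"""Dual regression: project group spatial modes onto individual runs.

Stage one (spatial regression) regresses each timepoint's volume on all
group modes jointly, yielding one time course per mode. Stage two (temporal
regression) regresses each voxel's time course on all mode time courses
jointly, yielding subject-level spatial beta maps. Both stages include an
intercept and use every mode simultaneously, which prevents shared variance
between correlated modes from leaking into single-mode estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import VolumeSeries
from .ica import GroupDecomposition

logger = logging.getLogger(__name__)

__all__ = ["DualRegressionResult", "spatial_regress", "temporal_regress", "dual_regress_run"]


def _lstsq_with_rank_warning(X: np.ndarray, Y: np.ndarray, what: str) -> np.ndarray:
    """Least squares via pseudoinverse; warn when the design is rank-deficient."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "%s design is rank-deficient (rank %d < %d columns); "
            "pseudoinverse solution used", what, rank, X.shape[1]
        )
    return beta


def spatial_regress(modes: np.ndarray, run: VolumeSeries) -> np.ndarray:
    """Regress each volume on all modes jointly (with intercept).

    Returns a ``T x k`` matrix of mode time courses.
    """
    modes = np.asarray(modes, float)
    if modes.shape[1] != run.n_voxels:
        raise ValueError(
            f"modes have {modes.shape[1]} voxels but run has {run.n_voxels}"
        )
    X = np.column_stack([np.ones(run.n_voxels), modes.T])  # V x (k+1)
    beta = _lstsq_with_rank_warning(X, np.asarray(run.data, float).T, "spatial regression")
    return beta[1:].T  # T x k


def temporal_regress(timecourses: np.ndarray, run: VolumeSeries) -> np.ndarray:
    """Regress each voxel's course on all mode time courses jointly (with
    intercept). Returns ``k x V`` beta maps."""
    timecourses = np.asarray(timecourses, float)
    if timecourses.shape[0] != run.n_timepoints:
        raise ValueError(
            f"timecourses have {timecourses.shape[0]} rows but run has "
            f"{run.n_timepoints} timepoints"
        )
    X = np.column_stack([np.ones(run.n_timepoints), timecourses])  # T x (k+1)
    beta = _lstsq_with_rank_warning(X, np.asarray(run.data, float), "temporal regression")
    return beta[1:]  # k x V


@dataclass
class DualRegressionResult:
    """Per-run mode time courses and subject-level spatial beta maps."""

    timecourses: np.ndarray  # T x k
    subject_maps: np.ndarray  # k x V
    run_id: str = ""

    @property
    def k(self) -> int:
        return int(self.subject_maps.shape[0])


def dual_regress_run(decomp: GroupDecomposition, run: VolumeSeries) -> DualRegressionResult:
    """Both dual-regression stages on one run.

    Applied both to the segment the modes were estimated from and to a
    held-out segment of the same subjects.
    """
    tc = spatial_regress(decomp.modes, run)
    maps = temporal_regress(tc, run)
    return DualRegressionResult(timecourses=tc, subject_maps=maps, run_id=run.run_id)
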