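"""Group spatial ICA and template-based DMN component selection.

One resting segment per subject is variance-normalized, temporally
concatenated across subjects within a drug condition, reduced with PCA and
decomposed with symmetric FastICA into ``k`` spatial modes (voxels are the
samples, timepoints the features — spatial ICA). The default-mode component
is the mode with the highest absolute spatial correlation against a
posterior-cingulate template, sign-flipped to correlate positively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import VolumeSeries
from .preprocess import znormalize_time

logger = logging.getLogger(__name__)

__all__ = [
    "PcaReduction",
    "GroupDecomposition",
    "TemplateMatch",
    "concatenate_group",
    "pca_reduce",
    "fastica_spatial",
    "select_dmn_component",
]


def concatenate_group(segments: Sequence[VolumeSeries]) -> np.ndarray:
    """Normalize each subject's segment per voxel and stack across time.

    Returns an ``(n_subjects * T) x n_voxels`` aggregate matrix. All
    segments must share the mask and timepoint count.
    """
    if not segments:
        raise ValueError("no segments to concatenate")
    ref = segments[0]
    for seg in segments[1:]:
        if not seg.mask.same_as(ref.mask):
            raise ValueError(
                f"mask mismatch between {ref.run_id} and {seg.run_id}"
            )
        if seg.n_timepoints != ref.n_timepoints:
            raise ValueError(
                f"timepoint mismatch: {ref.run_id} has {ref.n_timepoints}, "
                f"{seg.run_id} has {seg.n_timepoints}"
            )
    blocks = [znormalize_time(seg).data for seg in segments]
    agg = np.vstack(blocks)
    logger.info(
        "aggregated %d segments of %d volumes -> %d x %d matrix",
        len(segments), ref.n_timepoints, agg.shape[0], agg.shape[1],
    )
    return agg


@dataclass
class PcaReduction:
    """Whitened spatial scores from PCA of the aggregate matrix.

    ``scores`` is ``n_voxels x k`` with unit-variance, mutually uncorrelated
    columns (voxels are samples); ``explained_variance_ratio`` is per
    retained component. The aggregate is kept for mixing-matrix estimation.
    """

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    aggregate: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return int(self.scores.shape[1])


def pca_reduce(aggregate: np.ndarray, k: int = 40) -> PcaReduction:
    """Reduce the temporal dimension of the aggregate to ``k`` whitened
    spatial component scores."""
    aggregate = np.asarray(aggregate, float)
    n_time, n_vox = aggregate.shape
    if k > min(n_time, n_vox):
        raise ValueError(f"k={k} exceeds min(time, voxels)={min(n_time, n_vox)}")
    pca = PCA(n_components=k, whiten=True, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(aggregate.T)  # voxels are samples
    logger.info(
        "PCA: %d components explain %.1f%% of variance",
        k, 100.0 * pca.explained_variance_ratio_.sum(),
    )
    return PcaReduction(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        aggregate=aggregate,
    )


@dataclass
class GroupDecomposition:
    """``k`` spatially Z-scored independent modes plus their aggregate-time
    mixing courses."""

    modes: np.ndarray  # k x n_voxels, each spatial mean 0 / sd 1
    mixing: np.ndarray  # aggregated-time x k
    condition: str = ""
    segment: str = ""
    seed: int = 0

    @property
    def k(self) -> int:
        return int(self.modes.shape[0])


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (m - mean) / sd


def fastica_spatial(
    reduced: PcaReduction,
    k: Optional[int] = None,
    seed: int = 0,
    fun: str = "logcosh",
    tol: float = 1e-4,
    max_iter: int = 1000,
    max_restarts: int = 8,
    condition: str = "",
    segment: str = "",
) -> GroupDecomposition:
    """Symmetric (parallel) FastICA on the whitened spatial scores.

    The tanh (log-cosh) contrast is the default — the cubic (kurtosis)
    contrast, selectable via ``fun="cube"``, oscillates without converging
    on realistic noisy mixtures. Non-convergence triggers a restart with a new
    derived seed — and, from the third attempt on, a ten-fold relaxed
    tolerance, since symmetric FastICA commonly oscillates within a
    near-Gaussian subspace — up to ``max_restarts`` attempts, then raises.
    Fixed seeds give reproducible modes up to permutation. Sign is fixed per
    mode by positive spatial skewness.
    """
    if k is None:
        k = reduced.k
    if k > reduced.k:
        raise ValueError(f"k={k} exceeds the {reduced.k} retained PCA components")
    X = reduced.scores[:, :k]

    last_err: Optional[str] = None
    for attempt in range(max_restarts):
        tol_eff = tol * 10 ** (attempt // 2)
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            whiten=False,
            fun=fun,
            tol=tol_eff,
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(X)  # n_voxels x k
        conv_warns = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
        if not conv_warns:
            if attempt:
                logger.info("FastICA converged on restart %d", attempt)
            break
        last_err = str(conv_warns[-1].message)
        logger.warning("FastICA did not converge (attempt %d): %s", attempt + 1, last_err)
    else:
        raise RuntimeError(
            f"FastICA failed to converge after {max_restarts} restarts "
            f"(k={k}, fun={fun}, tol={tol}, max_iter={max_iter}): {last_err}"
        )

    modes = sources.T  # k x n_voxels
    # sign is intrinsically arbitrary: orient each mode to positive skewness
    flip = np.where(stats.skew(modes, axis=1) < 0, -1.0, 1.0)
    modes = modes * flip[:, None]
    modes = _zscore_rows(modes)

    # aggregate-time mixing courses: least squares of the aggregate on the
    # modes (with intercept: modes are spatially centered, aggregate rows not)
    design = np.column_stack([np.ones(modes.shape[1]), modes.T])
    coef, *_ = np.linalg.lstsq(design, reduced.aggregate.T, rcond=None)
    mixing = coef[1:].T  # aggregated-time x k
    return GroupDecomposition(
        modes=modes, mixing=mixing, condition=condition, segment=segment, seed=seed
    )


@dataclass
class TemplateMatch:
    """Result of matching decomposition modes against a spatial template."""

    index: int
    r_abs: float
    all_r: np.ndarray
    mode: np.ndarray  # selected mode, oriented to correlate positively

    def __post_init__(self) -> None:
        assert np.isclose(self.r_abs, np.abs(self.all_r).max())


def select_dmn_component(decomp: GroupDecomposition, template: np.ndarray) -> TemplateMatch:
    """Pick the mode with the highest absolute spatial correlation with the
    template, returned sign-flipped so the correlation is positive."""
    template = np.asarray(template, float)
    if template.shape[0] != decomp.modes.shape[1]:
        raise ValueError("template must live on the decomposition's mask")
    if template.std() == 0:
        raise ValueError("template has zero variance")
    tz = (template - template.mean()) / template.std()
    # modes are already spatially Z-scored
    all_r = decomp.modes @ tz / template.shape[0]
    index = int(np.argmax(np.abs(all_r)))
    r = float(all_r[index])
    mode = decomp.modes[index] * (1.0 if r >= 0 else -1.0)
    logger.info(
        "DMN component: mode %d, max |r| = %.3f (%s %s)",
        index, abs(r), decomp.condition, decomp.segment,
    )
    return TemplateMatch(index=index, r_abs=abs(r), all_r=all_r, mode=mode)
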