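"""Statistical inference for the connectivity pipeline.

Covers the one-sample t-map used for ROI definition, Benjamini-Hochberg FDR,
spatial-smoothness estimation with Monte-Carlo cluster-extent calibration,
the 2x2 within-subject repeated-measures ANOVA (factors Drug and Time, df
(1, n-1)) at voxel and connection level, post-hoc paired t-tests, and the
across-subject brain-behavior correlation.

The RM-ANOVA uses the explicit sum-of-squares decomposition: for each
within-subject factor, the effect mean square is tested against the
factor-by-subject interaction mean square. In a 2x2 design every F equals
the squared paired t on the corresponding within-subject contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from .core import VolumeMask
from .connectivity import FACE_STRUCTURE

logger = logging.getLogger(__name__)

__all__ = [
    "RmAnovaTable",
    "ClusterThreshold",
    "one_sample_tmap",
    "bh_fdr",
    "estimate_smoothness",
    "montecarlo_cluster_threshold",
    "rmanova_2x2",
    "rmanova_from_table",
    "voxelwise_rmanova",
    "posthoc_paired_t",
    "behavior_correlation",
]

FWHM_PER_SIGMA = np.sqrt(8.0 * np.log(2.0))  # 2.3548
FACTORS = ("drug", "time", "interaction")


def one_sample_tmap(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mass-univariate one-sample t-test across subjects.

    ``maps`` is ``n_subjects x n_voxels``; returns two-tailed ``(t, p)``
    with ``df = n - 1``. Zero-variance voxels get t = 0, p = 1 and a log
    message.
    """
    maps = np.asarray(maps, float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    flat = sd <= 1e-30
    if flat.any():
        logger.warning("one_sample_tmap: %d zero-variance voxels set to t=0, p=1", flat.sum())
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~flat)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    p[flat] = 1.0
    return t, p


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns a rejection mask and the realized p-value threshold (the largest
    rejected p, or 0.0 when nothing is rejected).
    """
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(0, bool), 0.0
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    thr = float(pvals[reject].max()) if reject.any() else 0.0
    return reject, thr


def estimate_smoothness(residual_map: np.ndarray, mask: VolumeMask) -> float:
    """Estimate the Gaussian-kernel FWHM (mm) of a spatial map.

    Per axis, the lag-one autocorrelation ``rho = 1 - vardiff / (2 var)`` of
    in-mask neighbour differences is inverted under a Gaussian
    autocorrelation model, ``FWHM = delta * sqrt(-2 ln 2 / ln rho)``, and
    floored at one voxel width (smoothness below the sampling width is not
    resolvable). The axis estimates are combined by geometric mean.
    """
    vec = np.asarray(residual_map, float)
    if vec.shape[0] != mask.n_voxels:
        raise ValueError("map must match mask voxel count")
    vol = mask.unmask(vec, fill=np.nan)
    vol[~mask.inside] = np.nan
    var = float(np.nanvar(vol))
    if var <= 1e-30:
        raise ValueError("cannot estimate smoothness of a constant image")
    delta = mask.grid.voxel_size
    fwhms = []
    for axis in range(3):
        if mask.grid.shape[axis] < 2:
            continue
        d = np.diff(vol, axis=axis)
        d = d[np.isfinite(d)]
        if d.size == 0:
            continue
        vardiff = float(np.mean(d**2))
        rho = 1.0 - vardiff / (2.0 * var)
        if rho <= 0.0:
            fwhm_ax = delta  # rougher than resolvable: floor at voxel size
        else:
            fwhm_ax = max(delta * np.sqrt(-2.0 * np.log(2.0) / np.log(rho)), delta)
        fwhms.append(fwhm_ax)
    if not fwhms:
        raise ValueError("mask must span at least 2 voxels on some axis")
    return float(np.exp(np.mean(np.log(fwhms))))


@dataclass
class ClusterThreshold:
    """Monte-Carlo-calibrated minimum cluster extent."""

    alpha: float
    n_iter: int
    fwhm_mm: float
    voxel_p: float
    min_size_voxels: int
    min_size_mm3: float
    exceed_fraction: float  # realized P(max cluster >= min_size) under null


def _max_cluster_size(sig3d: np.ndarray) -> int:
    labels, n = ndimage.label(sig3d, structure=FACE_STRUCTURE)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def montecarlo_cluster_threshold(
    mask: VolumeMask,
    fwhm_mm: float,
    voxel_p: float,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
) -> ClusterThreshold:
    """Calibrate the minimum cluster size by smoothness-matched noise
    simulation.

    Each iteration draws Gaussian noise on the grid, smooths it with a
    kernel of ``fwhm_mm`` (the same convention :func:`estimate_smoothness`
    inverts), standardizes it in-mask, thresholds at the two-tailed
    ``voxel_p`` and records the largest face-connected cluster over both
    signs. The returned minimum size is the smallest extent exceeded in at
    most ``alpha`` of iterations.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    if mask.n_voxels < 2:
        raise ValueError("mask is degenerate")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xC1)))
    sigma_vox = fwhm_mm / FWHM_PER_SIGMA / mask.grid.voxel_size if fwhm_mm > 0 else 0.0
    zthr = sps.norm.isf(voxel_p / 2.0)

    maxes = np.empty(n_iter, int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.grid.shape)
        if sigma_vox > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
        vals = noise[mask.inside]
        vals = (vals - vals.mean()) / vals.std()
        field = np.zeros(mask.grid.shape)
        field[mask.inside] = vals
        size = max(
            _max_cluster_size(field > zthr),
            _max_cluster_size(field < -zthr),
        )
        maxes[it] = size

    k = 1
    while np.mean(maxes >= k) > alpha:
        k += 1
    frac = float(np.mean(maxes >= k))
    voxvol = mask.grid.voxel_volume_mm3
    logger.info(
        "cluster threshold: %d voxels (%.0f mm^3) at alpha=%g "
        "(fwhm %.2f mm, voxel p=%g, %d iterations)",
        k, k * voxvol, alpha, fwhm_mm, voxel_p, n_iter,
    )
    return ClusterThreshold(
        alpha=alpha, n_iter=n_iter, fwhm_mm=fwhm_mm, voxel_p=voxel_p,
        min_size_voxels=k, min_size_mm3=k * voxvol, exceed_fraction=frac,
    )


@dataclass
class RmAnovaTable:
    """F and p per factor for the 2x2 within-subject design.

    Each entry is an array (scalar for a single analysis unit); degrees of
    freedom are (1, n_subjects - 1) for every factor.
    """

    F: dict
    p: dict
    df_num: int
    df_den: int


def _ss_f(effect_means: np.ndarray, cell_means: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """F and p from effect and per-subject contrast arrays (trailing dims ok)."""
    # effect_means: signed effect per analysis unit; cell_means: per-subject contrast
    num = n * effect_means**2  # SS_effect with df 1 (contrast scaled to unit norm)
    resid = cell_means - effect_means
    den = np.sum(resid**2, axis=0) / (n - 1)
    F = np.zeros(np.broadcast(num, den).shape)
    ok = den > 1e-300
    np.divide(num, den, out=F, where=ok)
    F = np.where(ok | (num > 1e-300), F, 0.0)
    p = sps.f.sf(F, 1, n - 1)
    p = np.where(ok, p, 1.0)
    return F, p


def rmanova_2x2(y: np.ndarray) -> RmAnovaTable:
    """Within-subject 2x2 repeated-measures ANOVA.

    ``y`` has shape ``(n_subjects, 2, 2[, ...])`` with axis 1 the drug
    factor and axis 2 the time factor; trailing axes are independent
    analysis units (e.g. voxels or connections). Each factor's F carries
    df (1, n-1) and equals the squared paired t on the corresponding
    within-subject contrast.
    """
    y = np.asarray(y, float)
    if y.ndim < 3 or y.shape[1] != 2 or y.shape[2] != 2:
        raise ValueError("y must have shape (n_subjects, 2, 2[, ...])")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))
        raise ValueError(f"missing cell for subject index {int(bad[0][0])}")

    # per-subject unit-norm contrasts: main effects and interaction
    c_drug = (y[:, 0] - y[:, 1]).mean(axis=1) / 1.0  # mean over time of drug diff
    c_time = (y[:, :, 0] - y[:, :, 1]).mean(axis=1)
    c_inter = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])

    out_F, out_p = {}, {}
    for name, c in (("drug", c_drug), ("time", c_time), ("interaction", c_inter)):
        F, p = _ss_f(c.mean(axis=0), c, n)
        out_F[name], out_p[name] = F, p
    return RmAnovaTable(F=out_F, p=out_p, df_num=1, df_den=n - 1)


def rmanova_from_table(
    df: pd.DataFrame,
    value: str = "z",
    subject: str = "subject",
    drug: str = "condition",
    time: str = "segment",
) -> RmAnovaTable:
    """RM-ANOVA from a long-format table; errors name any subject with a
    missing cell."""
    piv = df.pivot_table(index=subject, columns=[drug, time], values=value, aggfunc="mean")
    drugs = sorted(df[drug].unique())
    times = sorted(df[time].unique())
    if len(drugs) != 2 or len(times) != 2:
        raise ValueError("design must have exactly two drug and two time levels")
    n = piv.shape[0]
    y = np.empty((n, 2, 2))
    for a, d in enumerate(drugs):
        for b, t in enumerate(times):
            col = piv[(d, t)]
            if col.isna().any():
                missing = piv.index[col.isna()][0]
                raise ValueError(f"missing cell ({d}, {t}) for subject {missing!r}")
            y[:, a, b] = col.to_numpy()
    return rmanova_2x2(y)


def voxelwise_rmanova(
    subject_maps: Mapping[tuple[str, str], np.ndarray],
    mask: VolumeMask,
    q: float = 0.05,
    min_cluster_mm3: float = 270.0,
    conditions: Optional[Sequence[str]] = None,
    segments: Sequence[str] = ("RS1", "RS2"),
) -> dict:
    """Mass-univariate 2x2 RM-ANOVA over voxels with FDR + cluster rule.

    ``subject_maps`` maps ``(condition, segment)`` to an
    ``n_subjects x n_voxels`` array of dual-regression betas. Per factor the
    p-map is FDR-thresholded at ``q`` (the cluster-forming threshold is that
    map's realized FDR p-threshold) and surviving voxels must form
    face-connected clusters of at least ``min_cluster_mm3``.
    """
    keys = list(subject_maps)
    if conditions is None:
        conditions = sorted({c for c, _ in keys})
    if len(conditions) != 2 or len(segments) != 2:
        raise ValueError("need exactly two conditions and two segments")
    n = subject_maps[(conditions[0], segments[0])].shape[0]
    V = mask.n_voxels
    y = np.empty((n, 2, 2, V))
    for a, cond in enumerate(conditions):
        for b, seg in enumerate(segments):
            m = np.asarray(subject_maps[(cond, seg)], float)
            if m.shape != (n, V):
                raise ValueError(f"maps for ({cond}, {seg}) have shape {m.shape}")
            y[:, a, b] = m
    table = rmanova_2x2(y)

    min_vox = int(np.ceil(min_cluster_mm3 / mask.grid.voxel_volume_mm3))
    out = {}
    for factor in FACTORS:
        p = table.p[factor]
        reject, thr = bh_fdr(p, q)
        sig = np.zeros(V, bool)
        if reject.any():
            sig3d = mask.unmask(reject.astype(np.uint8)).astype(bool)
            labels3d, n_cl = ndimage.label(sig3d, structure=FACE_STRUCTURE)
            for c in range(1, n_cl + 1):
                where = labels3d == c
                if where.sum() >= min_vox:
                    cols = mask.column_lookup()[np.flatnonzero(where.ravel())]
                    sig[cols] = True
        out[factor] = {
            "F": table.F[factor],
            "p": p,
            "fdr_p_threshold": thr,
            "significant": sig,
        }
        logger.info(
            "voxelwise RM-ANOVA %s: %d FDR voxels, %d after %d-voxel cluster rule",
            factor, int(reject.sum()), int(sig.sum()), min_vox,
        )
    out["df"] = (table.df_num, table.df_den)
    return out


def posthoc_paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-tailed paired t-test; returns (t, p, df).

    A zero-variance difference is flagged: identical columns give (0, 1),
    a constant non-zero difference gives (inf, 0) with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    n = len(x)
    d = x - y
    if d.std(ddof=1) <= 1e-12 * max(float(np.abs(d).max()), 1e-30):
        if abs(d.mean()) <= 1e-30:
            return 0.0, 1.0, n - 1
        logger.warning("paired t: zero-variance non-zero difference")
        return float(np.sign(d.mean()) * np.inf), 0.0, n - 1
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p), n - 1


def behavior_correlation(
    conn_z: np.ndarray, behavior: np.ndarray
) -> tuple[float, float]:
    """Across-subject Pearson correlation between condition-averaged
    connectivity and condition-averaged behavior.

    Inputs are ``n_subjects x n_conditions``; each is averaged over
    conditions per subject before correlating (two-tailed p, df = n - 2).
    """
    conn_z = np.asarray(conn_z, float)
    behavior = np.asarray(behavior, float)
    if conn_z.shape[0] != behavior.shape[0]:
        raise ValueError("subject counts differ")
    if conn_z.shape[0] < 3:
        raise ValueError("need at least three subjects")
    x = conn_z.mean(axis=1) if conn_z.ndim > 1 else conn_z
    b = behavior.mean(axis=1) if behavior.ndim > 1 else behavior
    if x.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in connectivity or behavior")
    r, p = sps.pearsonr(x, b)
    return float(r), float(p)
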