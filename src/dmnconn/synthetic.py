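"""Synthetic multi-subject resting-state cohorts with known ground truth.

The generator emulates a double-blind, placebo-controlled, two-way cross-over
pharmacological resting-state fMRI study: each of ``n_subjects`` participants
is scanned once per drug condition, each run comprising 1,316 whole-brain
volumes at TR = 2 s that contain two task-free resting segments (204 retained
timepoints each) flanking a task block. Brain activity is modelled as a small
set of Gaussian-blob network nodes (default: seven default-mode-network
regions at standard-space coordinates) whose time courses are drawn with a
condition-dependent target correlation structure; slow scanner drift, a
high-frequency physiological-like oscillation, motion-like confound series
and white measurement noise are added on top. The drug manipulation lives in
the node correlation matrix only, not in signal amplitude, so downstream
effects are purely connectivity-level.

Every simulated quantity is recorded in :class:`CohortTruth`, giving each
pipeline stage an exact ground truth to recover.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Grid, VolumeMask, VolumeSeries, full_mask

logger = logging.getLogger(__name__)

__all__ = [
    "NodeSpec",
    "RunLayout",
    "compact_layout",
    "NoiseSpec",
    "ZERO_NOISE",
    "CohortTruth",
    "DEFAULT_GRID",
    "default_nodes",
    "default_corr_by_condition",
    "make_spatial_modes",
    "make_pcc_template",
    "sample_node_courses",
    "simulate_cohort",
    "make_behavior",
    "write_cohort",
    "validate_correlation",
]

# Seven default-mode-network nodes: label and standard-space center (mm).
_DMN_CENTERS = {
    "PCC": (0.0, -51.0, 25.0),
    "RIPC": (44.0, -59.0, 22.0),
    "LIPC": (-44.0, -59.0, 20.0),
    "RPHC": (21.0, -14.0, -18.0),
    "ACC": (1.0, 53.0, 6.0),
    "LPHC": (-22.0, -11.0, -18.0),
    "RMFG": (23.0, 21.0, 48.0),
}

# 3-mm grid whose bounding box contains every default node center.
DEFAULT_GRID = Grid(shape=(31, 40, 25), voxel_size=3.0, origin=(-45.0, -63.0, -24.0))

# Posterior cingulate template: center of mass and volume of an
# independent-study PCC map used to label the DMN component.
PCC_TEMPLATE_CENTER = (-1.0, -47.0, 24.0)
PCC_TEMPLATE_SIZE_MM3 = 13319.0


@dataclass(frozen=True)
class NodeSpec:
    """One spatial network node rendered as an isotropic Gaussian blob."""

    label: str
    center: tuple[float, float, float]
    fwhm: float = 15.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm < 0:
            raise ValueError(f"node {self.label!r}: fwhm must be >= 0")
        if self.amplitude <= 0:
            raise ValueError(f"node {self.label!r}: amplitude must be > 0")


def default_nodes(fwhm: float = 15.0, amplitude: float = 1.0) -> list[NodeSpec]:
    """The seven default DMN nodes."""
    return [NodeSpec(lab, ctr, fwhm, amplitude) for lab, ctr in _DMN_CENTERS.items()]


@dataclass(frozen=True)
class RunLayout:
    """Volume numbering of one functional run.

    Windows are inclusive ranges of 1-based original volume numbers. The
    default reproduces the study layout: 1,316 volumes, first two discarded
    for saturation, resting segment RS1 = volumes 1-210 with the last four
    dropped (task onset), RS2 = volumes 1107-1316 with the first four dropped
    (task offset); 204 retained timepoints per segment.
    """

    n_volumes: int = 1316
    tr: float = 2.0
    discard_initial: int = 2
    rs1_window: tuple[int, int] = (1, 210)
    rs1_trim_tail: int = 4
    rs2_window: tuple[int, int] = (1107, 1316)
    rs2_trim_head: int = 4

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        for name, (lo, hi) in (("rs1", self.rs1_window), ("rs2", self.rs2_window)):
            if not (1 <= lo <= hi <= self.n_volumes):
                raise ValueError(f"{name}_window {lo}-{hi} outside run of {self.n_volumes} volumes")
        if set(self._window_range(self.rs1_window)) & set(self._window_range(self.rs2_window)):
            raise ValueError("rs1 and rs2 windows overlap")

    @staticmethod
    def _window_range(window: tuple[int, int]) -> range:
        return range(window[0], window[1] + 1)

    def rs1_volumes(self) -> np.ndarray:
        vols = np.arange(self.rs1_window[0], self.rs1_window[1] + 1)
        vols = vols[vols > self.discard_initial]
        if self.rs1_trim_tail:
            vols = vols[: len(vols) - self.rs1_trim_tail]
        return vols

    def rs2_volumes(self) -> np.ndarray:
        vols = np.arange(self.rs2_window[0], self.rs2_window[1] + 1)
        vols = vols[vols > self.discard_initial]
        if self.rs2_trim_head:
            vols = vols[self.rs2_trim_head:]
        return vols

    def segment_volumes(self) -> dict[str, np.ndarray]:
        return {"RS1": self.rs1_volumes(), "RS2": self.rs2_volumes()}


def compact_layout(tr: float = 2.0) -> RunLayout:
    """A segments-only layout (418 volumes, no task block) for fast runs.

    Keeps the study's segment arithmetic (204 retained timepoints per
    segment after discard and trims) without the 896-volume task block.
    """
    return RunLayout(
        n_volumes=418,
        tr=tr,
        discard_initial=2,
        rs1_window=(1, 210),
        rs1_trim_tail=4,
        rs2_window=(211, 418),
        rs2_trim_head=4,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes of the non-neural signal components (node courses have
    unit variance, so amplitudes are in signal-sd units)."""

    white_sd: float = 0.3
    drift_amp: float = 0.5
    highfreq_amp: float = 0.3
    highfreq_hz: float = 0.15
    confound_amp: float = 0.4
    confound_fwhm: float = 20.0  # spatial extent of confound loadings, mm

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(
            white_sd=self.white_sd * factor,
            drift_amp=self.drift_amp * factor,
            highfreq_amp=self.highfreq_amp * factor,
            highfreq_hz=self.highfreq_hz,
            confound_amp=self.confound_amp * factor,
            confound_fwhm=self.confound_fwhm,
        )


ZERO_NOISE = NoiseSpec(white_sd=0.0, drift_amp=0.0, highfreq_amp=0.0, confound_amp=0.0)


@dataclass
class CohortTruth:
    """Everything the generator planted, for downstream recovery checks."""

    nodes: list[NodeSpec]
    grid: Grid
    mask: VolumeMask
    modes_true: np.ndarray  # n_nodes x n_voxels
    corr_true: dict  # (condition, segment) -> n_nodes x n_nodes
    realized_corr: dict  # (subject, condition, segment) -> n_nodes x n_nodes
    confounds: dict  # (subject, condition) -> T x m array (motion + tissue)
    confound_names: list[str]
    layout: RunLayout
    subjects: list[str]
    conditions: list[str]
    seed: int
    behavior_true: dict = field(default_factory=dict)  # (subject, condition) -> VAS

    @property
    def node_labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def node_index(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown node label {label!r}; known: {self.node_labels}"
            ) from None


def make_spatial_modes(
    nodes: Sequence[NodeSpec],
    grid: Grid,
    mask: Optional[VolumeMask] = None,
) -> np.ndarray:
    """Render nodes as non-negative Gaussian blobs over the mask.

    Returns an ``n_nodes x n_voxels`` matrix; each row peaks at the voxel
    nearest the node center and follows ``amplitude * exp(-4 ln2 d^2 / fwhm^2)``.
    A vanishing fwhm degenerates to a single-voxel indicator.
    """
    if not nodes:
        raise ValueError("nodes must be non-empty")
    if mask is None:
        mask = full_mask(grid)
    coords = mask.coords_mm()
    rows = np.empty((len(nodes), mask.n_voxels))
    for i, node in enumerate(nodes):
        if not grid.contains(node.center):
            raise ValueError(
                f"node {node.label!r} center {node.center} lies outside the grid"
            )
        d2 = np.sum((coords - np.asarray(node.center)) ** 2, axis=1)
        if node.fwhm < 1e-3 * grid.voxel_size:
            row = np.zeros(mask.n_voxels)
            row[np.argmin(d2)] = node.amplitude
        else:
            row = node.amplitude * np.exp(-4.0 * np.log(2.0) * d2 / node.fwhm**2)
        rows[i] = row
    return rows


def make_pcc_template(
    grid: Grid,
    mask: Optional[VolumeMask] = None,
    center: tuple[float, float, float] = PCC_TEMPLATE_CENTER,
    size_mm3: float = PCC_TEMPLATE_SIZE_MM3,
) -> np.ndarray:
    """Posterior-cingulate spatial template for labelling the DMN component.

    A Gaussian blob at the template's center of mass whose full-width at
    half-maximum matches the diameter of a sphere with the template's volume.
    """
    radius = (3.0 * size_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    node = NodeSpec("PCC_template", center, fwhm=2.0 * radius)
    return make_spatial_modes([node], grid, mask)[0]


def validate_correlation(corr: np.ndarray, labels: Optional[Sequence[str]] = None) -> np.ndarray:
    """Check symmetry, unit diagonal and positive semi-definiteness.

    Raises ``ValueError`` naming the offending node pair where one can be
    identified (an off-diagonal entry outside [-1, 1], or — for an
    indefinite matrix — the strongest off-diagonal pair, the usual culprit).
    """
    corr = np.asarray(corr, float)
    n = corr.shape[0]
    if corr.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    names = list(labels) if labels is not None else [str(i) for i in range(n)]

    def pair(i, j):
        return f"({names[i]}, {names[j]})"

    if not np.allclose(corr, corr.T, atol=1e-10):
        i, j = np.unravel_index(np.argmax(np.abs(corr - corr.T)), corr.shape)
        raise ValueError(f"correlation matrix not symmetric at pair {pair(i, j)}")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix diagonal must be 1")
    off = np.abs(corr - np.eye(n))
    if off.max() > 1 + 1e-12:
        i, j = np.unravel_index(np.argmax(off), corr.shape)
        raise ValueError(f"|r| > 1 at pair {pair(i, j)}")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        i, j = np.unravel_index(np.argmax(off), corr.shape)
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g}); strongest off-diagonal pair {pair(i, j)}"
        )
    return corr


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """Square root factor L with L @ L.T = corr (Cholesky; eigen fallback
    for PSD-but-singular matrices)."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def sample_node_courses(corr: np.ndarray, n_timepoints: int, rng: np.random.Generator,
                        labels: Optional[Sequence[str]] = None) -> np.ndarray:
    """Draw ``n_nodes x T`` unit-variance Gaussian courses with the target
    cross-correlation (Cholesky transform of i.i.d. innovations)."""
    corr = validate_correlation(corr, labels)
    L = _corr_factor(corr)
    z = rng.standard_normal((corr.shape[0], n_timepoints))
    return L @ z


def default_corr_by_condition(
    baseline_r: float = 0.5,
    delta_r: float = 0.4,
    affected_pairs: Sequence[tuple[str, str]] = (
        ("PCC", "RIPC"),
        ("LIPC", "RPHC"),
        ("ACC", "LPHC"),
    ),
    labels: Optional[Sequence[str]] = None,
    conditions: tuple[str, str] = ("escitalopram", "placebo"),
) -> dict[str, np.ndarray]:
    """Planted study conditions: uniform baseline connectivity under placebo,
    reduced by ``delta_r`` on three node-disjoint connections under drug.

    The affected pairs share no node, so the drug matrix remains positive
    semi-definite at the default baseline.
    """
    if labels is None:
        labels = list(_DMN_CENTERS)
    labels = list(labels)
    n = len(labels)
    base = np.full((n, n), baseline_r)
    np.fill_diagonal(base, 1.0)
    drug = base.copy()
    for a, b in affected_pairs:
        i, j = labels.index(a), labels.index(b)
        drug[i, j] = drug[j, i] = baseline_r - delta_r
    validate_correlation(base, labels)
    validate_correlation(drug, labels)
    return {conditions[0]: drug, conditions[1]: base}


def _motion_like(rng: np.random.Generator, n_t: int, n_series: int = 6) -> np.ndarray:
    """Slow random-walk series resembling rigid-body motion parameters."""
    steps = rng.normal(0.0, 1.0, (n_t, n_series))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return walk / sd


def _tissue_like(rng: np.random.Generator, n_t: int, n_series: int = 2) -> np.ndarray:
    """Smooth autocorrelated series standing in for ventricle/white-matter
    mean signals."""
    from scipy.ndimage import gaussian_filter1d

    raw = rng.standard_normal((n_t, n_series))
    sm = gaussian_filter1d(raw, sigma=4.0, axis=0, mode="reflect")
    sm -= sm.mean(axis=0)
    sd = sm.std(axis=0)
    sd[sd == 0] = 1.0
    return sm / sd


def simulate_cohort(
    nodes: Optional[Sequence[NodeSpec]] = None,
    corr_by_condition: Optional[Mapping[str, np.ndarray]] = None,
    n_subjects: int = 10,
    layout: Optional[RunLayout] = None,
    noise: Optional[NoiseSpec] = None,
    grid: Optional[Grid] = None,
    mask: Optional[VolumeMask] = None,
    seed: int = 0,
    dtype=np.float32,
) -> tuple[list[VolumeSeries], CohortTruth]:
    """Simulate one full run per subject and condition.

    Node courses are drawn per run with the condition's target correlation,
    projected through the spatial modes, and contaminated with a random
    linear + one-cycle cosine drift, a >0.1 Hz sinusoid with random phase,
    motion/tissue-like confound series (also returned for nuisance
    regression) and white noise. Identical seeds give bit-identical output.
    """
    if nodes is None:
        nodes = default_nodes()
    if corr_by_condition is None:
        corr_by_condition = default_corr_by_condition()
    if layout is None:
        layout = RunLayout()
    if noise is None:
        noise = NoiseSpec()
    if grid is None:
        grid = DEFAULT_GRID
    if mask is None:
        mask = full_mask(grid)
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")

    labels = [n.label for n in nodes]
    conditions = list(corr_by_condition)
    for cond in conditions:
        validate_correlation(np.asarray(corr_by_condition[cond], float), labels)

    modes = make_spatial_modes(nodes, grid, mask)
    amps = np.array([n.amplitude for n in nodes])
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    T = layout.n_volumes
    t = np.arange(T)
    seg_vols = layout.segment_volumes()

    confound_names = [f"motion_{i + 1}" for i in range(6)] + ["ventricle", "white_matter"]
    runs: list[VolumeSeries] = []
    realized: dict = {}
    confounds: dict = {}

    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_subjects * len(conditions))
    k = 0
    for subject in subjects:
        for cond in conditions:
            rng = np.random.default_rng(streams[k])
            k += 1
            corr = np.asarray(corr_by_condition[cond], float)
            courses = sample_node_courses(corr, T, rng, labels)
            for seg, vols in seg_vols.items():
                realized[(subject, cond, seg)] = np.corrcoef(courses[:, vols - 1])

            data = (amps[:, None] * courses).T @ modes  # T x V

            lin = (t - t.mean()) / max(t.std(), 1.0)
            cosine = np.cos(2.0 * np.pi * t / T)
            drift = noise.drift_amp * (rng.normal() * lin + rng.normal() * cosine)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            hf = noise.highfreq_amp * np.sin(
                2.0 * np.pi * noise.highfreq_hz * t * layout.tr + phase
            )
            data += (drift + hf)[:, None]

            conf = np.column_stack([_motion_like(rng, T), _tissue_like(rng, T)])
            confounds[(subject, cond)] = conf
            if noise.confound_amp > 0:
                # each confound loads on a compact random region (artifacts
                # such as ventricle/white-matter signal or motion-related
                # intensity shifts are spatially localized, which is also
                # what lets spatial ICA separate them on real data)
                coords = mask.coords_mm()
                centers = coords[rng.integers(0, mask.n_voxels, conf.shape[1])]
                loadings = np.empty((conf.shape[1], mask.n_voxels))
                for ci, ctr in enumerate(centers):
                    d2 = np.sum((coords - ctr) ** 2, axis=1)
                    loadings[ci] = noise.confound_amp * np.exp(
                        -4.0 * np.log(2.0) * d2 / noise.confound_fwhm**2
                    )
                data += conf @ loadings

            if noise.white_sd > 0:
                data += rng.normal(0.0, noise.white_sd, data.shape)

            runs.append(
                VolumeSeries(
                    data=data.astype(dtype),
                    mask=mask,
                    tr=layout.tr,
                    subject=subject,
                    condition=cond,
                    segment="full",
                )
            )

    truth = CohortTruth(
        nodes=list(nodes),
        grid=grid,
        mask=mask,
        modes_true=modes,
        corr_true={
            (cond, seg): np.asarray(corr_by_condition[cond], float)
            for cond in conditions
            for seg in seg_vols
        },
        realized_corr=realized,
        confounds=confounds,
        confound_names=confound_names,
        layout=layout,
        subjects=subjects,
        conditions=conditions,
        seed=seed,
    )
    return runs, truth


def make_behavior(
    truth: CohortTruth,
    link_connection: tuple[str, str] = ("PCC", "RIPC"),
    rho: float = 0.8,
    means: Optional[Mapping[str, float]] = None,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-(subject, condition) alertness ratings (VAS, 0-100).

    Each subject's condition-averaged alertness correlates ``rho`` (in
    expectation) with that subject's condition-averaged realized Fisher-Z
    connectivity on ``link_connection``; condition means are as requested
    (defaults: 67.0 under drug, 81.4 under placebo). Subject-level noise is
    shared across conditions so the condition average attains ``rho``.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if means is None:
        means = {c: m for c, m in zip(truth.conditions, (67.0, 81.4))}
    i = truth.node_index(link_connection[0])
    j = truth.node_index(link_connection[1])
    if i == j:
        raise ValueError("link_connection must name two distinct nodes")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xBEAF)))
    segs = sorted({s for (_, _, s) in truth.realized_corr})
    x = np.array(
        [
            np.mean(
                [
                    np.arctanh(np.clip(truth.realized_corr[(s, c, seg)][i, j], -1 + 1e-7, 1 - 1e-7))
                    for c in truth.conditions
                    for seg in segs
                ]
            )
            for s in truth.subjects
        ]
    )
    sd_x = x.std()
    u = (x - x.mean()) / sd_x if sd_x > 0 else np.zeros_like(x)
    eps = rng.standard_normal(len(truth.subjects))
    eps -= eps.mean()  # keep the requested condition means exact
    latent = rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * eps

    rows = []
    for si, subject in enumerate(truth.subjects):
        for cond in truth.conditions:
            score = float(np.clip(means[cond] + noise_sd * latent[si], 0.0, 100.0))
            truth.behavior_true[(subject, cond)] = score
            rows.append({"subject": subject, "condition": cond, "alertness": score})
    return pd.DataFrame(rows)


def write_cohort(
    runs: Sequence[VolumeSeries],
    truth: CohortTruth,
    outdir: str | Path,
    behavior: Optional[pd.DataFrame] = None,
) -> dict:
    """Write the cohort to disk: one 4-D NIfTI per run, the mask, a
    ground-truth JSON and (optionally) a behavior TSV. Returns a manifest."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask_path = outdir / "mask.nii.gz"
    _io.save_mask(truth.mask, mask_path)

    entries = []
    for run in runs:
        name = f"{run.subject}_{run.condition}_bold.nii.gz"
        _io.save_series(run, outdir / name)
        entries.append(
            {"subject": run.subject, "condition": run.condition, "bold": name}
        )

    truth_dict = {
        "seed": truth.seed,
        "subjects": truth.subjects,
        "conditions": truth.conditions,
        "nodes": [
            {"label": n.label, "center": list(n.center), "fwhm": n.fwhm, "amplitude": n.amplitude}
            for n in truth.nodes
        ],
        "corr_true": {
            f"{cond}|{seg}": m.tolist() for (cond, seg), m in truth.corr_true.items()
        },
        "layout": {
            "n_volumes": truth.layout.n_volumes,
            "tr": truth.layout.tr,
            "discard_initial": truth.layout.discard_initial,
            "rs1_window": list(truth.layout.rs1_window),
            "rs1_trim_tail": truth.layout.rs1_trim_tail,
            "rs2_window": list(truth.layout.rs2_window),
            "rs2_trim_head": truth.layout.rs2_trim_head,
        },
        "grid": {
            "shape": list(truth.grid.shape),
            "voxel_size": truth.grid.voxel_size,
            "origin": list(truth.grid.origin),
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth_dict, indent=2))

    conf_dir = outdir / "confounds"
    conf_dir.mkdir(exist_ok=True)
    for (subject, cond), conf in truth.confounds.items():
        pd.DataFrame(conf, columns=truth.confound_names).to_csv(
            conf_dir / f"{subject}_{cond}_confounds.tsv", sep="\t", index=False
        )
        for e in entries:
            if e["subject"] == subject and e["condition"] == cond:
                e["confounds"] = f"confounds/{subject}_{cond}_confounds.tsv"

    manifest = {"mask": "mask.nii.gz", "truth": "truth.json", "runs": entries}
    if behavior is not None:
        behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
        manifest["behavior"] = "behavior.tsv"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote cohort with %d runs to %s", len(runs), outdir)
    return manifest
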