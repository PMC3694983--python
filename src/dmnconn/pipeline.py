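"""End-to-end orchestration of the connectivity analysis.

The pipeline mirrors a pharmacological cross-over resting-state study:
synthetic (or manifest-listed) runs are preprocessed, one resting segment is
concatenated per drug condition and decomposed with group spatial ICA, the
DMN component is selected by template correlation and dual-regressed onto
both resting segments of every run, voxelwise and ROI-level 2x2
repeated-measures inference is applied, and regional connectivity is
correlated with alertness ratings across participants.

Stages exchange intermediate artifacts through a :class:`Workspace` whose
files carry the configuration hash, so partial reruns with a different
configuration are refused.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .connectivity import (
    define_rois,
    extract_roi_timeseries,
    highfreq_regressors,
    nuisance_regress,
    pair_labels,
    pairwise_connectivity,
)
from .core import Grid, VolumeMask, VolumeSeries, full_mask
from .dualreg import dual_regress_run, spatial_regress
from .ica import concatenate_group, fastica_spatial, pca_reduce, select_dmn_component
from .preprocess import discard_and_segment, highpass_cutoff_hz, preprocess_run, znormalize_time
from .stats import (
    bh_fdr,
    behavior_correlation,
    estimate_smoothness,
    montecarlo_cluster_threshold,
    one_sample_tmap,
    posthoc_paired_t,
    rmanova_2x2,
    voxelwise_rmanova,
    FACTORS,
)
from .synthetic import (
    DEFAULT_GRID,
    CohortTruth,
    NoiseSpec,
    RunLayout,
    default_corr_by_condition,
    default_nodes,
    make_behavior,
    make_pcc_template,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_table", "read_table"]

SEGMENTS = ("RS1", "RS2")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the analysis; serializable and hashed."""

    n_subjects: int = 10
    conditions: tuple[str, str] = ("escitalopram", "placebo")
    layout: RunLayout = field(default_factory=RunLayout)
    grid: Grid = field(default_factory=lambda: DEFAULT_GRID)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    k_components: int = 40
    highpass_cycles: int = 5
    smooth_fwhm_mm: float = 6.0
    q_fdr: float = 0.05
    cluster_alpha: float = 0.05
    n_montecarlo: int = 1000
    nuisance_cutoff_hz: float = 0.1
    template_path: Optional[str] = None
    baseline_r: float = 0.5
    delta_r: float = 0.4
    affected_pairs: tuple[tuple[str, str], ...] = (
        ("PCC", "RIPC"), ("LIPC", "RPHC"), ("ACC", "LPHC"),
    )
    link_connection: tuple[str, str] = ("PCC", "RIPC")
    behavior_rho: float = 0.8
    behavior_means: tuple[float, float] = (67.0, 81.4)
    node_fwhm_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q_fdr <= 1 and 0 < self.cluster_alpha <= 1):
            raise ValueError("q_fdr and cluster_alpha must lie in (0, 1]")
        if self.k_components < 1 or self.highpass_cycles < 1:
            raise ValueError("k_components and highpass_cycles must be >= 1")
        if self.nuisance_cutoff_hz <= 0:
            raise ValueError("nuisance_cutoff_hz must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"] = asdict(self.layout)
        d["grid"] = {"shape": list(self.grid.shape), "voxel_size": self.grid.voxel_size,
                     "origin": list(self.grid.origin)}
        d["noise"] = asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("layout"), Mapping):
            lay = dict(d["layout"])
            lay["rs1_window"] = tuple(lay["rs1_window"])
            lay["rs2_window"] = tuple(lay["rs2_window"])
            d["layout"] = RunLayout(**lay)
        if isinstance(d.get("grid"), Mapping):
            g = d["grid"]
            d["grid"] = Grid(tuple(g["shape"]), g["voxel_size"], tuple(g["origin"]))
        if isinstance(d.get("noise"), Mapping):
            d["noise"] = NoiseSpec(**d["noise"])
        for key in ("conditions", "link_connection", "behavior_means"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("affected_pairs") is not None:
            d["affected_pairs"] = tuple(tuple(p) for p in d["affected_pairs"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """Write a TSV whose first line records the configuration hash."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, expect_hash: Optional[str] = None) -> pd.DataFrame:
    """Read a hash-stamped TSV, refusing a mismatched configuration hash."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# config_hash="):
            raise ValueError(f"{path} carries no config hash")
        found = first.split("=", 1)[1]
        if expect_hash is not None and found != expect_hash:
            raise ValueError(
                f"{path} was produced under config {found}, expected {expect_hash}"
            )
        return pd.read_csv(fh, sep="\t")


class Workspace:
    """Directory of stage intermediates, all stamped with the config hash."""

    def __init__(self, root: str | Path, config: PipelineConfig, create: bool = True):
        self.root = Path(root)
        self.config = config
        if create:
            self.root.mkdir(parents=True, exist_ok=True)
            cfg_path = self.root / "config.json"
            if cfg_path.exists():
                stored = PipelineConfig.from_json(cfg_path.read_text())
                if stored.hash != config.hash:
                    raise ValueError(
                        f"workspace {self.root} holds config {stored.hash}, "
                        f"current is {config.hash}; refusing partial rerun"
                    )
            else:
                cfg_path.write_text(config.to_json())

    def save_arrays(self, name: str, **arrays: np.ndarray) -> None:
        np.savez(self.root / f"{name}.npz", _config_hash=self.config.hash, **arrays)

    def load_arrays(self, name: str) -> dict:
        path = self.root / f"{name}.npz"
        if not path.exists():
            raise FileNotFoundError(f"intermediate {name!r} missing; run earlier stages first")
        with np.load(path, allow_pickle=False) as z:
            found = str(z["_config_hash"])
            if found != self.config.hash:
                raise ValueError(
                    f"{path} was produced under config {found}, expected {self.config.hash}"
                )
            return {k: z[k] for k in z.files if k != "_config_hash"}

    def save_json(self, name: str, obj) -> None:
        payload = {"_config_hash": self.config.hash, "data": obj}
        (self.root / f"{name}.json").write_text(json.dumps(payload, indent=2))

    def load_json(self, name: str):
        path = self.root / f"{name}.json"
        if not path.exists():
            raise FileNotFoundError(f"intermediate {name!r} missing; run earlier stages first")
        payload = json.loads(path.read_text())
        if payload.get("_config_hash") != self.config.hash:
            raise ValueError(f"{path} carries a mismatched config hash")
        return payload["data"]


@dataclass
class PipelineResult:
    """Tables and summaries produced by one pipeline run."""

    config: PipelineConfig
    roi_table: pd.DataFrame
    connectivity: pd.DataFrame
    rmanova: pd.DataFrame
    posthoc: pd.DataFrame
    behavior_corr: pd.DataFrame
    template_match: dict
    aggregate_rows: int
    voxelwise: dict
    cluster_threshold_mm3: float
    smoothness_fwhm_mm: float
    drug_significant: list
    behavior: Optional[pd.DataFrame] = None
    truth: Optional[CohortTruth] = None
    rois: list = field(default_factory=list)

    @property
    def n_connections(self) -> int:
        return int(self.rmanova.shape[0])


# ---------------------------------------------------------------------------
# input assembly


def _synthetic_inputs(config: PipelineConfig):
    nodes = default_nodes(fwhm=config.node_fwhm_mm)
    corr = default_corr_by_condition(
        baseline_r=config.baseline_r,
        delta_r=config.delta_r,
        affected_pairs=config.affected_pairs,
        conditions=config.conditions,
    )
    runs, truth = simulate_cohort(
        nodes=nodes,
        corr_by_condition=corr,
        n_subjects=config.n_subjects,
        layout=config.layout,
        noise=config.noise,
        grid=config.grid,
        seed=config.seed,
    )
    behavior = make_behavior(
        truth,
        link_connection=config.link_connection,
        rho=config.behavior_rho,
        means=dict(zip(config.conditions, config.behavior_means)),
        seed=config.seed,
    )
    template = make_pcc_template(config.grid, truth.mask)
    confounds = truth.confounds
    return runs, truth.mask, template, confounds, behavior, truth


def _manifest_inputs(config: PipelineConfig, manifest_path: str | Path):
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    for key in ("mask", "runs"):
        if key not in manifest:
            raise ValueError(f"manifest missing required entry {key!r}")
    mask = _io.load_mask(base / manifest["mask"])
    runs, confounds = [], {}
    for entry in manifest["runs"]:
        bold = base / entry["bold"]
        if not bold.exists():
            raise FileNotFoundError(f"manifest lists missing run {bold}")
        runs.append(
            _io.load_series(
                bold, mask, tr=config.layout.tr,
                subject=entry["subject"], condition=entry["condition"],
            )
        )
        if "confounds" in entry:
            conf = pd.read_csv(base / entry["confounds"], sep="\t")
            confounds[(entry["subject"], entry["condition"])] = conf.to_numpy(float)
    if config.template_path:
        template = _io.load_map(config.template_path, mask)
    elif "template" in manifest:
        template = _io.load_map(base / manifest["template"], mask)
    else:
        template = make_pcc_template(mask.grid, mask)
    behavior = None
    if "behavior" in manifest:
        behavior = pd.read_csv(base / manifest["behavior"], sep="\t")
    return runs, mask, template, confounds, behavior, None


# ---------------------------------------------------------------------------
# stages


def preprocess_stage(
    runs: Sequence[VolumeSeries], config: PipelineConfig
) -> dict[tuple[str, str], dict[str, VolumeSeries]]:
    """Filter every run and extract the two resting segments."""
    out: dict[tuple[str, str], dict[str, VolumeSeries]] = {}
    for run in runs:
        filtered = preprocess_run(
            run, config.layout,
            n_cycles=config.highpass_cycles,
            smooth_fwhm_mm=config.smooth_fwhm_mm,
        )
        rs1, rs2 = discard_and_segment(filtered, config.layout)
        out[(run.subject, run.condition)] = {"full": filtered, "RS1": rs1, "RS2": rs2}
    return out


def ica_stage(
    prepped: Mapping[tuple[str, str], Mapping[str, VolumeSeries]],
    template: np.ndarray,
    config: PipelineConfig,
) -> dict[str, dict]:
    """Per-condition group ICA of the first resting segment + DMN selection."""
    out = {}
    for cond in config.conditions:
        segs = [
            prepped[(subj, cond)]["RS1"]
            for subj, c in sorted(prepped) if c == cond
        ]
        agg = concatenate_group(segs)
        reduced = pca_reduce(agg, k=config.k_components)
        decomp = fastica_spatial(
            reduced, k=config.k_components, seed=config.seed,
            condition=cond, segment="RS1",
        )
        match = select_dmn_component(decomp, template)
        out[cond] = {"decomp": decomp, "match": match, "agg_rows": int(agg.shape[0])}
    return out


def dualreg_stage(
    prepped: Mapping[tuple[str, str], Mapping[str, VolumeSeries]],
    ica_out: Mapping[str, dict],
    config: PipelineConfig,
) -> tuple[dict, dict]:
    """Dual-regress each condition's modes onto both segments of its runs.

    Returns ``(dmn_maps, full_timecourses)`` where ``dmn_maps`` maps
    ``(condition, segment)`` to an ``n_subjects x V`` array of
    orientation-consistent DMN betas and ``full_timecourses`` maps
    ``(subject, condition)`` to the ``T x k`` mode courses of the complete
    filtered run (used downstream as nuisance regressors).
    """
    subjects = sorted({s for s, _ in prepped})
    dmn_maps: dict[tuple[str, str], np.ndarray] = {}
    full_tc: dict[tuple[str, str], np.ndarray] = {}
    for cond in config.conditions:
        decomp = ica_out[cond]["decomp"]
        match = ica_out[cond]["match"]
        sign = 1.0 if match.all_r[match.index] >= 0 else -1.0
        per_seg = {seg: [] for seg in SEGMENTS}
        # dual regression runs on the filtered (unnormalized) data: the
        # Z-normalization applies to the spatial modes, and per-voxel
        # variance scaling would erase the maps' amplitude profile
        for subj in subjects:
            run = prepped[(subj, cond)]
            full_tc[(subj, cond)] = spatial_regress(decomp.modes, run["full"])
            for seg in SEGMENTS:
                dr = dual_regress_run(decomp, run[seg])
                per_seg[seg].append(sign * dr.subject_maps[match.index])
        for seg in SEGMENTS:
            dmn_maps[(cond, seg)] = np.vstack(per_seg[seg])
    return dmn_maps, full_tc


def roi_stage(
    dmn_maps: Mapping[tuple[str, str], np.ndarray],
    mask: VolumeMask,
    config: PipelineConfig,
):
    """Average DMN maps, test against zero, calibrate the cluster rule and
    define ROIs."""
    cells = [dmn_maps[(c, s)] for c in config.conditions for s in SEGMENTS]
    avg_maps = np.mean(cells, axis=0)  # n_subjects x V
    t, p = one_sample_tmap(avg_maps)

    resid = avg_maps - avg_maps.mean(axis=0)
    fwhms = []
    for row in resid:
        try:
            fwhms.append(estimate_smoothness(row, mask))
        except ValueError:
            continue
    fwhm = float(np.mean(fwhms)) if fwhms else mask.grid.voxel_size

    _, fdr_thr = bh_fdr(p, config.q_fdr)
    voxel_p = fdr_thr if fdr_thr > 0 else 1e-3
    cluster = montecarlo_cluster_threshold(
        mask, fwhm, voxel_p=voxel_p, alpha=config.cluster_alpha,
        n_iter=config.n_montecarlo, seed=config.seed,
    )
    rois = define_rois(
        p, mask, q=config.q_fdr, min_cluster_mm3=cluster.min_size_mm3, tvals=t
    )
    return rois, t, p, fwhm, cluster


def connectivity_stage(
    prepped: Mapping[tuple[str, str], Mapping[str, VolumeSeries]],
    full_tc: Mapping[tuple[str, str], np.ndarray],
    ica_out: Mapping[str, dict],
    rois: Sequence,
    confounds: Mapping[tuple[str, str], np.ndarray],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Denoised pairwise ROI connectivity per subject, condition and segment."""
    labels = [r.label for r in rois]
    rows = []
    subjects = sorted({s for s, _ in prepped})
    for subj in subjects:
        for cond in config.conditions:
            run = prepped[(subj, cond)]
            full = run["full"]
            courses = np.vstack([extract_roi_timeseries(full, r) for r in rois])
            tc = full_tc[(subj, cond)]
            dmn_idx = ica_out[cond]["match"].index
            non_dmn = np.delete(tc, dmn_idx, axis=1)
            extra = confounds.get((subj, cond))
            if extra is not None:
                # confounds are tabulated per original volume; align to the
                # filtered run via its provenance indices
                extra = np.asarray(extra, float)[full.orig_index - 1]
                base_conf = np.column_stack([non_dmn, extra])
            else:
                base_conf = non_dmn
            pos_by_seg = {}
            for seg in SEGMENTS:
                seg_vols = set(run[seg].orig_index.tolist())
                pos_by_seg[seg] = np.flatnonzero(
                    np.isin(full.orig_index, list(seg_vols))
                )
            for seg in SEGMENTS:
                pos = pos_by_seg[seg]
                hf = highfreq_regressors(len(pos), full.tr, config.nuisance_cutoff_hz)
                conf_seg = np.column_stack([base_conf[pos], hf])
                resid = np.vstack(
                    [nuisance_regress(c[pos], conf_seg) for c in courses]
                )
                rec = pairwise_connectivity(
                    resid, labels, subject=subj, condition=cond,
                )["full"]
                for a, b in pair_labels(labels):
                    rows.append(
                        {
                            "subject": subj, "condition": cond, "segment": seg,
                            "roi_a": a, "roi_b": b, "z": rec.pair(a, b),
                        }
                    )
    return pd.DataFrame(rows)


def stats_stage(
    conn: pd.DataFrame,
    behavior: Optional[pd.DataFrame],
    config: PipelineConfig,
):
    """Connection-level RM-ANOVA with FDR, post-hoc paired t-tests, and
    brain-behavior correlations."""
    subjects = sorted(conn["subject"].unique())
    pairs = sorted({(a, b) for a, b in zip(conn["roi_a"], conn["roi_b"])})
    n, m = len(subjects), len(pairs)
    y = np.full((n, 2, 2, m), np.nan)
    lookup = {
        (r.subject, r.condition, r.segment, r.roi_a, r.roi_b): r.z
        for r in conn.itertuples()
    }
    for si, subj in enumerate(subjects):
        for ci, cond in enumerate(config.conditions):
            for gi, seg in enumerate(SEGMENTS):
                for pi, (a, b) in enumerate(pairs):
                    y[si, ci, gi, pi] = lookup[(subj, cond, seg, a, b)]
    table = rmanova_2x2(y)

    reject = {}
    rows = []
    for factor in FACTORS:
        reject[factor], _ = bh_fdr(table.p[factor], config.q_fdr)
    for pi, (a, b) in enumerate(pairs):
        row = {"roi_a": a, "roi_b": b}
        for factor in FACTORS:
            row[f"F_{factor}"] = float(table.F[factor][pi])
            row[f"p_{factor}"] = float(table.p[factor][pi])
            row[f"sig_{factor}"] = bool(reject[factor][pi])
        rows.append(row)
    rmanova_df = pd.DataFrame(rows)
    rmanova_df.attrs["df"] = (table.df_num, table.df_den)

    # post-hoc paired t for connections significant on any factor
    posthoc_rows = []
    any_sig = rmanova_df[[f"sig_{f}" for f in FACTORS]].any(axis=1)
    for pi, (a, b) in enumerate(pairs):
        if not any_sig.iloc[pi]:
            continue
        row = {"roi_a": a, "roi_b": b}
        for gi, seg in enumerate(SEGMENTS):
            x = y[:, 0, gi, pi]  # first condition (drug)
            z = y[:, 1, gi, pi]  # second condition (placebo)
            t, p, df = posthoc_paired_t(x, z)
            row[f"{seg}_{config.conditions[0]}"] = float(x.mean())
            row[f"{seg}_{config.conditions[1]}"] = float(z.mean())
            row[f"{seg}_t"] = t
            row[f"{seg}_p"] = p
        row["df"] = df
        posthoc_rows.append(row)
    posthoc_df = pd.DataFrame(posthoc_rows)

    behavior_rows = []
    if behavior is not None and len(behavior):
        piv = behavior.pivot_table(index="subject", columns="condition", values="alertness")
        piv = piv.loc[subjects, list(config.conditions)]
        for pi, (a, b) in enumerate(pairs):
            conn_by_cond = y[:, :, :, pi].mean(axis=2)  # n x 2, averaged over segments
            try:
                r, p = behavior_correlation(conn_by_cond, piv.to_numpy())
            except ValueError:
                r, p = np.nan, np.nan
            behavior_rows.append({"roi_a": a, "roi_b": b, "r": r, "p": p})
    behavior_df = pd.DataFrame(behavior_rows)

    drug_sig = [
        (r.roi_a, r.roi_b) for r in rmanova_df.itertuples() if r.sig_drug
    ]
    return rmanova_df, posthoc_df, behavior_df, drug_sig


# ---------------------------------------------------------------------------
# top level


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    manifest: Optional[str | Path] = None,
    write_volumes: bool = True,
    make_figures: bool = True,
) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("dmnconn")
    root_logger.addHandler(handler)
    prev_level = root_logger.level
    root_logger.setLevel(logging.INFO)
    try:
        if manifest is None:
            runs, mask, template, confounds, behavior, truth = _synthetic_inputs(config)
        else:
            runs, mask, template, confounds, behavior, truth = _manifest_inputs(
                config, manifest
            )
        logger.info("pipeline %s: %d runs, mask of %d voxels", cfg_hash, len(runs), mask.n_voxels)

        prepped = preprocess_stage(runs, config)
        del runs
        ica_out = ica_stage(prepped, template, config)
        dmn_maps, full_tc = dualreg_stage(prepped, ica_out, config)
        rois, tmap, pmap, fwhm, cluster = roi_stage(dmn_maps, mask, config)
        voxelwise = voxelwise_rmanova(
            dmn_maps, mask, q=config.q_fdr,
            min_cluster_mm3=cluster.min_size_mm3,
            conditions=config.conditions, segments=SEGMENTS,
        )

        roi_table = pd.DataFrame(
            [
                {
                    "label": r.label, "k_mm3": r.size_mm3,
                    "x": round(r.center[0], 1), "y": round(r.center[1], 1),
                    "z": round(r.center[2], 1), "n_voxels": r.n_voxels,
                }
                for r in rois
            ]
        )

        if len(rois) >= 2:
            conn = connectivity_stage(prepped, full_tc, ica_out, rois, confounds, config)
            rmanova_df, posthoc_df, behavior_df, drug_sig = stats_stage(
                conn, behavior, config
            )
        else:
            logger.warning("fewer than 2 ROIs; skipping connectivity stages")
            conn = pd.DataFrame()
            rmanova_df = posthoc_df = behavior_df = pd.DataFrame()
            drug_sig = []

        match_summary = {
            cond: {
                "index": int(ica_out[cond]["match"].index),
                "r_abs": float(ica_out[cond]["match"].r_abs),
            }
            for cond in config.conditions
        }

        write_table(roi_table, outdir / "roi_table.tsv", cfg_hash)
        write_table(conn, outdir / "connectivity.tsv", cfg_hash)
        write_table(rmanova_df, outdir / "rmanova.tsv", cfg_hash)
        write_table(posthoc_df, outdir / "posthoc.tsv", cfg_hash)
        write_table(behavior_df, outdir / "behavior_correlation.tsv", cfg_hash)
        if behavior is not None:
            write_table(behavior, outdir / "behavior.tsv", cfg_hash)

        if write_volumes:
            for cond in config.conditions:
                _io.save_map(
                    ica_out[cond]["match"].mode, mask, outdir / f"dmn_mode_{cond}.nii.gz"
                )
            _io.save_map(tmap, mask, outdir / "one_sample_t.nii.gz")
            _io.save_mask(mask, outdir / "mask.nii.gz")

        import importlib.metadata as _md

        provenance = {
            "config": config.to_dict(),
            "config_hash": cfg_hash,
            "seed": config.seed,
            "n_runs": len(prepped),
            "mask_voxels": mask.n_voxels,
            "aggregate_rows": ica_out[config.conditions[0]]["agg_rows"],
            "highpass_cutoff_hz": highpass_cutoff_hz(
                config.layout.n_volumes - config.layout.discard_initial,
                config.layout.tr, config.highpass_cycles,
            ),
            "smoothness_fwhm_mm": fwhm,
            "cluster_min_size_mm3": cluster.min_size_mm3,
            "template_match": match_summary,
            "versions": {
                pkg: _md.version(pkg)
                for pkg in ("numpy", "scipy", "pandas", "scikit-learn", "statsmodels", "nibabel")
            },
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

        if make_figures and len(rmanova_df):
            _figure_fmatrix(rmanova_df, outdir / "rmanova_f.png")

        return PipelineResult(
            config=config,
            roi_table=roi_table,
            connectivity=conn,
            rmanova=rmanova_df,
            posthoc=posthoc_df,
            behavior_corr=behavior_df,
            template_match=match_summary,
            aggregate_rows=ica_out[config.conditions[0]]["agg_rows"],
            voxelwise={
                f: {"n_significant": int(voxelwise[f]["significant"].sum())}
                for f in FACTORS
            },
            cluster_threshold_mm3=cluster.min_size_mm3,
            smoothness_fwhm_mm=fwhm,
            drug_significant=drug_sig,
            behavior=behavior,
            truth=truth,
            rois=list(rois),
        )
    finally:
        root_logger.removeHandler(handler)
        root_logger.setLevel(prev_level)
        handler.close()


def _figure_fmatrix(rmanova_df: pd.DataFrame, path: Path) -> None:
    """Color-coded F-value matrices per factor (simple static rendering)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(set(rmanova_df["roi_a"]) | set(rmanova_df["roi_b"]))
    idx = {lab: i for i, lab in enumerate(labels)}
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, factor in zip(axes, FACTORS):
        m = np.full((len(labels), len(labels)), np.nan)
        for r in rmanova_df.itertuples():
            i, j = idx[r.roi_a], idx[r.roi_b]
            val = getattr(r, f"F_{factor}")
            m[i, j] = m[j, i] = val
        im = ax.imshow(m, cmap="viridis")
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(labels)), labels, fontsize=7)
        ax.set_title(f"F ({factor})")
        for r in rmanova_df.itertuples():
            if getattr(r, f"sig_{factor}"):
                for i, j in ((idx[r.roi_a], idx[r.roi_b]), (idx[r.roi_b], idx[r.roi_a])):
                    ax.text(j, i, "*", ha="center", va="center", color="w")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def simulate_to_dir(config: PipelineConfig, outdir: str | Path) -> Path:
    """Simulate a cohort under the config and write it (NIfTI + truth JSON +
    behavior TSV + manifest) to ``outdir``; returns the manifest path."""
    runs, mask, template, confounds, behavior, truth = _synthetic_inputs(config)
    write_cohort(runs, truth, outdir, behavior=behavior)
    _io.save_map(template, mask, Path(outdir) / "pcc_template.nii.gz")
    manifest_path = Path(outdir) / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    manifest["template"] = "pcc_template.nii.gz"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
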