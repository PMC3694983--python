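"""Parameter-recovery studies on the synthetic model.

These routines replay the study's inference chain on many simulated cohorts
to measure operating characteristics: how reliably a planted drug-only
connectivity change is flagged by the Drug factor of the 2x2 RM-ANOVA after
FDR correction, how often unaffected connections are flagged, and how well
the alertness-connectivity link correlation is recovered. They work at the
node-course level — regional mean courses with measurement noise — because
the voxel stages (spatial rendering, smoothing, dual regression) are
deterministic linear maps whose fidelity is established by their own tests;
repeating them per seed would add runtime, not statistical information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import pairwise_connectivity, pair_labels
from .core import Grid, full_mask
from .stats import bh_fdr, behavior_correlation, rmanova_2x2
from .synthetic import (
    CohortTruth,
    RunLayout,
    default_corr_by_condition,
    default_nodes,
    make_behavior,
    sample_node_courses,
)

logger = logging.getLogger(__name__)

__all__ = ["RecoveryResult", "drug_effect_recovery", "behavior_link_recovery"]


@dataclass
class RecoveryResult:
    """Operating characteristics of Drug-factor detection over seeds."""

    sensitivity: float
    false_positive_rate: float
    sign_agreement: float
    n_seeds: int
    n_flagged_true: int
    n_flagged_false: int


def _segment_connectivity(
    corr: np.ndarray,
    labels: list[str],
    T: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fisher-Z matrix of one run segment: target-correlated node courses
    plus white measurement noise on the regional means."""
    courses = sample_node_courses(corr, T, rng, labels)
    if noise_sd > 0:
        courses = courses + rng.normal(0.0, noise_sd, courses.shape)
    rec = pairwise_connectivity(courses, labels)["full"]
    return rec.z


def drug_effect_recovery(
    n_seeds: int = 50,
    n_subjects: int = 10,
    n_timepoints: int = 204,
    baseline_r: float = 0.5,
    delta_r: float = 0.4,
    affected_pairs: tuple = (("PCC", "RIPC"), ("LIPC", "RPHC"), ("ACC", "LPHC")),
    noise_sd: float = 0.3,
    q: float = 0.05,
    seed: int = 0,
) -> RecoveryResult:
    """Detection of a planted drug-only connectivity decrease.

    Per seed: simulate a full 2 (drug) x 2 (segment) within-subject design
    of node-course connectivity with ``delta_r`` removed from the affected
    pairs under drug, run the per-connection 2x2 RM-ANOVA, apply BH-FDR at
    ``q`` to the Drug factor, and score flagged connections against the
    planted ground truth. Sign agreement checks that flagged planted
    connections show lower drug-condition connectivity.
    """
    labels = [n.label for n in default_nodes()]
    corr = default_corr_by_condition(
        baseline_r=baseline_r, delta_r=delta_r,
        affected_pairs=affected_pairs, labels=labels,
        conditions=("drug", "placebo"),
    )
    pairs = pair_labels(labels)
    affected = {tuple(sorted(p)) for p in affected_pairs}
    is_affected = np.array([tuple(sorted(p)) in affected for p in pairs])
    iu = np.triu_indices(len(labels), k=1)

    root = np.random.SeedSequence(entropy=(seed, 0xD06))
    hits = miss = fp = tn = 0
    sign_ok = sign_bad = 0
    for child in root.spawn(n_seeds):
        rng = np.random.default_rng(child)
        y = np.empty((n_subjects, 2, 2, len(pairs)))
        for s in range(n_subjects):
            for ci, cond in enumerate(("drug", "placebo")):
                for gi in range(2):
                    z = _segment_connectivity(
                        corr[cond], labels, n_timepoints, noise_sd, rng
                    )
                    y[s, ci, gi] = z[iu]
        table = rmanova_2x2(y)
        reject, _ = bh_fdr(table.p["drug"], q)
        drug_minus_placebo = (y[:, 0] - y[:, 1]).mean(axis=(0, 1))
        hits += int(np.sum(reject & is_affected))
        miss += int(np.sum(~reject & is_affected))
        fp += int(np.sum(reject & ~is_affected))
        tn += int(np.sum(~reject & ~is_affected))
        flagged_true = reject & is_affected
        sign_ok += int(np.sum(flagged_true & (drug_minus_placebo < 0)))
        sign_bad += int(np.sum(flagged_true & (drug_minus_placebo >= 0)))

    result = RecoveryResult(
        sensitivity=hits / max(hits + miss, 1),
        false_positive_rate=fp / max(fp + tn, 1),
        sign_agreement=sign_ok / max(sign_ok + sign_bad, 1),
        n_seeds=n_seeds,
        n_flagged_true=hits,
        n_flagged_false=fp,
    )
    logger.info(
        "drug-effect recovery over %d seeds: sensitivity %.3f, FPR %.3f, sign %.3f",
        n_seeds, result.sensitivity, result.false_positive_rate, result.sign_agreement,
    )
    return result


def _minimal_truth(
    labels: list[str], n_subjects: int, n_timepoints: int,
    corr_by_condition: dict, rng: np.random.Generator, seed: int,
) -> CohortTruth:
    """CohortTruth carrying only what behavior generation needs (realized
    node-course correlations per subject/condition/segment)."""
    nodes = [n for n in default_nodes() if n.label in labels]
    grid = Grid((2, 2, 2), 3.0, (-60.0, -60.0, -60.0))
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    conditions = list(corr_by_condition)
    realized = {}
    for s in subjects:
        for cond in conditions:
            for seg in ("RS1", "RS2"):
                courses = sample_node_courses(
                    corr_by_condition[cond], n_timepoints, rng, labels
                )
                realized[(s, cond, seg)] = np.corrcoef(courses)
    return CohortTruth(
        nodes=nodes, grid=grid, mask=full_mask(grid),
        modes_true=np.zeros((len(nodes), 8)),
        corr_true={(c, s): corr_by_condition[c] for c in conditions for s in ("RS1", "RS2")},
        realized_corr=realized, confounds={}, confound_names=[],
        layout=RunLayout(), subjects=subjects, conditions=conditions, seed=seed,
    )


def behavior_link_recovery(
    n_reps: int = 200,
    n_subjects: int = 10,
    n_timepoints: int = 204,
    rho: float = 0.8,
    link: tuple[str, str] = ("PCC", "RIPC"),
    seed: int = 0,
) -> tuple[float, float]:
    """Mean recovered alertness-connectivity correlation over replicates.

    Each replicate draws realized per-subject connectivity, generates
    alertness with link correlation ``rho``, and recomputes the
    across-subject condition-averaged Pearson correlation the study reports.
    Returns ``(mean r, sd of r)``.
    """
    labels = [n.label for n in default_nodes()]
    corr = default_corr_by_condition(labels=labels)
    i, j = labels.index(link[0]), labels.index(link[1])
    root = np.random.SeedSequence(entropy=(seed, 0xBE))
    rs = []
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        truth = _minimal_truth(labels, n_subjects, n_timepoints, corr, rng, seed)
        behavior = make_behavior(truth, link_connection=link, rho=rho, seed=seed + rep)
        z = np.array(
            [
                [
                    np.mean(
                        [
                            np.arctanh(truth.realized_corr[(s, c, seg)][i, j])
                            for seg in ("RS1", "RS2")
                        ]
                    )
                    for c in truth.conditions
                ]
                for s in truth.subjects
            ]
        )
        piv = behavior.pivot_table(index="subject", columns="condition", values="alertness")
        b = piv.loc[truth.subjects, truth.conditions].to_numpy()
        r, _ = behavior_correlation(z, b)
        rs.append(r)
    return float(np.mean(rs)), float(np.std(rs))
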