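"""Shared fixtures: small grids and a coarse synthetic cohort.

Everything is generated at test time; the coarse 6-mm grid keeps the
voxel-level fixtures fast while covering the same mm extent as the default
3-mm simulation grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from dmnconn.core import Grid, full_mask
from dmnconn.pipeline import PipelineConfig, ica_stage, preprocess_stage
from dmnconn.synthetic import (
    NoiseSpec,
    compact_layout,
    default_corr_by_condition,
    default_nodes,
    make_pcc_template,
    simulate_cohort,
)

COARSE_GRID = Grid((16, 20, 13), 6.0, (-45.0, -60.0, -24.0))


@pytest.fixture(scope="session")
def coarse_grid() -> Grid:
    return COARSE_GRID


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid((12, 14, 10), 3.0, (-18.0, -21.0, -15.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config(coarse_grid) -> PipelineConfig:
    """Fast full-pipeline configuration: coarse grid, segments-only layout."""
    return PipelineConfig(
        grid=coarse_grid,
        layout=compact_layout(),
        k_components=10,
        n_montecarlo=200,
        seed=1,
    )


@pytest.fixture(scope="session")
def cohesive_cohort(coarse_grid):
    """Cohort with a strongly shared network fluctuation (uniform r = 0.9):
    the regime in which the whole network emerges as a single spatial mode."""
    nodes = default_nodes()
    n = len(nodes)
    corr = np.full((n, n), 0.9)
    np.fill_diagonal(corr, 1.0)
    runs, truth = simulate_cohort(
        nodes=nodes,
        corr_by_condition={"a": corr, "b": corr},
        n_subjects=10,
        layout=compact_layout(),
        noise=NoiseSpec(white_sd=0.5),  # at the 0.5 x signal-sd boundary
        grid=coarse_grid,
        seed=7,
    )
    return runs, truth


@pytest.fixture(scope="session")
def cohesive_ica(cohesive_cohort, coarse_grid):
    """Preprocessed cohesive cohort plus its per-condition decomposition."""
    runs, truth = cohesive_cohort
    cfg = PipelineConfig(
        grid=coarse_grid, layout=truth.layout, k_components=10,
        conditions=("a", "b"), seed=7,
    )
    prepped = preprocess_stage(runs, cfg)
    template = make_pcc_template(coarse_grid, truth.mask)
    out = ica_stage(prepped, template, cfg)
    return {"prepped": prepped, "truth": truth, "ica": out, "config": cfg,
            "template": template}
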