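"""Generator tests: spatial modes, planted correlations, behavior link."""

import numpy as np
import pytest

from dmnconn.core import Grid, full_mask
from dmnconn.synthetic import (
    DEFAULT_GRID,
    NodeSpec,
    NoiseSpec,
    RunLayout,
    ZERO_NOISE,
    compact_layout,
    default_corr_by_condition,
    default_nodes,
    make_behavior,
    make_spatial_modes,
    sample_node_courses,
    simulate_cohort,
    validate_correlation,
)


class TestSpatialModes:
    def test_default_nodes_peak_at_their_centers(self):
        nodes = default_nodes()
        modes = make_spatial_modes(nodes, DEFAULT_GRID)
        assert modes.shape == (7, DEFAULT_GRID.n_voxels)
        centers = DEFAULT_GRID.all_centers_mm()
        for row, node in zip(modes, nodes):
            peak = centers[np.argmax(row)]
            nearest = DEFAULT_GRID.index_to_mm(DEFAULT_GRID.mm_to_index(node.center))
            assert np.allclose(peak, nearest)
        # posterior cingulate node peaks at the voxel nearest (0, -51, 25):
        # the grid samples z at ..., 24, 27, so the peak sits at (0, -51, 24)
        pcc = modes[0]
        peak = centers[np.argmax(pcc)]
        assert np.allclose(peak[:2], (0.0, -51.0))
        assert abs(peak[2] - 25.0) <= DEFAULT_GRID.voxel_size / 2

    def test_vanishing_fwhm_gives_single_voxel_indicator(self, small_grid):
        node = NodeSpec("pt", (0.0, 0.0, 0.0), fwhm=0.0, amplitude=2.0)
        row = make_spatial_modes([node], small_grid)[0]
        assert np.count_nonzero(row) == 1
        assert row.max() == 2.0

    def test_distant_nodes_are_spatially_uncorrelated(self):
        grid = Grid((30, 10, 10), 3.0, (-43.5, -13.5, -13.5))
        a = NodeSpec("a", (-20.0, 0.0, 0.0), fwhm=8.0)
        b = NodeSpec("b", (20.0, 0.0, 0.0), fwhm=8.0)
        modes = make_spatial_modes([a, b], grid)
        r = np.corrcoef(modes)[0, 1]
        assert abs(r) < 0.05

    def test_center_outside_grid_names_the_node(self, small_grid):
        node = NodeSpec("wayout", (500.0, 0.0, 0.0), fwhm=8.0)
        with pytest.raises(ValueError, match="wayout"):
            make_spatial_modes([node], small_grid)

    def test_empty_node_list_rejected(self, small_grid):
        with pytest.raises(ValueError):
            make_spatial_modes([], small_grid)


class TestCorrelationValidation:
    def test_non_psd_matrix_names_a_pair(self):
        m = np.array([[1.0, 0.95, -0.95], [0.95, 1.0, 0.95], [-0.95, 0.95, 1.0]])
        with pytest.raises(ValueError, match=r"\("):
            validate_correlation(m, ["x", "y", "z"])

    def test_out_of_range_entry_names_its_pair(self):
        m = np.eye(2)
        m[0, 1] = m[1, 0] = 1.2
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            validate_correlation(m, ["a", "b"])

    def test_default_condition_matrices_are_valid(self):
        for mat in default_corr_by_condition().values():
            validate_correlation(mat)


class TestSimulateCohort:
    def test_planted_correlations_recovered_from_noiseless_volumes(self, small_grid):
        """r(A,B) = 0.9 vs 0.3 per condition, T = 204, noise -> 0: node
        courses recomputed from the volumes match the targets within 0.05."""
        nodes = [
            NodeSpec("A", (-9.0, 0.0, 0.0), fwhm=6.0),
            NodeSpec("B", (9.0, 0.0, 0.0), fwhm=6.0),
        ]
        corr = {
            "condA": np.array([[1.0, 0.9], [0.9, 1.0]]),
            "condB": np.array([[1.0, 0.3], [0.3, 1.0]]),
        }
        layout = compact_layout()
        runs, truth = simulate_cohort(
            nodes, corr, n_subjects=10, layout=layout, noise=ZERO_NOISE,
            grid=small_grid, seed=3,
        )
        modes = truth.modes_true
        sampled = {c: [] for c in corr}
        for run in runs:
            rs1 = layout.rs1_volumes() - 1
            data = np.asarray(run.data, float)[rs1]
            # recover courses by least squares on the known spatial modes
            courses, *_ = np.linalg.lstsq(modes.T, data.T, rcond=None)
            sampled[run.condition].append(np.corrcoef(courses)[0, 1])
        # averaging over subjects beats the single-draw sampling sd of ~0.06
        for cond, rs in sampled.items():
            assert abs(np.mean(rs) - corr[cond][0, 1]) < 0.05

    def test_identity_correlation_matches_null_sampling(self, rng):
        """Independent courses: mean |off-diagonal r| at T = 204 agrees with
        the analytic null level E|r| = sqrt(2 / (pi (T-1)))."""
        T, reps = 204, 200
        vals = []
        for _ in range(reps):
            c = sample_node_courses(np.eye(3), T, rng)
            r = np.corrcoef(c)
            vals.extend(np.abs(r[np.triu_indices(3, 1)]))
        expected = np.sqrt(2.0 / (np.pi * (T - 1)))
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)

    def test_same_seed_is_bit_identical(self, small_grid):
        kw = dict(
            nodes=default_nodes()[:2],
            corr_by_condition={"a": np.eye(2)},
            n_subjects=2,
            layout=compact_layout(),
            grid=small_grid,
            seed=11,
        )
        # two distinct node centers inside the small grid
        kw["nodes"] = [
            NodeSpec("A", (-9.0, 0.0, 0.0), fwhm=6.0),
            NodeSpec("B", (9.0, 0.0, 0.0), fwhm=6.0),
        ]
        runs1, _ = simulate_cohort(**kw)
        runs2, _ = simulate_cohort(**kw)
        for r1, r2 in zip(runs1, runs2):
            assert np.array_equal(r1.data, r2.data)

    def test_output_finite_everywhere(self, small_grid):
        nodes = [NodeSpec("A", (0.0, 0.0, 0.0), fwhm=9.0)]
        runs, _ = simulate_cohort(
            nodes, {"a": np.eye(1)}, n_subjects=2, layout=compact_layout(),
            grid=small_grid, seed=5,
        )
        for run in runs:
            assert np.all(np.isfinite(run.data))

    def test_long_run_converges_to_target(self, rng):
        """Sample correlation converges to the target: within 0.01 at T=20,000."""
        corr = default_corr_by_condition()["placebo"]
        c = sample_node_courses(corr, 20_000, rng)
        r = np.corrcoef(c)
        assert np.max(np.abs(r - corr)) < 0.01

    def test_fewer_than_two_subjects_rejected(self, small_grid):
        with pytest.raises(ValueError):
            simulate_cohort(
                [NodeSpec("A", (0.0, 0.0, 0.0), fwhm=6.0)], {"a": np.eye(1)},
                n_subjects=1, layout=compact_layout(), grid=small_grid,
            )


class TestRunLayout:
    def test_study_layout_segment_lengths(self):
        """RS1: 210 window - 2 discarded - 4 trimmed = 204. RS2: the
        210-volume window loses only its first four volumes, giving 206 by
        index arithmetic (the stated per-segment count of 204 holds for RS1)."""
        layout = RunLayout()
        assert len(layout.rs1_volumes()) == 204
        assert len(layout.rs2_volumes()) == 206

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RunLayout(rs1_window=(1, 700), rs2_window=(600, 1316))

    def test_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            RunLayout(rs2_window=(1107, 2000))


def _cohort_for_behavior(small_grid, seed=9):
    nodes = [
        NodeSpec("A", (-9.0, 0.0, 0.0), fwhm=6.0),
        NodeSpec("B", (9.0, 0.0, 0.0), fwhm=6.0),
    ]
    corr = {"drug": np.eye(2), "placebo": np.eye(2)}
    _, truth = simulate_cohort(
        nodes, corr, n_subjects=10, layout=compact_layout(), noise=ZERO_NOISE,
        grid=small_grid, seed=seed,
    )
    return truth


class TestBehavior:
    def test_default_condition_means(self, small_grid):
        truth = _cohort_for_behavior(small_grid)
        df = make_behavior(truth, link_connection=("A", "B"), rho=0.5, seed=2)
        means = df.groupby("condition")["alertness"].mean()
        assert means["drug"] == pytest.approx(67.0, abs=1e-9)
        assert means["placebo"] == pytest.approx(81.4, abs=1e-9)

    def test_scores_stay_in_vas_range(self, small_grid):
        truth = _cohort_for_behavior(small_grid)
        df = make_behavior(truth, link_connection=("A", "B"), rho=0.0,
                           noise_sd=60.0, seed=3)
        assert df["alertness"].between(0.0, 100.0).all()

    def test_rho_one_zero_noise_is_exact_affine(self, small_grid):
        truth = _cohort_for_behavior(small_grid)
        df = make_behavior(truth, link_connection=("A", "B"), rho=1.0, seed=4)
        piv = df.pivot_table(index="subject", columns="condition", values="alertness")
        avg_alert = piv.mean(axis=1).loc[truth.subjects].to_numpy()
        z = np.array(
            [
                np.mean(
                    [
                        np.arctanh(truth.realized_corr[(s, c, seg)][0, 1])
                        for c in truth.conditions
                        for seg in ("RS1", "RS2")
                    ]
                )
                for s in truth.subjects
            ]
        )
        r = np.corrcoef(avg_alert, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rho_zero_independent_of_connectivity(self, small_grid):
        """Over many replicates the link correlation is centred at zero."""
        truth = _cohort_for_behavior(small_grid)
        z = np.array(
            [
                np.mean(
                    [
                        np.arctanh(truth.realized_corr[(s, c, seg)][0, 1])
                        for c in truth.conditions
                        for seg in ("RS1", "RS2")
                    ]
                )
                for s in truth.subjects
            ]
        )
        rs = []
        for rep in range(500):
            df = make_behavior(truth, link_connection=("A", "B"), rho=0.0, seed=rep)
            piv = df.pivot_table(index="subject", columns="condition", values="alertness")
            avg = piv.mean(axis=1).loc[truth.subjects].to_numpy()
            rs.append(np.corrcoef(avg, z)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_unknown_connection_label_rejected(self, small_grid):
        truth = _cohort_for_behavior(small_grid)
        with pytest.raises(KeyError, match="nope"):
            make_behavior(truth, link_connection=("A", "nope"))
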