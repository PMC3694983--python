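"""Inference tests: t-maps, FDR, smoothness, cluster calibration, RM-ANOVA,
post-hoc tests and the brain-behavior correlation."""

import numpy as np
import pytest
from scipy import ndimage, stats as sps

from dmnconn.core import Grid, VolumeMask, full_mask
from dmnconn.stats import (
    bh_fdr,
    behavior_correlation,
    estimate_smoothness,
    montecarlo_cluster_threshold,
    one_sample_tmap,
    posthoc_paired_t,
    rmanova_2x2,
    rmanova_from_table,
    voxelwise_rmanova,
)


class TestOneSampleTmap:
    def test_symmetric_values_give_null(self):
        maps = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        t, p = one_sample_tmap(maps)
        assert t[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)

    def test_one_to_ten_matches_arithmetic_oracle(self):
        vals = np.arange(1.0, 11.0)[:, None]
        t, p = one_sample_tmap(vals)
        # mean 5.5, sd 3.0276503...; t = 5.5 / (sd / sqrt(10)), df = 9
        sd = 3.0276503540974917
        expected_t = 5.5 / (sd / np.sqrt(10))
        assert t[0] == pytest.approx(expected_t, abs=1e-10)
        assert p[0] == pytest.approx(2 * sps.t.sf(expected_t, df=9), abs=1e-12)

    def test_zero_variance_voxel_flagged(self):
        maps = np.column_stack([np.full(5, 2.0), np.arange(5.0)])
        t, p = one_sample_tmap(maps)
        assert t[0] == 0.0 and p[0] == 1.0


class TestBhFdr:
    def test_step_up_rule_by_hand(self):
        """p = {.01, .02, .04, .6} at q = .05: thresholds i*q/m are
        .0125/.025/.0375/.05; the largest i with p(i) <= i q/m is 2."""
        reject, thr = bh_fdr(np.array([0.01, 0.02, 0.04, 0.6]), q=0.05)
        assert reject.sum() == 2
        assert thr == pytest.approx(0.02)

    def test_all_tiny_pvalues_all_rejected(self):
        reject, _ = bh_fdr(np.full(21, 0.001), q=0.05)
        assert reject.all()

    def test_agrees_with_independent_step_up_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=40)
            reject, _ = bh_fdr(p, q=0.05)
            # independent step-up implementation
            order = np.argsort(p)
            m = len(p)
            below = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * 0.05 / m))
            expected = np.zeros(m, bool)
            if below.size:
                expected[order[: below.max() + 1]] = True
            assert np.array_equal(reject, expected)

    def test_empirical_fdr_controlled_under_null(self, rng):
        """2,000 uniform-null replicates, m = 100: empirical FDR <= q + 0.01."""
        q, m, reps = 0.05, 100, 2000
        fdp = []
        for _ in range(reps):
            reject, _ = bh_fdr(rng.uniform(size=m), q=q)
            fdp.append(reject.sum() > 0)  # all rejections are false under the null
        assert np.mean(fdp) <= q + 0.01

    def test_empty_input(self):
        reject, thr = bh_fdr(np.array([]), q=0.05)
        assert reject.size == 0


class TestSmoothness:
    def _field(self, rng, shape=(30, 30, 30), fwhm_vox=0.0):
        x = rng.standard_normal(shape)
        if fwhm_vox > 0:
            x = ndimage.gaussian_filter(x, sigma=fwhm_vox / 2.3548, mode="reflect")
        return x

    def test_white_noise_estimates_at_voxel_size(self, rng):
        grid = Grid((30, 30, 30), 3.0)
        mask = full_mask(grid)
        ests = [
            estimate_smoothness(self._field(rng).ravel(), mask) for _ in range(20)
        ]
        assert np.mean(ests) == pytest.approx(3.0, rel=0.15)

    def test_six_mm_smoothness_recovered(self, rng):
        grid = Grid((30, 30, 30), 3.0)
        mask = full_mask(grid)
        ests = [
            estimate_smoothness(self._field(rng, fwhm_vox=2.0).ravel(), mask)
            for _ in range(50)
        ]
        assert np.mean(ests) == pytest.approx(6.0, rel=0.15)

    def test_estimate_increases_with_applied_smoothing(self, rng):
        grid = Grid((30, 30, 30), 3.0)
        mask = full_mask(grid)
        x = rng.standard_normal(grid.shape)
        est3 = estimate_smoothness(
            ndimage.gaussian_filter(x, sigma=1.0 / 2.3548, mode="reflect").ravel(), mask
        )
        est9 = estimate_smoothness(
            ndimage.gaussian_filter(x, sigma=3.0 / 2.3548, mode="reflect").ravel(), mask
        )
        assert est9 > est3

    def test_constant_image_rejected(self):
        grid = Grid((5, 5, 5), 3.0)
        with pytest.raises(ValueError, match="constant"):
            estimate_smoothness(np.ones(grid.n_voxels), full_mask(grid))


class TestMonteCarloClusterThreshold:
    def test_alpha_one_gives_single_voxel(self):
        mask = full_mask(Grid((8, 8, 8), 3.0))
        thr = montecarlo_cluster_threshold(
            mask, fwhm_mm=0.0, voxel_p=0.01, alpha=1.0, n_iter=100, seed=0
        )
        assert thr.min_size_voxels == 1

    def test_unsmoothed_threshold_matches_analytic_approximation(self):
        """fwhm -> 0, voxel p = 0.001, 1,000-voxel mask: suprathreshold
        voxels are independent Bernoulli draws, and a binomial/Poisson
        argument fixes the threshold."""
        grid = Grid((10, 10, 10), 3.0)
        mask = full_mask(grid)
        voxel_p, alpha = 0.001, 0.05
        thr = montecarlo_cluster_threshold(
            mask, fwhm_mm=0.0, voxel_p=voxel_p, alpha=alpha, n_iter=1000, seed=3
        )
        # oracle: P(any suprathreshold voxel) per tail
        p_tail = voxel_p / 2.0
        n = grid.n_voxels
        p_any = 1.0 - (1.0 - voxel_p) ** n  # ~0.63 > alpha -> size 1 fails
        assert p_any > alpha
        # expected face-adjacent suprathreshold pairs (both tails):
        n_adj = 3 * 10 * 10 * 9
        lam = 2 * n_adj * p_tail**2
        p_pair = 1.0 - np.exp(-lam)  # ~0.0013 <= alpha -> size 2 passes
        assert p_pair <= alpha
        assert thr.min_size_voxels == 2

    def test_threshold_nondecreasing_in_smoothness(self):
        mask = full_mask(Grid((16, 16, 16), 3.0))
        kw = dict(voxel_p=0.01, alpha=0.05, n_iter=300, seed=5)
        t3 = montecarlo_cluster_threshold(mask, fwhm_mm=3.0, **kw)
        t9 = montecarlo_cluster_threshold(mask, fwhm_mm=9.0, **kw)
        assert t9.min_size_voxels >= t3.min_size_voxels

    def test_min_size_is_multiple_of_voxel_volume(self):
        mask = full_mask(Grid((8, 8, 8), 3.0))
        thr = montecarlo_cluster_threshold(mask, 6.0, 0.01, n_iter=100, seed=1)
        assert thr.min_size_mm3 == thr.min_size_voxels * 27.0


def _brute_force_rmanova(y):
    """Independent sum-of-squares oracle for the 2x2 within-subject design."""
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a = y.mean(axis=(0, 2))
    b = y.mean(axis=(0, 1))
    ab = y.mean(axis=0)
    out = {}
    # drug
    ss_a = 2 * n * np.sum((a - grand) ** 2) / 1  # 2 levels of the other factor
    sa = y.mean(axis=2)  # subject x drug
    ss_as = 2 * np.sum((sa - subj[:, None] - a[None, :] + grand) ** 2)
    out["drug"] = (ss_a / 1) / (ss_as / (n - 1))
    # time
    ss_b = 2 * n * np.sum((b - grand) ** 2)
    sb = y.mean(axis=1)
    ss_bs = 2 * np.sum((sb - subj[:, None] - b[None, :] + grand) ** 2)
    out["time"] = (ss_b / 1) / (ss_bs / (n - 1))
    # interaction
    ss_ab = n * np.sum((ab - a[:, None] - b[None, :] + grand) ** 2)
    resid = (
        y
        - sa[:, :, None]
        - sb[:, None, :]
        - ab[None, :, :]
        + subj[:, None, None]
        + a[None, :, None]
        + b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)
    out["interaction"] = (ss_ab / 1) / (ss_abs / (n - 1))
    return out


class TestRmAnova:
    def test_time_symmetric_data_has_zero_time_effect(self, rng):
        y = rng.normal(size=(8, 2, 2))
        y[:, :, 1] = y[:, :, 0]  # identical time levels
        table = rmanova_2x2(y)
        assert table.F["time"] == pytest.approx(0.0, abs=1e-20)

    def test_f_equals_squared_paired_contrast_t(self, rng):
        """For every factor, F equals the squared paired t on the
        corresponding within-subject contrast."""
        y = rng.normal(size=(10, 2, 2))
        table = rmanova_2x2(y)
        t_drug = sps.ttest_rel(y[:, 0].mean(axis=1), y[:, 1].mean(axis=1)).statistic
        t_time = sps.ttest_rel(y[:, :, 0].mean(axis=1), y[:, :, 1].mean(axis=1)).statistic
        inter = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])
        t_int = sps.ttest_1samp(inter, 0.0).statistic
        assert table.F["drug"] == pytest.approx(t_drug**2, abs=1e-8)
        assert table.F["time"] == pytest.approx(t_time**2, abs=1e-8)
        assert table.F["interaction"] == pytest.approx(t_int**2, abs=1e-8)
        assert (table.df_num, table.df_den) == (1, 9)

    def test_matches_brute_force_ss_oracle(self, rng):
        y = rng.normal(size=(3, 2, 2))
        table = rmanova_2x2(y)
        oracle = _brute_force_rmanova(y)
        for factor in ("drug", "time", "interaction"):
            assert table.F[factor] == pytest.approx(oracle[factor], abs=1e-8)

    def test_matches_pingouin_two_way_rm(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.normal(size=(10, 2, 2))
        rows = [
            {"subject": s, "drug": d, "time": t, "y": y[s, di, ti]}
            for s in range(10)
            for di, d in enumerate("AB")
            for ti, t in enumerate("XY")
        ]
        df = pd.DataFrame(rows)
        aov = pg.rm_anova(df, dv="y", within=["drug", "time"], subject="subject")
        table = rmanova_2x2(y)
        by_name = {"drug": "drug", "time": "time", "drug * time": "interaction"}
        for _, row in aov.iterrows():
            factor = by_name[row["Source"].lower()]
            assert table.F[factor] == pytest.approx(row["F"], rel=1e-8)
            assert table.p[factor] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_missing_cell_names_subject(self):
        import pandas as pd

        rows = [
            {"subject": s, "condition": c, "segment": g, "z": 0.1}
            for s in ("s1", "s2", "s3")
            for c in ("drug", "placebo")
            for g in ("RS1", "RS2")
        ]
        df = pd.DataFrame(rows[:-1])  # s3 lacks (placebo, RS2)
        with pytest.raises(ValueError, match="s3"):
            rmanova_from_table(df)

    def test_vectorized_matches_scalar(self, rng):
        y = rng.normal(size=(6, 2, 2, 15))
        table = rmanova_2x2(y)
        for v in range(15):
            single = rmanova_2x2(y[:, :, :, v])
            for factor in ("drug", "time", "interaction"):
                assert table.F[factor][v] == pytest.approx(single.F[factor], abs=1e-10)


class TestVoxelwiseRmAnova:
    def _maps(self, rng, n, V, effect=None):
        out = {}
        for ci, cond in enumerate(("drug", "placebo")):
            for seg in ("RS1", "RS2"):
                m = rng.normal(size=(n, V))
                if effect is not None and cond == "drug":
                    m[:, effect] += 3.0
                out[(cond, seg)] = m
        return out

    def test_global_null_survives_almost_nowhere(self, rng):
        grid = Grid((8, 8, 8), 3.0)
        mask = full_mask(grid)
        counts = []
        for _ in range(10):
            maps = self._maps(rng, n=10, V=grid.n_voxels)
            res = voxelwise_rmanova(maps, mask, q=0.05, min_cluster_mm3=27.0)
            counts.append(sum(res[f]["significant"].sum() for f in ("drug", "time", "interaction")))
        assert sorted(counts)[8] <= 1  # at most 1 voxel in >= 9 of 10 draws

    def test_planted_drug_effect_survives_in_region(self, rng):
        grid = Grid((10, 10, 10), 3.0)
        mask = full_mask(grid)
        region = np.zeros(grid.shape, bool)
        region[3:6, 3:6, 3:6] = True  # 27 contiguous voxels
        effect = np.flatnonzero(region.ravel())
        maps = self._maps(rng, n=10, V=grid.n_voxels, effect=effect)
        res = voxelwise_rmanova(maps, mask, q=0.05, min_cluster_mm3=270.0)
        sig = res["drug"]["significant"]
        assert sig[effect].mean() > 0.9
        assert sig[~np.isin(np.arange(grid.n_voxels), effect)].mean() < 0.01

    def test_single_voxel_reduces_to_rmanova(self, rng):
        grid = Grid((1, 1, 1), 3.0)
        mask = full_mask(grid)
        y = rng.normal(size=(8, 2, 2))
        maps = {
            (c, s): y[:, ci, si][:, None]
            for ci, c in enumerate(("drug", "placebo"))
            for si, s in enumerate(("RS1", "RS2"))
        }
        res = voxelwise_rmanova(maps, mask, q=0.05, min_cluster_mm3=27.0)
        table = rmanova_2x2(y)
        for factor in ("drug", "time", "interaction"):
            assert res[factor]["F"][0] == pytest.approx(table.F[factor], abs=1e-10)


class TestPosthocPairedT:
    def test_identical_columns_null(self, rng):
        x = rng.normal(size=10)
        t, p, df = posthoc_paired_t(x, x.copy())
        assert t == 0.0 and p == 1.0 and df == 9

    def test_matches_expected_effect_over_replicates(self, rng):
        """Constant difference d with within-pair noise sd s: mean t over
        replicates approaches d / (s / sqrt(n))."""
        n, d, s, reps = 10, 0.8, 1.0, 500
        ts = []
        for _ in range(reps):
            base = rng.normal(size=n)
            x = base + d + rng.normal(0, s, n)
            t, _, _ = posthoc_paired_t(x, base)
            ts.append(t)
        # noise enters the difference with sd s
        expected = d / (s / np.sqrt(n))
        assert np.mean(ts) == pytest.approx(expected, rel=0.15)

    def test_constant_nonzero_difference_flagged(self, rng):
        x = rng.normal(size=6)
        t, p, _ = posthoc_paired_t(x + 1.0, x)
        assert np.isinf(t) and p == 0.0


class TestBehaviorCorrelation:
    def test_exact_affine_link_gives_r_one(self, rng):
        conn = rng.normal(size=(10, 2))
        behavior = 3.0 + 2.0 * conn
        r, p = behavior_correlation(conn, behavior)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            behavior_correlation(np.ones((5, 2)), np.random.rand(5, 2))

    def test_generator_link_recovered(self):
        """Planted link rho = 0.8, n = 10: mean recovered correlation over
        replicates lies within 0.8 +/- 0.1."""
        from dmnconn.evaluation import behavior_link_recovery

        mean_r, _ = behavior_link_recovery(n_reps=200, rho=0.8, seed=3)
        assert mean_r == pytest.approx(0.8, abs=0.1)
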