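"""Inferential building blocks: closed-form agreement, symmetry,
robustness and permutation behavior."""

import numpy as np
import pytest
from scipy import stats as sps

from eegcrit.stats import (
    band_contrasts,
    bh_fdr,
    cohens_d,
    design_matrix,
    freedman_lane,
    lzc_tests,
    robust_fit,
    welch,
)

X1 = np.array([4.2, 5.1, 3.8, 6.0, 5.5, 4.9, 5.2])
Y1 = np.array([3.1, 4.0, 3.5, 2.9, 4.4, 3.3])


class TestWelch:
    def test_matches_textbook_formula(self):
        res = welch(X1, Y1)
        nx, ny = X1.size, Y1.size
        vx, vy = X1.var(ddof=1), Y1.var(ddof=1)
        se2 = vx / nx + vy / ny
        t = (X1.mean() - Y1.mean()) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        assert abs(res.t - t) < 1e-12
        assert abs(res.df - df) < 1e-12
        # independent implementation
        ref = sps.ttest_ind(X1, Y1, equal_var=False)
        assert abs(res.t - ref.statistic) < 1e-12
        assert abs(res.p - ref.pvalue) < 1e-12

    def test_identical_samples_null(self):
        res = welch(X1, X1)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_swap_antisymmetry(self):
        a, b = welch(X1, Y1), welch(Y1, X1)
        assert np.isclose(a.t, -b.t)
        assert np.isclose(a.p, b.p)
        assert np.isclose(a.ci[0], -b.ci[1])

    def test_ci_covers_difference(self):
        res = welch(X1, Y1)
        assert res.ci[0] < res.mean_diff < res.ci[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch(np.ones(5), np.ones(5))


class TestCohensD:
    def test_matches_formula(self):
        d, ci = cohens_d(X1, Y1)
        nx, ny = X1.size, Y1.size
        sp = np.sqrt(((nx - 1) * X1.var(ddof=1) + (ny - 1) * Y1.var(ddof=1)) / (nx + ny - 2))
        d_ref = (X1.mean() - Y1.mean()) / sp
        assert abs(d - d_ref) < 1e-12
        var_d = (nx + ny) / (nx * ny) + d_ref**2 / (2 * (nx + ny))
        half = sps.norm.ppf(0.975) * np.sqrt(var_d)
        assert abs(ci[0] - (d_ref - half)) < 1e-12

    def test_one_pooled_sd_shift_gives_unit_d(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2_000)
        nx = x.size
        sp = np.sqrt(x.var(ddof=1))  # pooled SD of two equal copies
        d, _ = cohens_d(x + sp, x)
        assert abs(d - 1.0) < 1e-9

    def test_equal_means_symmetric_ci(self):
        d, ci = cohens_d(X1, X1 + 0.0)
        assert d == 0.0
        assert np.isclose(ci[0], -ci[1])


class TestBhFdr:
    def test_hand_computed_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # step-up: p*(m/rank) then monotone from the largest down
        expected = np.array([0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr(p), expected)
        p2 = np.array([0.005, 0.04, 0.03, 0.9])
        expected2 = np.array([0.02, 0.0533333333, 0.0533333333, 0.9])
        np.testing.assert_allclose(bh_fdr(p2), expected2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(13)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref)

    def test_identities_and_monotonicity(self):
        p = np.full(5, 0.03)
        np.testing.assert_allclose(bh_fdr(p), p)
        np.testing.assert_allclose(bh_fdr(np.array([0.2])), [0.2])
        rng = np.random.default_rng(2)
        p = rng.random(13)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_nan_passthrough(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1])
        assert not np.isnan(q[0])


class TestRobustFit:
    @staticmethod
    def _data(n=80, seed=0, outliers=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
        beta = np.array([1.0, 2.0, -0.5])
        y = X @ beta + rng.standard_normal(n)
        if outliers:
            y[:outliers] += 20.0 * y.std()
        return X, y, beta

    def test_matches_statsmodels_rlm(self):
        import statsmodels.api as sm

        X, y, _ = self._data()
        res = robust_fit(y, X)
        ref = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(scale_est="mad")
        # small differences remain (residual-centering of the MAD scale),
        # so agreement is asserted to ~2% of an SE, not machine precision
        np.testing.assert_allclose(res.beta, ref.params, atol=0.02)
        assert np.all((res.se > 0.7 * ref.bse) & (res.se < 1.3 * ref.bse))

    def test_close_to_ols_on_clean_data(self):
        X, y, _ = self._data()
        res = robust_fit(y, X)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.all(np.abs(res.beta - ols) < 2 * res.se)
        assert res.weights.mean() > 0.85

    def test_resists_gross_outliers(self):
        X, y, beta = self._data(outliers=4, seed=3)
        rob = robust_fit(y, X).beta
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.abs(rob[1] - beta[1]) < np.abs(ols[1] - beta[1])

    def test_group_ci_coverage_near_nominal(self):
        # null group coefficient: CI should cover 0 in ~95% of replicates
        rng = np.random.default_rng(11)
        n, covered = 60, 0
        reps = 200
        for _ in range(reps):
            group = (rng.random(n) < 0.5).astype(float)
            X = design_matrix(group, rng.normal(45, 15, n), rng.random(n) < 0.4)
            y = rng.standard_normal(n)
            res = robust_fit(y, X)
            tcrit = sps.t.ppf(0.975, res.df_resid)
            covered += abs(res.beta[1]) <= tcrit * res.se[1]
        se = np.sqrt(0.95 * 0.05 / reps)
        assert abs(covered / reps - 0.95) < 3 * se + 0.01

    def test_rank_deficiency_reported(self):
        X, y, _ = self._data()
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            robust_fit(y, X)


class TestFreedmanLane:
    def test_reduces_to_label_permutation_without_covariates(self):
        rng = np.random.default_rng(5)
        n = 40
        group = np.repeat([0.0, 1.0], n // 2)
        y = rng.standard_normal(n) + 0.6 * group
        X_full = np.column_stack([np.ones(n), group])
        X_red = np.ones((n, 1))
        _, p_fl = freedman_lane(y, X_full, X_red, coef=1, n_perm=2000, rng=1)
        # direct label permutation of the same statistic
        t_obs = robust_fit(y, X_full).t[1]
        rng2 = np.random.default_rng(2)
        count = sum(
            abs(robust_fit(y, np.column_stack([np.ones(n), rng2.permutation(group)])).t[1])
            >= abs(t_obs)
            for _ in range(2000)
        )
        p_label = (1 + count) / 2001
        assert abs(p_fl - p_label) < 0.03

    def test_huge_effect_hits_floor(self):
        rng = np.random.default_rng(6)
        n = 60
        group = np.repeat([0.0, 1.0], n // 2)
        y = 10.0 * group + 0.1 * rng.standard_normal(n)
        X_full = design_matrix(group, rng.normal(45, 10, n), rng.random(n) < 0.5)
        _, p = freedman_lane(y, X_full, X_full[:, [0, 2, 3]], coef=1, n_perm=199, rng=0)
        assert p == 1.0 / 200.0

    def test_small_b_warns(self):
        rng = np.random.default_rng(7)
        n = 20
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        with pytest.warns(UserWarning, match="small"):
            freedman_lane(rng.standard_normal(n), X, X[:, :1], coef=1, n_perm=50, rng=0)


class TestLzcTests:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(40)
        res = lzc_tests(x, x + rng.standard_normal(40) * 1e-12, n_perm=500, rng=0)
        assert res["welch_p"] > 0.9
        assert res["perm_p"] > 0.9

    def test_mannwhitney_exact_on_full_separation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 11.0, 12.0, 13.0])
        res = lzc_tests(x, y, n_perm=200, rng=0)
        # exact two-sided p for complete separation: 2 / C(8,4)
        assert np.isclose(res["mannwhitney_p"], 2.0 / 70.0)

    def test_effect_direction(self):
        rng = np.random.default_rng(9)
        res = lzc_tests(rng.standard_normal(50) + 1.0, rng.standard_normal(50),
                        n_perm=200, rng=1)
        assert res["cohens_d"] > 0.5
        assert res["welch_t"] > 0


class TestBandContrasts:
    def test_structure_and_group_swap(self, mini_cohort):
        from eegcrit.metrics import metric_table

        recs, _ = mini_cohort
        table = metric_table(recs)
        res = band_contrasts(table, n_perm=30, rng=0)
        assert set(res["metric"]) == {"bis", "dfa", "ei_hlp", "fei", "ei_hls"}
        ok = res[res["p"].notna()]
        assert np.all((ok["p"] >= 0) & (ok["p"] <= 1))
        # q >= p within each family
        assert np.all(ok["q"] >= ok["p"] - 1e-12)
        # swapping group labels flips the signed statistics
        swapped = table.copy()
        swapped["group"] = swapped["group"].map({"HC": "MDD", "MDD": "HC"})
        res2 = band_contrasts(swapped, n_perm=30, rng=0)
        m = res.merge(res2, on=["metric", "band"], suffixes=("", "_sw"))
        ok2 = m[m["t"].notna() & m["t_sw"].notna()]
        np.testing.assert_allclose(ok2["t"], -ok2["t_sw"], atol=1e-10)
        np.testing.assert_allclose(ok2["d"], -ok2["d_sw"], atol=1e-10)
        np.testing.assert_allclose(ok2["p"], ok2["p_sw"], atol=1e-10)

    def test_cellwise_n_tracks_fei_gating(self, mini_cohort):
        from eegcrit.metrics import metric_table

        recs, _ = mini_cohort
        table = metric_table(recs)
        res = band_contrasts(table, n_perm=10, rng=0, metrics=("fei",))
        for _, row in res.iterrows():
            col = f"fei@{row['band']}"
            vals = table[col]
            expected = int(((table["group"] == "MDD") & vals.notna()).sum())
            assert row["n_mdd"] == expected
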