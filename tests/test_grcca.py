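"""Group-regularized CCA: metric algebra, oracle equivalence, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from grccax import (
    GRCCA,
    build_group_metric,
    fit_grcca,
    optimize_variance_fraction,
    significant_features,
    structure_correlations,
)


def dense_grcca_oracle(X, Y, groups, lam, mu):
    """Penalized generalized-eigenproblem solution, dense and brute force.

    maximize w_x' C_xy w_y subject to w_x' R w_x = 1, w_y' C_yy w_y = 1,
    solved by SVD of R^{-1/2} C_xy C_yy^{-1/2} with matrix powers computed
    numerically (no shared code with the estimator).
    """
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    Cxy = Xs.T @ Ys / (n - 1)
    Cyy = Ys.T @ Ys / (n - 1)
    p = X.shape[1]
    R = np.zeros((p, p))
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        B_block = np.ones((len(idx), len(idx))) / len(idx)
        R[np.ix_(idx, idx)] = lam * (np.eye(len(idx)) - B_block) + mu * B_block
    R_m = linalg.fractional_matrix_power(R, -0.5).real
    C_m = linalg.fractional_matrix_power(Cyy, -0.5).real
    U, s, Vt = np.linalg.svd(R_m @ Cxy @ C_m)
    wx = R_m @ U[:, 0]
    wy = C_m @ Vt[0]
    lc = abs(np.corrcoef(Xs @ wx, Ys @ wy)[0, 1])
    return wx, wy, lc


class TestGroupMetric:
    def test_singleton_groups_reduce_to_ridge(self, rng):
        m = build_group_metric(np.arange(6), lam=0.9, mu=0.1)
        np.testing.assert_allclose(m.dense(), 0.1 * np.eye(6), atol=1e-12)

    def test_global_group_quadratic_form(self, rng):
        """One group: w'Rw = lam * sum (w_i - wbar)^2 + mu * n * wbar^2."""
        w = rng.normal(size=8)
        lam, mu = 0.7, 0.05
        m = build_group_metric(np.zeros(8, dtype=int), lam, mu)
        expected = lam * np.sum((w - w.mean()) ** 2) + mu * 8 * w.mean() ** 2
        assert m.quadratic_form(w) == pytest.approx(expected, rel=1e-12)

    def test_inverse_sqrt_identity(self, rng):
        groups = rng.integers(0, 4, size=12)
        m = build_group_metric(groups, lam=0.99, mu=0.1)
        R = m.dense()
        Rinv_half = m.apply_inv_sqrt(np.eye(12))
        np.testing.assert_allclose(Rinv_half @ Rinv_half @ R, np.eye(12), atol=1e-10)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            build_group_metric(np.array([]), 0.5, 0.1)


class TestFitGrcca:
    def test_identity_problem_correlation_one(self, rng):
        Y = rng.normal(size=(40, 3))
        model = fit_grcca(Y.copy(), Y, mu=1e-6, variance_fraction=1.0)
        assert model.latent_correlation_ == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_eigenproblem_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, p, q = 50, 30, 4
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        groups = rng.integers(0, 5, size=p)
        model = fit_grcca(X, Y, groups=groups, mu=0.1, variance_fraction=1.0)
        wx, wy, lc = dense_grcca_oracle(X, Y, groups, 1 - 1 / p, 0.1)
        assert abs(model.latent_correlation_) == pytest.approx(lc, abs=1e-8)
        mx = model.x_weights_.to_numpy()
        cos = abs(wx @ mx) / (np.linalg.norm(wx) * np.linalg.norm(mx))
        assert 1 - cos < 1e-6

    def test_singleton_groups_equal_ridge_metric(self, rng):
        n, p, q = 40, 20, 3
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        a = fit_grcca(X, Y, groups=np.arange(p), mu=0.1, variance_fraction=1.0)
        b = fit_grcca(X, Y, groups=None, mu=0.1, variance_fraction=1.0)
        assert a.latent_correlation_ == pytest.approx(b.latent_correlation_, abs=1e-10)
        np.testing.assert_allclose(a.x_weights_, b.x_weights_, atol=1e-10)
        # and the ridge metric is exactly mu * I
        wx, _, lc = dense_grcca_oracle(X, Y, np.arange(p), 0.1, 0.1)  # lam irrelevant: B = I
        assert abs(a.latent_correlation_) == pytest.approx(lc, abs=1e-8)

    def test_scale_invariance_of_x_columns(self, rng):
        n, p = 30, 10
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 2))
        scaled = X.copy()
        scaled[:, 3] *= 17.0
        a = fit_grcca(X, Y, variance_fraction=0.8)
        b = fit_grcca(scaled, Y, variance_fraction=0.8)
        assert a.latent_correlation_ == pytest.approx(b.latent_correlation_, abs=1e-10)
        np.testing.assert_allclose(a.x_weights_, b.x_weights_, atol=1e-8)

    def test_sign_convention_largest_ry_positive(self, rng):
        X = rng.standard_normal((50, 15))
        Y = rng.standard_normal((50, 4))
        model = fit_grcca(X, Y)
        ry = model.y_structure_["r"]
        assert ry[ry.abs().idxmax()] > 0

    def test_lv_definitions_hold(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 8)))
        Y = pd.DataFrame(rng.standard_normal((30, 3)))
        model = fit_grcca(X, Y, variance_fraction=0.6)
        Xs = (X - X.mean()) / X.std(ddof=1)
        Ys = (Y - Y.mean()) / Y.std(ddof=1)
        np.testing.assert_allclose(Xs.to_numpy() @ model.x_weights_, model.x_scores_, atol=1e-10)
        np.testing.assert_allclose(Ys.to_numpy() @ model.y_weights_, model.y_scores_, atol=1e-10)

    def test_rank_deficient_y_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 2))
        Y = np.column_stack([Y, Y[:, 0] + Y[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            fit_grcca(X, Y)


class TestPermutation:
    def test_minimum_p_with_1000_perms(self, rng):
        """A signal exceeding every null gives p = 1/1001 -> 0.001 at 3 dp."""
        z = rng.standard_normal(60)
        X = np.column_stack([z, rng.standard_normal((60, 4))])
        Y = np.column_stack([z + 0.01 * rng.standard_normal(60)])
        model = fit_grcca(X, Y, variance_fraction=1.0)
        res = model.permutation_test(n_perm=1000, seed=0)
        assert res.p == pytest.approx(1 / 1001)
        assert round(res.p, 3) == 0.001

    def test_observed_below_all_nulls_gives_one(self, rng):
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 2))
        model = fit_grcca(X, Y)
        model.latent_correlation_ = -1.0  # forcibly below any null statistic
        res = model.permutation_test(n_perm=99, seed=1)
        assert res.p == 1.0

    def test_permutation_reproducible(self, rng):
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 2))
        model = fit_grcca(X, Y)
        a = model.permutation_test(n_perm=50, seed=5)
        b = model.permutation_test(n_perm=50, seed=5)
        np.testing.assert_array_equal(a.null, b.null)


class TestOptimizeVarianceFraction:
    def test_single_grid_point(self, rng):
        X = rng.standard_normal((30, 8))
        Y = rng.standard_normal((30, 2))
        model, table = optimize_variance_fraction(X, Y, grid=[0.5], n_perm=19, seed=0)
        assert model.chosen_f_ == 0.5 and len(table) == 1

    def test_chosen_f_minimizes_p(self, rng):
        z = rng.standard_normal(50)
        X = np.column_stack([z[:, None] + 0.3 * rng.standard_normal((50, 2)),
                             rng.standard_normal((50, 8))])
        Y = z[:, None] + 0.2 * rng.standard_normal((50, 1))
        model, table = optimize_variance_fraction(X, Y, grid=[0.2, 0.6, 1.0], n_perm=99, seed=2)
        assert model.perm_p_ == table["perm_p"].min()

    def test_tie_break_prefers_larger_correlation(self):
        # both f values hit the p floor; the one with larger observed r wins
        rng = np.random.default_rng(0)
        z = rng.standard_normal(80)
        X = np.column_stack([z + 0.05 * rng.standard_normal(80) for _ in range(4)])
        Y = z[:, None]
        model, table = optimize_variance_fraction(X, Y, grid=[0.5, 1.0], n_perm=49, seed=3)
        floor = table["perm_p"].min()
        tied = table[table["perm_p"] == floor]
        if len(tied) > 1:
            assert model.latent_correlation_ == pytest.approx(tied["latent_correlation"].max())


class TestBootstrap:
    def test_planted_covariate_strong_z(self, rng):
        z = rng.standard_normal(80)
        X = np.column_stack([z[:, None] + 0.3 * rng.standard_normal((80, 3)),
                             rng.standard_normal((80, 5))])
        Y = np.column_stack([z + 0.2 * rng.standard_normal(80), rng.standard_normal(80)])
        model = fit_grcca(X, Y, variance_fraction=1.0)
        zx, zy = model.bootstrap_z(X, Y, n_boot=100, seed=0)
        assert abs(zy.iloc[0]) >= 2

    def test_deterministic_weight_capped(self, rng):
        """q = 1 after Y standardization: w_y is constant, sd = 0, Z capped."""
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 1))
        model = fit_grcca(X, Y)
        _, zy = model.bootstrap_z(X, Y, n_boot=50, seed=0)
        assert model.z_y_capped_.iloc[0]
        assert abs(zy.iloc[0]) == pytest.approx(1e6)

    def test_bootstrap_reproducible(self, rng):
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 3))
        m1 = fit_grcca(X, Y)
        m2 = fit_grcca(X, Y)
        zx1, _ = m1.bootstrap_z(X, Y, n_boot=30, seed=9)
        zx2, _ = m2.bootstrap_z(X, Y, n_boot=30, seed=9)
        pd.testing.assert_series_equal(zx1, zx2)


class TestStructureCorrelations:
    def test_proportional_feature_r_one(self, rng):
        lv = rng.standard_normal(25)
        M = np.column_stack([2.0 * lv, rng.standard_normal(25)])
        out = structure_correlations(M, lv)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_feature_r_zero(self, rng):
        lv = rng.standard_normal(30)
        x = rng.standard_normal(30)
        x = x - x.mean() - ((x - x.mean()) @ (lv - lv.mean())) / ((lv - lv.mean()) @ (lv - lv.mean())) * (lv - lv.mean())
        out = structure_correlations(x[:, None], lv)
        assert abs(out["r"].iloc[0]) < 1e-10

    def test_matches_loop_oracle(self, rng):
        from scipy import stats

        M = rng.standard_normal((30, 5))
        lv = rng.standard_normal(30)
        out = structure_correlations(M, lv)
        for j in range(5):
            r, p = stats.pearsonr(M[:, j], lv)
            assert out["r"].iloc[j] == pytest.approx(r, abs=1e-12)
            assert out["p"].iloc[j] == pytest.approx(p, rel=1e-8)


class TestSignificantFeatures:
    def make_model(self, r, fdr, z):
        model = GRCCA()
        names = [f"g{i}" for i in range(len(r))]
        model.x_structure_ = pd.DataFrame({"r": r, "p": fdr, "fdr": fdr}, index=names)
        model.z_x_ = pd.Series(z, index=names)
        return model

    def test_boundary_inclusion_rules(self):
        """|Z| = 2 exactly is included; FDR = 0.05 exactly is excluded."""
        model = self.make_model(r=[0.5, 0.4, 0.3], fdr=[0.01, 0.05, 0.01], z=[2.0, 5.0, 1.99])
        out = significant_features(model)
        assert list(out.index) == ["g0"]

    def test_sorted_by_abs_structure_correlation(self):
        model = self.make_model(r=[0.2, -0.9, 0.5], fdr=[0.001] * 3, z=[3, -4, 5])
        out = significant_features(model)
        assert list(out.index) == ["g1", "g2", "g0"]

    def test_requires_bootstrap_first(self, rng):
        model = fit_grcca(rng.standard_normal((20, 4)), rng.standard_normal((20, 2)))
        with pytest.raises(ValueError, match="bootstrap"):
            significant_features(model)
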