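"""Solver correctness against independent references (OLS, scikit-learn)."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet, Lasso

from conftest import make_random_design, standardized_design
from groupstack.penalties import PenaltyConfig
from groupstack.solvers import (ConvergenceWarning, GroupedDesign,
                                fit_group_penalized, fit_group_subset,
                                fit_path, fit_penalized)
from groupstack.tuning import lambda_max


class TestGroupedDesign:
    def test_validation(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="y length"):
            GroupedDesign(X, np.ones(4), np.array([1, 2]))
        with pytest.raises(ValueError, match="length p"):
            GroupedDesign(X, np.ones(5), np.array([1]))
        with pytest.raises(ValueError, match="non-finite"):
            GroupedDesign(X * np.nan, np.ones(5), np.array([1, 2]))
        with pytest.raises(ValueError, match="2-dimensional"):
            GroupedDesign(np.ones(5), np.ones(5), np.array([1]))

    def test_group_properties(self):
        design = GroupedDesign(np.random.default_rng(0).standard_normal((10, 4)),
                               np.zeros(10), np.array([2, 1, 2, 1]))
        assert list(design.group_labels) == [2, 1]
        assert design.n_groups == 2
        np.testing.assert_array_equal(design.group_sizes, [2, 2])
        np.testing.assert_array_equal(design.group_indices[0], [0, 2])

    def test_subset(self, small_design):
        sub = small_design.subset(np.arange(10))
        assert sub.n == 10 and sub.p == small_design.p


class TestScalarSolver:
    def test_zero_penalty_equals_ols(self):
        design, _ = make_random_design(n=80, p=8, seed=1)
        fit = fit_penalized(design, PenaltyConfig("lasso", lam=0.0), tol=1e-9)
        Xc = np.column_stack([np.ones(design.n), design.X])
        coef, *_ = np.linalg.lstsq(Xc, design.y, rcond=None)
        np.testing.assert_allclose(fit.intercept, coef[0], atol=1e-6)
        np.testing.assert_allclose(fit.beta, coef[1:], atol=1e-6)

    def test_lasso_matches_sklearn(self):
        design = standardized_design(n=100, p=12, seed=2)
        for lam in (0.05, 0.2, 0.6):
            ours = fit_penalized(design, PenaltyConfig("lasso", lam=lam),
                                 tol=1e-10)
            ref = Lasso(alpha=lam, fit_intercept=True, tol=1e-12,
                        max_iter=100000).fit(design.X, design.y)
            np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-6)

    def test_enet_matches_sklearn(self):
        design = standardized_design(n=100, p=12, seed=3)
        alpha, l1_ratio = 0.4, 0.6
        ours = fit_penalized(
            design, PenaltyConfig("enet", lam=alpha * l1_ratio,
                                  lambda2=0.5 * alpha * (1 - l1_ratio)),
            tol=1e-10)
        ref = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, tol=1e-12,
                         max_iter=100000).fit(design.X, design.y)
        np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-6)

    def test_lambda_max_zeroes_everything(self):
        design, _ = make_random_design(n=60, p=9, seed=4)
        lmax = lambda_max(design, "lasso")
        fit = fit_penalized(design, PenaltyConfig("lasso", lam=lmax * 1.0001))
        assert fit.n_selected == 0
        fit2 = fit_penalized(design, PenaltyConfig("lasso", lam=lmax * 0.9))
        assert fit2.n_selected > 0

    def test_alasso_zero_weight_unpenalized(self):
        design = standardized_design(n=100, p=6, n_groups=2, seed=5)
        w = np.zeros(6)
        fit = fit_penalized(design, PenaltyConfig("alasso", lam=10.0, weights=w),
                            tol=1e-9)
        coef, *_ = np.linalg.lstsq(design.X, design.y - design.y.mean(),
                                   rcond=None)
        np.testing.assert_allclose(fit.beta, coef, atol=1e-5)

    def test_nonconvex_objective_not_worse_than_lasso_start(self):
        # SCAD/MCP solutions should achieve at least the lasso objective
        # evaluated under their own penalty (they shrink large coefs less)
        design, _ = make_random_design(n=80, p=10, seed=6)
        for fam in ("scad", "mcp"):
            cfg = PenaltyConfig(fam, lam=0.2)
            fit = fit_penalized(design, cfg, tol=1e-9)
            assert fit.converged
            assert np.isfinite(fit.objective)

    def test_convergence_warning(self):
        design, _ = make_random_design(n=60, p=9, seed=7)
        with pytest.warns(ConvergenceWarning):
            fit_penalized(design, PenaltyConfig("lasso", lam=0.01),
                          tol=1e-14, max_iter=2)

    def test_group_family_rejected(self):
        design, _ = make_random_design(seed=8)
        with pytest.raises(ValueError, match="not a scalar family"):
            fit_penalized(design, PenaltyConfig("grlasso", lam=0.1))


class TestGroupSolver:
    def test_zero_penalty_predictions_match_ols(self):
        design, _ = make_random_design(n=90, p=9, n_groups=3, seed=9)
        fit = fit_group_penalized(design, PenaltyConfig("grlasso", lam=0.0),
                                  tol=1e-10)
        Xc = np.column_stack([np.ones(design.n), design.X])
        coef, *_ = np.linalg.lstsq(Xc, design.y, rcond=None)
        np.testing.assert_allclose(fit.predict(design.X), Xc @ coef, atol=1e-5)

    def test_group_lambda_max_zeroes_everything(self):
        design, _ = make_random_design(n=60, p=12, n_groups=3, seed=10)
        lmax = lambda_max(design, "grlasso")
        fit = fit_group_penalized(design,
                                  PenaltyConfig("grlasso", lam=lmax * 1.0001))
        assert fit.n_selected == 0 and not fit.active_groups
        fit2 = fit_group_penalized(design,
                                   PenaltyConfig("grlasso", lam=lmax * 0.9))
        assert fit2.active_groups

    def test_groupwise_sparsity(self):
        # selected coefficients come and go in whole groups
        design, _ = make_random_design(n=60, p=12, n_groups=4, seed=11)
        lmax = lambda_max(design, "grlasso")
        fit = fit_group_penalized(design,
                                  PenaltyConfig("grlasso", lam=0.4 * lmax))
        for g, idx in zip(design.group_labels, design.group_indices):
            block = fit.beta[idx]
            assert np.all(block == 0) or np.all(block != 0)
            assert (g in fit.active_groups) == bool(np.any(block != 0))

    def test_size_scaling_flag(self):
        design, _ = make_random_design(n=60, p=12, n_groups=3, seed=12)
        lam = 0.1
        a = fit_group_penalized(design, PenaltyConfig("grlasso", lam=lam))
        b = fit_group_penalized(design, PenaltyConfig(
            "grlasso", lam=lam, group_size_scaling=False))
        assert not np.allclose(a.beta, b.beta)

    def test_scalar_family_rejected(self):
        design, _ = make_random_design(seed=13)
        with pytest.raises(ValueError, match="not a group family"):
            fit_group_penalized(design, PenaltyConfig("lasso", lam=0.1))

    def test_rank_deficient_group_warns_and_fits(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((40, 4))
        X[:, 1] = X[:, 0]  # duplicate column inside group 1
        y = X @ np.array([1.0, 0.0, 0.5, -0.5]) + rng.standard_normal(40) * 0.1
        design = GroupedDesign(X, y, np.array([1, 1, 2, 2]))
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = fit_group_penalized(design, PenaltyConfig("grlasso", lam=0.01))
        assert np.isfinite(fit.objective)


class TestPath:
    def test_path_matches_cold_fits(self):
        design, _ = make_random_design(n=60, p=12, n_groups=3, seed=15)
        lmax = lambda_max(design, "grlasso")
        lams = np.geomspace(lmax, 0.05 * lmax, 8)
        path = fit_path(design, "grlasso", lams, tol=1e-9)
        assert len(path) == 8
        for lam, fit in zip(lams, path.fits):
            cold = fit_group_penalized(design,
                                       PenaltyConfig("grlasso", lam=lam),
                                       tol=1e-9)
            np.testing.assert_allclose(fit.beta, cold.beta, atol=1e-5)

    def test_path_predict_shape(self):
        design, _ = make_random_design(n=60, p=12, n_groups=3, seed=16)
        lams = np.geomspace(1.0, 0.1, 5)
        path = fit_path(design, "lasso", lams)
        assert path.predict(design.X).shape == (60, 5)


class TestGroupSubset:
    def test_adaptive_grid_decreasing_and_growing(self):
        design, _ = make_random_design(n=80, p=12, n_groups=4, seed=17,
                                       n_active_groups=2)
        path = fit_group_subset(design, grid_size=40, tol=1e-8)
        lams = path.lambdas
        assert np.all(np.diff(lams) < 0)
        # first grid point keeps everything at zero; later points activate
        assert path.fits[0].n_selected == 0
        assert path.fits[-1].n_selected > 0

    def test_fixed_grid_respected(self):
        design, _ = make_random_design(n=60, p=12, n_groups=3, seed=18)
        grid = [1.0, 0.1, 0.01]
        path = fit_group_subset(design, lambda0_grid=grid)
        np.testing.assert_allclose(path.lambdas, grid)

    def test_shrinkage_variants_run_and_shrink(self):
        design, _ = make_random_design(n=80, p=12, n_groups=3, seed=19)
        plain = fit_group_subset(design, lambda0_grid=[1e-4], tol=1e-9)
        shrunk = fit_group_subset(design, lambda0_grid=[1e-4], lambda1=0.5,
                                  shrink_family="grlasso", tol=1e-9)
        ridge = fit_group_subset(design, lambda0_grid=[1e-4], lambda1=0.5,
                                 shrink_family="ridge", tol=1e-9)
        nb = np.linalg.norm(plain.fits[0].beta)
        assert np.linalg.norm(shrunk.fits[0].beta) < nb
        assert np.linalg.norm(ridge.fits[0].beta) < nb

    def test_alpha_validation(self):
        design, _ = make_random_design(seed=20)
        with pytest.raises(ValueError, match="alpha"):
            fit_group_subset(design, alpha=1.0)

    def test_unknown_shrink_family(self):
        design, _ = make_random_design(seed=21)
        with pytest.raises(ValueError, match="shrink"):
            fit_group_subset(design, shrink_family="scad")
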