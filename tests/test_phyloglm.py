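"""Phylogenetic logistic regression: correlation structure, estimation,
independence-limit equivalence, Wald inference, batched fitting."""

import numpy as np
import pytest
from scipy.special import expit
from sklearn.base import clone

from phylosyndrome.phylo import patristic_matrix
from phylosyndrome.phyloglm import (
    PhyloLogisticRegression,
    _chol_with_jitter,
    _firth_irls,
    alpha_grid,
    batch_fit_bivariate,
    fit_phyloglm,
    grid_cholesky,
    tip_correlation,
    wald_p,
)
from phylosyndrome.simulate import SimConfig, simulate_response, simulate_tree

from .oracles import firth_logistic_oracle


class TestTipCorrelation:
    def test_alpha_zero_gives_all_ones(self, star_distances):
        assert np.allclose(tip_correlation(star_distances(5), 0.0), 1.0)

    def test_large_alpha_approaches_identity(self, star_distances):
        R = tip_correlation(star_distances(5), 1e4)
        assert np.allclose(R, np.eye(5), atol=1e-12)

    def test_three_taxon_hand_values(self, three_taxon_tree):
        d = patristic_matrix(three_taxon_tree, normalize=True)
        R = tip_correlation(d, 1.0)
        df_idx = {lb: i for i, lb in enumerate(d.labels)}
        assert R[df_idx["A"], df_idx["B"]] == pytest.approx(np.exp(-1.0))
        assert R[df_idx["A"], df_idx["C"]] == pytest.approx(np.exp(-2.0))

    def test_negative_alpha_rejected(self, star_distances):
        with pytest.raises(ValueError, match="alpha"):
            tip_correlation(star_distances(4), -0.1)

    @pytest.mark.parametrize("alpha", [1e-3, 0.5, 5.0, 1e3])
    def test_valid_correlation_matrix_on_random_trees(self, alpha):
        tree = simulate_tree(SimConfig(n_tips=40, seed=11))
        d = patristic_matrix(tree)
        R = tip_correlation(d, alpha)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        # PSD after the jitter rule used by the solver
        L, _ = _chol_with_jitter(R)
        assert np.all(np.isfinite(L))


def _iid_logistic(n, beta, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (rng.uniform(size=n) < expit(beta[0] + beta[1] * x)).astype(float)
    return y, x


class TestIndependenceLimit:
    @pytest.mark.parametrize("n", [100, 300])
    def test_matches_ordinary_firth_logistic(self, star_distances, n):
        # on a star tree with i.i.d. data the fit must reduce to ordinary
        # Firth-penalized logistic regression
        y, x = _iid_logistic(n, (-0.5, 1.0), seed=n)
        fit = fit_phyloglm(y, x, star_distances(n))
        oracle = firth_logistic_oracle(y, np.column_stack([np.ones(n), x]))
        assert np.abs(fit.beta - oracle).max() < 1e-4

    def test_separation_stays_finite(self, star_distances):
        n = 40
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()  # perfect separation
        fit = fit_phyloglm(y, x, star_distances(n))
        assert np.all(np.isfinite(fit.beta))
        assert np.all(np.isfinite(fit.se))


class TestFitValidation:
    def test_constant_response_rejected(self, star_distances):
        with pytest.raises(ValueError, match="degenerate response"):
            fit_phyloglm(np.ones(10), np.arange(10.0), star_distances(10))

    def test_non_binary_rejected(self, star_distances):
        with pytest.raises(ValueError, match="binary"):
            fit_phyloglm(np.arange(10.0), np.arange(10.0), star_distances(10))

    def test_singular_design_rejected(self, star_distances):
        y = np.r_[np.zeros(5), np.ones(5)]
        X = np.ones((10, 2))  # duplicates the intercept twice over
        with pytest.raises(np.linalg.LinAlgError):
            fit_phyloglm(y, X, star_distances(10))

    def test_shape_mismatch_rejected(self, star_distances):
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(ValueError, match="shape"):
            fit_phyloglm(y, np.arange(10.0), star_distances(11))


class TestPermutationInvariance:
    def test_estimates_unchanged_by_tip_reordering(self):
        tree = simulate_tree(SimConfig(n_tips=60, seed=3))
        d = patristic_matrix(tree)
        rng = np.random.default_rng(3)
        cfg = SimConfig(n_tips=60, beta_true=(-0.5, 1.0), seed=3)
        x = rng.integers(0, 2, size=60).astype(float)
        y = simulate_response(d, x, cfg, rng=rng).astype(float)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        fit = fit_phyloglm(y, x, d)
        perm = rng.permutation(60)
        fit_p = fit_phyloglm(y[perm], x[perm], d.matrix[np.ix_(perm, perm)])
        assert np.allclose(fit.beta, fit_p.beta, atol=1e-4)
        assert fit.alpha == pytest.approx(fit_p.alpha, rel=1e-2)


class TestWaldP:
    def _fit(self, beta, se):
        from phylosyndrome.phyloglm import PhyloGLMFit

        return PhyloGLMFit(
            beta=np.array(beta),
            se=np.array(se),
            alpha=1.0,
            p_values=np.ones(len(beta)),
            converged=True,
            alpha_at_bound=False,
            n_tips=10,
        )

    def test_zero_coefficient(self):
        p, sign = wald_p(self._fit([0.0, 0.0], [1.0, 1.0]), 1)
        assert p == 1.0 and sign == 0

    def test_z_of_1_96(self):
        p, sign = wald_p(self._fit([0.0, 1.96], [1.0, 1.0]), 1)
        assert p == pytest.approx(0.05, abs=1e-3)
        assert sign == 1

    def test_z_of_minus_3(self):
        p, sign = wald_p(self._fit([0.0, -3.0], [1.0, 1.0]), 1)
        assert p == pytest.approx(0.0027, abs=1e-4)
        assert sign == -1

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            wald_p(self._fit([0.0], [1.0]), 3)


class TestSklearnSurface:
    def test_get_set_params_and_clone(self):
        est = PhyloLogisticRegression(alpha_bounds=(1e-2, 10.0), firth=False)
        est2 = clone(est)
        assert est2.get_params()["alpha_bounds"] == (1e-2, 10.0)
        est2.set_params(firth=True)
        assert est2.firth is True

    def test_fitted_attributes_and_predict(self, star_distances):
        n = 80
        y, x = _iid_logistic(n, (0.0, 1.5), seed=1)
        est = PhyloLogisticRegression().fit(x, y, D=star_distances(n))
        for attr in ("coef_", "intercept_", "se_", "alpha_", "p_values_", "converged_", "n_tips_"):
            assert hasattr(est, attr)
        proba = est.predict_proba(x)
        assert proba.shape == (n, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(est.predict(x))) <= {0, 1}


class TestBatchFitter:
    def test_matches_per_model_solver_at_fixed_alpha(self):
        tree = simulate_tree(SimConfig(n_tips=80, seed=21))
        d = patristic_matrix(tree)
        rng = np.random.default_rng(21)
        J = 4
        Xp = rng.integers(0, 2, size=(80, J)).astype(float)
        Y = (rng.uniform(size=(80, J)) < 0.4).astype(float)
        chols = grid_cholesky(d, np.array([5.0]))  # single grid point
        res = batch_fit_bivariate(Y, Xp, chols)
        for j in range(J):
            X = np.column_stack([np.ones(80), Xp[:, j]])
            beta, F, _ = _firth_irls(Y[:, j], X, chols[0].L, np.zeros(2))
            assert res.beta1[j] == pytest.approx(beta[1], abs=1e-5)
            Finv = np.linalg.inv(F)
            assert res.se1[j] == pytest.approx(np.sqrt(Finv[1, 1]), rel=1e-4)

    def test_degenerate_columns_masked(self, star_distances):
        n = 30
        Y = np.column_stack([np.r_[np.zeros(15), np.ones(15)], np.zeros(n)])
        Xp = np.column_stack([np.r_[np.zeros(10), np.ones(20)], np.r_[np.zeros(10), np.ones(20)]])
        chols = grid_cholesky(star_distances(n), alpha_grid(size=3))
        res = batch_fit_bivariate(Y, Xp, chols)
        assert res.valid[0] and not res.valid[1]
        assert np.isnan(res.p1[1])


class TestSignalRecovery:
    def test_switching_trait_alpha_recovered(self):
        # the exact two-state switching generator has binary correlation
        # exp(-rate d), precisely the working form: the moment estimator
        # should land near the true rate on average
        from phylosyndrome.simulate import simulate_switching_trait

        rate = 3.0
        alphas = []
        for s in range(15):
            tree = simulate_tree(SimConfig(n_tips=200, seed=100 + s))
            d = patristic_matrix(tree)
            rng = np.random.default_rng(200 + s)
            y = simulate_switching_trait(tree, rate=rate, stationary_p=0.4, rng=rng).astype(float)
            if y.min() == y.max():
                continue
            x = rng.integers(0, 2, 200).astype(float)  # irrelevant covariate
            fit = fit_phyloglm(y, x, d)
            alphas.append(fit.alpha)
        med = float(np.median(alphas))
        assert rate / 2.5 < med < rate * 2.5
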