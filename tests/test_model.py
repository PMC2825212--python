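"""Brownian-motion likelihood, scaling transforms, ML fit, PGLS, LR test."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2, multivariate_normal

from paleobrain import read_newick
from paleobrain.model import (BrownianMotion, EvoModelParams, PGLS, bm_loglik,
                              fit_ml, lr_test, pgls, transform_covariance)
from paleobrain.simulate import SimConfig, simulate_dataset

from conftest import random_tree


class TestTransform:
    @pytest.mark.parametrize("seed", range(50))
    def test_identity_at_ones(self, seed):
        t = random_tree(seed, n_extant=6, n_fossils=1)
        base = t.vcv().matrix
        T = transform_covariance(t, 1.0, 1.0, 1.0).matrix
        assert np.allclose(T, base)

    def test_lambda_zero_star_structure(self):
        t = random_tree(0, n_extant=6)
        T = transform_covariance(t, lambda_=0.0).matrix
        assert np.allclose(T - np.diag(np.diag(T)), 0.0)
        assert np.allclose(np.diag(T), np.diag(t.vcv().matrix))

    def test_kappa_on_single_branch(self):
        t = read_newick("(A:4);")
        T = transform_covariance(t, kappa=0.5).matrix
        assert T[0, 0] == pytest.approx(2.0)  # 4**0.5

    def test_delta_powers_entries(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        T = transform_covariance(t, delta=2.0).matrix
        assert np.allclose(T, t.vcv().matrix ** 2)

    def test_domain_validation(self):
        t = random_tree(0, n_extant=4)
        with pytest.raises(ValueError):
            transform_covariance(t, lambda_=1.5)
        with pytest.raises(ValueError):
            transform_covariance(t, kappa=-1.0)


class TestLoglik:
    def test_single_tip_closed_form(self):
        t = read_newick("(A:3);")
        C = t.vcv().matrix
        p = EvoModelParams(alpha=0.7, root_state=1.5)
        ll = bm_loglik([1.5], C, p)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 0.7 * 3.0))

    def test_independent_tips_sum_of_univariates(self):
        t = read_newick("(A:2,B:5);")
        C = t.vcv().matrix
        p = EvoModelParams(alpha=0.3, root_state=0.2)
        ll = bm_loglik([0.5, -0.1], C, p)
        from scipy.stats import norm
        expect = (norm.logpdf(0.5, 0.2, np.sqrt(0.3 * 2))
                  + norm.logpdf(-0.1, 0.2, np.sqrt(0.3 * 5)))
        assert ll == pytest.approx(expect)

    def test_matches_dense_mvn_oracle(self):
        t = random_tree(7, n_extant=5, n_fossils=1)
        taxa = t.tip_labels
        C = t.vcv(taxa).matrix
        rng = np.random.default_rng(1)
        x = rng.normal(size=len(taxa))
        p = EvoModelParams(alpha=0.4, root_state=0.1, beta=0.05)
        paths = t.path_lengths(taxa)
        expect = multivariate_normal.logpdf(x, 0.1 + 0.05 * paths, 0.4 * C)
        assert bm_loglik(x, C, p, paths=paths) == pytest.approx(expect,
                                                                abs=1e-8)

    def test_invariant_to_taxon_ordering(self):
        t = random_tree(2, n_extant=8, n_fossils=2)
        vals = {l: v for l, v in zip(
            t.tip_labels, np.random.default_rng(0).normal(size=10))}
        p = EvoModelParams(alpha=0.5, root_state=0.0, beta=0.02)
        lls = []
        for order in (sorted(vals), sorted(vals, reverse=True)):
            C = t.vcv(order).matrix
            lls.append(bm_loglik([vals[l] for l in order], C, p,
                                 paths=t.path_lengths(order)))
        assert lls[0] == pytest.approx(lls[1], abs=1e-9)

    def test_singular_covariance_error(self):
        C = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            bm_loglik([0.0, 1.0], C, EvoModelParams())


class TestFitML:
    def test_star_tree_root_is_mean(self, star_tree):
        x = np.arange(12, dtype=float)
        est = BrownianMotion(tree=star_tree).fit(x)
        assert est.root_state_ == pytest.approx(x.mean())

    def test_alpha_recovery(self):
        # ML rate on whitened BM data: n*alpha_hat/alpha ~ chi2(n-1), so
        # each estimate is checked against the exact 99.95% sampling band
        # and the 20-seed mean against a tight interval around 1
        n = 100
        lo, hi = chi2.ppf([2.5e-4, 1 - 2.5e-4], n - 1) / n
        alphas = []
        for seed in range(20):
            tree, traits, truth = simulate_dataset(SimConfig(
                n_extant=n, n_fossils=0, alpha_body=1.0, seed=500 + seed,
                height=1.0))
            est = BrownianMotion(tree=tree).fit(
                traits.data.loc[tree.tip_labels, "log10_body"].to_numpy())
            alphas.append(est.alpha_)
        assert all(lo <= a <= hi for a in alphas)
        assert 0.9 <= np.mean(alphas) <= 1.1

    def test_optimum_beats_random_draws(self):
        tree, traits, _ = simulate_dataset(SimConfig(
            n_extant=15, n_fossils=4, seed=9))
        taxa = tree.tip_labels
        x = traits.data.loc[taxa, "log10_brain"].to_numpy()
        params, ll = fit_ml(x, tree, directional=True)
        C = tree.vcv(taxa).matrix
        paths = tree.path_lengths(taxa)
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = EvoModelParams(alpha=rng.uniform(0.001, 2),
                               root_state=rng.uniform(-3, 3),
                               beta=rng.uniform(-0.1, 0.1))
            assert bm_loglik(x, C, p, paths=paths) <= ll + 1e-9

    def test_directional_needs_path_variation(self, star_tree):
        with pytest.raises(ValueError, match="path-length"):
            BrownianMotion(tree=star_tree, directional=True).fit(
                np.arange(12, dtype=float))

    def test_beta_sign_recovery(self):
        hits = 0
        for seed in range(20):
            tree, traits, truth = simulate_dataset(SimConfig(
                n_extant=30, n_fossils=8, beta_brain=0.2, alpha_resid=0.01,
                seed=700 + seed))
            resid = truth.residual[tree.tips]
            est = BrownianMotion(tree=tree, directional=True).fit(
                resid, taxa=[tree.labels[i] for i in tree.tips])
            hits += est.beta_ > 0
        assert hits >= 18

    def test_scaling_estimation_recovers_unit_kappa_region(self):
        tree, traits, _ = simulate_dataset(SimConfig(
            n_extant=60, n_fossils=0, seed=12))
        x = traits.data.loc[tree.tip_labels, "log10_body"].to_numpy()
        est = BrownianMotion(tree=tree, estimate_kappa=True).fit(x)
        assert 0.2 <= est.params_.kappa <= 2.5
        assert est.log_likelihood_ >= BrownianMotion(
            tree=tree).fit(x).log_likelihood_ - 1e-9


class TestPGLS:
    def test_exact_line(self):
        tree = random_tree(5, n_extant=15)
        x = np.linspace(0, 3, 15)
        fit = pgls(1.0 + 2.0 * x, x, tree, taxa=tree.tip_labels)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert max(abs(v) for v in fit.residuals.values()) < 1e-10

    def test_identity_covariance_equals_ols(self, star_tree):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = 0.4 + 0.9 * x + rng.normal(size=12) * 0.3
        fit = pgls(y, x, star_tree, taxa=star_tree.tip_labels)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.t_statistic == pytest.approx(ols.tvalues[1], abs=1e-8)
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)

    def test_slope_recovery(self):
        slopes = []
        for seed in range(20):
            tree, traits, _ = simulate_dataset(SimConfig(
                n_extant=200, n_fossils=0, seed=300 + seed))
            d = traits.data.loc[tree.tip_labels]
            fit = pgls(d["log10_brain"].to_numpy(),
                       d["log10_body"].to_numpy(), tree)
            slopes.append(fit.slope)
        assert all(abs(s - 0.684) <= 0.05 for s in slopes)

    def test_constant_predictor_raises(self):
        tree = random_tree(1, n_extant=6)
        with pytest.raises(ValueError, match="constant"):
            pgls(np.arange(6.0), np.ones(6), tree)

    def test_estimator_api(self):
        tree = random_tree(8, n_extant=10)
        x = np.linspace(-1, 1, 10)
        est = PGLS(tree=tree).fit(x, 0.5 + 0.2 * x)
        assert est.get_params()["estimate_kappa"] is False
        assert np.allclose(est.predict(np.array([0.0, 1.0])), [0.5, 0.7])


class TestLRTest:
    def test_equal_logliks(self):
        r = lr_test(-10.0, -10.0)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_lr_eight(self):
        r = lr_test(-26.0, -30.0)
        assert r.statistic == pytest.approx(8.0)
        assert r.p_value == pytest.approx(chi2.sf(8.0, 1), abs=1e-12)
        assert r.p_value == pytest.approx(0.0047, abs=5e-4)

    def test_published_kappa_shape(self):
        # LR = 8.132 maps to p = 0.004 at df 1
        assert chi2.sf(8.132, 1) == pytest.approx(0.004, abs=5e-4)
        r = lr_test(-20.0, -20.0 - 8.132 / 2)
        assert r.p_value == pytest.approx(0.004, abs=5e-4)

    def test_negative_lr_raises(self):
        with pytest.raises(RuntimeError):
            lr_test(-30.0, -26.0)
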