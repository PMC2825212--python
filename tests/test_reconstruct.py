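"""Ancestral reconstruction: parsimony, ML, MCMC, Bayes factors."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

from paleobrain import (AncestralStates, McmcSettings, asr_mcmc, asr_ml,
                        asr_parsimony, bayes_factor, congruence,
                        log_harmonic_mean, mcmc_fit, read_newick,
                        write_newick)
from paleobrain.simulate import SimConfig, simulate_dataset

from conftest import random_tree

FAST = McmcSettings(iterations=50_000, burn_in=10_000, thin=10, seed=0)


def _settings(seed, iterations=50_000, burn_in=10_000, thin=10):
    return McmcSettings(iterations=iterations, burn_in=burn_in, thin=thin,
                        seed=seed)


class TestParsimony:
    def test_symmetric_two_tips(self):
        t = read_newick("(A:1,B:1);")
        est = asr_parsimony(t, {"A": 0.0, "B": 2.0})
        assert est["estimate"].iloc[0] == pytest.approx(1.0)

    def test_unequal_branches(self):
        # minimize r^2/1 + (r-2)^2/3  ->  r = 0.5
        t = read_newick("(A:1,B:3);")
        est = asr_parsimony(t, {"A": 0.0, "B": 2.0})
        assert est["estimate"].iloc[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_numerical_minimizer(self, seed):
        t = random_tree(seed, n_extant=10)
        rng = np.random.default_rng(seed)
        vals = dict(zip(t.tip_labels, rng.normal(size=10)))
        est = asr_parsimony(t, vals)
        internal = list(est.index)

        def cost(s):
            states = dict(zip(internal, s))
            states.update({t.tip(l): v for l, v in vals.items()})
            return sum((states[c] - states[int(t.parent[c])]) ** 2
                       / t.lengths[c] for c in range(t.n_nodes - 1))

        res = minimize(cost, np.zeros(len(internal)), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.allclose(est["estimate"].to_numpy(), res.x, atol=1e-4)
        assert cost(est["estimate"].to_numpy()) <= res.fun + 1e-10

    def test_zero_length_branches_merge_states(self):
        t = read_newick("(A:1,B:1,C:1);").resolve_polytomies(seed=0)
        base = read_newick("(A:1,B:1,C:1);")
        vals = {"A": 0.0, "B": 1.0, "C": 2.0}
        est = asr_parsimony(t, vals)
        est0 = asr_parsimony(base, vals)
        # the two internal nodes (joined by the zero branch) share the state
        assert np.allclose(est["estimate"].to_numpy(),
                           est0["estimate"].iloc[0])


class TestML:
    def test_symmetric_two_tips(self):
        t = read_newick("(A:1,B:1);")
        est = asr_ml(t, {"A": 0.0, "B": 2.0})
        assert est["estimate"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_parsimony(self, seed):
        tree, traits, _ = simulate_dataset(SimConfig(
            n_extant=12, n_fossils=3, seed=seed))
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        p = asr_parsimony(tree, vals)["estimate"]
        m = asr_ml(tree, vals)["estimate"]
        assert np.abs(p - m).max() < 1e-8

    def test_se_grows_with_depth(self):
        tree, traits, _ = simulate_dataset(SimConfig(
            n_extant=20, n_fossils=0, seed=6))
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        est = asr_ml(tree, vals)
        ages = tree.node_ages
        root_se = est.loc[tree.root, "se"]
        shallowest = min(est.index, key=lambda i: ages[i])
        assert root_se > est.loc[shallowest, "se"]

    def test_matches_independent_r_oracle(self, tmp_path):
        tree, traits, _ = simulate_dataset(SimConfig(
            n_extant=10, n_fossils=0, seed=8))
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        est = asr_ml(tree, vals)
        nwk = tmp_path / "t.nwk"
        write_newick(tree, nwk)
        csv = tmp_path / "v.csv"
        pd.Series(vals).to_csv(csv, header=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(phytools))
            tr <- read.tree("{nwk}")
            v <- read.csv("{csv}", header=FALSE)
            fa <- fastAnc(tr, setNames(v$V2, v$V1))
            for (i in seq_along(fa)) {{
              node <- as.integer(names(fa)[i])
              tips <- paste(sort(extract.clade(tr, node)$tip.label),
                            collapse=";")
              cat(tips, sprintf("%.10f", fa[i]), "\\n")
            }}
        """)
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, check=True).stdout
        oracle = {}
        for line in out.strip().splitlines():
            parts = line.split()
            oracle[parts[0]] = float(parts[1])
        for node in est.index:
            clade = ";".join(sorted(tree.clade_tips(node)))
            assert est.loc[node, "estimate"] == pytest.approx(
                oracle[clade], abs=1e-6)


class TestMcmc:
    def test_determinism(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        s = _settings(7, iterations=5_000, burn_in=1_000)
        r1 = mcmc_fit(tree, vals, settings=s)
        r2 = mcmc_fit(tree, vals, settings=s)
        assert np.array_equal(r1.loglik, r2.loglik)
        assert np.array_equal(r1.node_draws, r2.node_draws)
        assert r1.params.equals(r2.params)

    def test_acceptance_in_target_band(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        run = mcmc_fit(tree, vals, settings=_settings(1))
        assert 0.20 <= run.acceptance_rate <= 0.40

    def test_draw_count_and_prior_bounds(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        s = _settings(2, iterations=10_000, burn_in=2_000, thin=20)
        run = mcmc_fit(tree, vals, settings=s)
        assert len(run.params) == 10_000 // 20
        assert (run.params["root_state"].between(
            s.prior_low, s.prior_high)).all()
        assert (run.params["alpha"] > 0).all()

    def test_posterior_mean_matches_ml(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        run = mcmc_fit(tree, vals, settings=_settings(3))
        summ = asr_mcmc(run)
        ml = asr_ml(tree, vals)
        z = (summ["estimate"] - ml["estimate"]).abs() / summ["mc_se"]
        assert z.max() <= 3.0

    def test_mcmc_ml_congruence_above_099(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        run = mcmc_fit(tree, vals, settings=_settings(4))
        summ = asr_mcmc(run)
        ml = asr_ml(tree, vals)
        c = congruence(summ["estimate"].to_numpy(),
                       ml["estimate"].to_numpy())
        assert c.r_s > 0.99

    def test_symmetric_root_posterior(self):
        t = read_newick("(A:1,B:1);")
        run = mcmc_fit(t, {"A": 0.0, "B": 2.0}, settings=_settings(5))
        summ = asr_mcmc(run)
        root = summ.iloc[0]
        assert abs(root["estimate"] - 1.0) <= 3 * root["mc_se"]

    def test_intervals_widen_with_node_age(self):
        tree, traits, _ = simulate_dataset(SimConfig(
            n_extant=25, n_fossils=0, seed=10))
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        run = mcmc_fit(tree, vals, settings=_settings(6))
        summ = asr_mcmc(run)
        width = summ["ci_high"] - summ["ci_low"]
        ages = tree.node_ages[summ.index.to_numpy()]
        rho = spearmanr(width, ages).statistic
        assert rho > 0

    def test_requesting_tip_node_raises(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        run = mcmc_fit(tree, vals,
                       settings=_settings(8, iterations=2_000, burn_in=500))
        with pytest.raises(ValueError):
            asr_mcmc(run, nodes=[int(tree.tips[0])])

    def test_chain_shorter_than_thin_raises(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        with pytest.raises(ValueError):
            mcmc_fit(tree, vals, settings=McmcSettings(
                iterations=5, burn_in=0, thin=10))


class TestHarmonicMeanAndBF:
    def test_constant_trace(self):
        assert log_harmonic_mean([-3.2] * 10) == pytest.approx(-3.2)

    def test_two_point_trace(self):
        # likelihoods 1 and 0.5 -> HM = 1/mean(1, 2) = 2/3
        assert log_harmonic_mean([np.log(1.0), np.log(0.5)]) == \
            pytest.approx(np.log(2.0 / 3.0))

    def test_duplication_invariance(self):
        ll = np.array([-1.0, -2.0, -5.0])
        assert log_harmonic_mean(np.repeat(ll, 2)) == \
            pytest.approx(log_harmonic_mean(ll))

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            log_harmonic_mean([])

    def test_published_table_arithmetic(self):
        brain = bayes_factor(-27.087, -30.282)
        assert brain.bayes_factor == pytest.approx(6.390, abs=1e-9)
        assert brain.verdict == "strong"
        body = bayes_factor(-45.275, -44.688)
        assert body.bayes_factor == pytest.approx(-1.174, abs=1e-9)
        assert body.verdict == "none"

    def test_equal_inputs(self):
        c = bayes_factor(-5.0, -5.0)
        assert c.bayes_factor == 0.0
        assert c.verdict == "none"

    @pytest.mark.parametrize("bf,verdict", [
        (2.5, "positive"), (6.0, "strong"), (11.0, "very strong"),
        (1.9, "none")])
    def test_verdict_thresholds(self, bf, verdict):
        assert bayes_factor(bf / 2.0, 0.0).verdict == verdict


class TestCongruence:
    def test_identical_vectors(self):
        assert congruence([1, 2, 3], [1, 2, 3]).r_s == pytest.approx(1.0)

    def test_reversed_ranks(self):
        assert congruence([1, 2, 3, 4], [4, 3, 2, 1]).r_s == \
            pytest.approx(-1.0)

    def test_known_rank_formula_value(self):
        c = congruence([1, 2, 3, 4, 5], [1, 3, 2, 4, 5])
        assert c.r_s == pytest.approx(0.9)

    def test_too_few_nodes_raises(self):
        with pytest.raises(ValueError):
            congruence([1, 2], [1, 2])


class TestEstimatorFacade:
    def test_methods_agree(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        est_p = AncestralStates(tree=tree, method="parsimony").fit(vals)
        est_m = AncestralStates(tree=tree, method="ml").fit(vals)
        assert np.allclose(est_p.predict(), est_m.predict(), atol=1e-8)

    def test_predict_subset(self, small_fossil_dataset):
        tree, traits, _ = small_fossil_dataset
        vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
        est = AncestralStates(tree=tree, method="ml").fit(vals)
        out = est.predict([int(tree.root)])
        assert out.shape == (1,)
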