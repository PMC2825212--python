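# paleobrain

Phylogenetic comparative analysis of brain and body mass evolution:
ancestral-state reconstruction, directional-trend testing, and evaluation
of dwarfism scenarios for small-brained lineages.

## Who this is for

Evolutionary biologists asking whether a continuous trait — here log10
brain and body mass on a time-calibrated primate phylogeny, but the
machinery is trait-agnostic — has tended to increase through time, what
its values were at ancestral nodes, on which branches it decreased, and
whether a proposed episode of reduction (the canonical case being a
small-bodied, small-brained island hominin) looks like reductions observed
elsewhere in the clade.

## The models

Tip values **x** follow a constant-variance random walk (Brownian motion)
on the tree: jointly Gaussian with mean equal to the root state *a* and
covariance α**C**, where **C**ᵢⱼ is the shared root-to-MRCA path length
(Myr) between taxa *i* and *j* and α is the evolutionary rate (trait² per
Myr). The *directional* random walk adds a drift β per Myr, so
E[xᵢ] = a + β·pathᵢ; β is identifiable only when root-to-tip path lengths
vary, which fossil tips provide. Branch-length scalings κ (branch lengths
raised to a power), λ (off-diagonal discounting) and δ (entrywise power on
**C**) measure punctuational change, phylogenetic signal and early-vs-late
change; each can be fixed, ML-estimated, or tested against 1 by likelihood
ratio.

Ancestral states come from three routes that can be cross-checked:

* **weighted squared-change parsimony** — minimise Σ (Δ per branch)²/length
  (a sparse linear system; zero-length branches from polytomy resolution
  are contracted);
* **ML / GLS** — each node's conditional expectation given the tips, with
  a standard error that includes root (and drift) uncertainty; identical
  point estimates to parsimony under Brownian motion;
* **Bayesian MCMC** — Metropolis-within-Gibbs over (α, a, β, scalings)
  with uniform priors, proposal widths tuned during burn-in to a 20–40%
  acceptance band, node states drawn from their exact conditional Gaussian
  at every retained iteration.

Trend support is summarised the way the comparative literature does it
with harmonic-mean marginal likelihoods: BF = 2·(log HM_directional −
log HM_constant), read against thresholds 2 (positive), 5 (strong), 10
(very strong). Relative brain size is the residual from a phylogenetic
GLS (PGLS) regression of log brain on log body mass; per-branch change
statistics and a census of decreasing branches feed a scenario calculator
that flags whether a hypothesised ancestor→descendant reduction falls
inside the empirical "decrease envelope".

## Worked example

Everything below is computed from the package's deterministic primate-like
fixture (37 extant + 23 fossil tips on a 77-Myr crown, generated under the
model above with a brain trend of 0.005 /Myr):

```python
from paleobrain import (primate_fixture, pgls, AllometryLine, mcmc_fit,
                        asr_mcmc, trend_test, McmcSettings, tip_residuals,
                        cranial_capacity_from_brain_mass)

tree, traits = primate_fixture()
ext = traits.extant_taxa
etree = tree.drop_tips(traits.fossil_taxa)
d = traits.subset(ext).data
fit = pgls(d["log10_brain"].to_numpy(), d["log10_body"].to_numpy(),
           etree, taxa=ext, estimate_kappa=True)

vals = dict(zip(traits.taxa, traits.data["log10_brain"]))
run = mcmc_fit(tree, vals, directional=True,
               settings=McmcSettings(iterations=50_000, burn_in=10_000,
                                     thin=10, seed=0))
root = asr_mcmc(run).loc[tree.root]

resid = tip_residuals(traits, AllometryLine(fit.intercept, fit.slope))
comp, _, _ = trend_test(tree, dict(resid),
                        settings=McmcSettings(iterations=50_000,
                                              burn_in=10_000, thin=10,
                                              seed=1))
```

printing, in order:

```
PGLS: log10(brain) = -0.371 + 0.638 log10(body)
      t_35 = 14.06, R^2 = 0.850, kappa = 0.999
root log10 brain mass: 0.462 (95% CI -1.032 to 2.052); acceptance 0.29
root brain mass: 2.90 g -> cranial capacity 2.79 cm^3
trend in relative brain size: BF = 8.88 (strong)
```

Reading this: the extant allometry has slope 0.638 (the generator's true
slope is 0.684 and the fit recovers it within sampling error), κ is not
distinguishable from 1 (gradualism), the reconstructed crown-ancestor
brain mass is small with a wide credible interval (deep nodes are weakly
informed — the MCMC acceptance rate sits in the tuned 20–40% band), and
the directional model for relative brain size is strongly preferred
(BF > 5), recovering the positive trend the fixture was generated with.

A command-line interface mirrors the library
(`paleobrain simulate | fit-pgls | asr | trend-test | branch-changes |
scenarios | run-all`); `run-all` writes TSV tables (regression, node
estimates, congruence, trend Bayes factors, branch changes, decrease
census) plus a JSON manifest, byte-identical for identical seeds.

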