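# Methods notes

## Data model and units

Time is in Myr throughout; node ages are Ma before present with extant
tips at age 0. A `Phylogeny` stores parent links, branch lengths and
labels in a stable postorder (root last); node identity is the postorder
index, so any operation that edits the tree (fossil grafting, polytomy
resolution, tip dropping) returns a new tree with fresh indices. When two
trees must be compared node-by-node (e.g. reconstructions with and
without fossils), internal nodes are matched by the MRCA of their shared
extant tip set, which fossil grafting provably preserves.

Masses are log10 grams internally. The allometric line is stored with
explicit unit conventions because its intercept is unit-dependent;
absolute residual values shift by a constant under a unit change (at a
fixed slope) while residual *differences* are unit-invariant, so every
downstream statistic (branch changes, decrease ratios, scenario
statistics) is built from differences only. Cranial capacities are
converted to brain mass with the standard primate relation
log10(cc) = 1.018·log10(m) − 0.025 (Martin 1981) and its exact inverse.

## Likelihood machinery

The constant-variance random walk gives tip data a multivariate normal
density with mean a·**1** (or a + β·path under the directional model) and
covariance α**C**. Likelihoods are evaluated through a Cholesky factor of
**C**; α and the mean coefficients are profiled analytically (GLS), so
numerical optimisation only ever runs over the branch-scaling parameters,
using bounded L-BFGS-B with five seeded restarts and an ftol of 1e-10.
Scaling order: κ is applied to branch lengths before covariance assembly,
λ multiplies off-diagonal covariances, δ raises the assembled entries to
a power — the standard ordering; (1,1,1) is the identity. Powers use the
convention 0^p = 0 so zero-length branches stay zero. Bounds are
κ, δ ∈ (0, 3], λ ∈ [0, 1]. For non-ultrametric (fossil-bearing) trees the
transforms act on the actual branch lengths; no re-ultrametricisation.
Likelihood-ratio tests of a scaling parameter against 1 use the χ²(1)
tail; this is approximate when λ is estimated at its boundary.

The PGLS regression profiles the same scaling parameters by ML and
delegates the fixed-covariance fit to statsmodels GLS (coefficients,
t-statistic, centred R²). Residuals are reported on the original scale,
y − (a + b·x) per taxon.

## Ancestral states

Weighted squared-change parsimony minimises Σ (child − parent)²/length,
solved as the linear system of a weighted graph Laplacian with tips
clamped. Zero-length branches (introduced by polytomy resolution, which
pairs children of a multifurcation under new zero-length nodes chosen by
a seeded generator) are contracted by union-find so both endpoints share
one state: an infinite weight taken to its limit, which leaves the
optimum of the remaining system unchanged. Under Brownian motion these
estimates coincide with the ML/GLS conditional expectations (the joint
Gaussian mode equals the marginal means), which the test suite checks to
1e-8 and against an independent R implementation (phytools `fastAnc`).

The ML route also reports standard errors: for node *a* with tip
covariance vector **c** and design **X** (intercept, optionally path
length), var(â − a) = α[(C_aa − **c**ᵀC⁻¹**c**) +
(**x**_a − **c**ᵀC⁻¹**X**)(**X**ᵀC⁻¹**X**)⁻¹(·)ᵀ], i.e. the conditional
variance plus the propagated uncertainty of the estimated root and drift.
SEs grow toward the root on ultrametric trees.

## MCMC

Parameters (α, root state, β when directional, any scaling parameters
enabled for sampling) are updated one at a time by Gaussian random-walk
Metropolis steps against the *marginal* tip likelihood, with uniform
priors as hard bounds (default ±100 for location parameters; α > 0). The
marginal likelihood for fixed **C** reduces to six precomputed scalar
products, so a proposal costs a handful of scalar operations; sampled
scaling parameters trigger a covariance rebuild only when proposed.

The chain starts at the GLS profile and proposal widths are initialised
at three asymptotic posterior standard deviations, then tuned only during
burn-in (×1.1 / ×0.9 per 1000-iteration window, steering acceptance into
the 20–40% band) and frozen afterwards; a run whose post-burn-in
acceptance leaves [0.05, 0.8] warns. Ancestral states are drawn at every
retained iteration from their exact conditional Gaussian given the
sampled parameters. This is a Rao-Blackwellised joint draw from the same
posterior that an additional tuned Metropolis layer over node states
("data deviation") would target, with none of that layer's tuning error;
it is the package's chosen reading of the two-stage reconstruct-after-fit
scheme. When scaling parameters are sampled, the conditioning matrices
for node draws are built at their posterior means (they vary smoothly and
per-draw rebuilds would dominate run time).

Default chain settings mirror the classical setup (2,000,000 post-burn-in
iterations, thinning 100, burn-in 500,000); the test suite and the
acceptance script use reduced chains (50,000 / 10 / 10,000), which the
acceptance-band, determinism and ML-agreement checks show to be adequate
at the problem sizes used there. Reported MC standard errors use batch
means, which are robust to residual autocorrelation in the thinned chain.

Model comparison uses the harmonic mean of sampled likelihoods, computed
stably in log space (log-sum-exp), with BF = 2·Δlog HM and verdicts at
2/5/10. The harmonic-mean estimator is retained deliberately for fidelity
to the comparative-methods literature this package follows; it is known
to be unstable in general (its variance can be infinite), and the
package's Bayes factors should be read in that tradition rather than as
state-of-the-art marginal likelihoods. Posterior normality per node is
reported via Shapiro–Wilk but never alters estimates.

## Branch changes and scenarios

Differences of log10 values at consecutive nodes give proportional
changes (also reported as 10^Δ − 1); back-transformed differences give
absolute changes; dividing by branch length gives rates, undefined and
flagged on zero-length branches (which are excluded from rate statistics
but counted in the census). Quartile thresholds use linear interpolation
between closest ranks. The decrease census records, for every branch on
which brain mass falls, the ratio of log brain to log body change; the
resulting envelope (ratio range, most extreme brain and relative-mass
decreases) is what a dwarfism scenario is flagged against, using
closed-interval membership. A reference envelope from a published
primate-wide census ships as a documented constant (ratio 0.006–0.825;
the brain and relative minima are not printed in that source and are
carried as the largest published terminal-branch decrease, −0.273, and
the most negative boundary cell, −0.020 with one guard digit so the
boundary cell itself flags as within range); envelopes computed from the
user's own census are preferred and the constant is only a fallback.

Scenario statistics are exact algebra: Δlog brain, Δlog body, their
ratio, and Δrelative = Δlog brain − slope·Δlog body, which satisfies the
per-cell identity Δrel = Δlb − slope·(Δlb/ratio) by construction. Two
known published scenario cells violate that identity in the source tables
and are excluded from verification.

## Synthetic data

The generator is the package's model of the study conditions: a seeded
pure-birth topology rescaled to a 77-Myr crown (the published molecular
age estimate for crown primates), 37 extant + 23 fossil tips by default,
fossils grafted at uniformly chosen interior nodes with last occurrence
uniform on (0, node age) — one code path with real-data grafting. Body
mass evolves by Brownian motion (α_body = 0.02 log10²/Myr from a root of
log10 body = 2.5, spanning a few grams to ~10⁵ g at the tips); the
allometric residual evolves by Brownian motion (α_resid = 0.0015,
calibrated so the extant brain~body R² is near 0.86) with an optional
drift in the residual only — brain trends, body does not; log brain is
intercept + slope·body + residual at every node with slope 0.684 and
intercept −0.82 (the grams-scale equivalent of the published
mg-scale intercept). All generators take explicit integer seeds and use
numpy Generators only, so outputs are platform-stable; the deterministic
fixture uses a fixed seed and a 0.005 /Myr brain trend.

What the generator does *not* emulate: diversified or body-mass-biased
fossil sampling, extinction (the topology is pure-birth), measurement
error in masses, and the real dataset's deep-node imbalance. Passing
recovery tests therefore show the estimators work under the assumed
model, not that any particular empirical reconstruction is correct.

## Problem sizes and known limitations

Statistical checks run at deliberately modest sizes chosen to make their
sampling error analysable: trend detection at 40 extant + 10 fossil tips
with β = 0.1 /Myr over 20 replicates; PGLS slope recovery at n = 200;
rate recovery at n = 100 against the exact χ² sampling band; reduced
MCMC chains as above. One property worth knowing: for no-trend Brownian
motion, the Spearman correlation between reconstructed and true internal
states is invariant to the rate α and tops out around 0.88 on 40-tip
pure-birth trees — deep nodes simply carry little tip information, and
the conditional mean is already the minimum-MSE estimator. With a
directional signal and the directional model selected by the Bayes
factor, the same quantity exceeds 0.99, while ignoring the trend degrades
it to ~0.7: the quantitative version of why model selection precedes
reconstruction in this pipeline.

Other limitations: no Ornstein–Uhlenbeck or multi-rate models, no
measurement-error variance, no stepping-stone marginal likelihoods, no
NEXUS I/O, and λ's treatment of internal-node covariances in the node
conditional (off-diagonals scaled, variances untouched) is a convention —
λ is not well defined for ancestors in the way it is for tips.
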