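"""Ancestral-state reconstruction and directional-trend testing.

Three reconstruction routes are provided:

* weighted squared-change parsimony — internal states minimise the sum of
  squared changes per branch, each weighted by the inverse branch length;
* maximum likelihood under Brownian motion — each internal state is the GLS
  conditional expectation given the tip data, with a standard error that
  includes the uncertainty of the estimated root (and drift, if any);
* Bayesian MCMC — Metropolis-within-Gibbs over the random-walk parameters
  with uniform priors, with ancestral states drawn at every retained
  iteration from their exact conditional Gaussian given the sampled
  parameters (a Rao-Blackwellised joint posterior draw).

Model comparison between the directional and constant-variance random walks
follows the harmonic-mean marginal-likelihood convention: the Bayes factor
is twice the difference of log harmonic means, read against the usual
2 / 5 / 10 evidence thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .model import (BrownianMotion, EvoModelParams, _chol, _pow0,
                    transform_covariance, _LOG2PI)
from .tree import Phylogeny

__all__ = [
    "NodeEstimate", "McmcSettings", "McmcRun", "ModelComparison",
    "CongruenceResult", "asr_parsimony", "asr_ml", "mcmc_fit", "asr_mcmc",
    "log_harmonic_mean", "bayes_factor", "congruence", "trend_test",
    "AncestralStates",
]


@dataclass
class NodeEstimate:
    node: int
    method: str
    estimate: float
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    normality_p: float = np.nan


@dataclass
class CongruenceResult:
    labels: tuple
    r_s: float
    p_value: float


@dataclass
class ModelComparison:
    log_hm_a: float
    log_hm_b: float
    bayes_factor: float
    verdict: str


@dataclass
class McmcSettings:
    """Chain settings; the defaults mirror a typical BayesTraits-style run
    (two million post-burn-in iterations sampled every 100 after a burn-in
    of half a million, uniform priors on [-100, 100])."""

    iterations: int = 2_000_000
    burn_in: int = 500_000
    thin: int = 100
    prior_low: float = -100.0
    prior_high: float = 100.0
    seed: int = 0
    tune_interval: int = 1_000
    target_acceptance: tuple = (0.20, 0.40)

    def validate(self):
        if self.iterations <= 0 or self.burn_in < 0 or self.thin <= 0:
            raise ValueError("invalid chain lengths")
        if self.iterations < self.thin:
            raise ValueError("chain shorter than thinning interval")
        if not np.isfinite([self.prior_low, self.prior_high]).all():
            raise ValueError("prior bounds must be finite")


@dataclass
class McmcRun:
    params: pd.DataFrame            # one row per retained draw
    loglik: np.ndarray              # marginal tip log-likelihood per draw
    node_draws: np.ndarray          # (n_draws, n_internal_nodes)
    node_ids: list
    acceptance_rate: float
    acceptance_by_param: dict
    proposal_widths: dict
    settings: McmcSettings
    tree: Phylogeny = None
    taxa: list = field(default_factory=list)
    warnings_: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# weighted squared-change parsimony
# ---------------------------------------------------------------------------

def _values_by_tip(tree, x, taxa):
    if taxa is None:
        if isinstance(x, dict):
            taxa = list(x)
            x = [x[t] for t in taxa]
        else:
            taxa = tree.tip_labels
    x = np.asarray(x, float)
    if x.size != len(taxa):
        raise ValueError("x length does not match taxa")
    if set(taxa) != set(tree.tip_labels):
        raise ValueError("tip values must cover every tip exactly once")
    return dict(zip(taxa, x))


def asr_parsimony(tree, x, taxa=None):
    """Weighted squared-change parsimony ancestral states.

    Minimises sum over branches of (child - parent)^2 / length.  Zero-length
    branches (from polytomy resolution) are contracted so that both ends
    share one state, avoiding infinite weights without changing the optimum.
    Returns a DataFrame indexed by internal node id with column 'estimate'.
    """
    vals = _values_by_tip(tree, x, taxa)
    n = tree.n_nodes
    # union-find over zero-length edges
    group = list(range(n))

    def find(i):
        while group[i] != i:
            group[i] = group[group[i]]
            i = group[i]
        return i

    for i in range(n - 1):
        if tree.lengths[i] == 0.0:
            group[find(i)] = find(tree.parent[i])
    comp = [find(i) for i in range(n)]

    fixed = {}
    for t in tree.tips:
        g = comp[t]
        v = vals[tree.labels[t]]
        if g in fixed and abs(fixed[g] - v) > 0:
            raise ValueError(
                "conflicting tip values joined by zero-length branches")
        fixed[g] = v
    free = sorted({g for g in comp if g not in fixed})
    gi = {g: k for k, g in enumerate(free)}
    nf = len(free)
    L = np.zeros((nf, nf))
    b = np.zeros(nf)
    for i in range(n - 1):
        l = tree.lengths[i]
        if l == 0.0:
            continue
        gc, gp = comp[i], comp[tree.parent[i]]
        if gc == gp:
            continue
        w = 1.0 / l
        for ga, gb in ((gc, gp), (gp, gc)):
            if ga in gi:
                L[gi[ga], gi[ga]] += w
                if gb in gi:
                    L[gi[ga], gi[gb]] -= w
                else:
                    b[gi[ga]] += w * fixed[gb]
    if nf:
        try:
            sol = np.linalg.solve(L, b)
        except np.linalg.LinAlgError as e:
            raise ValueError("disconnected data: parsimony system singular") from e
        states = {g: sol[k] for g, k in gi.items()}
    else:
        states = {}
    states.update(fixed)
    idx = [int(i) for i in tree.internal_nodes]
    return pd.DataFrame({"estimate": [states[comp[i]] for i in idx]},
                        index=pd.Index(idx, name="node"))


# ---------------------------------------------------------------------------
# ML / GLS reconstruction
# ---------------------------------------------------------------------------

def _node_blocks(tree, taxa, nodes, kappa=1.0, lambda_=1.0, delta=1.0):
    """Tip covariance, node-tip and node-node shared-path blocks under the
    kappa/lambda/delta transforms (kappa at branch level, lambda on all
    off-diagonal entries, delta entrywise on the assembled matrix)."""
    if kappa != 1.0:
        tree_k = Phylogeny(tree.parent, _pow0(tree.lengths, kappa),
                           tree.labels)
    else:
        tree_k = tree
    tips = [tree_k.tip(t) for t in taxa]
    C = tree_k.node_cov(tips)
    Vnt = tree_k.node_cov(list(nodes), tips)
    Vnn = tree_k.node_cov(list(nodes))
    if lambda_ != 1.0:
        dC = np.diag(C).copy()
        C = C * lambda_
        np.fill_diagonal(C, dC)
        dV = np.diag(Vnn).copy()
        Vnn = Vnn * lambda_
        np.fill_diagonal(Vnn, dV)
        Vnt = Vnt * lambda_
    if delta != 1.0:
        C = _pow0(C, delta)
        Vnt = _pow0(Vnt, delta)
        Vnn = _pow0(Vnn, delta)
    return C, Vnt, Vnn


def asr_ml(tree, x, taxa=None, params=None, nodes=None):
    """Brownian-motion (GLS) ancestral states with standard errors.

    Each internal state is the conditional expectation of the node value
    given the tips; the SE combines the conditional variance with the
    uncertainty of the estimated root (and drift when the fitted model is
    directional).  If ``params`` is None a non-directional model is fitted
    by ML first.  Returns a DataFrame with columns 'estimate' and 'se'.
    """
    vals = _values_by_tip(tree, x, taxa)
    taxa = list(vals)
    xv = np.array([vals[t] for t in taxa])
    if params is None:
        params = BrownianMotion(tree=tree).fit(xv, taxa=taxa).params_
    if nodes is None:
        nodes = [int(i) for i in tree.internal_nodes]
    else:
        nodes = [int(i) for i in nodes]
        bad = [i for i in nodes if tree.is_tip(i)]
        if bad:
            raise ValueError(f"nodes {bad} are tips, not internal nodes")

    C, Vnt, _ = _node_blocks(tree, taxa, nodes, params.kappa, params.lambda_,
                             params.delta)
    paths_t = tree.path_lengths(taxa)
    paths_n = tree.depths[nodes]
    directional = params.beta != 0.0
    X = (np.column_stack([np.ones_like(paths_t), paths_t]) if directional
         else np.ones((len(taxa), 1)))
    Xn = (np.column_stack([np.ones_like(paths_n), paths_n]) if directional
          else np.ones((len(nodes), 1)))
    coef = np.array([params.root_state, params.beta])[:X.shape[1]]

    cf = _chol(C)
    r = xv - X @ coef
    Ci_r = cho_solve(cf, r)
    est = Xn @ coef + Vnt @ Ci_r

    Ci_X = cho_solve(cf, X)
    XtCiX_inv = np.linalg.inv(X.T @ Ci_X)
    G = Vnt @ Ci_X                      # (k, p)
    D = Xn - G
    cond_var = (tree.depths[nodes]
                if (params.kappa == 1.0 and params.delta == 1.0)
                else np.diag(_node_blocks(tree, taxa, nodes, params.kappa,
                                          params.lambda_, params.delta)[2]))
    quad = np.einsum("ij,ij->i", Vnt, cho_solve(cf, Vnt.T).T)
    corr = np.einsum("ij,jk,ik->i", D, XtCiX_inv, D)
    var = params.alpha * np.maximum(cond_var - quad + corr, 0.0)
    return pd.DataFrame({"estimate": est, "se": np.sqrt(var)},
                        index=pd.Index(nodes, name="node"))


# ---------------------------------------------------------------------------
# Bayesian MCMC
# ---------------------------------------------------------------------------

def _lik_scalars(C, xv, paths):
    """Sufficient scalars for the MVN profile likelihood on mean = a + b*p."""
    cf = _chol(C)
    one = np.ones_like(xv)
    Ci = {
        "x": cho_solve(cf, xv),
        "1": cho_solve(cf, one),
        "p": cho_solve(cf, paths),
    }
    return {
        "logdet": 2.0 * np.sum(np.log(np.diag(cf[0]))),
        "sxx": xv @ Ci["x"], "s1x": one @ Ci["x"], "spx": paths @ Ci["x"],
        "s11": one @ Ci["1"], "s1p": one @ Ci["p"], "spp": paths @ Ci["p"],
    }


def _scalar_loglik(s, n, alpha, root, beta):
    quad = (s["sxx"] - 2.0 * root * s["s1x"] - 2.0 * beta * s["spx"]
            + root * root * s["s11"] + 2.0 * root * beta * s["s1p"]
            + beta * beta * s["spp"])
    return -0.5 * (n * (_LOG2PI + np.log(alpha)) + s["logdet"] + quad / alpha)


def mcmc_fit(tree, x, taxa=None, directional=False, kappa=1.0, lambda_=1.0,
             delta=1.0, sample_scaling=(), settings=None, nodes=None,
             initial_widths=None):
    """Metropolis-within-Gibbs sampler for the (directional) random walk.

    Parameters are updated one at a time with Gaussian random-walk proposals
    against the marginal tip likelihood; uniform priors (hard bounds) make
    the acceptance ratio a pure likelihood ratio.  Proposal widths are tuned
    only during burn-in (multiplied by 1.1 / 0.9 per ``tune_interval`` block
    to steer acceptance into the 20-40% band) and frozen afterwards.
    Ancestral states for ``nodes`` (default: all internal nodes) are drawn
    at each retained iteration from their exact conditional Gaussian.

    ``sample_scaling`` may list any of "kappa", "lambda_", "delta" to sample
    that scaling parameter; otherwise the fixed values are used.
    """
    settings = settings or McmcSettings()
    settings.validate()
    vals = _values_by_tip(tree, x, taxa)
    taxa = list(vals)
    xv = np.array([vals[t] for t in taxa])
    n = xv.size
    paths = tree.path_lengths(taxa)
    if directional and np.ptp(paths) < 1e-9:
        raise ValueError("directional model requires root-to-tip path-length "
                         "variation; the tree is ultrametric")
    if nodes is None:
        nodes = [int(i) for i in tree.internal_nodes]

    sample_scaling = tuple(sample_scaling)
    bounds = {
        "alpha": (1e-12, settings.prior_high),
        "root_state": (settings.prior_low, settings.prior_high),
        "beta": (settings.prior_low, settings.prior_high),
        "kappa": (1e-6, 3.0), "lambda_": (0.0, 1.0), "delta": (1e-6, 3.0),
    }
    names = ["alpha", "root_state"] + (["beta"] if directional else []) \
        + list(sample_scaling)

    rng = np.random.default_rng(settings.seed)
    scaling = {"kappa": kappa, "lambda_": lambda_, "delta": delta}
    state = {"alpha": 0.1, "root_state": float(np.mean(xv)), "beta": 0.0}
    state.update({k: scaling[k] for k in sample_scaling})

    def scalars_for(st):
        sc = dict(scaling)
        sc.update({k: st[k] for k in sample_scaling})
        C = transform_covariance(tree, sc["kappa"], sc["lambda_"],
                                 sc["delta"], taxa).matrix
        return _lik_scalars(C, xv, paths)

    s = scalars_for(state)
    # start at the GLS profile and scale proposals to the asymptotic
    # posterior spread; windowed 1.1/0.9 tuning then refines toward the
    # 20-40% acceptance band during burn-in
    if directional:
        XtCiX = np.array([[s["s11"], s["s1p"]], [s["s1p"], s["spp"]]])
        coef = np.linalg.solve(XtCiX, [s["s1x"], s["spx"]])
        state["root_state"], state["beta"] = float(coef[0]), float(coef[1])
        cov_coef = np.linalg.inv(XtCiX)
    else:
        state["root_state"] = float(s["s1x"] / s["s11"])
        cov_coef = np.array([[1.0 / s["s11"]]])
    quad0 = (s["sxx"] - 2 * state["root_state"] * s["s1x"]
             - 2 * state["beta"] * s["spx"]
             + state["root_state"] ** 2 * s["s11"]
             + 2 * state["root_state"] * state["beta"] * s["s1p"]
             + state["beta"] ** 2 * s["spp"])
    state["alpha"] = float(np.clip(quad0 / n, 1e-8, bounds["alpha"][1]))
    lo, hi = bounds["root_state"]
    state["root_state"] = float(np.clip(state["root_state"], lo, hi))
    state["beta"] = float(np.clip(state["beta"], *bounds["beta"]))
    a = state["alpha"]
    widths = {"alpha": 3.0 * a * np.sqrt(2.0 / n),
              "root_state": 3.0 * np.sqrt(a * cov_coef[0, 0]),
              "beta": (3.0 * np.sqrt(a * cov_coef[1, 1])
                       if directional else 0.1)}
    widths.update({k: 0.1 for k in sample_scaling})
    widths = {k: widths[k] for k in names}
    if initial_widths:
        widths.update(initial_widths)
    ll = _scalar_loglik(s, n, state["alpha"], state["root_state"],
                        state["beta"])

    total = settings.burn_in + settings.iterations
    n_draws = settings.iterations // settings.thin
    draws = {k: np.empty(n_draws) for k in names}
    ll_trace = np.empty(n_draws)
    acc = {k: 0 for k in names}
    prop = {k: 0 for k in names}
    acc_win = {k: 0 for k in names}
    prop_win = {k: 0 for k in names}
    d = 0

    block = 4096
    normals = rng.standard_normal((block, len(names)))
    unifs = rng.random((block, len(names)))
    bi = block  # force refill

    for it in range(total):
        if bi >= block:
            normals = rng.standard_normal((block, len(names)))
            unifs = rng.random((block, len(names)))
            bi = 0
        burning = it < settings.burn_in
        for j, name in enumerate(names):
            cand = state[name] + widths[name] * normals[bi, j]
            if burning:
                prop_win[name] += 1
            else:
                prop[name] += 1
            lo, hi = bounds[name]
            if cand < lo or cand > hi:
                continue
            if name in sample_scaling:
                old_val, old_s = state[name], s
                state[name] = cand
                s_new = scalars_for(state)
                ll_new = _scalar_loglik(s_new, n, state["alpha"],
                                        state["root_state"], state["beta"])
                if np.log(unifs[bi, j] + 1e-300) < ll_new - ll:
                    s, ll = s_new, ll_new
                    (acc_win if burning else acc)[name] += 1
                else:
                    state[name] = old_val
                    s = old_s
            else:
                trial = dict(state)
                trial[name] = cand
                ll_new = _scalar_loglik(s, n, trial["alpha"],
                                        trial["root_state"], trial["beta"])
                if np.log(unifs[bi, j] + 1e-300) < ll_new - ll:
                    state = trial
                    ll = ll_new
                    (acc_win if burning else acc)[name] += 1
        bi += 1
        if burning and (it + 1) % settings.tune_interval == 0:
            lo_t, hi_t = settings.target_acceptance
            for name in names:
                if prop_win[name] == 0:
                    continue
                rate = acc_win[name] / prop_win[name]
                if rate > hi_t:
                    widths[name] *= 1.1
                elif rate < lo_t:
                    widths[name] *= 0.9
                acc_win[name] = prop_win[name] = 0
        if not burning and (it - settings.burn_in + 1) % settings.thin == 0:
            for k in names:
                draws[k][d] = state[k]
            ll_trace[d] = ll
            d += 1

    rates = {k: (acc[k] / prop[k] if prop[k] else np.nan) for k in names}
    overall = float(np.mean(list(rates.values())))
    warns = []
    if not 0.05 <= overall <= 0.8:
        msg = (f"post-tuning acceptance rate {overall:.2f} outside [0.05, 0.8]")
        warns.append(msg)
        warnings.warn(msg, RuntimeWarning)

    params_df = pd.DataFrame(draws)
    if not directional:
        params_df["beta"] = 0.0

    node_draws = _draw_node_states(
        tree, taxa, xv, nodes, params_df, paths, scaling, sample_scaling, rng)

    return McmcRun(params=params_df, loglik=ll_trace, node_draws=node_draws,
                   node_ids=list(nodes), acceptance_rate=overall,
                   acceptance_by_param=rates, proposal_widths=dict(widths),
                   settings=settings, tree=tree, taxa=taxa, warnings_=warns)


def _draw_node_states(tree, taxa, xv, nodes, params_df, paths, scaling,
                      sample_scaling, rng):
    """Conditional Gaussian draws of internal states for each retained draw.

    Given (alpha, root, beta) the internal states are jointly Gaussian with
    mean ``root + beta*path + Vnt C^-1 (x - root - beta*path_tips)`` and
    covariance ``alpha * (Vnn - Vnt C^-1 Vtn)``.  When scaling parameters
    were sampled the conditioning matrices are built at their posterior
    means (the matrices vary smoothly and rebuilding them per draw would
    dominate run time).
    """
    sc = dict(scaling)
    for k in sample_scaling:
        sc[k] = float(params_df[k].mean())
    C, Vnt, Vnn = _node_blocks(tree, taxa, nodes, sc["kappa"], sc["lambda_"],
                               sc["delta"])
    cf = _chol(C)
    A = cho_solve(cf, Vnt.T).T          # Vnt C^-1
    S = Vnn - A @ Vnt.T
    # guard tiny negative eigenvalues from rounding
    S = (S + S.T) / 2.0 + 1e-12 * np.eye(len(nodes))
    Ls = np.linalg.cholesky(S)
    paths_n = tree.depths[list(nodes)]

    m = len(params_df)
    roots = params_df["root_state"].to_numpy()
    betas = params_df["beta"].to_numpy()
    alphas = params_df["alpha"].to_numpy()
    R = xv[None, :] - roots[:, None] - betas[:, None] * paths[None, :]
    means = roots[:, None] + betas[:, None] * paths_n[None, :] + R @ A.T
    Z = rng.standard_normal((m, len(nodes)))
    return means + np.sqrt(alphas)[:, None] * (Z @ Ls.T)


def _batch_means_se(draws):
    """Monte-Carlo SE of the mean by batch means (autocorrelation-robust)."""
    m = draws.size
    nb = max(int(np.sqrt(m)), 2)
    bs = m // nb
    means = draws[: nb * bs].reshape(nb, bs).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


def asr_mcmc(run, nodes=None):
    """Summarise MCMC node draws: posterior mean, batch-means MC standard
    error, 95% credible interval and a Shapiro-Wilk normality p-value per
    node.  Returns a DataFrame indexed by node id."""
    if nodes is None:
        nodes = run.node_ids
    out = []
    pos = {nid: k for k, nid in enumerate(run.node_ids)}
    for nid in nodes:
        if nid not in pos:
            raise ValueError(f"node {nid} was not sampled (not internal?)")
        dr = run.node_draws[:, pos[nid]]
        lo, hi = np.percentile(dr, [2.5, 97.5])
        sw = stats.shapiro(dr if dr.size <= 4999 else
                           dr[:: max(1, dr.size // 4000)])
        out.append({"node": int(nid), "estimate": float(dr.mean()),
                    "mc_se": _batch_means_se(dr),
                    "ci_low": float(lo), "ci_high": float(hi),
                    "normality_p": float(sw.pvalue)})
    return pd.DataFrame(out).set_index("node")


# ---------------------------------------------------------------------------
# model comparison and congruence
# ---------------------------------------------------------------------------

def log_harmonic_mean(loglik_trace):
    """Log harmonic mean of likelihoods, computed stably in log space."""
    ll = np.asarray(loglik_trace, float)
    if ll.size == 0:
        raise ValueError("empty likelihood trace")
    return float(-(logsumexp(-ll) - np.log(ll.size)))


def bayes_factor(log_hm_a, log_hm_b):
    """BF = 2 (logHM_A - logHM_B); evidence for A over B at 2 / 5 / 10."""
    bf = 2.0 * (log_hm_a - log_hm_b)
    if bf > 10:
        verdict = "very strong"
    elif bf > 5:
        verdict = "strong"
    elif bf > 2:
        verdict = "positive"
    else:
        verdict = "none"
    return ModelComparison(log_hm_a=float(log_hm_a), log_hm_b=float(log_hm_b),
                           bayes_factor=float(bf), verdict=verdict)


def congruence(est_a, est_b, labels=("A", "B")):
    """Spearman rank correlation between two node-estimate vectors."""
    a = np.asarray(est_a, float)
    b = np.asarray(est_b, float)
    if a.size != b.size:
        raise ValueError("estimate vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 shared nodes")
    r = stats.spearmanr(a, b)
    return CongruenceResult(labels=tuple(labels), r_s=float(r.statistic),
                            p_value=float(r.pvalue))


def trend_test(tree, x, taxa=None, settings=None, **mcmc_kw):
    """Directional vs constant-variance random walk via harmonic-mean BF.

    Runs both models with identical settings and returns
    ``(ModelComparison, run_directional, run_constant)`` where the Bayes
    factor is evidence for the directional model.
    """
    run_dir = mcmc_fit(tree, x, taxa=taxa, directional=True,
                       settings=settings, **mcmc_kw)
    run_con = mcmc_fit(tree, x, taxa=taxa, directional=False,
                       settings=settings, **mcmc_kw)
    comp = bayes_factor(log_harmonic_mean(run_dir.loglik),
                        log_harmonic_mean(run_con.loglik))
    return comp, run_dir, run_con


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class AncestralStates(BaseEstimator):
    """Ancestral-state reconstruction as a fit/predict estimator.

    Parameters
    ----------
    tree : Phylogeny
    method : {"parsimony", "ml", "mcmc"}
    directional : bool
        For "ml"/"mcmc": fit the directional random walk.
    settings : McmcSettings, optional
        Chain settings for method="mcmc".
    """

    def __init__(self, tree=None, method="ml", directional=False,
                 settings=None):
        self.tree = tree
        self.method = method
        self.directional = directional
        self.settings = settings

    def fit(self, x, taxa=None):
        if self.method == "parsimony":
            if self.directional:
                raise ValueError("parsimony cannot model a trend")
            self.estimates_ = asr_parsimony(self.tree, x, taxa)
        elif self.method == "ml":
            params = None
            if self.directional:
                params = BrownianMotion(tree=self.tree, directional=True) \
                    .fit(np.asarray(x, float), taxa=taxa).params_
            self.estimates_ = asr_ml(self.tree, x, taxa, params=params)
            self.params_ = params
        elif self.method == "mcmc":
            self.run_ = mcmc_fit(self.tree, x, taxa,
                                 directional=self.directional,
                                 settings=self.settings)
            self.estimates_ = asr_mcmc(self.run_)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def predict(self, nodes=None):
        """Point estimates for the requested internal nodes."""
        est = self.estimates_
        if nodes is None:
            return est["estimate"].to_numpy()
        return est.loc[list(nodes), "estimate"].to_numpy()
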