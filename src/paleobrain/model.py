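"""Brownian-motion likelihood machinery for continuous traits on trees.

The constant-variance random walk (Brownian motion) model has a single rate
parameter ``alpha`` (trait^2 per Myr); tip values are jointly Gaussian with
mean equal to the root state and covariance ``alpha * C`` where ``C`` is the
shared-path matrix of the tree.  The directional random walk adds a drift
``beta`` (trait units per Myr): the expected tip value becomes
``root_state + beta * path_length``, identifiable only when root-to-tip path
lengths vary (i.e. on trees with fossil tips).

Branch-length scaling parameters follow the standard kappa/lambda/delta
family: ``kappa`` raises each branch length to a power (kappa < 1 compresses
long branches toward punctuational change), ``lambda`` discounts the
off-diagonal covariances (phylogenetic signal), and ``delta`` raises the
assembled covariance entries to a power (early vs late change).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from .tree import Phylogeny, PhyloCovariance

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class EvoModelParams:
    """Parameters of a (possibly directional, possibly rescaled) random walk."""

    alpha: float = 1.0           # instantaneous variance, trait^2 / Myr
    root_state: float = 0.0      # trait units
    beta: float = 0.0            # directional trend, trait units / Myr
    kappa: float = 1.0
    lambda_: float = 1.0
    delta: float = 1.0

    def validate(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        _check_scaling(self.kappa, self.lambda_, self.delta)

    def to_dict(self):
        return asdict(self)


@dataclass
class RegressionFit:
    """A fitted (phylogenetic) regression y = intercept + slope * x."""

    intercept: float
    slope: float
    t_statistic: float
    df: int
    r_squared: float
    residuals: dict
    kappa: float = 1.0
    lambda_: float = 1.0
    delta: float = 1.0
    log_likelihood: float = np.nan

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass
class LRTestResult:
    statistic: float
    p_value: float
    null_value: float = 1.0


def _check_scaling(kappa, lambda_, delta):
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if delta < 0:
        raise ValueError("delta must be >= 0")


def _pow0(a, p):
    """Elementwise power with the convention 0**p == 0 (p >= 0)."""
    a = np.asarray(a, float)
    out = np.zeros_like(a)
    nz = a > 0
    out[nz] = a[nz] ** p
    return out


def transform_covariance(tree, kappa=1.0, lambda_=1.0, delta=1.0, taxa=None):
    """Build the phylogenetic covariance under kappa/lambda/delta scaling.

    kappa acts on individual branch lengths before the covariance is
    assembled; lambda multiplies the off-diagonal entries; delta raises the
    resulting entries to a power.  ``(1, 1, 1)`` is the identity.
    """
    _check_scaling(kappa, lambda_, delta)
    if taxa is None:
        taxa = tree.tip_labels
    if kappa != 1.0:
        tree = Phylogeny(tree.parent, _pow0(tree.lengths, kappa), tree.labels)
    C = tree.vcv(taxa).matrix.copy()
    if lambda_ != 1.0:
        d = np.diag(C).copy()
        C *= lambda_
        np.fill_diagonal(C, d)
    if delta != 1.0:
        C = _pow0(C, delta)
    return PhyloCovariance(tuple(taxa), C)


def _chol(C):
    try:
        return cho_factor(np.asarray(C, float), lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance: identical tip paths "
            "(e.g. duplicated zero-length tips) make the model degenerate"
        ) from e


def bm_loglik(x, C, params, paths=None):
    """Log-likelihood of tip data under the (directional) random walk.

    ``mean_i = root_state + beta * path_i`` and covariance ``alpha * C``.
    ``paths`` defaults to the diagonal of ``C``.
    """
    if isinstance(C, PhyloCovariance):
        C = C.matrix
    x = np.asarray(x, float)
    n = x.size
    if C.shape != (n, n):
        raise ValueError("data/covariance dimension mismatch")
    params.validate()
    if paths is None:
        paths = np.diag(C)
    mu = params.root_state + params.beta * np.asarray(paths, float)
    cf = _chol(C)
    r = x - mu
    quad = r @ cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return -0.5 * (n * (_LOG2PI + np.log(params.alpha)) + logdet
                   + quad / params.alpha)


def _gls_profile(x, C, X):
    """Profile the GLS mean coefficients and the ML variance scale.

    Returns (coef, alpha_ml, loglik, cov_unscaled) where ``cov_unscaled`` is
    ``(X' C^-1 X)^-1`` (multiply by the variance estimate for coef vars).
    """
    x = np.asarray(x, float)
    n = x.size
    cf = _chol(C)
    Ci_X = cho_solve(cf, X)
    XtCiX = X.T @ Ci_X
    coef = np.linalg.solve(XtCiX, Ci_X.T @ x)
    r = x - X @ coef
    quad = r @ cho_solve(cf, r)
    alpha = quad / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    if alpha <= 0:
        alpha = np.finfo(float).tiny
    ll = -0.5 * (n * (_LOG2PI + np.log(alpha) + 1.0) + logdet)
    return coef, alpha, ll, np.linalg.inv(XtCiX)


class BrownianMotion(BaseEstimator):
    """ML fit of a (directional) random walk with optional branch scaling.

    Parameters
    ----------
    tree : Phylogeny
    directional : bool
        Estimate the drift ``beta`` (requires root-to-tip path variation).
    estimate_kappa, estimate_lambda, estimate_delta : bool
        Free the corresponding scaling parameter; otherwise it is fixed at
        the ``kappa``/``lambda_``/``delta`` value (default 1 = gradualism).
    n_restarts : int
        Seeded multi-start count for the bounded quasi-Newton optimizer
        (used only when scaling parameters are free).
    """

    def __init__(self, tree=None, directional=False, estimate_kappa=False,
                 estimate_lambda=False, estimate_delta=False, kappa=1.0,
                 lambda_=1.0, delta=1.0, n_restarts=5, random_state=0):
        self.tree = tree
        self.directional = directional
        self.estimate_kappa = estimate_kappa
        self.estimate_lambda = estimate_lambda
        self.estimate_delta = estimate_delta
        self.kappa = kappa
        self.lambda_ = lambda_
        self.delta = delta
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _design(self, paths):
        if not self.directional:
            return np.ones((paths.size, 1))
        if np.ptp(paths) < 1e-9:
            raise ValueError(
                "directional model requires root-to-tip path-length "
                "variation; the tree is ultrametric")
        return np.column_stack([np.ones_like(paths), paths])

    def fit(self, x, taxa=None):
        """Fit to tip values ``x`` ordered as ``taxa`` (default: tip order)."""
        tree = self.tree
        if taxa is None:
            taxa = tree.tip_labels
        x = np.asarray(x, float)
        if x.size != len(taxa):
            raise ValueError("x length does not match taxa")
        if x.size < 3 and self.directional:
            raise ValueError("trend estimation needs >= 3 taxa")
        paths = tree.path_lengths(taxa)
        X = self._design(paths)

        free = [name for name, flag in
                [("kappa", self.estimate_kappa),
                 ("lambda_", self.estimate_lambda),
                 ("delta", self.estimate_delta)] if flag]
        fixed = {"kappa": self.kappa, "lambda_": self.lambda_,
                 "delta": self.delta}
        _check_scaling(fixed["kappa"], fixed["lambda_"], fixed["delta"])

        def profile(theta):
            sc = dict(fixed)
            sc.update(zip(free, theta))
            C = transform_covariance(tree, sc["kappa"], sc["lambda_"],
                                     sc["delta"], taxa).matrix
            coef, alpha, ll, cov = _gls_profile(x, C, X)
            return sc, coef, alpha, ll, cov

        if free:
            bounds = {"kappa": (1e-6, 3.0), "lambda_": (0.0, 1.0),
                      "delta": (1e-6, 3.0)}
            bnds = [bounds[n] for n in free]
            rng = np.random.default_rng(self.random_state)
            starts = [[1.0 if n != "lambda_" else 0.9 for n in free]]
            starts += [[rng.uniform(lo + 1e-3, hi) for lo, hi in bnds]
                       for _ in range(self.n_restarts - 1)]
            best = None
            for s0 in starts:
                res = optimize.minimize(
                    lambda th: -profile(th)[3], s0, method="L-BFGS-B",
                    bounds=bnds, options={"ftol": 1e-10})
                if best is None or res.fun < best.fun:
                    best = res
            sc, coef, alpha, ll, cov = profile(best.x)
        else:
            sc, coef, alpha, ll, cov = profile([])

        self.params_ = EvoModelParams(
            alpha=float(alpha), root_state=float(coef[0]),
            beta=float(coef[1]) if self.directional else 0.0,
            kappa=float(sc["kappa"]), lambda_=float(sc["lambda_"]),
            delta=float(sc["delta"]))
        self.log_likelihood_ = float(ll)
        self.alpha_ = self.params_.alpha
        self.root_state_ = self.params_.root_state
        self.beta_ = self.params_.beta
        self.n_features_in_ = 1
        self.taxa_ = list(taxa)
        return self


def fit_ml(x, tree, directional=False, estimate_kappa=False,
           estimate_lambda=False, estimate_delta=False, taxa=None, **kw):
    """Functional wrapper over :class:`BrownianMotion`.

    Returns ``(EvoModelParams, max log-likelihood)``.
    """
    est = BrownianMotion(tree=tree, directional=directional,
                         estimate_kappa=estimate_kappa,
                         estimate_lambda=estimate_lambda,
                         estimate_delta=estimate_delta, **kw).fit(x, taxa=taxa)
    return est.params_, est.log_likelihood_


class PGLS(BaseEstimator, RegressorMixin):
    """Phylogenetic generalized least squares regression.

    Ordinary GLS with error covariance proportional to the (optionally
    kappa/lambda/delta-rescaled) phylogenetic covariance; scaling parameters
    flagged for estimation are profiled by maximum likelihood.  The fixed-
    covariance fit itself is delegated to :class:`statsmodels` GLS.
    """

    def __init__(self, tree=None, estimate_kappa=False, estimate_lambda=False,
                 estimate_delta=False, kappa=1.0, lambda_=1.0, delta=1.0,
                 n_restarts=5, random_state=0):
        self.tree = tree
        self.estimate_kappa = estimate_kappa
        self.estimate_lambda = estimate_lambda
        self.estimate_delta = estimate_delta
        self.kappa = kappa
        self.lambda_ = lambda_
        self.delta = delta
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y, taxa=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("PGLS here is simple regression: one predictor")
        y = np.asarray(y, float)
        if taxa is None:
            taxa = self.tree.tip_labels
        if len(taxa) != y.size or X.shape[0] != y.size:
            raise ValueError("X/y/taxa size mismatch")
        if np.ptp(X[:, 0]) < 1e-12:
            raise ValueError("constant predictor: slope is unidentifiable")

        design = sm.add_constant(X)

        def profile(sc):
            C = transform_covariance(self.tree, sc["kappa"], sc["lambda_"],
                                     sc["delta"], taxa).matrix
            _, _, ll, _ = _gls_profile(y, C, design)
            return ll, C

        free = [n for n, f in [("kappa", self.estimate_kappa),
                               ("lambda_", self.estimate_lambda),
                               ("delta", self.estimate_delta)] if f]
        sc = {"kappa": self.kappa, "lambda_": self.lambda_,
              "delta": self.delta}
        _check_scaling(sc["kappa"], sc["lambda_"], sc["delta"])
        if free:
            bounds = {"kappa": (1e-6, 3.0), "lambda_": (0.0, 1.0),
                      "delta": (1e-6, 3.0)}
            bnds = [bounds[n] for n in free]
            rng = np.random.default_rng(self.random_state)
            starts = [[1.0 if n != "lambda_" else 0.9 for n in free]]
            starts += [[rng.uniform(lo + 1e-3, hi) for lo, hi in bnds]
                       for _ in range(self.n_restarts - 1)]

            def neg(th):
                s = dict(sc)
                s.update(zip(free, th))
                return -profile(s)[0]

            best = None
            for s0 in starts:
                res = optimize.minimize(neg, s0, method="L-BFGS-B",
                                        bounds=bnds, options={"ftol": 1e-10})
                if best is None or res.fun < best.fun:
                    best = res
            sc.update(zip(free, best.x))

        ll, C = profile(sc)
        gls = sm.GLS(y, design, sigma=C).fit()
        resid = y - gls.fittedvalues
        self.intercept_ = float(gls.params[0])
        self.coef_ = np.array([gls.params[1]])
        self.slope_ = float(gls.params[1])
        self.t_statistic_ = float(gls.tvalues[1])
        self.df_ = int(y.size - 2)
        self.r_squared_ = float(gls.rsquared)
        self.residuals_ = dict(zip(taxa, resid))
        self.log_likelihood_ = float(ll)
        self.scaling_ = {k: float(v) for k, v in sc.items()}
        self.n_features_in_ = 1
        self.fit_ = RegressionFit(
            intercept=self.intercept_, slope=self.slope_,
            t_statistic=self.t_statistic_, df=self.df_,
            r_squared=self.r_squared_, residuals=self.residuals_,
            kappa=self.scaling_["kappa"], lambda_=self.scaling_["lambda_"],
            delta=self.scaling_["delta"],
            log_likelihood=self.log_likelihood_)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.intercept_ + self.slope_ * X


def pgls(y, x, tree, taxa=None, **kw):
    """Fit y = a + b*x under phylogenetic GLS; returns :class:`RegressionFit`."""
    return PGLS(tree=tree, **kw).fit(np.asarray(x, float), y, taxa=taxa).fit_


def lr_test(loglik_free, loglik_constrained, null_value=1.0, tol=1e-6):
    """Likelihood-ratio test of a single constrained parameter (chi2, df=1)."""
    lr = 2.0 * (loglik_free - loglik_constrained)
    if lr < -tol:
        raise RuntimeError(
            f"free model log-likelihood below constrained ({lr/2:+.3g}): "
            "optimization failure")
    lr = max(lr, 0.0)
    return LRTestResult(statistic=lr, p_value=float(stats.chi2.sf(lr, 1)),
                        null_value=null_value)
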