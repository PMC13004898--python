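"""Estimation likelihoods and the gene-by-environment inference layer.

Three maximum-likelihood families cover the outcome types the preference
instruments produce:

* interval regression — a Gaussian latent outcome observed only as an
  interval (possibly half-infinite), the natural model for CRRA and
  discount-rate bounds; the per-row likelihood is a normal density for point
  rows and a normal-CDF difference for censored rows;
* logistic regression for binary collapses;
* ordered (proportional-odds) logistic regression for the 6/7-point scales,
  with thresholds kept strictly increasing through a log-difference
  reparameterization and reported on the original scale by the delta method.

All fits expose per-observation score contributions, so a cluster-robust
sandwich covariance can replace the model-based one for person-wave panels.
The GxE layer builds fully interacted designs (every term appears both on its
own and multiplied with the binary moderator), computes implied group effects
(main + interaction, delta-method SE) and model-scale prediction profiles over
a grid of the predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

__all__ = [
    "ConvergenceError",
    "SeparationError",
    "FitResult",
    "ContrastResult",
    "GxeSpec",
    "interval_loglik",
    "fit_interval",
    "fit_logit",
    "fit_ologit",
    "prop_odds_test",
    "cluster_vcov",
    "build_gxe_design",
    "fit_gxe",
    "GxeResult",
    "implied_effect",
    "predict_profile",
]

_LOG2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# results containers


@dataclass(frozen=True)
class FitResult:
    """One fitted likelihood: named coefficients, covariance, diagnostics.

    ``params``/``cov`` are on the reporting scale (ordered-logit thresholds
    back-transformed).  ``scores`` holds per-observation score contributions
    on the internal optimization scale and ``jac`` the Jacobian of reported
    w.r.t. internal parameters, which is what the cluster sandwich needs.
    """

    family: str
    names: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray
    llf: float
    n: int
    converged: bool
    grad_norm: float
    scores: np.ndarray = field(repr=False, default=None)
    cov_internal: np.ndarray = field(repr=False, default=None)
    jac: np.ndarray = field(repr=False, default=None)
    sigma: np.ndarray | None = None  # interval model residual SD (per group)
    thresholds: np.ndarray | None = None  # ordered model cutpoints, original scale
    extra: dict = field(default_factory=dict, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, conf: float = 0.95) -> np.ndarray:
        zc = stats.norm.ppf(0.5 + conf / 2.0)
        se = self.se
        return np.column_stack([self.params - zc * se, self.params + zc * se])

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=list(self.names),
        )
        if self.family in ("logit", "ologit"):
            out["odds_ratio"] = np.exp(self.params)
        return out

    def with_cov(self, cov: np.ndarray) -> "FitResult":
        return replace(self, cov=np.asarray(cov))


@dataclass(frozen=True)
class ContrastResult:
    """A linear combination of coefficients with its Wald inference."""

    estimate: float
    se: float
    z: float
    p: float
    ci: tuple[float, float]
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None


def _wald(estimate: float, se: float, logit_family: bool) -> ContrastResult:
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    lo, hi = estimate - 1.96 * se, estimate + 1.96 * se
    if logit_family:
        return ContrastResult(estimate, se, z, p, (lo, hi), math.exp(estimate),
                              (math.exp(lo), math.exp(hi)))
    return ContrastResult(estimate, se, z, p, (lo, hi))


# ---------------------------------------------------------------------------
# helpers


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{j}" for j in range(X.shape[1]))


def _observed_info(grad: Callable[[np.ndarray], np.ndarray], theta: np.ndarray) -> np.ndarray:
    """Observed information = Hessian of the NLL, by differencing the analytic gradient."""
    h = numdiff.approx_fprime(theta, grad, centered=True)
    return 0.5 * (h + h.T)


def _minimize(nll, grad, start, what: str) -> optimize.OptimizeResult:
    res = optimize.minimize(nll, start, jac=grad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 1000})
    gnorm = float(np.max(np.abs(res.jac)))
    if gnorm > 1e-5:
        # one Newton-style polish pass via the observed information
        try:
            hinv = np.linalg.inv(_observed_info(grad, res.x))
            x2 = res.x - hinv @ res.jac
            if nll(x2) <= res.fun:
                res.x, res.fun, res.jac = x2, nll(x2), grad(x2)
                gnorm = float(np.max(np.abs(res.jac)))
        except np.linalg.LinAlgError:
            pass
    if gnorm > 1e-4:
        raise ConvergenceError(
            f"{what} did not converge: max |gradient| = {gnorm:.3g}"
        )
    return res


# ---------------------------------------------------------------------------
# interval-censored Gaussian regression


def _interval_parts(lower, upper):
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape:
        raise ValueError("lower/upper bound length mismatch")
    if np.any(lower > upper):
        raise ValueError("some lower bounds exceed upper bounds")
    lo_fin = np.isfinite(lower)
    up_fin = np.isfinite(upper)
    if not np.all(lo_fin | up_fin):
        raise ValueError("every row needs at least one finite bound")
    point = lo_fin & up_fin & (lower == upper)
    interval = lo_fin & up_fin & ~point
    right = lo_fin & ~up_fin  # upper = +inf
    left = ~lo_fin & up_fin  # lower = -inf
    return lower, upper, point, interval, right, left


def _log_norm_interval(zl: np.ndarray, zu: np.ndarray) -> np.ndarray:
    """log(Phi(zu) - Phi(zl)), computed in the better-conditioned tail."""
    flip = (zl + zu) > 0  # both in the upper tail: use survival functions
    a = np.where(flip, -zu, zl)
    b = np.where(flip, -zl, zu)
    # now b >= a and the mass sits toward the lower tail
    logp = special.log_ndtr(b) + np.log1p(
        -np.exp(np.clip(special.log_ndtr(a) - special.log_ndtr(b), -745, 0))
    )
    return logp


def interval_loglik(lower, upper, mu, sigma) -> np.ndarray:
    """Per-row log-likelihood of the censored-normal model.

    Point rows contribute the normal density, bounded intervals a CDF
    difference, half-infinite rows a single tail probability.  This is the
    exact quantity ``fit_interval`` maximizes the sum of.
    """
    lower, upper, pt, iv, rc, lc = _interval_parts(lower, upper)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), lower.shape)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), lower.shape)
    ll = np.zeros(lower.shape)
    if pt.any():
        z = (lower[pt] - mu[pt]) / sig[pt]
        ll[pt] = -0.5 * z**2 - np.log(sig[pt]) - 0.5 * _LOG2PI
    if iv.any():
        zl = (lower[iv] - mu[iv]) / sig[iv]
        zu = (upper[iv] - mu[iv]) / sig[iv]
        ll[iv] = _log_norm_interval(zl, zu)
    if rc.any():
        ll[rc] = special.log_ndtr(-(lower[rc] - mu[rc]) / sig[rc])
    if lc.any():
        ll[lc] = special.log_ndtr((upper[lc] - mu[lc]) / sig[lc])
    return ll


def fit_interval(
    lower,
    upper,
    X,
    sigma_groups=None,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
) -> FitResult:
    """Gaussian MLE for an interval-censored outcome Y* = X b + e, e ~ N(0, s^2).

    Rows may be point-valued (lower == upper), bounded intervals, or
    half-infinite (never-switchers).  ``sigma_groups`` optionally maps each row
    to its own residual-SD group, which is what makes a single fully
    interacted fit reproduce two separate group-wise fits exactly.  The SD is
    optimized on the log scale; reported parameters are the slopes followed by
    ``lnsigma`` terms.
    """
    lower, upper, pt, iv, rc, lc = _interval_parts(lower, upper)
    Xm, names = _as_matrix(X)
    n, p = Xm.shape
    if sigma_groups is None:
        groups = np.zeros(n, dtype=int)
    else:
        groups = np.asarray(sigma_groups).astype(int)
    glevels = np.unique(groups)
    gidx = np.searchsorted(glevels, groups)
    ng = len(glevels)
    if not (pt.any() or iv.any()) and (rc.all() or lc.all()):
        raise ValueError("all rows censored on the same side; model degenerate")

    mid = np.where(pt | iv, 0.5 * (lower + upper), np.where(rc, lower, upper))

    def unpack(theta):
        beta = theta[:p]
        sig = np.exp(theta[p:])[gidx]
        return beta, sig

    def nll(theta):
        beta, sig = unpack(theta)
        return -float(np.sum(interval_loglik(lower, upper, Xm @ beta, sig)))

    def score_matrix(theta):
        beta, sig = unpack(theta)
        mu = Xm @ beta
        dmu = np.zeros(n)  # d ll / d mu
        dls = np.zeros(n)  # d ll / d ln sigma
        if pt.any():
            z = (mid[pt] - mu[pt]) / sig[pt]
            dmu[pt] = z / sig[pt]
            dls[pt] = z**2 - 1.0
        if iv.any():
            zl = (lower[iv] - mu[iv]) / sig[iv]
            zu = (upper[iv] - mu[iv]) / sig[iv]
            logp = _log_norm_interval(zl, zu)
            # density/probability ratios on the log scale: stable when the
            # interval is far in a tail and prob underflows
            ru = np.exp(stats.norm.logpdf(zu) - logp)
            rl = np.exp(stats.norm.logpdf(zl) - logp)
            dmu[iv] = -(ru - rl) / sig[iv]
            dls[iv] = -(zu * ru - zl * rl)
        if rc.any():
            zl = (lower[rc] - mu[rc]) / sig[rc]
            ratio = np.exp(stats.norm.logpdf(zl) - special.log_ndtr(-zl))
            dmu[rc] = ratio / sig[rc]
            dls[rc] = zl * ratio
        if lc.any():
            zu = (upper[lc] - mu[lc]) / sig[lc]
            ratio = np.exp(stats.norm.logpdf(zu) - special.log_ndtr(zu))
            dmu[lc] = -ratio / sig[lc]
            dls[lc] = -zu * ratio
        scores = np.empty((n, p + ng))
        scores[:, :p] = Xm * dmu[:, None]
        scores[:, p:] = 0.0
        scores[np.arange(n), p + gidx] = dls
        return scores

    def grad(theta):
        return -score_matrix(theta).sum(axis=0)

    if start is None:
        beta0, *_ = np.linalg.lstsq(Xm, mid, rcond=None)
        resid = mid - Xm @ beta0
        s0 = max(float(np.std(resid, ddof=min(p, n - 1))), 1e-3)
        start = np.concatenate([beta0, np.full(ng, math.log(s0))])
    res = _minimize(nll, grad, np.asarray(start, dtype=float), "interval regression")
    theta = res.x
    info = _observed_info(grad, theta)
    cov = np.linalg.inv(info)
    all_names = names + tuple(
        "lnsigma" if ng == 1 else f"lnsigma_g{g}" for g in glevels
    )
    return FitResult(
        family="interval",
        names=all_names,
        params=theta,
        cov=cov,
        llf=-res.fun,
        n=n,
        converged=True,
        grad_norm=float(np.max(np.abs(res.jac))),
        scores=score_matrix(theta),
        cov_internal=cov,
        jac=np.eye(p + ng),
        sigma=np.exp(theta[p:]),
    )


# ---------------------------------------------------------------------------
# logistic regression


def fit_logit(y, X, tol: float = 1e-10, maxiter: int = 100) -> FitResult:
    """Binary-outcome MLE by Newton-Raphson with observed-information covariance."""
    y = np.asarray(y, dtype=float)
    Xm, names = _as_matrix(X)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("logit outcome must be 0/1")
    n, p = Xm.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = Xm @ beta
        prob = special.expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        g = Xm.T @ (y - prob)
        w = prob * (1.0 - prob)
        H = Xm.T @ (Xm * w[:, None]) + 1e-12 * np.eye(p)
        step = np.linalg.solve(H, g)
        # step halving to guarantee ascent
        lam = 1.0
        while lam > 1e-8:
            cand = beta + lam * step
            eta_c = Xm @ cand
            ll_c = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
            if ll_c >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        if np.max(np.abs(g)) < tol and abs(ll - ll_old) < 1e-12 * (1 + abs(ll)):
            break
        ll_old = ll
    eta = Xm @ beta
    prob = special.expit(eta)
    g = Xm.T @ (y - prob)
    if np.max(np.abs(beta)) > 30.0:
        raise SeparationError(
            "quasi-complete separation suspected: a coefficient diverged during fitting"
        )
    if np.max(np.abs(g)) > 1e-5:
        raise ConvergenceError(f"logit did not converge: max |gradient| = {np.max(np.abs(g)):.3g}")
    w = prob * (1.0 - prob)
    info = Xm.T @ (Xm * w[:, None])
    cov = np.linalg.inv(info)
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return FitResult(
        family="logit",
        names=names,
        params=beta,
        cov=cov,
        llf=llf,
        n=n,
        converged=True,
        grad_norm=float(np.max(np.abs(g))),
        scores=Xm * (y - prob)[:, None],
        cov_internal=cov,
        jac=np.eye(p),
    )


# ---------------------------------------------------------------------------
# ordered (proportional-odds) logistic regression


def _ologit_prepare(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("ordinal outcome needs at least 2 observed levels")
    codes = np.searchsorted(levels, y)
    return codes, levels


def fit_ologit(y, X, tol: float = 1e-8) -> FitResult:
    """Proportional-odds MLE: P(y <= j | x) = logistic(kappa_j - x b).

    ``X`` must not contain an intercept (the thresholds absorb it).  The
    thresholds are optimized as (kappa_1, log successive differences), which
    keeps them strictly ordered; reported thresholds and their covariance are
    mapped back to the original scale with the delta method.
    """
    codes, levels = _ologit_prepare(y)
    Xm, names = _as_matrix(X)
    n, p = Xm.shape
    if np.any(np.ptp(Xm, axis=0) == 0):
        raise ValueError("ordered logit design must not contain a constant column")
    J = len(levels)
    ncut = J - 1

    def cutpoints(theta):
        a = theta[p]
        if ncut == 1:
            return np.array([a])
        return a + np.concatenate([[0.0], np.cumsum(np.exp(theta[p + 1:]))])

    def nll(theta):
        kap = cutpoints(theta)
        eta = Xm @ theta[:p]
        zu = np.where(codes < ncut, kap[np.minimum(codes, ncut - 1)] - eta, np.inf)
        zl = np.where(codes > 0, kap[np.maximum(codes - 1, 0)] - eta, -np.inf)
        # P = expit(zu) - expit(zl), stable via log-diff
        with np.errstate(over="ignore"):
            pu = special.expit(zu)
            pl = special.expit(zl)
        prob = np.clip(pu - pl, 1e-300, 1.0)
        return -float(np.sum(np.log(prob)))

    def kappa_scores(theta):
        """Scores w.r.t. (beta, kappa_1..kappa_{J-1}) per observation."""
        kap = cutpoints(theta)
        eta = Xm @ theta[:p]
        zu = np.where(codes < ncut, kap[np.minimum(codes, ncut - 1)] - eta, np.inf)
        zl = np.where(codes > 0, kap[np.maximum(codes - 1, 0)] - eta, -np.inf)
        pu = special.expit(zu)
        pl = special.expit(zl)
        prob = np.clip(pu - pl, 1e-300, 1.0)
        fu = np.where(np.isfinite(zu), pu * (1.0 - pu), 0.0)
        fl = np.where(np.isfinite(zl), pl * (1.0 - pl), 0.0)
        s = np.zeros((n, p + ncut))
        s[:, :p] = Xm * (-(fu - fl) / prob)[:, None]
        rows = np.arange(n)
        upper_idx = np.minimum(codes, ncut - 1)
        mask_u = codes < ncut
        s[rows[mask_u], p + upper_idx[mask_u]] += (fu / prob)[mask_u]
        lower_idx = np.maximum(codes - 1, 0)
        mask_l = codes > 0
        s[rows[mask_l], p + lower_idx[mask_l]] -= (fl / prob)[mask_l]
        return s

    def theta_jacobian(theta):
        """d(beta, kappa) / d(beta, a1, delta): maps internal to kappa scale."""
        T = np.eye(p + ncut)
        for j in range(1, ncut):
            for m in range(j, ncut):
                T[p + m, p + j] = math.exp(theta[p + j])
        T[p:, p] = 1.0
        return T

    def grad(theta):
        return -(kappa_scores(theta) @ theta_jacobian(theta)).sum(axis=0)

    # start: zero slopes, cutpoints at empirical cumulative logits
    cum = np.cumsum(np.bincount(codes, minlength=J))[:-1] / n
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    kap0 = special.logit(cum)
    start = np.zeros(p + ncut)
    start[p] = kap0[0]
    if ncut > 1:
        start[p + 1:] = np.log(np.maximum(np.diff(kap0), 1e-3))
    res = _minimize(nll, grad, start, "ordered logit")
    theta = res.x
    info = _observed_info(grad, theta)
    cov_int = np.linalg.inv(info)
    kap = cutpoints(theta)
    Jt = theta_jacobian(theta)  # reported scale = (beta, kappa)
    params = np.concatenate([theta[:p], kap])
    cov = Jt @ cov_int @ Jt.T
    all_names = names + tuple(f"cut_{j + 1}" for j in range(ncut))
    return FitResult(
        family="ologit",
        names=all_names,
        params=params,
        cov=cov,
        llf=-res.fun,
        n=n,
        converged=True,
        grad_norm=float(np.max(np.abs(res.jac))),
        scores=kappa_scores(theta) @ Jt,  # internal-scale scores
        cov_internal=cov_int,
        jac=Jt,
        thresholds=kap,
        extra={"levels": levels},
    )


def ologit_probs(fit: FitResult, X) -> np.ndarray:
    """Category probabilities at each design row of a proportional-odds fit."""
    Xm, _ = _as_matrix(X)
    p = Xm.shape[1]
    kap = fit.thresholds
    eta = Xm @ fit.params[:p]
    cum = special.expit(kap[None, :] - eta[:, None])
    cum = np.column_stack([np.zeros(len(eta)), cum, np.ones(len(eta))])
    return np.diff(cum, axis=1)


def prop_odds_test(y, X, min_per_split: int = 5) -> dict:
    """Wald check of the proportional-odds assumption on cumulative splits.

    Each of the J-1 cumulative splits of the outcome is fitted as a separate
    binary logit; under proportional odds their slope vectors coincide, so
    the test contrasts all adjacent slope differences with the joint
    covariance of the split estimates (which accounts for the splits sharing
    observations) and refers the quadratic form to chi-square with (J-2)*p
    degrees of freedom.  The split fits are working models, not the joint
    ordinal likelihood, so the test is approximate; that caveat travels in
    the output.
    """
    codes, levels = _ologit_prepare(y)
    Xm, _ = _as_matrix(X)
    n, p = Xm.shape
    J = len(levels)
    df = (J - 2) * p
    if J == 2:
        return {"stat": None, "df": 0, "p": None,
                "note": "only two outcome levels: proportional odds is vacuous"}
    K = J - 1
    splits = []
    for j in range(K):
        yj = (codes > j).astype(float)
        nj = min(yj.sum(), (1 - yj).sum())
        if nj < min_per_split:
            return {"stat": None, "df": df, "p": None,
                    "note": f"cumulative split {j + 1} too sparse ({int(nj)} cases); test skipped"}
        splits.append(yj)

    Xt = np.column_stack([np.ones(n), Xm])  # intercept-augmented design
    q = p + 1
    try:
        fits = [fit_logit(yj, Xt) for yj in splits]
    except (SeparationError, ConvergenceError) as err:
        return {"stat": None, "df": df, "p": None,
                "note": f"a cumulative split is quasi-separated ({err}); test skipped"}
    probs = [special.expit(Xt @ f.params) for f in fits]
    breads = [np.linalg.inv(Xt.T @ (Xt * (pi * (1 - pi))[:, None])) for pi in probs]

    # joint covariance of the split estimates: splits j <= l share observations,
    # with cross-weight pi_l - pi_j * pi_l (split l nested in split j)
    V = np.zeros((K * q, K * q))
    for j in range(K):
        for l in range(j, K):
            w = probs[l] - probs[j] * probs[l] if l != j else probs[j] * (1 - probs[j])
            block = breads[j] @ (Xt.T @ (Xt * w[:, None])) @ breads[l]
            V[j * q:(j + 1) * q, l * q:(l + 1) * q] = block
            if l != j:
                V[l * q:(l + 1) * q, j * q:(j + 1) * q] = block.T
    slope_idx = np.concatenate([np.arange(1, q) + j * q for j in range(K)])
    beta = np.concatenate([f.params[1:] for f in fits])
    Vs = V[np.ix_(slope_idx, slope_idx)]
    D = np.zeros(((K - 1) * p, K * p))
    for j in range(K - 1):
        D[j * p:(j + 1) * p, :p] = np.eye(p)
        D[j * p:(j + 1) * p, (j + 1) * p:(j + 2) * p] = -np.eye(p)
    delta = D @ beta
    try:
        stat = float(delta @ np.linalg.solve(D @ Vs @ D.T, delta))
    except np.linalg.LinAlgError:
        return {"stat": None, "df": df, "p": None,
                "note": "singular contrast covariance; test skipped"}
    return {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df)),
            "note": "Wald test on separate cumulative-split logits (approximate)"}


# ---------------------------------------------------------------------------
# cluster-robust covariance


def cluster_vcov(fit: FitResult, clusters) -> np.ndarray:
    """Cluster-robust sandwich covariance on the fit's reporting scale.

    Scores are summed within clusters, the meat is their outer-product sum
    with a G/(G-1) small-sample factor, and the bread is the model-based
    covariance.  With every observation its own cluster this reduces to the
    heteroskedasticity-robust sandwich times n/(n-1).
    """
    clusters = np.asarray(clusters)
    if fit.scores is None:
        raise ValueError("fit carries no per-observation scores")
    if len(clusters) != fit.scores.shape[0]:
        raise ValueError("cluster vector length does not match the fit")
    _, idx = np.unique(clusters, return_inverse=True)
    G = idx.max() + 1
    if G < 2:
        raise ValueError("cluster-robust covariance needs at least two clusters")
    sg = np.zeros((G, fit.scores.shape[1]))
    np.add.at(sg, idx, fit.scores)
    meat = sg.T @ sg * (G / (G - 1.0))
    v_int = fit.cov_internal @ meat @ fit.cov_internal
    return fit.jac @ v_int @ fit.jac.T


# ---------------------------------------------------------------------------
# GxE design and inference


@dataclass(frozen=True)
class GxeSpec:
    """What to fit: outcome, predictor, moderator, covariates, family."""

    outcome: str | tuple[str, str]
    family: str  # interval | logit | ologit
    predictor: str = "pgs"
    moderator: str = "disadvantage"
    covariates: tuple[str, ...] = ()
    cluster: str | None = None
    shared_sigma: bool = False  # interval family: share residual SD across groups
    name: str = ""


def build_gxe_design(data: pd.DataFrame, spec: GxeSpec) -> pd.DataFrame:
    """Fully interacted design: every term plus its product with the moderator.

    Column order is deterministic: const, moderator, predictor,
    predictor x moderator, then each covariate followed by its moderator
    interaction.
    """
    mod = data[spec.moderator].to_numpy(dtype=float)
    if np.ptp(mod) == 0:
        raise ValueError(f"moderator {spec.moderator!r} is constant; no interaction identifiable")
    cols: dict[str, np.ndarray] = {
        "const": np.ones(len(data)),
        spec.moderator: mod,
        spec.predictor: data[spec.predictor].to_numpy(dtype=float),
        f"{spec.predictor}:{spec.moderator}": data[spec.predictor].to_numpy(dtype=float) * mod,
    }
    for c in spec.covariates:
        v = data[c].to_numpy(dtype=float)
        cols[c] = v
        cols[f"{c}:{spec.moderator}"] = v * mod
    X = pd.DataFrame(cols, index=data.index)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in design columns {bad}")
    return X


@dataclass(frozen=True)
class GxeResult:
    """A fitted GxE model plus the design context needed for contrasts/profiles."""

    fit: FitResult
    spec: GxeSpec
    design_means: pd.Series
    predictor_sd: float

    def implied_effect(self) -> ContrastResult:
        return implied_effect(
            self.fit, self.spec.predictor, f"{self.spec.predictor}:{self.spec.moderator}"
        )

    def main_effect(self) -> ContrastResult:
        i = self.fit.names.index(self.spec.predictor)
        return _wald(float(self.fit.params[i]), float(self.fit.se[i]),
                     self.fit.family in ("logit", "ologit"))

    def interaction_effect(self) -> ContrastResult:
        name = f"{self.spec.predictor}:{self.spec.moderator}"
        i = self.fit.names.index(name)
        return _wald(float(self.fit.params[i]), float(self.fit.se[i]),
                     self.fit.family in ("logit", "ologit"))


def fit_gxe(data: pd.DataFrame, spec: GxeSpec, **fit_kwargs) -> GxeResult:
    """Build the fully interacted design and fit the requested likelihood.

    For the interval family the residual SD is group-specific by default
    (``spec.shared_sigma=False``), which makes the single interacted fit
    identical to two separate group-wise fits.  If a cluster column is named,
    the covariance is replaced by the cluster-robust sandwich.
    """
    X = build_gxe_design(data, spec)
    if spec.family == "interval":
        lo = data[spec.outcome[0]].to_numpy(dtype=float)
        up = data[spec.outcome[1]].to_numpy(dtype=float)
        groups = None if spec.shared_sigma else data[spec.moderator].to_numpy(dtype=int)
        fit = fit_interval(lo, up, X, sigma_groups=groups, **fit_kwargs)
    elif spec.family == "logit":
        fit = fit_logit(data[spec.outcome].to_numpy(dtype=float), X, **fit_kwargs)
    elif spec.family == "ologit":
        fit = fit_ologit(data[spec.outcome].to_numpy(), X.drop(columns="const"), **fit_kwargs)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    if spec.cluster is not None:
        fit = fit.with_cov(cluster_vcov(fit, data[spec.cluster].to_numpy()))
    means = X.drop(columns="const", errors="ignore").mean()
    return GxeResult(
        fit=fit,
        spec=spec,
        design_means=means,
        predictor_sd=float(data[spec.predictor].std(ddof=1)),
    )


def implied_effect(fit: FitResult, main_term: str, interaction_term: str) -> ContrastResult:
    """Predictor effect in the moderated group: b_main + b_interaction.

    Variance by the delta method: V_mm + V_ii + 2 V_mi.  Reported with an
    odds-ratio transform when the family is logistic.
    """
    for t in (main_term, interaction_term):
        if t not in fit.names:
            raise KeyError(f"term {t!r} not in fit ({fit.names})")
    i = fit.names.index(main_term)
    j = fit.names.index(interaction_term)
    est = float(fit.params[i] + fit.params[j])
    var = float(fit.cov[i, i] + fit.cov[j, j] + 2.0 * fit.cov[i, j])
    return _wald(est, math.sqrt(var), fit.family in ("logit", "ologit"))


def predict_profile(
    result: GxeResult,
    pgs_grid: np.ndarray | None = None,
    category: int | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Model-scale predictions over a predictor grid for both moderator groups.

    Covariates sit at estimation-sample means.  For the interval family the
    profile is the latent mean; for logit the event probability; for the
    ordered family the probability of ``category`` (default: the top level).
    Confidence bands use the delta method on the linear predictor.
    """
    spec, fit = result.spec, result.fit
    if pgs_grid is None:
        pgs_grid = np.linspace(-2.0, 2.0, 9) * result.predictor_sd
    pgs_grid = np.asarray(pgs_grid, dtype=float)
    zc = stats.norm.ppf(0.5 + conf / 2.0)
    has_const = spec.family != "ologit"
    names = list(fit.names)
    rows = []
    for g in (0, 1):
        for v in pgs_grid:
            x = np.zeros(len(fit.params))
            for k, name in enumerate(names):
                if name == "const":
                    x[k] = 1.0
                elif name == spec.moderator:
                    x[k] = g
                elif name == spec.predictor:
                    x[k] = v
                elif name == f"{spec.predictor}:{spec.moderator}":
                    x[k] = v * g
                elif name in result.design_means.index:
                    x[k] = result.design_means[name]
                elif name.endswith(f":{spec.moderator}") and name in result.design_means.index:
                    x[k] = result.design_means[name]
                # lnsigma / cut terms stay 0 in the linear contrast
            for c in spec.covariates:
                k = names.index(f"{c}:{spec.moderator}")
                x[k] = result.design_means[c] * g
            rows.append((g, v, x))

    out = []
    for g, v, x in rows:
        if spec.family == "ologit":
            # linear predictor eta = x b (x has no const, cut entries zero)
            eta = float(x @ fit.params)
            var_eta_part = x @ fit.cov @ x
            kap = fit.thresholds
            J = len(kap) + 1
            cat = (J - 1) if category is None else int(category)
            # P(y = top) = 1 - expit(kap_last - eta); P(y = j) = F(k_j - eta) - F(k_{j-1} - eta)
            grad = np.zeros(len(fit.params))
            pcut = len(fit.params) - len(kap)
            cum_hi = 1.0 if cat == J - 1 else special.expit(kap[cat] - eta)
            cum_lo = 0.0 if cat == 0 else special.expit(kap[cat - 1] - eta)
            prob = cum_hi - cum_lo
            d_hi = cum_hi * (1 - cum_hi) if cat < J - 1 else 0.0
            d_lo = cum_lo * (1 - cum_lo) if cat > 0 else 0.0
            grad[:pcut] = -(d_hi - d_lo) * x[:pcut]
            if cat < J - 1:
                grad[pcut + cat] += d_hi
            if cat > 0:
                grad[pcut + cat - 1] -= d_lo
            se = math.sqrt(max(float(grad @ fit.cov @ grad), 0.0))
            out.append((g, v, prob, se, prob - zc * se, prob + zc * se))
        else:
            eta = float(x @ fit.params)
            se_eta = math.sqrt(max(float(x @ fit.cov @ x), 0.0))
            if spec.family == "logit":
                prob = special.expit(eta)
                se = prob * (1 - prob) * se_eta
                lo = special.expit(eta - zc * se_eta)
                hi = special.expit(eta + zc * se_eta)
                out.append((g, v, prob, se, lo, hi))
            else:
                out.append((g, v, eta, se_eta, eta - zc * se_eta, eta + zc * se_eta))
    return pd.DataFrame(
        out, columns=["group", "pgs", "prediction", "se", "ci_low", "ci_high"]
    )
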