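"""Multilevel proportional-odds model for binned weight-of-advice scores.

Cumulative-logit model with a participant random intercept:

    P(Y_ij <= k | u_j) = logistic(kappa_k - x_ij' beta - u_j),
    u_j ~ N(0, sigma_u^2),

with strictly increasing thresholds ``kappa_1 < ... < kappa_{K-1}``.  The
marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature: for each cluster the integrand's mode and
curvature are located by damped Newton steps (the integrand is strictly
log-concave), the quadrature grid is centred and scaled there, and the
cluster log-likelihood is accumulated with a log-sum-exp.  Thresholds are
parameterised as a first cutpoint plus log-increments, which enforces
monotonicity; ``sigma_u`` is optimised on the log scale with a wide lower
bound so the zero-variance boundary is reachable and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special

from .spec import ModelSpec, build_design

_LOG_SIGMA_BOUNDS = (-7.0, 3.0)


@dataclass
class OrdinalFit:
    """Fitted multilevel proportional-odds model."""

    thresholds: np.ndarray
    beta: pd.Series
    se: pd.Series
    sigma_u2: float
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    n_groups: int
    n_nodes: int
    categories: list[int]
    merged_categories: bool
    term_map: dict[str, list[str]] = field(default_factory=dict)
    loglik_at_nodes: Callable[[int], float] | None = None

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "sigma_u2": self.sigma_u2,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "categories": self.categories,
            "merged_categories": self.merged_categories,
        }


def _logistic_cdf(x):
    return special.expit(x)


def _logistic_pdf(x):
    p = special.expit(x)
    return p * (1.0 - p)


def _cluster_loglik(theta, K, Xb_parts, n_nodes):
    """Marginal log-likelihood given packed parameters.

    theta = [kappa_1, log diff_2..K-1, beta, log sigma_u].
    """
    y, X, codes, n_groups = Xb_parts
    n_cut = K - 1
    kappa = np.empty(n_cut)
    kappa[0] = theta[0]
    if n_cut > 1:
        kappa[1:] = theta[0] + np.cumsum(np.exp(theta[1:n_cut]))
    p = X.shape[1]
    beta = theta[n_cut:n_cut + p]
    sigma = math.exp(theta[-1])

    eta = X @ beta if p else np.zeros(len(y))
    # upper and lower threshold per observation (+-inf at the extremes)
    upper = np.where(y < K, kappa[np.minimum(y, K - 1) - 1], np.inf)
    lower = np.where(y > 1, kappa[np.maximum(y - 2, 0)], -np.inf)

    def h_terms(u_per_obs):
        b = upper - eta - u_per_obs
        a = lower - eta - u_per_obs
        Fb, Fa = _logistic_cdf(b), _logistic_cdf(a)
        prob = np.clip(Fb - Fa, 1e-300, None)
        fb = np.where(np.isfinite(b), _logistic_pdf(b), 0.0)
        fa = np.where(np.isfinite(a), _logistic_pdf(a), 0.0)
        d1 = (fa - fb) / prob
        fpb = np.where(np.isfinite(b), fb * (1.0 - 2.0 * Fb), 0.0)
        fpa = np.where(np.isfinite(a), fa * (1.0 - 2.0 * Fa), 0.0)
        d2 = (fpb - fpa) / prob - d1**2
        return np.log(prob), d1, d2

    def sum_by_cluster(v):
        out = np.zeros(n_groups)
        np.add.at(out, codes, v)
        return out

    if sigma < 1e-6:
        logp, _, _ = h_terms(np.zeros(len(y)))
        return float(np.sum(logp))

    # damped Newton for the mode of h(u) = sum log p + log phi(u; sigma)
    u = np.zeros(n_groups)
    for _ in range(25):
        logp, d1, d2 = h_terms(u[codes])
        g = sum_by_cluster(d1) - u / sigma**2
        hess = sum_by_cluster(d2) - 1.0 / sigma**2
        step = g / hess
        new_u = u - np.clip(step, -3 * sigma - 1, 3 * sigma + 1)
        if np.max(np.abs(new_u - u)) < 1e-10:
            u = new_u
            break
        u = new_u
    logp, d1, d2 = h_terms(u[codes])
    hess = sum_by_cluster(d2) - 1.0 / sigma**2
    tau = 1.0 / np.sqrt(-hess)

    x_m, w_m = np.polynomial.hermite.hermgauss(n_nodes)
    # adaptive nodes u_jm = u_j + sqrt(2) tau_j x_m
    U = u[:, None] + math.sqrt(2.0) * tau[:, None] * x_m[None, :]
    # log integrand at the nodes: sum_i log p_i(u) + log phi(u; sigma)
    H = np.zeros((n_groups, n_nodes))
    for m in range(n_nodes):
        logp_m, _, _ = h_terms(U[:, m][codes])
        H[:, m] = sum_by_cluster(logp_m)
    H += -0.5 * (U / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
    log_w = np.log(w_m) + x_m**2
    ll = special.logsumexp(H + log_w[None, :], axis=1)
    ll += 0.5 * math.log(2.0) + np.log(tau)
    return float(np.sum(ll))


def fit_multilevel_ordinal(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_nodes: int = 15,
    fix_sigma_u: float | None = None,
) -> OrdinalFit:
    """Fit the proportional-odds random-intercept model to binned WOA.

    ``spec.response`` must hold the ordinal category (1-5).  Categories
    absent from the data are merged away with a warning (their thresholds
    cannot be identified).  ``fix_sigma_u`` pins the random-intercept sd
    (``0`` collapses to an ordinary proportional-odds model).
    """
    spec = spec or ModelSpec(response="bin")
    df = data
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    df = df[df[spec.response].notna()]
    if df[spec.grouping].nunique() < 2:
        raise ValueError("need at least two participants")

    cats = sorted(int(c) for c in df[spec.response].unique())
    merged = len(cats) < 5
    if merged:
        warnings.warn(
            f"only categories {cats} observed; absent categories merged "
            "(their thresholds are not identifiable)",
            stacklevel=2,
        )
    remap = {c: k + 1 for k, c in enumerate(cats)}
    y = df[spec.response].map(remap).to_numpy(int)
    K = len(cats)
    if K < 2:
        raise ValueError("response has a single category; nothing to fit")

    if spec.fixed_effects:
        X, names, term_map = build_design(df, spec)
        X, names = X[:, 1:], names[1:]  # thresholds absorb the intercept
    else:
        X, names, term_map = np.empty((len(df), 0)), [], {}
    codes, _ = pd.factorize(df[spec.grouping])
    n_groups = int(codes.max()) + 1
    parts = (y, X, codes, n_groups)
    p = X.shape[1]

    # starting values: equiprobable thresholds, zero effects, sigma = 0.5
    cum = np.cumsum(np.bincount(y, minlength=K + 1)[1:K] / len(y))
    kappa0 = special.logit(np.clip(cum, 0.01, 0.99))
    theta0 = np.concatenate((
        [kappa0[0]],
        np.log(np.clip(np.diff(kappa0), 1e-3, None)),
        np.zeros(p),
        [math.log(0.5)],
    ))

    # sigma below exp(-30) collapses to the fixed-effects likelihood
    fixed_log_sigma = None if fix_sigma_u is None else (
        -30.0 if fix_sigma_u == 0 else math.log(fix_sigma_u)
    )
    if fixed_log_sigma is not None:
        theta0[-1] = fixed_log_sigma

    def nll(theta_free):
        theta = theta_free
        if fixed_log_sigma is not None:
            theta = np.concatenate((theta_free, [fixed_log_sigma]))
        return -_cluster_loglik(theta, K, parts, n_nodes)

    free0 = theta0[:-1] if fixed_log_sigma is not None else theta0
    bounds = [(None, None)] * (K - 1 + p)
    if fixed_log_sigma is None:
        bounds.append(_LOG_SIGMA_BOUNDS)
    res = optimize.minimize(
        nll, free0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta_free = res.x
    theta = (np.concatenate((theta_free, [fixed_log_sigma]))
             if fixed_log_sigma is not None else theta_free)

    n_cut = K - 1
    kappa = np.empty(n_cut)
    kappa[0] = theta[0]
    if n_cut > 1:
        kappa[1:] = theta[0] + np.cumsum(np.exp(theta[1:n_cut]))
    beta = theta[n_cut:n_cut + p]
    sigma = 0.0 if fix_sigma_u == 0 else math.exp(theta[-1])
    boundary = fix_sigma_u is None and theta[-1] <= _LOG_SIGMA_BOUNDS[0] + 1e-6
    if boundary:
        sigma = 0.0

    # observed-information standard errors for beta (central differences on
    # the free parameters)
    se = np.full(p, np.nan)
    if p and res.success:
        try:
            hess = _numerical_hessian(nll, theta_free)
            cov = np.linalg.inv(hess)
            se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
            se = se_all[n_cut:n_cut + p]
        except np.linalg.LinAlgError:
            pass

    def loglik_at_nodes(m: int) -> float:
        return _cluster_loglik(theta, K, parts, m)

    return OrdinalFit(
        thresholds=kappa,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma_u2=float(sigma**2),
        loglik=float(-res.fun),
        converged=bool(res.success),
        boundary=bool(boundary),
        n_obs=len(y),
        n_groups=n_groups,
        n_nodes=n_nodes,
        categories=cats,
        merged_categories=merged,
        term_map=term_map,
        loglik_at_nodes=loglik_at_nodes,
    )


def _numerical_hessian(f, x, eps=1e-4):
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for a in range(d):
        for b in range(a, d):
            ea, eb = np.zeros(d), np.zeros(d)
            ea[a], eb[b] = eps, eps
            H[a, b] = H[b, a] = (
                f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)
            ) / (4 * eps**2)
    return H
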