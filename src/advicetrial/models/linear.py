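"""Random-intercept linear mixed model, fitted by profiled REML.

Model: ``y = X beta + u_j + e`` with one random intercept per participant,
``u_j ~ N(0, sigma_u^2)`` and ``e ~ N(0, sigma_e^2)``.  Writing
``psi = sigma_u^2 / sigma_e^2``, both ``beta`` (by GLS) and ``sigma_e^2``
have closed forms given ``psi``, so the restricted likelihood is profiled
down to a one-dimensional function of ``psi`` and maximised by a bounded
scalar search.  This makes the fit deterministic, fast and easy to verify
against closed-form balanced-design estimators and brute-force
multivariate-normal likelihood evaluation.

The per-cluster inverse uses the rank-one Woodbury identity
``V_j^{-1} = (I - lambda_j 11') / sigma_e^2`` with
``lambda_j = psi / (1 + psi n_j)``, so all computations reduce to group
sums and no matrix larger than p x p is ever formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spec import ModelSpec, build_design

_PSI_LOG_BOUNDS = (-30.0, 8.0)


@dataclass
class RandomInterceptFit:
    """Fitted random-intercept model."""

    beta: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    sigma_u2: float
    sigma_e2: float
    loglik: float          # REML (or ML) log-likelihood at the optimum
    method: str
    converged: bool
    boundary: bool         # sigma_u^2 estimated at the zero boundary
    n_obs: int
    n_groups: int
    wald: pd.DataFrame     # per-coefficient z, p, 95% CI
    term_map: dict[str, list[str]] = field(default_factory=dict)
    criterion_trace: list[float] = field(default_factory=list)
    _loglik_parts: dict | None = None

    def ci95(self) -> pd.DataFrame:
        return self.wald[["ci_low", "ci_high"]]

    def loglik_at(self, beta: np.ndarray, sigma_u2: float, sigma_e2: float) -> float:
        """Full (ML) Gaussian log-likelihood at arbitrary parameter values.

        Used to verify the Woodbury-based evaluation against a brute-force
        per-cluster multivariate-normal density.
        """
        p = self._loglik_parts
        return _ml_loglik(p["y"], p["X"], p["codes"], p["sizes"],
                          np.asarray(beta, float), sigma_u2, sigma_e2)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "method": self.method,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "wald": self.wald.reset_index().to_dict(orient="records"),
        }


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
    sx = np.zeros((n_groups, X.shape[1]))
    sy = np.zeros(n_groups)
    np.add.at(sx, codes, X)
    np.add.at(sy, codes, y)
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    return sx, sy, sizes


def _profile(psi: float, X, y, XtX, Xty, yty, sx, sy, sizes):
    """GLS beta, residual quadratic form and log-determinants for given psi."""
    lam = psi / (1.0 + psi * sizes)
    Sxx = XtX - (sx * lam[:, None]).T @ sx
    Sxy = Xty - sx.T @ (lam * sy)
    beta = np.linalg.solve(Sxx, Sxy)
    resid = y - X @ beta
    sr = sy - sx @ beta
    quad = float(resid @ resid - lam @ (sr**2))
    sign, logdet_sxx = np.linalg.slogdet(Sxx)
    logdet_v = float(np.sum(np.log1p(psi * sizes)))
    return beta, Sxx, quad, logdet_sxx, logdet_v


def _ml_loglik(y, X, codes, sizes, beta, sigma_u2, sigma_e2) -> float:
    psi = sigma_u2 / sigma_e2
    lam = psi / (1.0 + psi * sizes)
    resid = y - X @ beta
    sr = np.zeros(sizes.size)
    np.add.at(sr, codes, resid)
    quad = float(resid @ resid - lam @ (sr**2)) / sigma_e2
    n = y.size
    logdet = n * math.log(sigma_e2) + float(np.sum(np.log1p(psi * sizes)))
    return -0.5 * (n * math.log(2 * math.pi) + logdet + quad)


def fit_random_intercept(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    method: str = "reml",
) -> RandomInterceptFit:
    """Fit the random-intercept model to scored weight-of-advice records.

    Rows with an undefined response are dropped.  ``method`` is ``"reml"``
    (default, conventional for variance components) or ``"ml"`` (for
    likelihood-ratio comparisons).  Raises on rank-deficient designs and
    flags (never silences) non-convergence.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    spec = spec or ModelSpec()
    df = data
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    df = df[df[spec.response].notna()]
    if df[spec.grouping].nunique() < 2:
        raise ValueError("need at least two participants")

    X, names, term_map = build_design(df, spec)
    y = df[spec.response].to_numpy(float)
    codes, _ = pd.factorize(df[spec.grouping])
    n, p = X.shape
    n_groups = int(codes.max()) + 1

    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    sx, sy, sizes = _group_stats(X, y, codes, n_groups)
    dof = n - p if method == "reml" else n

    trace: list[float] = []

    def criterion(psi: float) -> float:
        _, _, quad, logdet_sxx, logdet_v = _profile(
            psi, X, y, XtX, Xty, yty, sx, sy, sizes
        )
        val = dof * math.log(quad / dof) + logdet_v
        if method == "reml":
            val += logdet_sxx
        trace.append(-0.5 * val)
        return val

    res = optimize.minimize_scalar(
        lambda t: criterion(math.exp(t)),
        bounds=_PSI_LOG_BOUNDS,
        method="bounded",
        options={"xatol": 1e-12},
    )
    psi_hat = math.exp(res.x)
    best = criterion(psi_hat)
    # the zero boundary is always a candidate
    at_zero = criterion(0.0)
    boundary = at_zero <= best + 1e-10 or psi_hat < 1e-8
    if boundary:
        psi_hat, best = 0.0, at_zero

    # convergence: interior optimum must have ~zero derivative
    converged = bool(res.success)
    if not boundary:
        h = max(psi_hat * 1e-6, 1e-12)
        grad = (criterion(psi_hat + h) - criterion(max(psi_hat - h, 0.0))) / (2 * h)
        # criterion is -2*loglik up to constants; scale-free check
        converged = converged and abs(grad) * max(psi_hat, 1.0) < 1e-4

    beta, Sxx, quad, logdet_sxx, logdet_v = _profile(
        psi_hat, X, y, XtX, Xty, yty, sx, sy, sizes
    )
    sigma_e2 = quad / dof
    sigma_u2 = psi_hat * sigma_e2
    cov = sigma_e2 * np.linalg.inv(Sxx)
    se = np.sqrt(np.diag(cov))

    if method == "reml":
        loglik = -0.5 * (
            dof * (math.log(2 * math.pi) + math.log(sigma_e2) + 1.0)
            + logdet_v + logdet_sxx
        )
    else:
        loglik = _ml_loglik(y, X, codes, sizes, beta, sigma_u2, sigma_e2)

    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    wald = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "z": z,
            "p": pvals,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
        },
        index=names,
    )

    return RandomInterceptFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        loglik=float(loglik),
        method=method,
        converged=converged,
        boundary=boundary,
        n_obs=n,
        n_groups=n_groups,
        wald=wald,
        term_map=term_map,
        criterion_trace=trace,
        _loglik_parts={"y": y, "X": X, "codes": codes, "sizes": sizes},
    )


def wald_test(fit: RandomInterceptFit, terms: list[str]) -> tuple[float, int, float]:
    """Joint Wald chi-square test that the named coefficients are all zero.

    ``terms`` may be coefficient names or model terms (e.g. ``"arm:strength"``,
    which expands to all its contrast columns).
    """
    if not terms:
        raise ValueError("empty term set")
    cols: list[str] = []
    for t in terms:
        if t in fit.term_map:
            cols.extend(fit.term_map[t])
        elif t in fit.beta.index:
            cols.append(t)
        else:
            raise ValueError(f"term {t!r} not in fit")
    b = fit.beta[cols].to_numpy()
    C = fit.cov.loc[cols, cols].to_numpy()
    stat = float(b @ np.linalg.solve(C, b))
    df = len(cols)
    return stat, df, float(stats.chi2.sf(stat, df))


def arm_difference(data: pd.DataFrame) -> tuple[float, tuple[float, float], float]:
    """Arm effect on WOA: clinician-arm minus algorithm-arm mean.

    Convenience wrapper fitting the arm-only random-intercept model and
    returning (estimate, 95% CI, p-value) for the clinician-arm contrast.
    """
    arms = data["arm"].unique()
    if len(arms) < 2:
        raise ValueError(f"need both arms, found {list(arms)}")
    fit = fit_random_intercept(data, ModelSpec(fixed_effects=["arm"]))
    name = "arm[CLINICIAN]"
    row = fit.wald.loc[name]
    return float(row["coef"]), (float(row["ci_low"]), float(row["ci_high"])), float(row["p"])
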