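"""Random-intercept GLMM fitting by adaptive Gauss-Hermite quadrature.

The model is a two-level generalized linear mixed model

    Y_ij | u_i ~ family(g^{-1}(x'_ij beta + u_i)),   u_i ~ N(0, sigma_u^2)

with subjects j nested in clusters i.  The marginal likelihood integrates
each cluster's conditional likelihood over its random intercept; the
integral is approximated with adaptive Gauss-Hermite quadrature: the
integrand is re-centered at its per-cluster mode and re-scaled by its
curvature there, so a modest number of nodes (default 15) is accurate even
for large clusters.  sigma_u is optimized on the log scale to enforce
positivity; standard errors come from the inverse observed information at
the optimum, with SE(sigma_u) back-transformed by the delta method.

Supported families: binomial-logit, poisson-log (optional offset), and
normal-identity (with a residual SD estimated alongside).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import linalg, optimize, special, stats

from .data import MultilevelDataset
from .measures import (
    BOUNDARY_SIGMA,
    EmpiricalRiskDistribution,
    NormalRandomEffect,
)

logger = logging.getLogger(__name__)

__all__ = ["FittedMixedModel", "fit_random_intercept", "SingularDesignError"]

_FAMILIES = ("binomial", "poisson", "normal")


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""


def _cond_loglik(y, eta, family, sigma_e=None):
    """Per-row conditional log-likelihood log f(y | eta)."""
    if family == "binomial":
        return y * eta - np.logaddexp(0.0, eta)
    if family == "poisson":
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)
    # normal-identity
    return -0.5 * np.log(2.0 * np.pi * sigma_e**2) - (y - eta) ** 2 / (2.0 * sigma_e**2)


def _cond_score_curv(y, eta, family, sigma_e=None):
    """(d/d eta) log f and -(d^2/d eta^2) log f, per row."""
    if family == "binomial":
        p = special.expit(eta)
        return y - p, p * (1.0 - p)
    if family == "poisson":
        mu = np.exp(eta)
        return y - mu, mu
    r = (y - eta) / sigma_e**2
    return r, np.full_like(eta, 1.0 / sigma_e**2)


class _MarginalLoglik:
    """Vectorized AGHQ marginal log-likelihood over all clusters."""

    def __init__(self, y, X, cluster_index, n_clusters, family, n_quad, offset=None):
        order = np.argsort(cluster_index, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.offset = offset[order] if offset is not None else None
        ci = cluster_index[order]
        self.starts = np.flatnonzero(np.r_[True, np.diff(ci) != 0])
        self.gidx = np.repeat(np.arange(n_clusters), np.diff(np.r_[self.starts, len(ci)]))
        self.n_clusters = n_clusters
        self.family = family
        z, w = hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)

    def _modes(self, eta0, sigma, sigma_e):
        """Per-cluster posterior modes of u and curvatures, by Newton."""
        m = np.zeros(self.n_clusters)
        inv_s2 = 1.0 / sigma**2
        for _ in range(100):
            eta = eta0 + m[self.gidx]
            score_row, curv_row = _cond_score_curv(self.y, eta, self.family, sigma_e)
            score = np.add.reduceat(score_row, self.starts) - m * inv_s2
            curv = np.add.reduceat(curv_row, self.starts) + inv_s2
            step = np.clip(score / curv, -4.0, 4.0)
            m += step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + m[self.gidx]
        _, curv_row = _cond_score_curv(self.y, eta, self.family, sigma_e)
        curv = np.add.reduceat(curv_row, self.starts) + inv_s2
        return m, curv

    def __call__(self, beta, sigma, sigma_e=None):
        eta0 = self.X @ beta
        if self.offset is not None:
            eta0 = eta0 + self.offset
        m, curv = self._modes(eta0, sigma, sigma_e)
        tau = 1.0 / np.sqrt(curv)
        # nodes u_ik = m_i + sqrt(2) tau_i z_k
        U = m[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]
        ll_rows = _cond_loglik(
            self.y[:, None], eta0[:, None] + U[self.gidx, :], self.family, sigma_e
        )
        ll_cond = np.add.reduceat(ll_rows, self.starts, axis=0)
        log_prior = stats.norm.logpdf(U, scale=sigma)
        inner = self.logw[None, :] + self.z[None, :] ** 2 + ll_cond + log_prior
        ll_i = 0.5 * np.log(2.0) + np.log(tau) + special.logsumexp(inner, axis=1)
        return float(np.sum(ll_i))


@dataclass
class FittedMixedModel:
    """Maximum marginal-likelihood fit of a random-intercept GLMM."""

    family: str
    beta: pd.Series
    sigma_u: float
    se_beta: pd.Series
    se_sigma_u: float
    vcov: pd.DataFrame
    loglik: float
    converged: bool
    boundary: bool
    n_quad: int
    message: str = ""
    sigma_e: float | None = None
    n_clusters: int = 0
    n_subjects: int = 0
    design: pd.DataFrame | None = field(default=None, repr=False)
    subject_cols: list[str] = field(default_factory=list)
    cluster_cols: list[str] = field(default_factory=list)

    @property
    def random_effect(self) -> NormalRandomEffect:
        return NormalRandomEffect(self.sigma_u)

    @property
    def linpred_parts(self) -> pd.DataFrame:
        """Per-subject linear-predictor contributions x'_s beta_s, x'_c beta_c."""
        if self.design is None:
            raise ValueError("fit retained no design matrix (measures-only model?)")
        parts = {}
        for name, cols in (("subject", self.subject_cols), ("cluster", self.cluster_cols)):
            if cols:
                parts[name] = self.design[cols].to_numpy() @ self.beta[cols].to_numpy()
            else:
                parts[name] = np.zeros(len(self.design))
        return pd.DataFrame(parts)

    def risk_distribution(self, subset, label: str | None = None) -> EmpiricalRiskDistribution:
        """Empirical distribution of {x'_S beta_S} for a covariate subset S.

        ``subset`` may be a list of covariate names, or one of the shorthands
        ``"subject"`` / ``"cluster"`` / ``"all"``.
        """
        if self.design is None:
            raise ValueError("fit retained no design matrix (measures-only model?)")
        if subset == "subject":
            cols, label = self.subject_cols, label or "subject factors"
        elif subset == "cluster":
            cols, label = self.cluster_cols, label or "cluster factors"
        elif subset == "all":
            cols = [*self.subject_cols, *self.cluster_cols]
            label = label or "all factors"
        else:
            cols = [subset] if isinstance(subset, str) else list(subset)
            label = label or "+".join(cols)
        if not cols:
            raise ValueError(f"covariate subset {subset!r} is empty")
        unknown = [c for c in cols if c not in self.design.columns]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}")
        vals = self.design[cols].to_numpy() @ self.beta[cols].to_numpy()
        return EmpiricalRiskDistribution(values=vals, label=label)

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, p, OR and 95% CI, sigma_u last."""
        z = self.beta / self.se_beta
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        zc = stats.norm.ppf(0.975)
        tab = pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se_beta,
                "p_value": pvals,
                "or": np.exp(self.beta),
                "or_low": np.exp(self.beta - zc * self.se_beta),
                "or_high": np.exp(self.beta + zc * self.se_beta),
            }
        )
        tab.loc["sigma_u"] = [self.sigma_u, self.se_sigma_u] + [np.nan] * 4
        return tab

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "beta": self.beta.to_dict(),
            "sigma_u": self.sigma_u,
            "se_beta": self.se_beta.to_dict(),
            "se_sigma_u": self.se_sigma_u,
            "sigma_e": self.sigma_e,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_quad": self.n_quad,
            "n_clusters": self.n_clusters,
            "n_subjects": self.n_subjects,
        }


def _check_design(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps if diag[0] > 0 else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise SingularDesignError(f"design matrix is singular; collinear columns: {bad}")


def _start_values(y, X, family, offset):
    """Single-level GLM fit for beta (robust starting point)."""
    import statsmodels.api as sm

    fam = {
        "binomial": sm.families.Binomial(),
        "poisson": sm.families.Poisson(),
        "normal": sm.families.Gaussian(),
    }[family]
    try:
        res = sm.GLM(y, X, family=fam, offset=offset).fit()
        beta0 = np.asarray(res.params, dtype=float)
    except Exception:  # fall back to zeros; the optimizer recovers
        beta0 = np.zeros(X.shape[1])
    if family == "normal":
        resid = y - X @ beta0
        s = max(float(np.std(resid)), 1e-3)
    else:
        s = None
    return beta0, s


def _numeric_hessian(fun, x, h=1e-4):
    p = len(x)
    H = np.empty((p, p))
    steps = h * (1.0 + np.abs(x))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = steps[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / steps[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = np.log(1e-8), np.log(50.0)


def fit_random_intercept(
    data: MultilevelDataset,
    family: str = "binomial",
    n_quad: int = 15,
    start: np.ndarray | None = None,
    keep_design: bool = True,
    fix_sigma_u: float | None = None,
) -> FittedMixedModel:
    """Fit the two-level random-intercept model by maximum marginal likelihood.

    Parameters
    ----------
    data
        Validated two-level dataset.
    family
        ``"binomial"`` (logit link), ``"poisson"`` (log link, honoring
        ``data.offset``), or ``"normal"`` (identity link, residual SD
        estimated).
    n_quad
        Number of adaptive Gauss-Hermite nodes (>= 3; default 15).
    start
        Optional starting values ``[beta..., sigma_u]`` (and ``sigma_e``
        appended for the normal family).  Defaults to a single-level GLM fit
        for beta and sigma_u = 0.3.
    keep_design
        Retain the covariate design for downstream empirical risk
        distributions (disabled inside bootstrap refits to save memory).
    fix_sigma_u
        Hold the random-intercept SD fixed at this value and profile only
        the remaining parameters (0 reduces the fit to a single-level GLM).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}, got {family!r}")
    if n_quad < 3:
        raise ValueError(f"n_quad must be >= 3, got {n_quad}")
    data.validate_outcome(family)
    if data.n_clusters < 2:
        raise ValueError("at least 2 clusters are required (sigma_u unidentifiable)")

    frame = data.frame
    y = frame[data.outcome].to_numpy(dtype=float)
    cov_cols = data.covariate_cols
    names = ["(Intercept)", *cov_cols]
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in cov_cols])
    _check_design(X, names)
    offset = None
    if data.offset is not None:
        if family != "poisson":
            raise ValueError("offset column supported for the poisson family only")
        offset = frame[data.offset].to_numpy(dtype=float)

    codes, _ = pd.factorize(frame[data.cluster], sort=True)
    ll = _MarginalLoglik(y, X, codes, data.n_clusters, family, n_quad, offset)

    p = X.shape[1]
    is_normal = family == "normal"
    if start is not None:
        start = np.asarray(start, dtype=float)
        beta0 = start[:p]
        sig0 = max(float(start[p]), 1e-6)
        s0 = float(start[p + 1]) if is_normal and len(start) > p + 1 else None
        if is_normal and s0 is None:
            _, s0 = _start_values(y, X, family, offset)
    else:
        beta0, s0 = _start_values(y, X, family, offset)
        sig0 = 0.3

    def unpack(theta):
        beta = theta[:p]
        sigma = np.exp(theta[p])
        sigma_e = np.exp(theta[p + 1]) if is_normal else None
        return beta, sigma, sigma_e

    def negll(theta):
        beta, sigma, sigma_e = unpack(theta)
        return -ll(beta, sigma, sigma_e)

    x0 = np.r_[beta0, np.log(sig0)] if not is_normal else np.r_[beta0, np.log(sig0), np.log(s0)]
    bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    if is_normal:
        bounds.append((np.log(1e-8), np.log(1e6)))
    fixed_sigma = fix_sigma_u is not None
    if fixed_sigma:
        if fix_sigma_u < 0:
            raise ValueError(f"fix_sigma_u must be >= 0, got {fix_sigma_u}")
        log_fix = float(np.log(max(fix_sigma_u, 1e-10)))
        x0[p] = log_fix
        bounds[p] = (log_fix, log_fix)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-5},
        )
    logger.debug("optimizer: %s (%d evaluations)", res.message, res.nfev)

    beta_hat, sigma_hat, sigma_e_hat = unpack(res.x)
    boundary = sigma_hat <= BOUNDARY_SIGMA or (
        not fixed_sigma and res.x[p] <= _LOG_SIGMA_MIN + 1e-9
    )
    converged = bool(res.success)
    message = str(res.message)
    if not converged:
        logger.warning("GLMM fit did not converge: %s", message)

    # observed information in the (beta, log sigma) parameterization
    n_free = p if (boundary or fixed_sigma) else len(res.x)
    se = np.full(len(res.x), np.nan)
    vcov_free = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            H = _numeric_hessian(lambda t: negll(np.r_[t, res.x[n_free:]]), res.x[:n_free])
            vcov_free = np.linalg.inv(H)
        diag = np.diag(vcov_free).copy()
        diag[diag < 0] = np.nan
        se[:n_free] = np.sqrt(diag)
    except np.linalg.LinAlgError:
        converged = False
        message += "; observed information not invertible"

    # delta method: SE(sigma) = sigma * SE(log sigma); vcov on the sigma scale
    names_all = list(names) + ["sigma_u"] + (["sigma_e"] if is_normal else [])
    jac = np.ones(len(res.x))
    jac[p] = sigma_hat
    if is_normal:
        jac[p + 1] = sigma_e_hat
    vcov = np.full((len(res.x), len(res.x)), np.nan)
    if vcov_free is not None:
        vcov[:n_free, :n_free] = vcov_free
        vcov = vcov * np.outer(jac, jac)
    se_nat = se * np.abs(jac)

    se_sigma_u = float("nan") if boundary else float(se_nat[p])
    if boundary:
        logger.warning("sigma_u estimate at the zero boundary; SE unavailable")

    return FittedMixedModel(
        family=family,
        beta=pd.Series(beta_hat, index=names),
        sigma_u=float(sigma_hat),
        se_beta=pd.Series(se_nat[:p], index=names),
        se_sigma_u=se_sigma_u,
        vcov=pd.DataFrame(vcov, index=names_all, columns=names_all),
        loglik=float(-res.fun),
        converged=converged,
        boundary=bool(boundary),
        n_quad=n_quad,
        message=message,
        sigma_e=float(sigma_e_hat) if is_normal else None,
        n_clusters=data.n_clusters,
        n_subjects=data.n_subjects,
        design=frame[cov_cols].copy() if keep_design else None,
        subject_cols=list(data.subject_cols),
        cluster_cols=list(data.cluster_cols),
    )
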