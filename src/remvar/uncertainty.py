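"""Confidence intervals for reference effect measures.

Two routes are provided.  The delta method propagates SE(sigma_u) through
the closed-form measures: a level-L interval for REM_u(a) is

    ( exp((sigma_u - z SE) Phi^{-1}(a)),  exp((sigma_u + z SE) Phi^{-1}(a)) )

with endpoints sorted (for a < 0.5 the transform is decreasing) and the
lower sigma bound truncated at zero.  The cluster (case) bootstrap resamples
whole clusters with replacement — respecting the two-level dependence —
refits the model per replicate, and takes percentile intervals of the
replicated statistic.  Sampling-distribution skew of variance components
makes the bootstrap the safer default for small numbers of clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import MultilevelDataset
from .glmm import FittedMixedModel, fit_random_intercept
from .measures import NormalRandomEffect, rem_random

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalEstimate",
    "delta_ci_rem",
    "cluster_bootstrap",
    "percentile_equivalent_ci",
]


@dataclass
class IntervalEstimate:
    """A point estimate with a confidence interval."""

    point: float
    low: float
    high: float
    level: float
    method: str
    n_boot: int | None = None
    seed: int | None = None
    n_failed: int = 0
    replicates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0,1), got {self.level}")
        if self.low > self.high:
            raise ValueError("interval endpoints out of order")

    def as_tuple(self) -> tuple[float, float]:
        return (self.low, self.high)

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "low": self.low,
            "high": self.high,
            "level": self.level,
            "method": self.method,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def delta_ci_rem(
    sigma_u: float, se_sigma_u: float, a: float, level: float = 0.95
) -> IntervalEstimate:
    """Delta-method CI for REM_u(a) from (sigma_u, SE(sigma_u))."""
    if se_sigma_u < 0:
        raise ValueError(f"se_sigma_u must be >= 0, got {se_sigma_u}")
    if not 0.0 < a < 1.0:
        raise ValueError(f"a must be in (0,1), got {a}")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    q = stats.norm.ppf(a)
    sig_lo = max(sigma_u - z * se_sigma_u, 0.0)
    sig_hi = sigma_u + z * se_sigma_u
    ends = sorted((float(np.exp(sig_lo * q)), float(np.exp(sig_hi * q))))
    return IntervalEstimate(
        point=rem_random(NormalRandomEffect(sigma_u), a),
        low=ends[0],
        high=ends[1],
        level=level,
        method="delta",
    )


def cluster_bootstrap(
    data: MultilevelDataset,
    statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    family: str = "binomial",
    n_quad: int = 15,
    fitted: FittedMixedModel | None = None,
    max_fail_frac: float = 0.2,
) -> IntervalEstimate:
    """Percentile CI from a cluster (case) bootstrap.

    Clusters are resampled with replacement at the top level only; all
    subjects of a sampled cluster are retained and duplicated clusters get
    fresh ids.  The model is refit on each replicate and ``statistic`` (a
    callable taking a :class:`FittedMixedModel`) is evaluated.  Replicates
    whose refit fails to converge are dropped and counted; more than
    ``max_fail_frac`` failures raises.
    """
    if seed is None:
        raise ValueError("cluster_bootstrap requires an explicit seed")
    if n_boot < 50:
        warnings.warn(f"n_boot = {n_boot} is small; percentile CIs will be noisy")
    if data.n_clusters < 2:
        raise ValueError("cluster bootstrap needs >= 2 clusters")

    if fitted is None:
        fitted = fit_random_intercept(data, family=family, n_quad=n_quad)
    point = float(statistic(fitted))
    start = np.r_[fitted.beta.to_numpy(), max(fitted.sigma_u, 1e-4)]
    if fitted.sigma_e is not None:
        start = np.r_[start, fitted.sigma_e]

    rng = np.random.default_rng(seed)
    ids = np.asarray(sorted(data.frame[data.cluster].unique()))
    vals = []
    n_failed = 0
    for b in range(n_boot):
        take = rng.integers(0, len(ids), size=len(ids))
        resampled = data.subset_clusters(ids[take])
        try:
            refit = fit_random_intercept(
                resampled, family=family, n_quad=n_quad, start=start, keep_design=True
            )
            if not refit.converged:
                raise RuntimeError(refit.message)
            vals.append(float(statistic(refit)))
        except Exception as exc:  # refit failures are counted, not fatal
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)

    if n_failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed to converge; "
            "the model may be unstable under cluster resampling"
        )
    vals = np.asarray(vals)
    alpha = (1.0 - level) / 2.0
    # order-statistic quantiles keep percentile intervals exactly
    # equivariant under monotone transforms of the statistic
    low, high = np.quantile(vals, [alpha, 1.0 - alpha], method="closest_observation")
    return IntervalEstimate(
        point=point,
        low=float(min(low, point)),
        high=float(max(high, point)),
        level=level,
        method="cluster-bootstrap",
        n_boot=n_boot,
        seed=seed,
        n_failed=n_failed,
        replicates=vals,
    )


def _delta_percentile_ci(beta_k, sigma_u, var_beta, var_sigma, cov_bs, level):
    """Wald CI for Phi(beta_k/sigma_u) via the bivariate delta method."""
    r = beta_k / sigma_u
    dphi = stats.norm.pdf(r)
    grad = np.array([dphi / sigma_u, -dphi * beta_k / sigma_u**2])
    V = np.array([[var_beta, cov_bs], [cov_bs, var_sigma]])
    se = float(np.sqrt(grad @ V @ grad))
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    point = float(stats.norm.cdf(r))
    return IntervalEstimate(
        point=point,
        low=max(point - z * se, 0.0),
        high=min(point + z * se, 1.0),
        level=level,
        method="delta",
    )


def percentile_equivalent_ci(
    term: str,
    fitted: FittedMixedModel,
    data: MultilevelDataset | None = None,
    method: str = "bootstrap",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    n_quad: int = 15,
) -> IntervalEstimate:
    """CI for the percentile equivalent Phi(beta_k / sigma_u) of a fixed effect.

    ``method="bootstrap"`` (default) cluster-bootstraps the ratio; it needs
    ``data``.  ``method="delta"`` propagates the joint covariance of
    (beta_k, sigma_u) through the ratio and needs only the fitted model.
    """
    if fitted.sigma_u <= 0:
        raise ValueError("percentile equivalence undefined at sigma_u = 0")
    if term not in fitted.beta.index:
        raise KeyError(f"unknown coefficient {term!r}")
    if method == "delta":
        V = fitted.vcov
        return _delta_percentile_ci(
            float(fitted.beta[term]),
            fitted.sigma_u,
            float(V.loc[term, term]),
            float(V.loc["sigma_u", "sigma_u"]),
            float(V.loc[term, "sigma_u"]),
            level,
        )
    if method != "bootstrap":
        raise ValueError(f"method must be 'bootstrap' or 'delta', got {method!r}")
    if data is None:
        raise ValueError("bootstrap percentile-equivalent CI requires the dataset")

    def stat(model: FittedMixedModel) -> float:
        if model.sigma_u <= 0:
            raise RuntimeError("boundary sigma_u in bootstrap replicate")
        return float(stats.norm.cdf(model.beta[term] / model.sigma_u))

    return cluster_bootstrap(
        data, stat, n_boot=n_boot, level=level, seed=seed,
        family=fitted.family, n_quad=n_quad, fitted=fitted,
    )
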