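"""Effect-scale measures of variation in multilevel models.

A two-level model for subjects nested in clusters carries two kinds of
variation: variation from measured fixed effects and unexplained
between-cluster variation (the general contextual effect, GCE) captured by
the random-intercept distribution.  Reference effect measures (REM) put both
on the same effect scale — odds ratios for logistic models — by comparing a
subject in a cluster at a chosen percentile of a distribution against a
subject in a median ("reference") cluster, covariates held equal:

    REM_u(a) = exp(sigma_u * Phi^{-1}(a))          (normal random intercept)
    REM_S(a) = exp(F_S^{-1}(a) - F_S^{-1}(0.5))    (empirical covariate set S)

where F_S is the empirical distribution of the linear-predictor
contributions {x'_S beta_S} over all subjects.  The same percentile logic
yields the classical comparison measures: the median odds ratio
MOR = exp(sqrt(2) sigma_u Phi^{-1}(0.75)), the per-SD odds ratio
PerSD = exp(sigma), the latent-scale intraclass correlation
ICC = sigma_u^2 / (sigma_u^2 + pi^2/3), the percentile equivalent
Phi(beta_k / sigma_u) of a fixed effect, and individual outcome measures
IOM(x, a) = expit(x'beta + sigma_u Phi^{-1}(a)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "EffectScale",
    "RandomEffectDistribution",
    "NormalRandomEffect",
    "LogGammaRandomEffect",
    "UserQuantileRandomEffect",
    "EmpiricalRiskDistribution",
    "rem_random",
    "rem_range",
    "percentile_equivalent",
    "rem_empirical",
    "rem_empirical_range",
    "iom",
    "mor",
    "mor_percentile",
    "per_sd",
    "icc_latent",
    "sigma_from_rem",
    "BOUNDARY_SIGMA",
]

#: Random-intercept SDs below this are treated as a boundary (zero) estimate;
#: every measure then collapses to its null value with a warning.
BOUNDARY_SIGMA = 1e-6


class EffectScale(Enum):
    """How a linear-predictor difference maps to the reported effect.

    ``RATIO`` exponentiates (odds/rate ratios for logit/log links);
    ``DIFFERENCE`` is the identity (mean differences, identity link).
    """

    RATIO = "ratio"
    DIFFERENCE = "difference"

    def apply(self, linpred_diff):
        if self is EffectScale.RATIO:
            return np.exp(linpred_diff)
        return linpred_diff


def _check_prob(a: float, name: str = "a") -> None:
    if not 0.0 < a < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1), got {a!r}")


class RandomEffectDistribution:
    """Median-centered distribution of the cluster random intercept u_i.

    Subclasses provide ``_raw_quantile``; :meth:`quantile` subtracts the raw
    median so that ``quantile(0.5) == 0`` for every family, which makes the
    median cluster the reference by construction.
    """

    kind: str = "user-quantile"

    def _raw_quantile(self, a: float) -> float:
        raise NotImplementedError

    def quantile(self, a: float) -> float:
        _check_prob(a)
        return self._raw_quantile(a) - self._raw_quantile(0.5)

    def percentile_of(self, value: float) -> float:
        """Invert the centered quantile function numerically."""
        lo, hi = 1e-12, 1.0 - 1e-12
        qlo, qhi = self.quantile(lo), self.quantile(hi)
        if not qlo <= value <= qhi:
            raise ValueError(
                f"value {value} outside the support [{qlo:.4g}, {qhi:.4g}] "
                "of the centered random-effect distribution"
            )
        return optimize.brentq(lambda a: self.quantile(a) - value, lo, hi)


@dataclass(frozen=True)
class NormalRandomEffect(RandomEffectDistribution):
    """u_i ~ N(0, sigma_u^2); quantile(a) = sigma_u * Phi^{-1}(a)."""

    sigma_u: float
    kind: str = field(default="normal", init=False)

    def __post_init__(self):
        if self.sigma_u < 0:
            raise ValueError(f"sigma_u must be >= 0, got {self.sigma_u}")

    def _raw_quantile(self, a: float) -> float:
        return self.sigma_u * stats.norm.ppf(a)

    def quantile(self, a: float) -> float:  # median is 0 already
        _check_prob(a)
        return self.sigma_u * stats.norm.ppf(a)

    def percentile_of(self, value: float) -> float:
        if self.sigma_u <= BOUNDARY_SIGMA:
            raise ValueError(
                "percentile equivalence undefined at sigma_u = 0 boundary"
            )
        return float(stats.norm.cdf(value / self.sigma_u))


@dataclass(frozen=True)
class LogGammaRandomEffect(RandomEffectDistribution):
    """u = log(G) with G ~ Gamma(shape k, rate k), so E[G] = 1.

    The log-Gamma family is the conjugate choice for Poisson outcomes (it
    yields a negative-binomial marginal); it is left-skewed on the log scale.
    Median-centering is applied so the reference cluster is the median one.
    """

    shape: float
    kind: str = field(default="log-gamma", init=False)

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")

    def _raw_quantile(self, a: float) -> float:
        return float(np.log(stats.gamma.ppf(a, self.shape, scale=1.0 / self.shape)))


@dataclass(frozen=True)
class UserQuantileRandomEffect(RandomEffectDistribution):
    """Arbitrary random-effect law supplied as a quantile function."""

    quantile_fn: Callable[[float], float]
    kind: str = field(default="user-quantile", init=False)

    def _raw_quantile(self, a: float) -> float:
        return float(self.quantile_fn(a))


@dataclass(frozen=True)
class EmpiricalRiskDistribution:
    """Empirical distribution of linear-predictor contributions {x'_S beta_S}.

    ``values`` holds one contribution per subject for a declared covariate
    subset S (all patient factors, all site factors, a single covariate, ...).
    Quantiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention).
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValueError("empirical risk distribution needs >= 1 value")
        if not np.all(np.isfinite(vals)):
            raise ValueError("empirical risk distribution values must be finite")
        object.__setattr__(self, "values", vals)

    def quantile(self, a: float) -> float:
        _check_prob(a)
        return float(np.quantile(self.values, a))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0


def rem_random(
    dist: RandomEffectDistribution | float,
    a: float,
    scale: EffectScale = EffectScale.RATIO,
) -> float:
    """Reference effect at the 100*a percentile of the random-effect law.

    For a normal random intercept on the ratio scale this is
    exp(sigma_u * Phi^{-1}(a)): the odds ratio comparing a subject in a
    100*a percentile cluster to the same subject in a median cluster.
    """
    if not isinstance(dist, RandomEffectDistribution):
        dist = NormalRandomEffect(float(dist))
    _check_prob(a)
    return float(scale.apply(dist.quantile(a)))


def rem_range(
    dist: RandomEffectDistribution | float,
    level: float = 0.95,
    scale: EffectScale = EffectScale.RATIO,
) -> tuple[float, float]:
    """Range enclosing the middle ``level`` of reference effects.

    At level 0.95 this is the 95% REM range [exp(-1.96 sigma_u),
    exp(1.96 sigma_u)] for normal random effects — a description of cluster
    variation, not a confidence interval.
    """
    _check_prob(level, "level")
    lo_a = (1.0 - level) / 2.0
    lo = rem_random(dist, lo_a, scale)
    hi = rem_random(dist, 1.0 - lo_a, scale)
    return (min(lo, hi), max(lo, hi))


def percentile_equivalent(
    beta_k: float, dist: RandomEffectDistribution | float
) -> float:
    """Percentile of the random-effect law whose REM equals exp(beta_k).

    For normal random effects this is Phi(beta_k / sigma_u): a one-unit
    covariate effect beta_k moves a subject as much as moving them from a
    median cluster to a 100*Phi(beta_k/sigma_u) percentile cluster.  Negative
    effects map below the 50th percentile; the flipped presentation
    1 - Phi(beta_k/sigma_u) is a display choice left to reporting.
    """
    if not isinstance(dist, RandomEffectDistribution):
        dist = NormalRandomEffect(float(dist))
    if isinstance(dist, NormalRandomEffect) and dist.sigma_u <= BOUNDARY_SIGMA:
        raise ValueError("percentile equivalence undefined at sigma_u = 0 boundary")
    return float(dist.percentile_of(beta_k))


def rem_empirical(
    riskdist: EmpiricalRiskDistribution,
    a: float,
    scale: EffectScale = EffectScale.RATIO,
) -> float:
    """Reference effect at the 100*a percentile of an empirical risk law.

    The empirical distribution is centered at its median, so the comparison
    is against a subject of median risk within the declared covariate subset.
    """
    _check_prob(a)
    centered = riskdist.quantile(a) - riskdist.quantile(0.5)
    return float(scale.apply(centered))


def rem_empirical_range(
    riskdist: EmpiricalRiskDistribution,
    level: float = 0.95,
    scale: EffectScale = EffectScale.RATIO,
) -> tuple[float, float]:
    """Middle-``level`` range of empirical reference effects (median-centered)."""
    _check_prob(level, "level")
    lo_a = (1.0 - level) / 2.0
    lo = rem_empirical(riskdist, lo_a, scale)
    hi = rem_empirical(riskdist, 1.0 - lo_a, scale)
    return (min(lo, hi), max(lo, hi))


def iom(linpred: float, dist: RandomEffectDistribution | float, a: float,
        family: str = "binomial") -> float:
    """Individual outcome measure: outcome probability for covariate pattern x
    at the 100*a percentile cluster, expit(x'beta + q_u(a)).

    Defined here on the probability scale, i.e. for the binomial-logit family
    only; the width of IOM ranges depends on the covariate pattern, which is
    exactly the limitation REM avoids.
    """
    if family != "binomial":
        raise ValueError("IOM is defined on the probability scale (binomial-logit family only)")
    if not isinstance(dist, RandomEffectDistribution):
        dist = NormalRandomEffect(float(dist))
    _check_prob(a)
    return float(special.expit(linpred + dist.quantile(a)))


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if sigma < 0:
        raise ValueError(f"standard deviation must be >= 0, got {sigma}")
    if 0 < sigma <= BOUNDARY_SIGMA:
        warnings.warn(
            "sigma_u at the zero boundary; measures collapse to their null values",
            stacklevel=3,
        )
    return sigma


def mor(sigma_u: float) -> float:
    """Median odds ratio, exp(sqrt(2) sigma_u Phi^{-1}(0.75)).

    The median of odds ratios comparing the higher- to the lower-risk subject
    across two randomly sampled clusters; equals REM_u(0.83).
    """
    sigma_u = _check_sigma(sigma_u)
    return float(np.exp(np.sqrt(2.0) * sigma_u * stats.norm.ppf(0.75)))


def mor_percentile() -> float:
    """The percentile a* with MOR = REM_u(a*): Phi(sqrt(2) Phi^{-1}(0.75)) ~ 0.83."""
    return float(stats.norm.cdf(np.sqrt(2.0) * stats.norm.ppf(0.75)))


def per_sd(sigma: float, scale: EffectScale = EffectScale.RATIO) -> float:
    """Effect of a one-SD shift: exp(sigma) on the ratio scale (= REM_u(Phi(1))).

    Applies to the random-intercept SD or to the SD of an empirical covariate
    (-set) distribution, making random and fixed sources directly comparable.
    """
    sigma = _check_sigma(sigma)
    return float(scale.apply(sigma))


def icc_latent(sigma_u: float) -> float:
    """Latent-scale intraclass correlation sigma_u^2 / (sigma_u^2 + pi^2/3).

    Assumes a logistic latent subject-level error (variance pi^2/3); the share
    of latent variance attributable to clusters.
    """
    sigma_u = _check_sigma(sigma_u)
    v = sigma_u**2
    return float(v / (v + np.pi**2 / 3.0))


def sigma_from_rem(rem_value: float, a: float) -> float:
    """Invert REM_u(a) = exp(sigma_u Phi^{-1}(a)) for a normal random effect.

    Useful when a published analysis reports a REM value but not sigma_u.
    """
    if rem_value <= 0:
        raise ValueError(f"rem_value must be > 0, got {rem_value}")
    _check_prob(a)
    if a == 0.5:
        raise ValueError("a = 0.5 carries no information about sigma_u")
    return float(np.log(rem_value) / stats.norm.ppf(a))
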