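# Methods

## Model

The package targets two-level designs: subjects j = 1..n_i nested in
clusters i = 1..N.  The default outcome model is the mixed logistic
regression

    Y_ij | p_ij ~ Bin(1, p_ij),  logit(p_ij) = β₀ + x'_sij β_s + x'_cij β_c + u_i

with subject-level covariates x_s, cluster-level covariates x_c (constant
within cluster, validated at load), and independent normal random
intercepts u_i ~ N(0, σ_u²).  Poisson-log (with optional offset) and
normal-identity families swap the conditional likelihood kernel; the normal
family carries an additional residual SD σ_e.

## Reference effect measures

All variation sources are summarized on the effect scale by comparing a
subject at a chosen percentile of a distribution with a subject at the
median of that distribution, covariates held equal.  Because the odds ratio
between two subjects is exp(L* − L), everything shared subtracts out:

- Random intercept: REM_u(a) = exp(σ_u Φ⁻¹(a)); the 95% range is
  [exp(−1.96 σ_u), exp(1.96 σ_u)] — a description of cluster variation
  (square-bracket convention), not a confidence interval.
- Covariate set S: REM_S(a) = exp(F⁻¹_S(a) − F⁻¹_S(0.5)) where F_S is the
  empirical distribution of {x'_S β̂_S} over all subjects.  Median-centering
  is always applied, so REM_S(0.5) = 1 by construction.
- Percentile equivalent of a coefficient: Φ(β_k/σ_u).  Negative effects are
  reported below the 50th percentile as-is; the report also carries the
  flipped presentation 1 − Φ(β_k/σ_u).
- MOR = exp(√2 σ_u Φ⁻¹(0.75)) = REM_u(Φ(√2 Φ⁻¹(0.75))) ≈ REM_u(0.83);
  PerSD = exp(σ) = REM_u(Φ(1)); ICC = σ_u²/(σ_u² + π²/3) (latent logistic
  subject-level error); IOM(x, a) = expit(x'β + σ_u Φ⁻¹(a)), defined on the
  probability scale and therefore restricted to the binomial-logit family.
- σ_u = ln(REM_u(a))/Φ⁻¹(a) inverts a published REM value when σ_u itself
  was not reported.

Non-normal random-effect laws replace σ_u Φ⁻¹(a) by their own centered
quantiles.  Every family is median-centered (raw median subtracted) so the
reference cluster is always the median one; the log-Gamma family uses
u = log(G), G ~ Gamma(k, rate k) (unit mean), shape configurable.  On the
ratio scale effects are exponentiated; the difference scale (identity) is
used for normal-family mean differences.

### Numerical conventions

Empirical quantiles use linear interpolation between order statistics
(numpy's default, the "type 7" convention).  With that estimator the median
of an even-sized sample is itself interpolated; all toy examples in the
test suite are computed under this convention.  Degenerate (constant) risk
distributions give REM ≡ 1.  σ̂_u ≤ 1e−6 is treated as a boundary estimate:
all measures collapse to their null values (REM = MOR = PerSD = 1, ICC = 0)
with a warning rather than an error, and the percentile equivalent — which
is undefined at σ_u = 0 — raises.

## Estimation

The marginal likelihood integrates each cluster's conditional likelihood
over u_i.  The integral is approximated by adaptive Gauss–Hermite
quadrature: per cluster, a damped Newton iteration (vectorized across
clusters) finds the mode of the log-integrand and its curvature; nodes are
placed at mode + √2·τ·z_k with τ the inverse-root curvature, and the sum is
accumulated in log space.  Default 15 nodes; 15 vs 25 nodes agree to ≥ 5
significant digits on the test fixture, and the total is checked against a
10001-point trapezoid integration (±8σ) to ≤ 1e−4 relative error.

σ_u (and σ_e) are optimized on the log scale to enforce positivity, with
L-BFGS-B over (β, log σ_u), numerically differenced gradients, and
convergence at projected-gradient norm ≤ 1e−5 / relative log-likelihood
change ≤ ~1e−11.  Starting values: a single-level GLM fit for β (via
statsmodels) and σ_u = 0.3.  Standard errors come from the inverse observed
information (central-difference Hessian) at the optimum; SE(σ̂_u) is
back-transformed by the delta method, and the reported covariance matrix is
on the (β, σ_u) scale.  log σ_u hitting its lower bound (σ < 1e−8) is
reported as a boundary fit with SE(σ̂_u) = NaN.  Non-convergence returns a
flagged result with the optimizer message, never a silent success.
`fix_sigma_u` profiles β with σ_u held fixed (0 reduces to a single-level
GLM; verified against statsmodels IRLS to 1e−6).  The normal family's
closed-form marginal (Σ = σ_e²I + σ_u²J) serves as an internal cross-check.
Rank-deficient designs are rejected with the collinear columns named (QR
with pivoting).

## Confidence intervals

- Delta method for REM_u(a): endpoints exp((σ̂_u ± z·SE(σ̂_u))·Φ⁻¹(a)),
  sorted (the transform is decreasing for a < 0.5) and with the lower σ
  bound truncated at 0.  The analogous bivariate delta method covers
  Φ(β_k/σ_u), propagating the joint covariance of (β̂_k, σ̂_u).
- Cluster (case) bootstrap: clusters are resampled with replacement at the
  top level only, all subjects retained, duplicates relabeled; the model is
  refit per replicate (warm-started at the original optimum) and percentile
  intervals are taken from the replicate statistics.  Default 1000
  replicates, mandatory seed.  Non-converged refits are dropped and
  counted, with a 20% failure ceiling.  Percentile endpoints use the
  closest-observation (order-statistic) quantile rule, which makes the
  intervals exactly equivariant under monotone transforms of the statistic;
  intervals are clamped to contain the point estimate.

Sampling distributions of variance components are right-skewed, so the
bootstrap is the safer default with few clusters; on well-behaved fixtures
the two methods agree closely (asserted in the tests as closeness, not as
specific endpoint values).

## Synthetic data

`SimulationDesign` draws cluster random intercepts by inverse-CDF from the
(median-centered) random-effect law, covariates per declared specs
(Bernoulli or normal, subject- or cluster-level), and outcomes from the
chosen family.  Cluster sizes are fixed or Poisson (floored at 1).  True
u_i are returned alongside the dataset, never written into it.

The standard fixture mimics a multi-site treatment-initiation registry:
60 clusters of Poisson(60) subjects, σ_u = 0.5, four subject-level risk
factors (binary and continuous, |β| 0.27–0.41) and two weak cluster-level
factors (|β| ≤ 0.08), intercept −2.11 calibrated once by simulation to a
~14.6% event rate.  By construction the subject-factor REM range is wide,
the cluster-factor range narrow, and the GCE comparable to the subject
factors.  What the generator deliberately does not emulate: covariate
correlation and confounding between levels, informative cluster size,
non-linear (spline) effects, and temporal trends — so passing tests
demonstrate correctness of the estimators and measures under the stated
model, not robustness to real-data violations of it.

## Problem sizes used in the checks

Monte-Carlo checks run at sizes chosen for tight, reproducible tolerances:
parameter recovery over 100 seeded replicates at 60 clusters × 50 subjects
(observed mean bias of σ̂_u: −0.016; 95% Wald coverage: 0.92), and a nested
bootstrap-coverage study at 60 outer × 100 inner replicates on 25 clusters
× 20 subjects (observed coverage 0.917 for the 95% interval of REM_u(0.75)).
Both are deterministic given their fixed seed grids.

## Known limitations

Single random intercept only (no random slopes, crossed or three-level
designs); IOM restricted to the logit family; no interval odds ratios,
frailty/hazard-scale measures, or probability-scale ICC variants; Wald
p-values in the coefficient table; the delta CI for REM inherits the
normal-theory approximation for σ̂_u and can undercover when the number of
clusters is small — prefer the bootstrap there.  Maximum marginal
likelihood carries the usual small-N downward bias in σ̂_u.
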