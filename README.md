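# remvar — reference effect measures for cluster variation in multilevel models

Multilevel studies in health services research — patients nested in
hospitals, subjects nested in sites — routinely fit random-intercept
logistic models and report odds ratios for the fixed effects.  The
unexplained between-cluster variation (the *general contextual effect*,
GCE), captured by the random-intercept SD σ_u, is just as often the real
scientific question ("how much does treatment vary across hospitals after
adjusting for case mix?"), yet it is usually left on the variance scale
where it cannot be compared with the fixed-effect odds ratios next to it.

**Reference effect measures (REM)** put every source of variation on the
effect scale.  For the mixed logistic model

```
Y_ij | p_ij ~ Bin(1, p_ij),   logit(p_ij) = x'_ij β + u_i,   u_i ~ N(0, σ_u²)
```

a subject in a cluster at the 100·a percentile of the random-effect
distribution, compared with the same subject in a median ("reference")
cluster, has odds ratio

```
REM_u(a) = exp(σ_u Φ⁻¹(a))
```

and the middle-95% band of such odds ratios is [exp(−1.96 σ_u),
exp(1.96 σ_u)].  The same percentile logic applies to *sets* of measured
covariates through the empirical distribution of their linear-predictor
contributions {x'_S β_S}, median-centered:

```
REM_S(a) = exp(F⁻¹_S(a) − F⁻¹_S(0.5))
```

so "all patient risk factors", "all site characteristics" and the GCE can
be drawn side by side and ranked by how much outcome variation each drives.
The classical summaries fall out as special cases: the median odds ratio
MOR = exp(√2 σ_u Φ⁻¹(0.75)) = REM_u(0.83), the per-SD odds ratio
PerSD = exp(σ_u) = REM_u(Φ(1)), the latent-scale intraclass correlation
ICC = σ_u²/(σ_u² + π²/3), the percentile equivalent Φ(β_k/σ_u) of a fixed
effect, and individual outcome measures IOM(x, a) = expit(x'β + σ_u Φ⁻¹(a)).

The package provides:

- `remvar.glmm` — a random-intercept GLMM fitter (binomial-logit,
  poisson-log, normal-identity) by maximum marginal likelihood with
  per-cluster adaptive Gauss–Hermite quadrature;
- `remvar.measures` — REM for random-effect and empirical distributions,
  percentile equivalents, MOR, PerSD, ICC, IOM, and the inversion
  σ_u = ln(REM)/Φ⁻¹(a);
- `remvar.uncertainty` — delta-method and cluster-bootstrap confidence
  intervals;
- `remvar.simulate` — two-level synthetic data with known parameters;
- `remvar.plots` — forest plots with shaded REM bands and
  variation-sources displays, with a unit-testable data layer;
- `remvar.report` / `remvar.cli` — report assembly and a `remvar`
  command line (`fit`, `measures`, `bootstrap`, `simulate`, `plot`, `run`).

## Worked example

A published two-level analysis of rhythm-control initiation reports a
hospital random-intercept SD of 0.511 (SE 0.040), a CHF coefficient of
0.409, and an intercept of −2.292.  Every REM-family summary follows from
those estimates alone — no subject-level data needed:

```python
from remvar import model_from_estimates, compute_report

model = model_from_estimates(
    beta={"(Intercept)": -2.292, "chf": 0.409},
    sigma_u=0.511, se_sigma_u=0.040,
    se_beta={"(Intercept)": 0.321, "chf": 0.039},
)
report = compute_report(model, ci="delta",
                        iom_patterns={"chf_patient": {"chf": 1.0}}, seed=1)
```

which prints (via `report.sources[-1]` and `report.comparison`):

```
95% REM range: [0.367, 2.72]
REM(0.75): 1.41 (1.34, 1.49)
MOR 1.63  PerSD 1.67  ICC 0.074
CHF percentile equivalent: 79th
IOM for a CHF patient: 13.2% [5.3%, 29.3%]
```

Reading: hospitals at the extremes of the random-effect distribution differ
from a median hospital by odds ratios between 0.37 and 2.72 — a larger
spread than the strongest patient-level effect (CHF, OR 1.51), whose impact
equals moving a patient from a median to a 79th-percentile hospital.  The
ICC of 0.074 looks small on the variance scale, which is exactly why the
effect-scale REM presentation matters.

With subject-level data the same report adds empirical covariate-set rows
and bootstrap CIs:

```sh
remvar simulate --seed 3 --out data.csv      # synthetic two-level dataset
remvar run config.yaml                       # fit + measures + CIs + figures
```

where `config.yaml` names the outcome/cluster/covariate columns, the CI
method (`delta`, `bootstrap`, or `both`) and the covariate subsets to
display.  Artifacts: `report.json`, `report.csv`, `table1.csv`, a forest
plot and a variation-sources plot.

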