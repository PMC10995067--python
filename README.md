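# agemeta

Estimate **main and age-varying genetic effects (SNP-by-age interactions)
from GWAS summary statistics** by random-effects meta-regression on
study-level age moments — plus the Monte Carlo machinery to evaluate when
meta-regression beats plain meta-analysis, and an applied pipeline for
cohort-by-occasion tables with overlap-adjusted standard errors.

## Who this is for

Genetic epidemiologists meta-analysing per-SNP results across studies whose
participants differ in age. If the per-allele effect changes with age,
inverse-variance meta-analysis silently returns the effect near the weighted
mean age of the included studies and files the age trend under
"heterogeneity". Meta-regression on age recovers the effect at any reference
age and the interaction coefficients, using only what GWAS routinely report:
the per-study estimate `b_j`, its SE `s_j`, and the study's mean and SD
of age.

## The model

Per-study effects are modelled as a polynomial in age evaluated over each
study's age distribution:

    b_j = c0 + c1 * m1_j + c2 * m2_j + c3 * m3_j + xi_j + eta_j,
    eta_j ~ N(0, s_j^2),   xi_j ~ N(0, tau2_res)

with `m_p_j = mean((age - centre)^p)` in study j. The intercept `c0` is the
per-allele effect at the centring age; `c1, c2, c3` are the linear, quadratic
and cubic SNP-by-age interaction coefficients. Higher moments are derived
from reported summaries: `mean(age^2) = SD(age)^2 + mean(age)^2`, and the
third moment assumes zero within-study age skewness unless supplied.
`tau2_res` is estimated by REML; degree 0 reduces exactly to REML
random-effects meta-analysis. See `docs/methods.md` for the full account.

## Worked example

Simulate the linear-interaction mechanism (per-allele effect 1.5 at age 0,
growing 0.020 per year; 40 studies × 1000 participants, ages 10–59, disjoint
study age windows), reduce each study to summary statistics, and fit a
degree-1 meta-regression centred at age 10:

```python
from agemeta import (ScenarioSpec, SimDesign, simulate_collection,
                     fit_collection, meta_regression)

summaries = fit_collection(simulate_collection(SimDesign(seed=7),
                                               ScenarioSpec(scenario_id=2)))
print(meta_regression(summaries, degree=1, centre=10.0).text_report())
```

```
metareg model, k=40 studies, degree=1, centre=10 years
tau^2 = 0.73068   Q = 9318 on 38 df   I^2 = 99.59%

          term     estimate         se                   95% CI
      beta_snp       1.7179     0.2709 [     1.187,      2.249]
  beta_snp_age     0.015832   0.009578 [ -0.002942,    0.03461]
```

`beta_snp` is the per-allele effect at age 10 (generating value
1.5 + 10×0.020 = 1.70) and `beta_snp_age` the interaction slope (generating
value 0.020); both cover the truth. A random-effects meta-analysis of the
same rows returns 2.106 — the effect at the weighted mean age (~34.6 years),
not at age 10.

The `examples/` directory holds one narrative script per capability:

| script | shows |
| --- | --- |
| `simulate_and_pool.py` | fixed- vs random-effects pooling under heterogeneity |
| `age_varying_metaregression.py` | interaction estimation, recentring, effect-by-age curve |
| `simulation_study.py` | the Monte Carlo harness and its performance measures |
| `overlap_adjustment.py` | covariance-aware weights for shared samples |
| `applied_cohort_occasions.py` | the full cohort-by-occasion cubic pipeline |

Running the applied pipeline on the built-in emulated cohort-by-occasion
table (8 cohorts, per-allele effects at 10 ages in 0–13 years, generating
effect negative in infancy and positive from mid-childhood) prints:

```
Fixed-effect meta-analysis (age-agnostic pooled effect):
  beta = +0.0601 (95% CI +0.0546 to +0.0656), I^2 = 93.27%

Meta-regression (degree 3, centre 0):
        beta_snp = -0.052547 (SE 0.011)
    ...
  residual I^2 = 25.54%
  fitted effect changes sign near age(s): 4.25 years
```

— the pooled estimate misses the sign change entirely, while the cubic
meta-regression recovers it and the age moderators absorb most of the
between-study heterogeneity (93% → 26% residual I²).

A thin CLI wraps the same functions
(`agemeta simulate | fit | evaluate | applied`, each emitting a reproducibility
manifest); `agemeta --help` lists the options.

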