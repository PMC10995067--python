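# Methods

`agemeta` estimates main and age-varying genetic effects (SNP-by-age
interactions) from per-study GWAS summary statistics by random-effects
meta-regression on study-level age moments, and provides the machinery to
evaluate those estimators by simulation. This note records the models, the
numerical choices, and what the synthetic data do and do not establish.

## The statistical problem

A GWAS consortium observes, for one SNP, per-study effect estimates
`b_j` with standard errors `s_j`, plus each study's mean and SD of age.
If the true per-allele effect varies with age, the usual inverse-variance
meta-analysis estimates the effect at (approximately) the weighted mean age of
the included studies — not at any age a user cares about — and between-study
heterogeneity statistics absorb the age trend. Meta-regression instead models
the per-study effect as a polynomial in age evaluated at the study's age
distribution, recovering both an effect at a chosen reference age and the
interaction coefficients, from summary data alone.

## Models

**Per-study reduction** (`studyfit`). Each study is summarised by OLS of the
phenotype on intercept, allele count and age:
`y_i = b0 + b1*snp_i + b2*age_i + e_i`. Deliberately no interaction or
quadratic terms — this is what a standard age-adjusted GWAS fits, whatever
the generating mechanism. The per-allele estimate `b1`, its conventional
residual-variance SE, and the sample mean/SD (n−1) of age are retained.
Monomorphic-SNP samples make the design singular; such studies are dropped
with a warning, never imputed.

**Fixed-effect meta-analysis**: weights `w_j = 1/s_j^2`, pooled estimate
`sum(w b)/sum(w)`, SE `(sum w)^(-1/2)`.

**Random-effects meta-analysis**: `b_j = mu + xi_j + eta_j` with
`xi_j ~ N(0, tau^2)`; weights `1/(s_j^2 + tau^2)`; `tau^2` by REML.

**Meta-regression** of degree d (1–3):

    b_j = c0 + c1*m1_j + c2*m2_j + c3*m3_j + xi_j + eta_j,

where `m_p_j = mean((age - centre)^p)` over study j's age distribution.
The intercept `c0` is the per-allele effect at the centring age; `c1..c3`
are the linear/quadratic/cubic interaction coefficients, invariant to the
centre. Studies report mean and SD of age, so higher moments are derived:

* `m2 = sd^2 + (mean - c)^2` — exact up to the n vs n−1 convention in the
  reported SD; studies report the sample SD (n−1) and the discrepancy is
  O(1/n), negligible at GWAS sample sizes. The derived value uses the SD
  exactly as reported.
* `m3 = (mean - c)^3 + 3*(mean - c)*sd^2`, which assumes zero within-study
  age skewness. This is exact for uniform age distributions (the simulator's
  case) and a documented approximation otherwise; a study-supplied raw third
  moment `mean(age^3)` (the `mean_age3` column) overrides it, in which case
  centring is done exactly.

Fitting is generalized least squares with weights `1/(s_j^2 + tau2_res)`,
`tau2_res` by REML with the full moderator matrix. Prediction of the effect
at an age uses powers of `(age - centre)` — the derived moments matter only
for fitting, because the moderator is the *mean of a power*, not the
*power of the mean*; the fitted polynomial itself is a function of age.

**Centring.** Recentring refits the model; interaction coefficients agree
across centres to ~1e-10 and the intercept transforms as the fitted
polynomial. The intercept SE is minimised when the centre equals the
weight-weighted mean age (weights `1/(s_j^2 + tau2)`); the package's
`weighted_mean_age` helper uses plain inverse-variance weights `1/s_j^2`,
which in practice sits within a couple of years of the exact minimiser.

**Heterogeneity.** `Q` is the weighted residual sum of squares about the
fixed-effect-weighted (moderator) fit with weights `1/s_j^2`;
`I^2 = max(0, (Q - df)/Q) * 100` with `df = k - p`. For meta-regression these
are residual statistics, so comparing `I^2` before and after adding age
moderators measures how much heterogeneity the age trend explains. Note this
is the classical Q-based convention; some software (e.g. metafor) prints a
tau2-based pseudo-I^2 instead, which differs by a few points — coefficient
estimates, SEs, tau2 and Q themselves agree with metafor to printed precision
(cross-checked in the test suite).

**Confidence intervals** are Wald, `estimate ± 1.96*SE`. The Knapp–Hartung
small-sample adjustment (variance rescaling by the weighted residual mean
square, truncated at 1, with t critical values) is available via
`knapp_hartung=True` but off by default: the plain-Wald behaviour, including
its known under-coverage with few studies, is the behaviour this package is
meant to exhibit and measure.

## REML

`tau^2` maximises the restricted log-likelihood of
`y ~ N(X beta, diag(v) + tau2 I)`,

    -2 llR = sum(log(v_j + tau2)) + log|X' W X| + sum(w_j r_j^2),

profiled as a 1-D problem and solved by bounded derivative-free search on
`[0, 1e3 * max(v_j)]` with tolerance 1e-8; a boundary check returns exactly 0
when the unconstrained optimum is negative. The scalar search is verified
against a brute-force grid of the restricted likelihood (step 1e-4) and
against metafor. Under correlated errors (overlap adjustment) the same
criterion is evaluated on the Cholesky-whitened problem with
`V = Sigma + tau2 I`.

## Overlapping samples

When one cohort contributes effect estimates at several measurement
occasions, the rows share participants. The covariance of the estimates is
modelled block-diagonally: within a cohort,
`cov(b_j, b_k) = r_jk * s_j * s_k`, with `r_jk` either user-supplied or
defaulting to the shared-sample rule `min(n_j, n_k)/sqrt(n_j n_k)` (full
overlap of the smaller occasion sample). Fitting is GLS with weight matrix
`(Sigma + tau2 I)^-1`, which reduces exactly to the independent-rows fit for
diagonal `Sigma`. Non-PSD user blocks are projected to the nearest PSD matrix
(eigenvalue clipping) with a warning reporting the Frobenius-norm adjustment.
A singular weight matrix (perfectly redundant rows, r = 1) falls back to the
Moore–Penrose limit, which reproduces the deduplicated fit.

Two behaviours of this adjustment deserve emphasis:

* For equal-variance equicorrelated blocks the pooled variance is
  `s^2 (1 + (m-1) r)/m >= s^2/m`, so the adjusted pooled SE never falls below
  the naive one — the familiar "overlap inflates SEs" picture, tested in
  closed form.
* In general, however, GLS with strong positive within-cohort correlation can
  *tighten* moderator-coefficient SEs (highly correlated occasions make
  within-cohort age contrasts precise, as in a paired design), and with
  heterogeneous occasion variances even the pooled SE can shrink (a
  correlated imprecise row acts as a control variate for a precise one).
  These are properties of the model, not artefacts; users expecting uniform
  SE inflation should supply the correlation structure they believe and
  inspect both fits.

Heterogeneity statistics under the adjusted fit keep the independence-form Q
(weights `1/s_j^2`), so I^2 values remain comparable with unadjusted fits.

## Synthetic data

**Simulated collections** follow five generating mechanisms for a single
quantitative-trait SNP (age main effect; + linear interaction; + quadratic
age; both; + quadratic interaction), with base-case parameters: baseline 25,
age effect 0.010/yr, quadratic age 0.001/yr², per-allele effect 1.5, linear
interaction 0.020 per allele-year, quadratic interaction 0.001 per
allele-year², MAF 0.2, unit within- and between-study SDs, 40 studies of
1000, ages 10–59. The study-level deviation `u_j` shifts the SNP coefficient
only. Ages are continuous uniform on per-study windows; genotypes
Binomial(2, MAF); windows have equal width with equally spaced centres and an
adjacent-overlap fraction equal to the design's overlap percentage
(0/25/50/75/100), solving `width = range / (1 + (k-1)(1-f))`; 0% gives
disjoint windows (maximal age diversity), 100% identical full-range windows.
Explicit per-study windows can be supplied to reproduce any published layout.
One root seed spawns independent per-study substreams, so changing one
study's size perturbs no other study.

**The emulated cohort-by-occasion table** mimics an early-life FTO/BMI-style
input: 8 cohorts, baseline sizes 569–7482, up to 10 occasion ages in 0–13
years with 96–99% retention per wave (attrition makes occasion sizes differ,
so the shared-sample rule yields correlations strictly below 1), SEs scaling
as `1.5/sqrt(n)`, a cohort-level shift (SD 0.02) and positively correlated
occasion noise. The generating per-allele effect is the cubic
`-0.06 + 0.002a + 0.003a^2 - 0.00012a^3`: negative at ages 0–3, one sign
change near 4.5 years, positive at 5.5–13.

What passing tests on these data show: the estimators recover their own
generating mechanisms (internal validity), the moment derivations are exact
for the simulated age distributions, and the pipeline's qualitative applied
behaviour (sign change, heterogeneity absorbed by age moderators) is correct.
What they do not show: robustness to non-uniform age distributions beyond the
third-moment override, to assortative or stratified sampling, to binary
phenotypes, or to misreported summary statistics — real-data concerns outside
the generator's scope.

## Monte Carlo harness

Each experiment cell fixes (scenario, overlap, k, n, sigma_within,
sigma_between); estimators are fixed-effect MA, REML random-effects MA and
meta-regression of degree 1–3, centred at age 10 by default. Per estimand the
harness reports mean, bias, 95% CI coverage, empirical SE and mean reported
SE with Monte Carlo SEs (bias: EmpSE/sqrt(R); coverage: sqrt(p(1-p)/R);
EmpSE: EmpSE/sqrt(2(R-1))). Truths are computed from the generating
coefficients and the centre — re-expressing `b1*a + b2*a^2` about centre c
gives intercept `p(c)`, linear `b1 + 2c*b2`, quadratic `b2` — never entered
by hand (note the centred linear truth under the quadratic-interaction
scenario is 0.04, twice the raw coefficient). Estimator failures are tallied
per replicate, not silently dropped. Default replication is 500 per cell,
which resolves coverage to ±1% (binomial MC SE ≈ 0.0097) and runs a base-case
cell in ~10 s on one core; the full grid is a configuration change
(`run_grid` writes per-cell results and resumes by skipping completed cells,
with per-cell seeds spawned deterministically from the grid seed by position,
so a resumed run reproduces the uninterrupted one).

## Degenerate inputs and tie-breaks

* k below the number of coefficients + 1 → `InsufficientStudiesError`.
* All study mean ages equal with degree ≥ 1 → `CollinearityError` naming the
  offending columns (the low-age-diversity failure mode; rank tolerance
  1e-8 relative to the largest matrix entry).
* `se = 0` rows are rejected by the meta-analysis entry points (a perfect
  per-study fit reports `se = 0` and is flagged for upstream exclusion).
* REML at the boundary: the bounded optimiser can stall a hair above an exact
  zero optimum, so the criterion is re-evaluated at 0 and the boundary taken
  when not worse.
* I^2 is truncated at 0; tau2 at 0.

## Known limitations

Single-variant focus (no genome-wide looping, LD, or multi-SNP models);
quantitative phenotypes only; no splines (polynomials up to cubic); overlap
correlations are modelled, not estimated from individual-level data; Wald
intervals by default (see Knapp–Hartung above). The applied pipeline's
published-data mode expects a cohort × occasion table with effect, SE, n and
occasion age per row; occasion rows are treated as narrow age bands
(`sd_age = 0`) unless per-occasion age SDs are supplied.
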