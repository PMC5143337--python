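# Methods

This note documents the statistical procedures implemented in
`rankdecomp`, the conventions that make its identities exact, the design
of the synthetic data generator, and the limits of what the test suite
demonstrates.

## Indices and ranks

The package measures socioeconomic inequality of health with
rank-dependent indices: weighted sums of health levels with weights
derived from positions in the socioeconomic ordering. The base index is
the Generalized Concentration Index `GC = 2 Cov(h, d)` with
`d = f − ½` the fractional-rank deviation. The derived indices are
`C = GC/μ_h` (ratio-scale health), `W = (b−a)GC/((b−μ_h)(μ_h−a))` and
`E = 4GC/(b−a)` (bounded health). Only GC and E have multipliers free of
health predictors (weighting-function ignorability), so the regression
decompositions are applied to GC; C and W are computed as index values
only.

Conventions, chosen so that the product and covariance forms of GC agree
to machine precision and all decompositions are exactly additive:

- **Weighted fractional ranks.** Each block of tied score values receives
  the cumulative-weight midpoint `(W_below + W_block/2)/W_total`; at unit
  weights this is `(r_i − ½)/n` with average ranks on ties. The deviation
  vector is centred by subtracting the *weighted mean* of f, so the
  weighted mean of d is zero exactly in floating point, not just in exact
  arithmetic.
- **Population covariances.** Every covariance and variance uses
  denominator = total weight (no degrees-of-freedom correction).
- **Orientation.** No sign flip is applied for ill-health variables;
  interpreting a negative GC as a pro-poor burden is the caller's reading.
- **Degenerate inputs.** A zero-variance score yields all ranks ½ and a
  warning that any index is trivially zero; `n < 2`, non-finite scores and
  nonpositive weights are rejected.
- Both weighting conventions for the outer covariance of GC are exposed
  (`gc_covariance(..., use_weights=False)` computes the unweighted
  covariance of h with the weighted rank deviations); the default weighs
  both the ranks and the covariance, which is the convention every other
  identity in the package relies on.

## Decompositions

Decomposition (I) substitutes a fitted health equation into the product
form of GC: `GC = 2 Σ_j β_j Cov(x_j, d) + 2 Cov(ε̂, d)`. Decomposition
(II) is the mirror image through a fitted rank-deviation equation.
Decomposition (III) substitutes the bivariate multiple regression of both
h and d on a shared set s₁…s_p, splitting GC into p direct terms
`2 λ_j π_j Var(s_j)`, p(p−1)/2 combined terms
`2(λ_j π_g + λ_g π_j) Cov(s_j, s_g)` and a residual `2 Cov(ψ̂, χ̂)`.

Because each fit satisfies response = fitted + residual identically,
additivity (terms + residual = GC) is exact algebra for *any* coefficient
vector; with least-squares coefficients the cross-tab of (III) has row
totals equal to the decomposition-(I) terms and column totals equal to
the decomposition-(II) terms, and the three residuals coincide on a
shared regressor set. Percentage shares are taken relative to GC (which
may be negative), so a contribution with GC's sign has a positive share
and every table closes to 100 before rounding; shares are refused when
|GC| ≤ 1e−12. Reports print two decimals; CSV output keeps full
precision. When an equation omits a variable present in the other, the
report prints a dash, not a zero.

The GMM-based variant of (I) replaces the endogenous rank regressor by
its first-stage prediction: the contribution of d is
`2 β̂_k Cov(d̂, d)` and the residual is GC minus the sum of terms, no
longer zero-forced. Note `Cov(d̂, d) = Var(d̂)` is the first-stage
explained variance, so this contribution is structurally smaller than the
OLS term `2 β̂ Var(d)` by roughly the first-stage R² even without
endogeneity — that scaling is the point: only the part of d's effect
carried by the exogenous variables is attributed to d.

## Estimation

- **WLS** minimises the weighted residual sum of squares; weighted
  residuals are orthogonal to every regressor column. Rank-deficient
  designs raise an error naming the collinear columns.
- **Robust covariance**: HC0/HC1 sandwich on the sqrt-weight-transformed
  model; HC1 (the common econometrics default) multiplies by n/(n−k) and
  is the package default. The reported F statistic is the robust Wald
  test of all slopes against the intercept-only model.
- **Two-step GMM (H2SLS)** for equations with an endogenous regressor:
  instruments = all included exogenous regressors plus the declared
  excluded instruments; step 1 is 2SLS; the weight matrix is the
  uncentered outer product of step-1 residual-scaled moments; step 2
  re-estimates in that metric. Hansen's J is n times the step-2 criterion
  (df = #instruments − #parameters) and is reported as exactly 0 in the
  just-identified case, where the criterion is identically zero and the
  two steps coincide with 2SLS. The Cragg–Donald F is the weighted
  first-stage F on the excluded instruments, implemented for a single
  endogenous regressor; multiple endogenous regressors are out of scope
  and yield no statistic.
- Sampling weights are supported in every estimator and default to the
  dataset's weight column when present.

## The SEM workflow

The two-equation model allows different regressor sets for h and d and
mutual inclusion of the endogenous variables. Estimation is
limited-information, equation by equation; the order condition (at least
one excluded exogenous variable per equation containing an endogenous
regressor) is checked up front, and instruments are always user-declared
— instrument choice is judgement-based and not automated. The
recommended pipeline estimates both equations by GMM, then refits any
equation whose endogenous regressor is insignificant (two-sided robust
t, default α = 5%, configurable) by WLS without it; all refit decisions
are logged, making the workflow deterministic given data, spec and α.
Decomposition (III) is computed by WLS on the reduced-form regressor
union (h-equation exogenous variables first, then d-equation-only ones),
which is numerically identical to the bivariate multiple regression
route; the structural-to-reduced-form mapping
`λ_v = (β_v + β_k γ_v)/(1 − β_k γ_q)` (variables absent from an equation
are structural zeros; shared variables follow the summed-numerator rule)
is exposed separately and refuses β_k γ_q within 1e−8 of 1.

## The synthetic generator

The generator emulates a DHS-like child-malnutrition extract: age
(integer-uniform 0–59 months, plus the square of the weighted-centred
age as a derived regressor), sex ≈ Bern(0.514), urban residence ≈
Bern(0.1237), safe water and satisfactory sanitation Bernoulli with
urban-dependent rates hitting means ≈ 0.4614 and 0.1234, parental
education as zero-inflated geometric counts with means ≈ 1.34/2.74 years
(any nonnegative integer distribution matching the first moment would
do), and lognormal sampling weights with mean 1.

The wealth score is `v = γ₀ + Σ γ_g z_g + ξ` with coefficients of
survey-typical magnitude (urban residence the strongest wealth correlate,
then water and sanitation access, then parental education per year) and a
uniform error whose half-width is auto-calibrated
(window length = 1 − Gini mean difference of the linear predictor) so
the score's marginal distribution is close to uniform on a unit-length
interval — then the empirical percentile transform from score to
fractional rank is approximately affine. The health equation
`h* = β₀ + Σ β_j x_j + β_k d + ε` is generated from the *emitted* d
column, so its coefficients are exact estimands; `h = clip(h*, 0, 1)`
with the intercept calibrated so ~44% of children have a positive
ill-health score. Endogeneity is dialled by `ρ = Corr(ε, ξ)`, default
−0.5: unobserved deprivation raises ill-health and lowers wealth, which
also reproduces the qualitative pattern of interest (negative GC, an
OLS-with-d contribution exceeding the instrument-based one). The default
coefficients are illustrative of that pattern, not estimates of any
particular survey.

Two switches trade realism for exact linearity, and recovery tests use
them because censoring and ranking both break the linear model the
estimators assume:

- `censor=False` keeps the latent health score (the censored equation is
  otherwise misspecified for WLS/GMM);
- `rank_transform=False` emits d as the weighted-centred latent score
  rather than the fractional-rank deviations (the percentile transform
  attenuates the wealth-equation coefficients by roughly 10–18% at the
  default calibration; with the switch off the d equation is exactly
  linear). In the default mode the emitted d *is* the weighted
  fractional-rank deviation of the wealth column, satisfying all rank
  invariants.

With feedback (γ_q ≠ 0) the two equations are solved linearly per
individual in the latent score before ranking and censoring.

What passing tests therefore show: the identities, estimators and
workflow behave as designed on a process with independent, cleanly
distributed covariates and a single-level sampling design. What they do
not show: robustness to DHS survey design (clustering, stratification,
weight–outcome dependence), correlated measurement error in anthropometry,
or misspecification of the structural equations beyond censoring.

## Problem sizes and numerical tolerances

Identity checks run on 1000 random small datasets (n between 5 and 30)
at 1e−10 relative tolerance; calibration uses one draw of n = 100 000
(covariate means within ±0.01, stunted share within ±5 points);
reduced-form mapping checks use one draw of n = 200 000 with a 5-robust-SE
Monte-Carlo band; the recovery study uses 100 replicates of n = 20 000
(GMM mean within 3 empirical SDs of truth, OLS biased by more than 3 SDs,
instrument-based d contribution smaller in magnitude in ≥95% of
replicates); smaller distributional checks (null Cragg–Donald) use 200
replicates of n = 300. These sizes are the package's chosen compromise
between Monte-Carlo resolution and a test suite that runs in well under a
minute for the unit tests and a few tens of seconds for the acceptance
suite.

## Known limitations

- Indices come without standard errors or dominance tests; inference is
  provided for regression coefficients only.
- C and W are not decomposed (their weighting functions depend on mean
  health); level-dependent and latent-variable extensions are out of
  scope.
- The Cragg–Donald statistic covers one endogenous regressor per
  equation; LIML, continuously-updated GMM, clustered errors and panel
  estimators are not implemented.
- CSV is the only tabular input format; conversion from proprietary
  survey files, and the computation of anthropometric z-scores, are the
  user's task.
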