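# rankdecomp

Rank-dependent measurement of socioeconomic inequality of health, its
regression-based decompositions, and a two-equation structural (SEM)
estimation framework with two-step GMM — for health economists and
epidemiologists working with survey microdata (e.g. DHS child-malnutrition
extracts).

## The problem and the model

How unequally is (ill-)health distributed across the socioeconomic
spectrum? With an individual health level *h_i* and a fractional
socioeconomic rank *f_i* (position in the wealth ordering scaled to (0,1);
deviation *d_i = f_i − ½*), the **Generalized Concentration Index** is

```
GC = (2/n) Σ_i h_i d_i = 2 Cov(h, d)
```

positive when health advantage is concentrated among the better-off,
negative when the burden (for an ill-health score such as degree of
stunting) falls on the poor. The standard Concentration Index
`C = GC/μ_h`, Wagstaff's `W = (b−a)·GC/((b−μ_h)(μ_h−a))` and Erreygers'
`E = 4·GC/(b−a)` are scalings for ratio-scale and bounded health
variables. With sampling weights, ranks use the cumulative-weight-midpoint
rule with average ranks on ties, and all covariances are weighted
population covariances.

Three exact decompositions attribute GC to explanatory variables:

- **(I) health-oriented** — from `h = β₀ + Σ β_j x_j + ε`:
  `GC = 2 Σ β_j Cov(x_j, d) + 2 Cov(ε, d)`;
- **(II) rank-oriented** — from `d = γ₀ + Σ γ_g z_g + ξ`:
  `GC = 2 Σ γ_g Cov(h, z_g) + 2 Cov(h, ξ)`;
- **(III) two-dimensional simultaneous** — from the bivariate multiple
  regression of both *h* and *d* on a shared set *s₁…s_p*:
  `GC = 2 Σ λ_j π_j Var(s_j) + 2 Σ_{j<g} (λ_j π_g + λ_g π_j) Cov(s_j, s_g) + 2 Cov(ψ, χ)`.

Including *d* among the regressors for *h* (or *h* for *d*) forces the
residual of (I) (resp. (II)) to zero — a least-squares artefact, not an
explanation. To measure the genuine contribution of socioeconomic status
under health↔status feedback, the package estimates the two-equation
structural model

```
h = β₀ + Σ β_j x_j + β_k d + ε        d = γ₀ + Σ γ_g z_g + γ_q h + ξ
```

by per-equation two-step GMM (H2SLS) with user-declared excluded
instruments, reports White-robust t-statistics, Hansen's J and the
Cragg–Donald first-stage F, and computes decomposition (I) with the
first-stage *prediction* of d, so the residual is no longer zero-forced.
The model's reduced form — `λ_v = (β_v + β_k γ_v)/(1 − β_k γ_q)`,
`π_v = (γ_v + γ_q β_v)/(1 − β_k γ_q)` over the union of exogenous
variables — is exactly the bivariate regression behind decomposition
(III).

A seeded synthetic generator (`rankdecomp.synthgen`) draws DHS-like
datasets from this structural process with known coefficients, so every
estimator and decomposition is testable for recovery. See
`docs/methods.md` for modelling details and limitations.

## Worked example

```python
import rankdecomp as rd
from rankdecomp._weights import wmean
from rankdecomp.synthgen import GeneratorParams, generate

df, _ = generate(GeneratorParams(n=5000, seed=42))
w = df["weight"].to_numpy()
ranks = rd.fractional_ranks(df["wealth"].to_numpy(), w)
gc = rd.gc_product(df["h"].to_numpy(), ranks)
print(gc.value, rd.scale_index(gc, "E", wmean(df["h"], w), 0, 1).value)
```

prints `GC = -0.031019` and `E = -0.124075` (see `examples/01_indices.py`
for the full script): the ill-health burden in this draw is concentrated
among the poor. Running the SEM workflow on the same process
(`examples/03_sem_gmm.py`) prints

```
h equation (two-step GMM), coefficient on d:
  estimate -0.0941  (truth -0.1000, robust se 0.0158)
  Hansen J = 0.09 (df 1, p = 0.77) -> instruments valid
  Cragg-Donald F = 1758.7 -> instruments strong
decomposition (I), contribution of d and residual (share of GC):
  OLS with d:  d  105.04%   residual   -0.00%  (artefact: forced to zero)
  GMM + dhat:  d    5.29%   residual   92.29%
```

— least squares attributes the whole index to the rank variable and hides
the residual; the instrument-based route recovers the structural
coefficient and leaves an honest unexplained share. The other scripts in
`examples/` cover the three OLS decompositions (with the cross-tab and the
direct/combined split) and the generator's calibration report.

A thin CLI mirrors the library: `rankdecomp simulate | index | decompose
| sem --help`.

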