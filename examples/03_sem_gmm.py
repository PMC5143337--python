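"""SEM estimation with two-step GMM and the instrument-based decomposition.

Health and socioeconomic rank are modelled as jointly determined: the
health equation contains the rank deviation d (instrumented by residence
and sanitation), the wealth equation contains h (instrumented by the
child's demographics). The workflow estimates both equations by two-step
GMM, drops an endogenous regressor when it is insignificant, and computes
decomposition (I) with the first-stage prediction of d — so its residual
is no longer forced to zero, unlike the OLS-with-d route.
"""

import rankdecomp as rd
from rankdecomp.synthgen import DEFAULT_SEM_SPEC, GeneratorParams, generate

df, truth = generate(GeneratorParams(n=20_000, seed=3, censor=False))
w = df["weight"].to_numpy()

pipe = rd.sem_pipeline(DEFAULT_SEM_SPEC, df, weights=w)

fit_h = pipe.estimates.fit_h
print("h equation (two-step GMM), coefficient on d:")
print(f"  estimate {fit_h.coefficients['d']: .4f}  "
      f"(truth {truth.beta['d']: .4f}, robust se {fit_h.robust_se['d']:.4f})")
j = fit_h.diagnostics["hansen_J"]
cd = fit_h.diagnostics["cragg_donald_F"]
print(f"  Hansen J = {j['stat']:.2f} (df {j['df']}, p = {j['p_value']:.2f}) "
      f"-> instruments valid")
print(f"  Cragg-Donald F = {cd['stat']:.1f} -> instruments strong")
print()
for line in pipe.log:
    print("workflow:", line)
print()

X = rd.add_constant(df[list(DEFAULT_SEM_SPEC.h_regressors)].copy())
X["d"] = df["d"].to_numpy()
fit_ols = rd.wls_fit(rd.DesignMatrix(df["h"], X, w))
dec_ols = rd.decompose_health(fit_ols, df["d"].to_numpy(), w)
dec_gmm = pipe.decomposition_I
print("decomposition (I), contribution of d and residual (share of GC):")
print(f"  OLS with d:  d {dec_ols.percentages['d']:7.2f}%   "
      f"residual {dec_ols.residual_pct:7.2f}%  (artefact: forced to zero)")
print(f"  GMM + dhat:  d {dec_gmm.percentages['d']:7.2f}%   "
      f"residual {dec_gmm.residual_pct:7.2f}%")
print()
print("The OLS route attributes the whole index to d; the instrument-based")
print("route measures only the part of d's contribution carried by the")
print("exogenous variables, leaving an honest residual.")
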