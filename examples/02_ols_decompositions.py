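"""The three OLS-based decompositions of GC, and the zero-residual artefact.

Decomposition (I) explains GC through a regression of health on
covariates, (II) through a regression of the rank deviation d, and (III)
through the bivariate multiple regression of both on a shared covariate
set. Including d itself in the health regression forces the residual to
zero — the index is then 'explained' by one of its own components, which
is why the comparison of the two residual columns matters.
"""

import pandas as pd

import rankdecomp as rd
from rankdecomp.synthgen import DEFAULT_SEM_SPEC, GeneratorParams, generate

df, _ = generate(GeneratorParams(n=20_000, seed=1))
w = df["weight"].to_numpy()
h, d = df["h"], df["d"]
covs = list(DEFAULT_SEM_SPEC.union)

X = rd.add_constant(df[covs].copy())
fit_h = rd.wls_fit(rd.DesignMatrix(h, X, w))
fit_d = rd.wls_fit(rd.DesignMatrix(d, X.copy(), w))
Xd = X.copy()
Xd["d"] = d.to_numpy()
fit_h_incl = rd.wls_fit(rd.DesignMatrix(h, Xd, w))

dec1 = rd.decompose_health(fit_h, d.to_numpy(), w)
dec1_incl = rd.decompose_health(fit_h_incl, d.to_numpy(), w)
dec2 = rd.decompose_rank(fit_d, h.to_numpy(), w)
dec3, crosstab, dc = rd.decompose_simultaneous(fit_h, fit_d)

table = pd.DataFrame(
    {
        "(I) excl d": dec1.percentages,
        "(I) incl d": dec1_incl.percentages,
        "(II) excl h": dec2.percentages,
        "(III)": dec3.percentages,
    }
)
table.loc["residual"] = [
    dec1.residual_pct,
    dec1_incl.residual_pct,
    dec2.residual_pct,
    dec3.residual_pct,
]
table.loc["total"] = table.sum()
print(f"GC = {dec1.index_value:.6f}; percentage contributions:\n")
print(table.round(2).fillna("—"))
print()
print("Note the zero residual in '(I) incl d': an artefact of regressing")
print("the index on its own rank component. The residual shares of")
print("(I) excl d, (II) excl h and (III) coincide — an exact identity on")
print("a shared regressor set.")
print(f"\nDecomposition (III) split: direct {dc.direct_total:.2f}%, "
      f"combined {dc.combined_total:.2f}%, residual {dc.residual_pct:.2f}%")
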