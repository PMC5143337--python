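"""Two-equation structural model for health and socioeconomic rank.

The structural system allows mutual causation (feedback) between an
(ill-)health variable h and the fractional socioeconomic rank deviation d:

    h_i = beta_0 + sum_j beta_j x_{j,i} + beta_k d_i + eps_i
    d_i = gamma_0 + sum_g gamma_g z_{g,i} + gamma_q h_i + xi_i

Both h and d are endogenous, so each equation containing the other
endogenous variable is estimated by single-equation two-step GMM with
user-declared excluded instruments (limited-information estimation,
equation by equation). A necessary order condition is that each such
equation has at least one exogenous variable not present in the other
equation.

Provided beta_k * gamma_q != 1 the system can be solved for the reduced
form, in which each endogenous variable depends on the union of exogenous
variables only:

    lambda_v = (beta_v + beta_k * gamma_v) / (1 - beta_k * gamma_q)
    pi_v     = (gamma_v + gamma_q * beta_v) / (1 - beta_k * gamma_q)

(a variable absent from an equation has a structural coefficient of zero).
The reduced form is exactly the bivariate multiple regression underlying
the two-dimensional decomposition (III), which is how the simultaneous
decomposition inherits the feedback structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decomp import (
    DecompositionResult,
    decompose_health,
    decompose_rank,
    decompose_simultaneous,
    gmm_decompose_health,
    gmm_decompose_rank,
)
from .errors import EstimationError, IdentificationError
from .regress import (
    CONST,
    DesignMatrix,
    FitResult,
    add_constant,
    first_stage_predict,
    gmm_iv_fit,
    wls_fit,
)

__all__ = [
    "SEMSpec",
    "StructuralEstimates",
    "ReducedForm",
    "check_identification",
    "estimate_sem",
    "reduced_form",
    "sem_pipeline",
    "SEMPipelineResult",
]


@dataclass(frozen=True)
class SEMSpec:
    """Specification of the two structural equations.

    ``h_regressors`` / ``d_regressors`` list the exogenous columns of each
    equation (the intercept is implicit). ``include_d_in_h`` /
    ``include_h_in_d`` control whether the other endogenous variable enters.
    ``instruments_for_h`` are the excluded exogenous columns instrumenting d
    in the h equation; ``instruments_for_d`` instrument h in the d equation.
    """

    h_regressors: tuple[str, ...]
    d_regressors: tuple[str, ...]
    instruments_for_h: tuple[str, ...] = ()
    instruments_for_d: tuple[str, ...] = ()
    include_d_in_h: bool = True
    include_h_in_d: bool = True

    def __post_init__(self):
        for name in ("h_regressors", "d_regressors", "instruments_for_h", "instruments_for_d"):
            object.__setattr__(self, name, tuple(getattr(self, name)))

    @property
    def union(self) -> tuple[str, ...]:
        """Deterministic reduced-form regressor union: h-equation exogenous
        first, then d-equation-only exogenous (instruments included)."""
        seen = []
        for name in (
            list(self.h_regressors)
            + list(self.instruments_for_h)
            + list(self.d_regressors)
            + list(self.instruments_for_d)
        ):
            if name not in seen:
                seen.append(name)
        return tuple(seen)


@dataclass(frozen=True)
class StructuralEstimates:
    """Per-equation coefficient vectors and fit results."""

    beta: pd.Series  # h equation (incl. const and, when present, "d")
    gamma: pd.Series  # d equation (incl. const and, when present, "h")
    fit_h: FitResult
    fit_d: FitResult


@dataclass(frozen=True)
class ReducedForm:
    """Reduced-form coefficients over the exogenous-regressor union.

    The reduced-form errors are psi = (eps + beta_k * xi) / (1 - beta_k *
    gamma_q) and chi = (xi + gamma_q * eps) / (1 - beta_k * gamma_q).
    """

    lam: pd.Series
    pi: pd.Series
    regressors: tuple[str, ...]


def check_identification(spec: SEMSpec) -> None:
    """Order-condition check; raises IdentificationError naming the
    under-identified equation."""
    if spec.include_d_in_h and len(spec.instruments_for_h) < 1:
        raise IdentificationError(
            "h equation includes the endogenous rank deviation d but declares "
            "no excluded instrument; each equation with an endogenous "
            "regressor needs at least one exogenous variable absent from it"
        )
    if spec.include_h_in_d and len(spec.instruments_for_d) < 1:
        raise IdentificationError(
            "d equation includes the endogenous health variable h but "
            "declares no excluded instrument"
        )
    bad_h = set(spec.instruments_for_h) & set(spec.h_regressors)
    if bad_h:
        raise IdentificationError(
            f"instrument(s) {sorted(bad_h)} already appear as regressors in the h equation"
        )
    bad_d = set(spec.instruments_for_d) & set(spec.d_regressors)
    if bad_d:
        raise IdentificationError(
            f"instrument(s) {sorted(bad_d)} already appear as regressors in the d equation"
        )


def _equation_fit(
    data: pd.DataFrame,
    response: str,
    exog: tuple[str, ...],
    endog_col: str | None,
    instruments: tuple[str, ...],
    weights,
) -> FitResult:
    X = add_constant(data[list(exog)].copy())
    if endog_col is not None:
        X[endog_col] = data[endog_col].to_numpy()
        design = DesignMatrix(data[response], X, weights, name=response)
        return gmm_iv_fit(design, [endog_col], data[list(instruments)])
    design = DesignMatrix(data[response], X, weights, name=response)
    return wls_fit(design)


def estimate_sem(
    spec: SEMSpec,
    data: pd.DataFrame,
    weights=None,
    h_col: str = "h",
    d_col: str = "d",
) -> StructuralEstimates:
    """Estimate each structural equation.

    Equations containing the other endogenous variable are estimated by
    two-step GMM with instrument set = own exogenous regressors plus the
    declared excluded instruments; equations without an endogenous
    regressor fall back to WLS.
    """
    check_identification(spec)
    try:
        fit_h = _equation_fit(
            data,
            h_col,
            spec.h_regressors,
            d_col if spec.include_d_in_h else None,
            spec.instruments_for_h,
            weights,
        )
    except EstimationError as exc:
        raise EstimationError(f"h equation: {exc}") from exc
    try:
        fit_d = _equation_fit(
            data,
            d_col,
            spec.d_regressors,
            h_col if spec.include_h_in_d else None,
            spec.instruments_for_d,
            weights,
        )
    except EstimationError as exc:
        raise EstimationError(f"d equation: {exc}") from exc
    return StructuralEstimates(
        beta=fit_h.coefficients, gamma=fit_d.coefficients, fit_h=fit_h, fit_d=fit_d
    )


def reduced_form(
    est: StructuralEstimates | tuple[pd.Series, pd.Series],
    spec: SEMSpec,
    h_col: str = "h",
    d_col: str = "d",
    tol: float = 1e-8,
) -> ReducedForm:
    """Map structural coefficients (beta, gamma) to reduced-form (lambda, pi).

    Coefficients of variables absent from an equation are structural zeros;
    a variable shared by both equations follows the summed-numerator rule
    lambda = (beta + beta_k * gamma) / (1 - beta_k * gamma_q).
    """
    if isinstance(est, StructuralEstimates):
        beta, gamma = est.beta, est.gamma
    else:
        beta, gamma = est
    beta_k = float(beta.get(d_col, 0.0))
    gamma_q = float(gamma.get(h_col, 0.0))
    denom = 1.0 - beta_k * gamma_q
    if abs(denom) < tol:
        raise EstimationError(
            f"reduced form is singular: beta_k * gamma_q = {beta_k * gamma_q:.6g} "
            "is within tolerance of 1"
        )
    union = spec.union
    lam = {CONST: (float(beta.get(CONST, 0.0)) + beta_k * float(gamma.get(CONST, 0.0))) / denom}
    pi = {CONST: (float(gamma.get(CONST, 0.0)) + gamma_q * float(beta.get(CONST, 0.0))) / denom}
    for v in union:
        b = float(beta.get(v, 0.0))
        g = float(gamma.get(v, 0.0))
        lam[v] = (b + beta_k * g) / denom
        pi[v] = (g + gamma_q * b) / denom
    index = [CONST] + list(union)
    return ReducedForm(
        lam=pd.Series(lam).reindex(index),
        pi=pd.Series(pi).reindex(index),
        regressors=union,
    )


@dataclass(frozen=True)
class SEMPipelineResult:
    """Full workflow output: structural estimates, the three decompositions,
    reduced-form fits, and a log of every refit decision."""

    estimates: StructuralEstimates
    final_fit_h: FitResult
    final_fit_d: FitResult
    decomposition_I: DecompositionResult
    decomposition_II: DecompositionResult
    decomposition_III: DecompositionResult
    crosstab: "pd.DataFrame | object"
    direct_combined: object
    reduced_form_fit_h: FitResult
    reduced_form_fit_d: FitResult
    log: tuple[str, ...]


def sem_pipeline(
    spec: SEMSpec,
    data: pd.DataFrame,
    weights=None,
    h_col: str = "h",
    d_col: str = "d",
    alpha: float = 0.05,
) -> SEMPipelineResult:
    """Recommended decomposition workflow under possible h<->d feedback.

    1. Estimate both structural equations by two-step GMM (WLS where no
       endogenous regressor is present).
    2. For each GMM equation whose endogenous regressor is insignificant at
       ``alpha`` (two-sided robust t), refit by WLS without it.
    3. Decomposition (I): from the h equation — the GMM variant with the
       first-stage prediction of d when d was kept, otherwise plain WLS.
    4. Decomposition (II): symmetric treatment of the d equation.
    5. Decomposition (III): WLS of both h and d on the reduced-form
       regressor union (the bivariate multiple regression).
    """
    est = estimate_sem(spec, data, weights, h_col=h_col, d_col=d_col)
    log: list[str] = []
    crit = stats.norm.ppf(1 - alpha / 2)

    fit_h = est.fit_h
    if spec.include_d_in_h:
        t_d = float(fit_h.t_stats[d_col])
        if abs(t_d) < crit:
            log.append(
                f"h equation: endogenous regressor '{d_col}' insignificant "
                f"(|t|={abs(t_d):.2f} < {crit:.2f}); refit by WLS without it"
            )
            X = add_constant(data[list(spec.h_regressors)].copy())
            fit_h = wls_fit(DesignMatrix(data[h_col], X, weights, name=h_col))
        else:
            log.append(
                f"h equation: endogenous regressor '{d_col}' kept "
                f"(|t|={abs(t_d):.2f} >= {crit:.2f}); GMM fit used"
            )

    fit_d = est.fit_d
    if spec.include_h_in_d:
        t_h = float(fit_d.t_stats[h_col])
        if abs(t_h) < crit:
            log.append(
                f"d equation: endogenous regressor '{h_col}' insignificant "
                f"(|t|={abs(t_h):.2f} < {crit:.2f}); refit by WLS without it"
            )
            X = add_constant(data[list(spec.d_regressors)].copy())
            fit_d = wls_fit(DesignMatrix(data[d_col], X, weights, name=d_col))
        else:
            log.append(
                f"d equation: endogenous regressor '{h_col}' kept "
                f"(|t|={abs(t_h):.2f} >= {crit:.2f}); GMM fit used"
            )

    d_vec = data[d_col].to_numpy(dtype=float)
    h_vec = data[h_col].to_numpy(dtype=float)
    w = fit_h.design.weights

    # decomposition (I)
    if fit_h.method == "GMM2STEP":
        Zfull = add_constant(
            data[list(spec.h_regressors) + list(spec.instruments_for_h)].copy()
        )
        dhat = first_stage_predict(d_vec, Zfull, weights)
        dec1 = gmm_decompose_health(fit_h, dhat, d_vec, w, endogenous=d_col)
    else:
        dec1 = decompose_health(fit_h, d_vec, w)

    # decomposition (II)
    if fit_d.method == "GMM2STEP":
        Zfull = add_constant(
            data[list(spec.d_regressors) + list(spec.instruments_for_d)].copy()
        )
        hhat = first_stage_predict(h_vec, Zfull, weights)
        dec2 = gmm_decompose_rank(fit_d, hhat, h_vec, w, endogenous=h_col)
    else:
        dec2 = decompose_rank(fit_d, h_vec, w)

    # decomposition (III) via WLS on the reduced-form union
    union = list(spec.union)
    Xu = add_constant(data[union].copy())
    rf_h = wls_fit(DesignMatrix(data[h_col], Xu, weights, name=h_col))
    rf_d = wls_fit(DesignMatrix(data[d_col], Xu.copy(), weights, name=d_col))
    dec3, crosstab, direct_combined = decompose_simultaneous(rf_h, rf_d)

    return SEMPipelineResult(
        estimates=est,
        final_fit_h=fit_h,
        final_fit_d=fit_d,
        decomposition_I=dec1,
        decomposition_II=dec2,
        decomposition_III=dec3,
        crosstab=crosstab,
        direct_combined=direct_combined,
        reduced_form_fit_h=rf_h,
        reduced_form_fit_d=rf_d,
        log=tuple(log),
    )
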