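"""Regression-based decompositions of the Generalized Concentration Index.

Three decompositions are provided, all exact algebraic identities when the
fitted equation(s) reproduce the response as fitted + residual:

(I)  health-oriented: from a regression of h on x_1..x_k,
         GC = 2 sum_j beta_j Cov(x_j, d) + 2 Cov(eps_hat, d)

(II) rank-oriented: from a regression of d on z_1..z_q,
         GC = 2 sum_g gamma_g Cov(h, z_g) + 2 Cov(h, xi_hat)

(III) two-dimensional simultaneous: from the bivariate multiple regression
      of h and d on a shared set s_1..s_p,
         GC = 2 sum_j lambda_j pi_j Var(s_j)
            + 2 sum_{j<g} (lambda_j pi_g + lambda_g pi_j) Cov(s_j, s_g)
            + 2 Cov(psi_hat, chi_hat)

All covariances use the weighted-population convention of
:mod:`rankdecomp.ranks`, which makes term + residual additivity exact.

A well-known artefact: including d itself among the regressors for h (or h
among the regressors for d) forces the residual of decomposition (I)
(resp. (II)) to zero under least squares — the index is then "explained"
by one of its own components. The GMM-based variant
(:func:`gmm_decompose_health`) replaces d by its first-stage prediction,
so the residual is no longer zero-forced and the contribution of the
socioeconomic rank is measured against instruments only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._weights import as_weights, wcov
from .ranks import HealthVector, RankStructure
from .regress import CONST, FitResult

__all__ = [
    "DecompositionResult",
    "CrossTab",
    "DirectCombinedSummary",
    "decompose_health",
    "decompose_rank",
    "decompose_simultaneous",
    "percentages",
    "gmm_decompose_health",
    "gmm_decompose_rank",
]

PCT_TOL = 1e-12


@dataclass(frozen=True)
class DecompositionResult:
    """Named level contributions to GC, their residual, and shares.

    Percentages are relative to the (possibly negative) GC, so a
    contribution with the same sign as GC has a positive share; shares sum
    to 100 exactly before rounding. ``percentages`` is None until
    :func:`percentages` has been applied (it is applied on construction
    whenever |GC| is above tolerance).
    """

    kind: str  # "I", "II" or "III"
    index_value: float
    terms: pd.Series
    residual: float
    method: str
    n: int
    weighted: bool
    percentages: pd.Series | None = None
    residual_pct: float | None = None

    @property
    def total(self) -> float:
        return float(self.terms.sum() + self.residual)


@dataclass(frozen=True)
class CrossTab:
    """(p+1) x (p+1) cross-tabulation of decomposition (III).

    Cell (j, g) holds the share 2 lambda_j pi_g Cov(s_j, s_g) / GC * 100;
    the extra row/column carry the single residual cell
    2 Cov(psi_hat, chi_hat). Row totals reproduce decomposition (I) from
    the reduced form, column totals decomposition (II); the grand total
    is 100%.
    """

    matrix: pd.DataFrame  # shares in percent, incl. residual row/col
    row_totals: pd.Series
    col_totals: pd.Series
    grand_total: float


@dataclass(frozen=True)
class DirectCombinedSummary:
    """Direct vs combined (correlated) split of decomposition (III).

    ``direct`` holds the p single-variable shares 2 lambda_j pi_j Var(s_j);
    ``combined`` is the strict lower triangle of two-variable shares
    2 (lambda_j pi_g + lambda_g pi_j) Cov(s_j, s_g), j > g.
    """

    direct: pd.Series
    combined: pd.DataFrame
    direct_total: float
    combined_total: float
    residual_pct: float

    @property
    def total(self) -> float:
        return self.direct_total + self.combined_total + self.residual_pct


def _health_array(h) -> np.ndarray:
    return h.h if isinstance(h, HealthVector) else np.asarray(h, dtype=float)


def _rank_array(ranks) -> np.ndarray:
    return ranks.d if isinstance(ranks, RankStructure) else np.asarray(ranks, dtype=float)


def _with_percentages(res: DecompositionResult) -> DecompositionResult:
    if abs(res.index_value) <= PCT_TOL:
        return res
    return percentages(res)


def percentages(result: DecompositionResult) -> DecompositionResult:
    """Express each contribution as a share of GC in percent."""
    gc = result.index_value
    if abs(gc) <= PCT_TOL:
        raise ValueError(
            "percentage shares are undefined: the index value is "
            f"{gc!r}, within tolerance of zero"
        )
    pct = 100.0 * result.terms / gc
    res_pct = 100.0 * result.residual / gc
    return DecompositionResult(
        kind=result.kind,
        index_value=gc,
        terms=result.terms,
        residual=result.residual,
        method=result.method,
        n=result.n,
        weighted=result.weighted,
        percentages=pct,
        residual_pct=res_pct,
    )


def _linear_decomposition(
    fit: FitResult, other: np.ndarray, weights: np.ndarray, kind: str
) -> DecompositionResult:
    """Shared core of decompositions (I) and (II).

    term_j = 2 * coef_j * Cov(x_j, other); residual = 2 Cov(resid, other).
    The intercept contributes exactly zero and is omitted from the terms.
    """
    X = fit.design.regressors
    w = weights
    terms = {}
    for col in X.columns:
        if col == CONST:
            continue
        terms[col] = 2.0 * fit.coefficients[col] * wcov(X[col].to_numpy(), other, w)
    residual = 2.0 * wcov(fit.residuals, other, w)
    gc = 2.0 * wcov(fit.design.response.to_numpy() if kind == "I" else other,
                    other if kind == "I" else fit.design.response.to_numpy(), w)
    return _with_percentages(
        DecompositionResult(
            kind=kind,
            index_value=gc,
            terms=pd.Series(terms, dtype=float),
            residual=residual,
            method=fit.method,
            n=fit.nobs,
            weighted=bool(np.ptp(w) > 0),
        )
    )


def decompose_health(fit_h: FitResult, ranks, weights=None) -> DecompositionResult:
    """Health-oriented decomposition (I) from a least-squares fit of h."""
    d = _rank_array(ranks)
    if len(d) != fit_h.nobs:
        raise ValueError("rank structure and fitted equation sample sizes differ")
    w = as_weights(weights, fit_h.nobs) if weights is not None else (
        ranks.w if isinstance(ranks, RankStructure) else fit_h.design.weights
    )
    return _linear_decomposition(fit_h, d, w, kind="I")


def decompose_rank(fit_d: FitResult, h, weights=None) -> DecompositionResult:
    """Rank-oriented decomposition (II) from a least-squares fit of d."""
    hv = _health_array(h)
    if len(hv) != fit_d.nobs:
        raise ValueError("health vector and fitted equation sample sizes differ")
    w = as_weights(weights, fit_d.nobs) if weights is not None else fit_d.design.weights
    return _linear_decomposition(fit_d, hv, w, kind="II")


def _shared_regressor_names(fit_h: FitResult, fit_d: FitResult) -> list[str]:
    cols_h = [c for c in fit_h.design.regressors.columns if c != CONST]
    cols_d = [c for c in fit_d.design.regressors.columns if c != CONST]
    if cols_h != cols_d:
        raise ValueError(
            "decomposition (III) requires both equations to share an identical "
            f"regressor set; got {cols_h} vs {cols_d}. For structural models "
            "with different regressor sets, map to the common reduced form "
            "first (see rankdecomp.sem.reduced_form)."
        )
    return cols_h


def decompose_simultaneous(
    fit_h: FitResult, fit_d: FitResult
) -> tuple[DecompositionResult, CrossTab, DirectCombinedSummary]:
    """Two-dimensional simultaneous decomposition (III).

    ``fit_h`` and ``fit_d`` must be least-squares fits of h and d on the
    identical regressor set (the bivariate multiple regression, equal to
    the reduced form of the two-equation structural model).
    """
    names = _shared_regressor_names(fit_h, fit_d)
    if fit_h.nobs != fit_d.nobs:
        raise ValueError("the two equations were fitted on different sample sizes")
    w = fit_h.design.weights
    S = fit_h.design.regressors[names]
    lam = fit_h.coefficients
    pi = fit_d.coefficients
    p = len(names)

    # weighted population covariance matrix of the shared regressors
    cov_s = np.empty((p, p))
    arr = S.to_numpy()
    W = w.sum()
    means = (w @ arr) / W
    centered = arr - means
    cov_s = (centered * w[:, None]).T @ centered / W

    cells = np.empty((p, p))
    for j in range(p):
        for g in range(p):
            cells[j, g] = 2.0 * lam[names[j]] * pi[names[g]] * cov_s[j, g]
    residual = 2.0 * wcov(fit_h.residuals, fit_d.residuals, w)

    singles = pd.Series({names[j]: cells[j, j] for j in range(p)})
    pairs_total = float(cells.sum() - np.trace(cells))
    gc = 2.0 * wcov(
        fit_h.design.response.to_numpy(), fit_d.design.response.to_numpy(), w
    )

    terms = singles.copy()
    terms["(combined)"] = pairs_total
    result = _with_percentages(
        DecompositionResult(
            kind="III",
            index_value=gc,
            terms=terms,
            residual=residual,
            method=f"{fit_h.method}+{fit_d.method}",
            n=fit_h.nobs,
            weighted=bool(np.ptp(w) > 0),
        )
    )

    crosstab, summary = _crosstab_and_summary(names, cells, residual, gc)
    return result, crosstab, summary


def _crosstab_and_summary(names, cells, residual, gc):
    if abs(gc) <= PCT_TOL:
        raise ValueError(
            "percentage cross-tabulation undefined: index value within "
            "tolerance of zero"
        )
    p = len(names)
    share = 100.0 / gc
    mat = pd.DataFrame(0.0, index=list(names) + ["residual"], columns=list(names) + ["residual"])
    mat.iloc[:p, :p] = cells * share
    mat.loc["residual", "residual"] = residual * share
    row_totals = mat.sum(axis=1)
    col_totals = mat.sum(axis=0)
    crosstab = CrossTab(
        matrix=mat,
        row_totals=row_totals,
        col_totals=col_totals,
        grand_total=float(mat.to_numpy().sum()),
    )

    direct = pd.Series({names[j]: cells[j, j] * share for j in range(p)})
    combined = pd.DataFrame(np.nan, index=names, columns=names)
    for j in range(p):
        for g in range(j):
            combined.iloc[j, g] = (cells[j, g] + cells[g, j]) * share
    combined_total = float(np.nansum(combined.to_numpy()))
    summary = DirectCombinedSummary(
        direct=direct,
        combined=combined,
        direct_total=float(direct.sum()),
        combined_total=combined_total,
        residual_pct=residual * share,
    )
    return crosstab, summary


def gmm_decompose_health(
    fit_h_gmm: FitResult,
    dhat: np.ndarray,
    ranks,
    weights=None,
    endogenous: str = "d",
) -> DecompositionResult:
    """Decomposition (I) from a GMM fit with an endogenous rank regressor.

    The contribution of the endogenous column is 2 * beta_k * Cov(dhat, d),
    with ``dhat`` the first-stage prediction of d on all exogenous
    variables and instruments; the other terms follow decomposition (I).
    The residual is GC minus the sum of terms and is no longer forced to
    zero.
    """
    d = _rank_array(ranks)
    dhat = np.asarray(dhat, dtype=float)
    if len(dhat) != fit_h_gmm.nobs:
        raise ValueError("first-stage prediction sample size differs from the fit")
    w = as_weights(weights, fit_h_gmm.nobs) if weights is not None else (
        ranks.w if isinstance(ranks, RankStructure) else fit_h_gmm.design.weights
    )
    X = fit_h_gmm.design.regressors
    if endogenous not in X.columns:
        raise ValueError(f"endogenous column {endogenous!r} not in the fitted equation")
    terms = {}
    for col in X.columns:
        if col == CONST:
            continue
        if col == endogenous:
            terms[col] = 2.0 * fit_h_gmm.coefficients[col] * wcov(dhat, d, w)
        else:
            terms[col] = 2.0 * fit_h_gmm.coefficients[col] * wcov(
                X[col].to_numpy(), d, w
            )
    gc = 2.0 * wcov(fit_h_gmm.design.response.to_numpy(), d, w)
    terms = pd.Series(terms, dtype=float)
    residual = gc - float(terms.sum())
    return _with_percentages(
        DecompositionResult(
            kind="I",
            index_value=gc,
            terms=terms,
            residual=residual,
            method=fit_h_gmm.method,
            n=fit_h_gmm.nobs,
            weighted=bool(np.ptp(w) > 0),
        )
    )


def gmm_decompose_rank(
    fit_d_gmm: FitResult,
    hhat: np.ndarray,
    h,
    weights=None,
    endogenous: str = "h",
) -> DecompositionResult:
    """Decomposition (II) from a GMM fit with an endogenous health regressor.

    Mirror image of :func:`gmm_decompose_health`: the contribution of the
    endogenous health column is 2 * gamma_q * Cov(hhat, h).
    """
    hv = _health_array(h)
    hhat = np.asarray(hhat, dtype=float)
    if len(hhat) != fit_d_gmm.nobs:
        raise ValueError("first-stage prediction sample size differs from the fit")
    w = as_weights(weights, fit_d_gmm.nobs) if weights is not None else fit_d_gmm.design.weights
    X = fit_d_gmm.design.regressors
    if endogenous not in X.columns:
        raise ValueError(f"endogenous column {endogenous!r} not in the fitted equation")
    terms = {}
    for col in X.columns:
        if col == CONST:
            continue
        if col == endogenous:
            terms[col] = 2.0 * fit_d_gmm.coefficients[col] * wcov(hhat, hv, w)
        else:
            terms[col] = 2.0 * fit_d_gmm.coefficients[col] * wcov(
                X[col].to_numpy(), hv, w
            )
    gc = 2.0 * wcov(fit_d_gmm.design.response.to_numpy(), hv, w)
    terms = pd.Series(terms, dtype=float)
    residual = gc - float(terms.sum())
    return _with_percentages(
        DecompositionResult(
            kind="II",
            index_value=gc,
            terms=terms,
            residual=residual,
            method=fit_d_gmm.method,
            n=fit_d_gmm.nobs,
            weighted=bool(np.ptp(w) > 0),
        )
    )
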