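"""Estimation engines: weighted least squares with heteroskedasticity-robust
inference, and single-equation instrumental-variables two-step GMM.

The two-step GMM estimator (also known as heteroskedastic two-stage least
squares, H2SLS) uses 2SLS as the first step, builds the moment weight
matrix from the first-step residual-scaled instrument outer products
(uncentered), and re-estimates in that metric.  Hansen's J over-
identification statistic and the Cragg-Donald first-stage F for weak
instruments are reported as diagnostics.

Sampling weights are supported throughout: the fit minimises the weighted
sum of squared residuals, and the GMM moments are weighted sample moments.
Robust covariances are HC0/HC1 sandwiches on the sqrt-weight-transformed
model (HC1 applies the n/(n-k) small-sample factor, the common default of
econometrics packages).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._weights import as_weights
from .errors import EstimationError, IdentificationError

__all__ = [
    "DesignMatrix",
    "FitResult",
    "wls_fit",
    "robust_covariance",
    "gmm_iv_fit",
    "first_stage_predict",
    "add_constant",
]

CONST = "const"


def add_constant(X: pd.DataFrame, name: str = CONST) -> pd.DataFrame:
    """Prepend an explicit named intercept column if not present."""
    if name in X.columns:
        return X
    out = X.copy()
    out.insert(0, name, 1.0)
    return out


@dataclass(frozen=True)
class DesignMatrix:
    """Response, named regressor matrix and weights for one equation.

    The intercept, when wanted, is an explicit column (conventionally named
    ``"const"``); nothing is added implicitly.
    """

    response: pd.Series
    regressors: pd.DataFrame
    weights: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        y = pd.Series(self.response, dtype=float)
        X = pd.DataFrame(self.regressors).astype(float)
        if len(y) != len(X):
            raise ValueError("response and regressor matrix lengths differ")
        if X.columns.duplicated().any():
            dupes = sorted(set(X.columns[X.columns.duplicated()]))
            raise EstimationError(f"duplicate regressor column(s): {dupes}")
        w = as_weights(self.weights, len(y))
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "regressors", X)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def k(self) -> int:
        return self.regressors.shape[1]


@dataclass(frozen=True)
class FitResult:
    """Coefficients, fit diagnostics and robust inference for one equation."""

    coefficients: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    robust_cov: pd.DataFrame
    robust_se: pd.Series
    t_stats: pd.Series
    r_squared: float
    f_stat: float
    method: str  # "WLS" or "GMM2STEP"
    robust_variant: str
    nobs: int
    design: DesignMatrix
    diagnostics: dict = field(default_factory=dict)

    @property
    def p_values(self) -> pd.Series:
        """Two-sided normal p-values of the robust t-statistics."""
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.t_stats.to_numpy())),
            index=self.t_stats.index,
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "robust_se": self.robust_se,
                "t_stat": self.t_stats,
                "p_value": self.p_values,
            }
        )


def _check_full_rank(X: pd.DataFrame, w: np.ndarray) -> None:
    Xw = X.to_numpy() * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # identify offending columns: those lying in the span of the others
        bad = []
        arr = Xw
        for j, col in enumerate(X.columns):
            others = np.delete(arr, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
            resid = arr[:, j] - others @ proj
            scale = np.linalg.norm(arr[:, j]) or 1.0
            if np.linalg.norm(resid) / scale < 1e-8:
                bad.append(str(col))
        raise EstimationError(
            f"regressor matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad or list(map(str, X.columns))}"
        )


def _sandwich(Xw: np.ndarray, uw: np.ndarray, variant: str) -> np.ndarray:
    """HC sandwich on the weighted model. Xw = sqrt(w) X, uw = sqrt(w) u."""
    n, k = Xw.shape
    XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    meat = (Xw * uw[:, None] ** 2).T @ Xw
    cov = XtX_inv @ meat @ XtX_inv
    if variant == "HC1":
        cov = cov * n / max(n - k, 1)
    elif variant != "HC0":
        raise ValueError(f"unknown robust variant {variant!r}; use HC0 or HC1")
    return cov


def wls_fit(design: DesignMatrix, robust: str = "HC1") -> FitResult:
    """Weighted least squares with heteroskedasticity-robust inference.

    Minimises sum_i w_i (y_i - x_i'b)^2.  The weighted residuals are
    orthogonal to every regressor column.  ``f_stat`` is the robust Wald
    test of all non-intercept coefficients against the intercept-only model.
    """
    X, y, w = design.regressors, design.response.to_numpy(), design.weights
    _check_full_rank(X, w)
    sw = np.sqrt(w)
    Xw = X.to_numpy() * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    fitted = X.to_numpy() @ beta
    resid = y - fitted

    cov = _sandwich(Xw, resid * sw, robust)
    se = np.sqrt(np.diag(cov))
    coefs = pd.Series(beta, index=X.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)

    W = w.sum()
    ybar = float(np.sum(w * y) / W)
    tss = float(np.sum(w * (y - ybar) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0

    # robust Wald F of the slope coefficients
    slope_idx = [j for j, c in enumerate(X.columns) if c != CONST]
    f_stat = np.nan
    if slope_idx:
        R = np.zeros((len(slope_idx), len(beta)))
        for i, j in enumerate(slope_idx):
            R[i, j] = 1.0
        Rb = R @ beta
        RVR = R @ cov @ R.T
        try:
            f_stat = float(Rb @ np.linalg.solve(RVR, Rb) / len(slope_idx))
        except np.linalg.LinAlgError:
            f_stat = np.nan

    return FitResult(
        coefficients=coefs,
        fitted=fitted,
        residuals=resid,
        robust_cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        robust_se=pd.Series(se, index=X.columns),
        t_stats=pd.Series(tvals, index=X.columns),
        r_squared=r2,
        f_stat=f_stat,
        method="WLS",
        robust_variant=robust,
        nobs=design.n,
        design=design,
    )


def robust_covariance(fit: FitResult, variant: str = "HC1") -> FitResult:
    """Re-derive the robust covariance of a WLS fit under HC0 or HC1."""
    if fit.method != "WLS":
        raise ValueError("robust_covariance applies to WLS fits only")
    X, w = fit.design.regressors, fit.design.weights
    sw = np.sqrt(w)
    cov = _sandwich(X.to_numpy() * sw[:, None], fit.residuals * sw, variant)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, fit.coefficients.to_numpy() / np.where(se > 0, se, 1.0), 0.0)
    return replace(
        fit,
        robust_cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        robust_se=pd.Series(se, index=X.columns),
        t_stats=pd.Series(tvals, index=X.columns),
        robust_variant=variant,
    )


def first_stage_predict(
    endogenous, exog_and_instruments: pd.DataFrame, weights=None
) -> np.ndarray:
    """Fitted values of an endogenous column regressed (WLS) on the full
    instrument set (all included exogenous regressors plus excluded
    instruments)."""
    e = np.asarray(endogenous, dtype=float)
    design = DesignMatrix(
        response=pd.Series(e), regressors=exog_and_instruments, weights=weights
    )
    return wls_fit(design).fitted


def _cragg_donald_f(
    endog: np.ndarray, exog: pd.DataFrame, excluded: pd.DataFrame, w: np.ndarray
) -> dict:
    """First-stage F on the excluded instruments, single endogenous regressor."""
    Zfull = pd.concat([exog, excluded], axis=1)
    full = wls_fit(DesignMatrix(pd.Series(endog), Zfull, w))
    rss_u = float(np.sum(w * full.residuals**2))
    if exog.shape[1] > 0:
        restr = wls_fit(DesignMatrix(pd.Series(endog), exog, w))
        rss_r = float(np.sum(w * restr.residuals**2))
    else:
        ybar = float(np.sum(w * endog) / w.sum())
        rss_r = float(np.sum(w * (endog - ybar) ** 2))
    m = excluded.shape[1]
    df_denom = len(endog) - Zfull.shape[1]
    f = ((rss_r - rss_u) / m) / (rss_u / df_denom)
    p = float(stats.f.sf(f, m, df_denom))
    return {"stat": float(f), "df": (m, df_denom), "p_value": p}


def gmm_iv_fit(
    design: DesignMatrix,
    endogenous: list[str],
    instruments: pd.DataFrame,
) -> FitResult:
    """Feasible efficient two-step GMM (H2SLS) for one equation.

    Parameters
    ----------
    design : DesignMatrix
        Response and full regressor matrix, *including* the endogenous
        column(s).
    endogenous : list of column names in ``design.regressors`` treated as
        endogenous.
    instruments : DataFrame of *excluded* instruments (exogenous variables
        not appearing in this equation).  The moment conditions use all
        included exogenous regressors plus these excluded instruments.

    Step 1 is 2SLS; step 2 re-estimates with the weight matrix built from
    the step-1 residual-scaled moment outer products (uncentered).  In the
    just-identified case the two steps coincide and Hansen's J is
    identically zero.
    """
    X, y, w = design.regressors, design.response.to_numpy(), design.weights
    missing = [c for c in endogenous if c not in X.columns]
    if missing:
        raise ValueError(f"endogenous column(s) not in regressors: {missing}")
    if instruments is not None and len(instruments) != design.n:
        raise ValueError("instrument matrix length differs from the design")

    exog_cols = [c for c in X.columns if c not in endogenous]
    exog = X[exog_cols]
    excluded = pd.DataFrame(instruments).astype(float) if instruments is not None else pd.DataFrame(index=X.index)
    overlap = [c for c in excluded.columns if c in X.columns]
    if overlap:
        raise ValueError(
            f"excluded instrument(s) {overlap} already appear as regressors"
        )
    if excluded.shape[1] < len(endogenous):
        raise IdentificationError(
            f"order condition fails: {len(endogenous)} endogenous regressor(s) "
            f"but only {excluded.shape[1]} excluded instrument(s)"
        )

    Z = pd.concat([exog, excluded], axis=1)
    _check_full_rank(X, w)
    _check_full_rank(Z, w)

    n, k = design.n, X.shape[1]
    q = Z.shape[1]
    Xa, Za = X.to_numpy(), Z.to_numpy()
    sw = np.sqrt(w)

    # step 1: 2SLS via projection of the weighted regressors on the
    # weighted instrument space
    Q, _ = np.linalg.qr(Za * sw[:, None])
    Xw = Xa * sw[:, None]
    Xhat = Q @ (Q.T @ Xw)
    b1, *_ = np.linalg.lstsq(Xhat, y * sw, rcond=None)
    r1 = y - Xa @ b1

    # step 2: efficient GMM in the metric of the step-1 moment variance
    Zw = Za * w[:, None]  # rows w_i z_i
    A = Zw.T @ Xa / n
    c = Zw.T @ y / n
    M = Za * (w * r1)[:, None]
    S = M.T @ M / n
    try:
        S_inv_A = np.linalg.solve(S, A)
        S_inv_c = np.linalg.solve(S, c)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "GMM weight matrix is numerically singular; instruments may be "
            "collinear or residual variation degenerate"
        ) from exc
    G = A.T @ S_inv_A
    try:
        b2 = np.linalg.solve(G, A.T @ S_inv_c)
        cov = np.linalg.inv(G) / n
    except np.linalg.LinAlgError as exc:
        raise EstimationError("GMM normal equations are singular") from exc

    resid = y - Xa @ b2
    fitted = y - resid

    # Hansen's J at the step-2 estimate, step-1 metric
    df_j = q - k
    if df_j == 0:
        j_stat, j_p = 0.0, 1.0
    else:
        gbar = Zw.T @ resid / n
        j_stat = float(n * gbar @ np.linalg.solve(S, gbar))
        j_p = float(stats.chi2.sf(j_stat, df_j))

    diagnostics = {"hansen_J": {"stat": j_stat, "df": df_j, "p_value": j_p}}
    if len(endogenous) == 1:
        diagnostics["cragg_donald_F"] = _cragg_donald_f(
            X[endogenous[0]].to_numpy(), exog, excluded, w
        )
    else:
        diagnostics["cragg_donald_F"] = None  # multi-endogenous: not implemented

    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, b2 / np.where(se > 0, se, 1.0), 0.0)

    W = w.sum()
    ybar = float(np.sum(w * y) / W)
    tss = float(np.sum(w * (y - ybar) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0

    return FitResult(
        coefficients=pd.Series(b2, index=X.columns),
        fitted=fitted,
        residuals=resid,
        robust_cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        robust_se=pd.Series(se, index=X.columns),
        t_stats=pd.Series(tvals, index=X.columns),
        r_squared=r2,
        f_stat=np.nan,
        method="GMM2STEP",
        robust_variant="HC0",
        nobs=n,
        design=design,
        diagnostics=diagnostics,
    )
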