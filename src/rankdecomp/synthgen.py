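"""Seeded generator of DHS-like child-malnutrition datasets from a known
two-equation structural process.

The generator emulates the structure of a Demographic and Health Survey
extract for children under five: a bounded ill-health score (degree of
stunting on [0, 1] with a point mass at zero), a continuous wealth score
inducing socioeconomic ranks, binary and count covariates with survey-like
means, and positive sampling weights. The coefficients are known, so every
estimator and decomposition in the package can be tested for recovery.

Structural process
------------------
    wealth*_i = gamma_0 + sum_g gamma_g z_{g,i} [+ gamma_q h_i] + xi_i
    d_i       = weighted fractional rank deviation of wealth*_i
    h*_i      = beta_0 + sum_j beta_j x_{j,i} + beta_k d_i + eps_i
    h_i       = clip(h*_i, 0, 1)            (when censoring is on)

with Corr(eps, xi) = rho, the endogeneity dial: unobserved deprivation
that raises ill-health and lowers wealth corresponds to rho < 0, the
default. With no feedback (gamma_q = 0, the default) the health equation
is generated from the *actual* rank deviations, so its coefficients are
exact estimands. With feedback the two equations are solved linearly per
individual in the latent (pre-rank) score.

The wealth-score error is uniform with a half-width calibrated so that the
score's percentile transform (score -> fractional rank) is approximately
affine; the rank-equation coefficients are then estimable to within a
small linearization error (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._weights import wmean, wsd
from .ranks import fractional_ranks
from .sem import SEMSpec, reduced_form

__all__ = ["GeneratorParams", "SyntheticTruth", "generate", "calibration_report", "DEFAULT_SEM_SPEC"]

H_EXOG = ("age", "agesq_c", "sex", "educ_mother", "educ_partner")
D_EXOG = ("residence", "educ_mother", "educ_partner", "water", "sanitation")

#: the structural layout the generator emulates: child demographics drive
#: ill-health, household infrastructure drives wealth, education enters
#: both; residence and sanitation instrument d in the h equation, the
#: child demographics instrument h in the d equation.
DEFAULT_SEM_SPEC = SEMSpec(
    h_regressors=H_EXOG,
    d_regressors=D_EXOG,
    instruments_for_h=("residence", "sanitation"),
    instruments_for_d=("age", "agesq_c", "sex"),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Generator configuration; the defaults are the study conditions.

    Covariate distributions target survey-like moments (sex share 0.514,
    urban share 0.1237, safe-water 0.4614, sanitation 0.1234, maternal /
    paternal education means 1.34 / 2.74 years); the censored ill-health
    score has a ~44% nonzero share.
    """

    n: int = 10_000
    seed: int = 0
    # health (beta) side; "d" is the coefficient on the rank deviation
    beta: dict = field(
        default_factory=lambda: {
            "const": -0.052,
            "age": 0.0017,
            "agesq_c": -0.0001,
            "sex": 0.0143,
            "educ_mother": -0.0022,
            "educ_partner": -0.0014,
            "d": -0.10,
        }
    )
    # wealth (gamma) side; "h" is the feedback coefficient gamma_q
    gamma: dict = field(
        default_factory=lambda: {
            "const": -0.1587,
            "residence": 0.25,
            "educ_mother": 0.0106,
            "educ_partner": 0.0146,
            "water": 0.129,
            "sanitation": 0.112,
            "h": 0.0,
        }
    )
    rho: float = -0.5  # Corr(eps, xi): negative = deprivation raises ill-health
    sigma_eps: float = 0.20
    xi_half_width: float | None = None  # None: auto-calibrated (see generate)
    censor: bool = True
    rank_transform: bool = True
    weighted: bool = True
    weight_sigma: float = 0.5  # lognormal sd of the sampling weights

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        if self.xi_half_width is not None and self.xi_half_width <= 0:
            raise ValueError("xi_half_width must be positive")
        bk = self.beta.get("d", 0.0)
        gq = self.gamma.get("h", 0.0)
        if abs(1.0 - bk * gq) < 1e-8:
            raise ValueError("beta_k * gamma_q must differ from 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a generated dataset.

    ``d`` is a deterministic (weighted empirical percentile) transform of
    the wealth score; with no feedback the beta side is exact, the gamma
    side exact up to the percentile-linearization error.
    """

    beta: pd.Series
    gamma: pd.Series
    lam: pd.Series  # implied reduced-form coefficients for h
    pi: pd.Series  # implied reduced-form coefficients for d
    rho: float
    sigma_eps: float
    sigma_xi: float
    xi_half_width: float
    spec: SEMSpec


def _gini_mean_difference(x: np.ndarray) -> float:
    """Mean absolute pairwise difference, O(n log n)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum((2 * i - n - 1) * xs) / (n * (n - 1)))


def _deviations(score: np.ndarray, weight: np.ndarray, rank_transform: bool) -> np.ndarray:
    """The socioeconomic deviation column: the weighted fractional-rank
    deviations of the score (the survey-emulating default), or the
    weighted-centered latent score itself.

    The rank transform — like censoring of the health score — breaks the
    exact linearity of the structural wealth equation (its coefficients are
    attenuated by the score-to-percentile map), so recovery tests switch it
    off; the two columns agree closely thanks to the near-uniform score
    design, and the emitted equation for h uses the chosen column either
    way, keeping the health equation exact in both modes.
    """
    if rank_transform:
        return fractional_ranks(score, weight).d
    return score - wmean(score, weight)


def _zig(rng, p_nonzero: np.ndarray, mean_nonzero: float) -> np.ndarray:
    """Zero-inflated geometric counts (education years)."""
    nz = rng.random(p_nonzero.shape[0]) < p_nonzero
    vals = rng.geometric(1.0 / mean_nonzero, p_nonzero.shape[0])
    return np.where(nz, vals, 0).astype(float)


def generate(params: GeneratorParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one dataset and its ground truth. Same seed, same table."""
    rng = np.random.default_rng(params.seed)
    n = params.n

    age = rng.integers(0, 60, n).astype(float)
    sex = rng.binomial(1, 0.514, n).astype(float)
    residence = rng.binomial(1, 0.1237, n).astype(float)
    water = rng.binomial(1, 0.40 + 0.50 * residence).astype(float)
    sanitation = rng.binomial(1, 0.06 + 0.52 * residence).astype(float)
    educ_mother = _zig(rng, 0.28 + 0.35 * residence, 4.159)
    educ_partner = _zig(rng, 0.45 + 0.30 * residence, 5.633)
    if params.weighted:
        s = params.weight_sigma
        weight = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)
    else:
        weight = np.ones(n)

    agesq_c = (age - wmean(age, weight)) ** 2

    cols = {
        "age": age,
        "agesq_c": agesq_c,
        "sex": sex,
        "residence": residence,
        "educ_mother": educ_mother,
        "educ_partner": educ_partner,
        "water": water,
        "sanitation": sanitation,
    }
    g = params.gamma
    lp_d = g["const"] + sum(
        g[v] * cols[v] for v in D_EXOG if v in g
    )
    b = params.beta
    lp_h = b["const"] + sum(b[v] * cols[v] for v in H_EXOG if v in b)

    # calibrate the score-error half-width so the score's empirical
    # percentile transform is close to affine (window length = 1 minus the
    # mean absolute spread of the linear predictor)
    if params.xi_half_width is not None:
        half = params.xi_half_width
    else:
        half = max(0.25, (1.0 - _gini_mean_difference(lp_d)) / 2.0)
    sigma_xi = half / np.sqrt(3.0)

    xi = rng.uniform(-half, half, n)
    rho = params.rho
    eps = rho * (params.sigma_eps / sigma_xi) * xi + np.sqrt(
        1.0 - rho**2
    ) * params.sigma_eps * rng.standard_normal(n)

    beta_k = b.get("d", 0.0)
    gamma_q = g.get("h", 0.0)
    if gamma_q == 0.0:
        wealth = lp_d + xi
        d = _deviations(wealth, weight, params.rank_transform)
        h_latent = lp_h + beta_k * d + eps
    else:
        # feedback: solve the two linear equations in the latent score
        denom = 1.0 - beta_k * gamma_q
        wealth = (lp_d + gamma_q * lp_h + xi + gamma_q * eps) / denom
        h_latent = (lp_h + beta_k * lp_d + eps + beta_k * xi) / denom
        d = _deviations(wealth, weight, params.rank_transform)

    h = np.clip(h_latent, 0.0, 1.0) if params.censor else h_latent

    df = pd.DataFrame(
        {
            "h": h,
            "wealth": wealth,
            "d": d,
            "weight": weight,
            **cols,
        }
    )

    beta_s = pd.Series(b, dtype=float)
    gamma_s = pd.Series(g, dtype=float)
    rf = reduced_form((beta_s, gamma_s), DEFAULT_SEM_SPEC)
    truth = SyntheticTruth(
        beta=beta_s,
        gamma=gamma_s,
        lam=rf.lam,
        pi=rf.pi,
        rho=rho,
        sigma_eps=params.sigma_eps,
        sigma_xi=float(sigma_xi),
        xi_half_width=float(half),
        spec=DEFAULT_SEM_SPEC,
    )
    return df, truth


def calibration_report(dataset: pd.DataFrame, weight_col: str = "weight") -> pd.DataFrame:
    """Weighted means and SDs per column, survey-table layout, plus the
    nonzero ill-health share."""
    w = dataset[weight_col].to_numpy(dtype=float)
    rows = {}
    for col in dataset.columns:
        if col == weight_col:
            continue
        x = dataset[col].to_numpy(dtype=float)
        rows[col] = {"mean": wmean(x, w), "sd": wsd(x, w)}
    out = pd.DataFrame(rows).T
    if "h" in dataset.columns:
        out.loc["share_h_positive", "mean"] = wmean(
            (dataset["h"].to_numpy(dtype=float) > 0).astype(float), w
        )
    return out
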