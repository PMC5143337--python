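"""Weighted fractional ranks and the family of rank-dependent indices.

Rank-dependent indicators of socioeconomic inequality of health express an
index as a weighted sum of individual health levels, with weights driven by
each individual's position (rank) in the socioeconomic distribution.  The
basic member of the family is the Generalized Concentration Index

    GC = (2/n) * sum_i h_i d_i  =  2 Cov(h, d),

where h_i is the (ill-)health level of individual i and d_i = f_i - 1/2 is
the deviation of the fractional socioeconomic rank f_i from its mean 1/2.
Positive GC means better measured "health" among the socioeconomically
better-off; when h is an ill-health score (e.g. degree of stunting) a
negative GC indicates a burden concentrated among the poor.

The standard Concentration Index C, Wagstaff's index W and Erreygers' index
E are scalar multiples of GC that depend on the mean and/or the bounds of
the health variable:

    C = GC / mu_h
    W = (b - a) * GC / ((b - mu_h) * (mu_h - a))
    E = 4 * GC / (b - a)

Only GC and E have multipliers that do not depend on the predictors of
health ("weighting function ignorability"); the regression decompositions
in :mod:`rankdecomp.decomp` therefore apply to GC (and trivially to E),
while C and W are provided as index values only.

With sampling weights w_i the fractional rank generalises to the
cumulative-weight midpoint: every member of a block of tied socioeconomic
values receives f = (W_below + W_block/2) / W_total.  At unit weights this
reduces exactly to f_i = (r_i - 1/2)/n with average ranks on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._weights import as_weights, wcov, wmean

__all__ = [
    "HealthVector",
    "RankStructure",
    "IndexValue",
    "fractional_ranks",
    "gc_product",
    "gc_covariance",
    "scale_index",
]


@dataclass(frozen=True)
class HealthVector:
    """A health (or ill-health) column with optional bounds.

    Bounds are only needed for the bounded-variable indices W and E.
    """

    h: np.ndarray
    a_h: float | None = None
    b_h: float | None = None

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 1:
            raise ValueError("health vector must be one-dimensional")
        if not np.all(np.isfinite(h)):
            raise ValueError("health vector contains non-finite values")
        if self.a_h is not None and self.b_h is not None:
            if not self.a_h < self.b_h:
                raise ValueError("health bounds require a_h < b_h")
            if np.any(h < self.a_h) or np.any(h > self.b_h):
                raise ValueError("health values fall outside the declared bounds")
        object.__setattr__(self, "h", h)

    def __len__(self) -> int:
        return self.h.shape[0]


@dataclass(frozen=True)
class RankStructure:
    """Socioeconomic ranks derived from a well-being score.

    Attributes
    ----------
    y : score the ranking was computed from (input order preserved)
    w : sampling weights (all ones if none supplied)
    r : average ranks on ties (1..n scale, unit-weight notion)
    f : weighted fractional ranks, strictly inside (0, 1)
    d : fractional rank deviations f - mean_w(f); weighted mean exactly 0
    """

    y: np.ndarray
    w: np.ndarray
    r: np.ndarray
    f: np.ndarray
    d: np.ndarray

    def __len__(self) -> int:
        return self.y.shape[0]

    @property
    def weighted(self) -> bool:
        return bool(np.ptp(self.w) > 0)


@dataclass(frozen=True)
class IndexValue:
    """A computed rank-dependent index."""

    kind: str  # one of {"GC", "C", "W", "E"}
    value: float
    n: int
    weighted: bool = False


def fractional_ranks(y, w=None) -> RankStructure:
    """Weighted fractional ranks with average-rank tie handling.

    Each block of tied values of ``y`` (in ascending order) receives the
    cumulative-weight midpoint rank ``(W_below + W_block / 2) / W_total``,
    which reduces to ``(r_i - 1/2) / n`` at unit weights.

    Parameters
    ----------
    y : array-like
        Socioeconomic well-being score (e.g. a wealth index). Finite.
    w : array-like, optional
        Strictly positive sampling weights; default all ones.

    Returns
    -------
    RankStructure
        In input order; the weighted mean of ``d`` is zero to machine
        precision by construction.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("score vector must be one-dimensional")
    n = y.shape[0]
    if n < 2:
        raise ValueError("at least two observations are required to rank")
    if not np.all(np.isfinite(y)):
        raise ValueError("score vector contains non-finite values")
    w = as_weights(w, n)

    order = np.argsort(y, kind="stable")
    ys = y[order]
    ws = w[order]
    W_total = ws.sum()

    # block boundaries of tied values in sorted order
    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    new_block[1:] = ys[1:] != ys[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    block_w = np.bincount(block_id, weights=ws, minlength=n_blocks)
    cum_below = np.concatenate(([0.0], np.cumsum(block_w)[:-1]))
    f_block = (cum_below + block_w / 2.0) / W_total

    f = np.empty(n, dtype=float)
    f[order] = f_block[block_id]
    # subtract the weighted mean rather than 1/2 so mean_w(d) is exactly 0
    d = f - wmean(f, w)

    r = rankdata(y, method="average")
    return RankStructure(y=y, w=w, r=r, f=f, d=d)


def _check_aligned(h: HealthVector, ranks: RankStructure) -> None:
    if len(h) != len(ranks):
        raise ValueError(
            f"health vector (n={len(h)}) and rank structure (n={len(ranks)}) "
            "have different lengths"
        )


def _warn_if_degenerate(ranks: RankStructure) -> None:
    if np.ptp(ranks.y) == 0:
        warnings.warn(
            "socioeconomic score has zero variance: all ranks are tied and "
            "any rank-dependent index is trivially 0",
            stacklevel=3,
        )


def gc_product(h: HealthVector | np.ndarray, ranks: RankStructure) -> IndexValue:
    """Generalized Concentration Index, product form.

    GC = (2 / W_total) * sum_i w_i h_i d_i; equals (2/n) sum h_i d_i at unit
    weights.
    """
    if not isinstance(h, HealthVector):
        h = HealthVector(np.asarray(h, dtype=float))
    _check_aligned(h, ranks)
    _warn_if_degenerate(ranks)
    w = ranks.w
    value = 2.0 * float(np.sum(w * h.h * ranks.d) / np.sum(w))
    return IndexValue(kind="GC", value=value, n=len(ranks), weighted=ranks.weighted)


def gc_covariance(
    h: HealthVector | np.ndarray, ranks: RankStructure, use_weights: bool = True
) -> IndexValue:
    """Generalized Concentration Index, covariance form: GC = 2 Cov(h, d).

    The covariance is the weighted *population* covariance (denominator =
    total weight), which makes this identical to :func:`gc_product`.

    ``use_weights=False`` computes the unweighted covariance of ``h`` with
    the (weighted) rank deviations — the alternative reading of a weighted
    GC in which weights enter only through the ranks.
    """
    if not isinstance(h, HealthVector):
        h = HealthVector(np.asarray(h, dtype=float))
    _check_aligned(h, ranks)
    _warn_if_degenerate(ranks)
    w = ranks.w if use_weights else np.ones(len(ranks))
    value = 2.0 * wcov(h.h, ranks.d, w)
    return IndexValue(
        kind="GC", value=value, n=len(ranks), weighted=ranks.weighted and use_weights
    )


def scale_index(
    gc: IndexValue,
    kind: str,
    mu_h: float,
    a_h: float | None = None,
    b_h: float | None = None,
) -> IndexValue:
    """Rescale a GC value to one of the derived indices C, W or E.

    C = GC / mu_h                                   (ratio-scale h)
    W = (b - a) GC / ((b - mu_h)(mu_h - a))         (bounded h, Wagstaff)
    E = 4 GC / (b - a)                              (bounded h, Erreygers)
    """
    if gc.kind != "GC":
        raise ValueError("scale_index expects a GC index as input")
    if kind == "C":
        if mu_h == 0:
            raise ValueError("index C is undefined when the mean health level is 0")
        value = gc.value / mu_h
    elif kind == "W":
        if a_h is None or b_h is None:
            raise ValueError("index W requires both health bounds a_h and b_h")
        if not (a_h < mu_h < b_h):
            raise ValueError(
                f"index W requires a_h < mu_h < b_h, got a_h={a_h}, "
                f"mu_h={mu_h}, b_h={b_h}"
            )
        value = (b_h - a_h) * gc.value / ((b_h - mu_h) * (mu_h - a_h))
    elif kind == "E":
        if a_h is None or b_h is None:
            raise ValueError("index E requires both health bounds a_h and b_h")
        if not a_h < b_h:
            raise ValueError(f"index E requires a_h < b_h, got a_h={a_h}, b_h={b_h}")
        value = 4.0 * gc.value / (b_h - a_h)
    else:
        raise ValueError(f"unknown index kind {kind!r}; expected one of C, W, E")
    return IndexValue(kind=kind, value=value, n=gc.n, weighted=gc.weighted)
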