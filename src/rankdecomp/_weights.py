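"""Weighted-population moment helpers shared across the package.

All covariances in this package use the *population* convention
(denominator = total weight, no degrees-of-freedom correction). This is
required for the exact algebraic identities between the product and
covariance forms of the concentration index and for exact additivity of
the decompositions.
"""

from __future__ import annotations

import numpy as np


def as_weights(w, n: int) -> np.ndarray:
    """Validate and broadcast a weight vector; ``None`` means unit weights."""
    if w is None:
        return np.ones(n, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weight vector has shape {w.shape}, expected ({n},)")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def wmean(x, w) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * x) / np.sum(w))


def wcov(x, y, w) -> float:
    """Weighted population covariance: sum w (x - xbar)(y - ybar) / sum w."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    W = np.sum(w)
    xc = x - np.sum(w * x) / W
    yc = y - np.sum(w * y) / W
    return float(np.sum(w * xc * yc) / W)


def wvar(x, w) -> float:
    return wcov(x, x, w)


def wsd(x, w) -> float:
    return float(np.sqrt(max(wvar(x, w), 0.0)))
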