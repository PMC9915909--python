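"""Getis–Ord Gi* cold/hot-spot statistic.

Gi* measures local clustering of high or low values around unit i,
including i itself (w_ii = 1).  With binary weights,

    G*_i = [sum_j w_ij x_j - Xbar W_i] /
           (S * sqrt((t * sum_j w_ij^2 - W_i^2) / (t - 1))),

where W_i = sum_j w_ij, Xbar and S the global mean and population
standard deviation over all t units.  The result is a z-score: z > 0
marks hot spots, z < 0 cold spots, tiered at |z| >= 1.65 / 1.96 / 2.58.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .weights import SpatialWeights

THRESHOLDS = (1.65, 1.96, 2.58)  # 90 / 95 / 99 percent tiers


@dataclass
class GiStarResult:
    ids: list[str]
    z: np.ndarray
    category: list[str]


def gi_star(x, w: SpatialWeights) -> GiStarResult:
    """Gi* z-score per unit; binary weights with self-inclusion.

    A constant field yields z = 0 everywhere (zero numerator limit).
    """
    x = np.asarray(x, dtype=float)
    t = x.size
    if t != w.n:
        raise ValueError(f"{t} values for {w.n} units")
    if t < 3:
        raise ValueError("need at least 3 units")
    W = w.to_dense(include_self=1.0)
    if w.standardized != "binary":
        # Gi* is conventionally run on binary weights; reset off-diagonals
        W = (W > 0).astype(float)
    xbar = x.mean()
    s = x.std(ddof=0)
    wsum = W.sum(axis=1)
    wsq = (W ** 2).sum(axis=1)
    num = W @ x - xbar * wsum
    inner = (t * wsq - wsum ** 2) / (t - 1)
    denom = s * np.sqrt(np.maximum(inner, 0.0))
    z = np.divide(num, denom, out=np.zeros(t), where=denom > 0)
    return GiStarResult(ids=list(w.ids), z=z, category=classify(z))


def classify(z) -> list[str]:
    """Three-tier hot/cold labels from a z-score vector."""
    out = []
    for v in np.asarray(z, dtype=float):
        a = abs(v)
        if a >= THRESHOLDS[2]:
            tier = "99"
        elif a >= THRESHOLDS[1]:
            tier = "95"
        elif a >= THRESHOLDS[0]:
            tier = "90"
        else:
            out.append("not_significant")
            continue
        out.append(("hot" if v > 0 else "cold") + tier)
    return out
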