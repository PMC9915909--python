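"""Theil–Sen slope and Mann–Kendall monotone-trend test.

The Sen slope is the median of all pairwise slopes (x_j - x_i)/(t_j -
t_i), j > i, computed over the actual time spacing (timepoints here are 5
years apart, so index spacing would misstate rates).  The MK statistic is
S = sum_{i<j} sign(x_j - x_i) with the tie-corrected variance

    Var(S) = [n(n-1)(2n+5) - sum_k t_k(t_k-1)(2t_k+5)] / 18

and the continuity-corrected normal deviate Z; Z = 0 exactly when S = 0,
signalling no tendency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import RasterGrid


@dataclass
class TrendResult:
    beta: float          # Sen slope, variable units per time unit
    S: int               # MK sign statistic
    Z: float             # normal deviate
    p_value: float       # two-sided
    direction: str       # {"up", "down", "none"}


def sen_slope(series, times=None) -> float:
    """Median of all pairwise slopes; even pair counts average the central
    pair.  ``times`` defaults to 0..n-1 (index spacing)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("Sen slope needs at least 2 observations")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, float)
    if t.size != x.size:
        raise ValueError("series and times lengths differ")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    i, j = np.triu_indices(x.size, k=1)
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def mk_statistic(series) -> int:
    x = np.asarray(series, dtype=float)
    i, j = np.triu_indices(x.size, k=1)
    return int(np.sign(x[j] - x[i]).sum())


def mk_test(series, times=None, alpha: float = 0.05) -> TrendResult:
    """Mann–Kendall test with tie correction and normal approximation."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Mann–Kendall test needs at least 3 observations")
    S = mk_statistic(x)
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if S > 0:
        Z = (S - 1) / np.sqrt(var_s)
    elif S < 0:
        Z = (S + 1) / np.sqrt(var_s)
    else:
        Z = 0.0
    p = 2 * stats.norm.sf(abs(Z))
    beta = sen_slope(x, times) if n >= 2 else 0.0
    if abs(Z) >= stats.norm.ppf(1 - alpha / 2):
        direction = "up" if Z > 0 else "down"
    else:
        direction = "none"
    return TrendResult(beta=beta, S=S, Z=float(Z), p_value=float(p),
                       direction=direction)


def trend_raster(stack: list[RasterGrid],
                 times=None) -> tuple[RasterGrid, RasterGrid]:
    """Per-pixel Sen slope and MK Z over a time-ordered raster stack.

    Pixels with fewer than 3 valid layers become nodata in both outputs.
    """
    if len(stack) < 3:
        raise ValueError("need at least 3 layers")
    shapes = {r.values.shape for r in stack}
    if len(shapes) != 1:
        raise ValueError(f"misaligned layer shapes: {sorted(shapes)}")
    t = (np.arange(len(stack), dtype=float) if times is None
         else np.asarray(times, dtype=float))
    cube = np.stack([r.values for r in stack])          # time x rows x cols
    valid = ~np.stack([r.nodata_mask for r in stack])
    nrow, ncol = stack[0].values.shape
    beta = np.full((nrow, ncol), np.nan)
    z = np.full((nrow, ncol), np.nan)
    for r in range(nrow):
        for c in range(ncol):
            ok = valid[:, r, c]
            if ok.sum() < 3:
                continue
            res = mk_test(cube[ok, r, c], times=t[ok])
            beta[r, c], z[r, c] = res.beta, res.Z
    mask = np.isnan(beta)
    tf = stack[0].transform
    return (RasterGrid(beta, mask, tf, variable="sen_slope"),
            RasterGrid(z, mask.copy(), tf, variable="mk_z"))
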