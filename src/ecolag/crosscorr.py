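"""Spatiotemporal-lag spatial cross-correlation.

The central statistic relates life expectancy at time t to an ecological
variable at time t - m at the *neighbours* of each region: a bivariate
Moran's I with a temporal offset.  With z_y, z_x the two variables
standardized by mean and population s.d.,

    global I = sum_i sum_j w_ij z_y,i z_x,j / S0,        S0 = sum_ij w_ij
    local  I_i = z_y,i * sum_j w_ij z_x,j,

so with row-standardized weights and no isolates the mean of the local
values equals the global value, and the through-origin slope of the Moran
scatter (spatial lag of z_x against z_y) is the global I.  Setting x = y
recovers the univariate Moran's I.  Significance is pseudo-p by
permutation, GeoDa-style: the lagged variable is shuffled over units
(conditionally on unit i for the local statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import PanelTable
from .weights import SpatialWeights


@dataclass(frozen=True)
class LagPair:
    """One lag design: y at y_time against x at x_time = y_time - m."""

    y_variable: str
    y_time: int
    x_variable: str
    x_time: int

    @property
    def m(self) -> int:
        return int(self.y_time) - int(self.x_time)

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"negative lag: x_time {self.x_time} after "
                             f"y_time {self.y_time}")


@dataclass
class CrossMoranResult:
    ids: list[str]
    global_I: float
    expected_I: float            # permutation mean of the global statistic
    p_value: float               # global pseudo p (two-sided on |I|)
    local_I: np.ndarray
    local_p: np.ndarray
    cluster: list[str]
    scatter: np.ndarray          # per-unit (spatial lag of z_x, z_y)
    scatter_slope: float


def _zscore(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    s = v.std(ddof=0)
    if s == 0:
        raise ValueError(f"{what} is constant; Moran statistics undefined")
    return (v - v.mean()) / s


def global_cross_moran(y, x_lagged, w: SpatialWeights) -> float:
    """Bivariate (lagged) global Moran's I."""
    zy = _zscore(np.asarray(y, float), "y")
    zx = _zscore(np.asarray(x_lagged, float), "x_lagged")
    if zy.size != w.n or zx.size != w.n:
        raise ValueError("variable length does not match weights")
    W = w.to_dense()
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("weights are all zero")
    return float(zy @ W @ zx / s0)


def local_cross_moran(y, x_lagged, w: SpatialWeights) -> np.ndarray:
    """Per-unit I_i = z_y,i * (spatial lag of z_x at i)."""
    zy = _zscore(np.asarray(y, float), "y")
    zx = _zscore(np.asarray(x_lagged, float), "x_lagged")
    return zy * (w.to_dense() @ zx)


def moran_scatter(y, x_lagged, w: SpatialWeights) -> tuple[np.ndarray, float]:
    """Moran scatter values (lag of z_x, z_y) and the through-origin
    regression slope of the lag on z_y — equal to global I when the
    weights are row-standardized with no isolates."""
    zy = _zscore(np.asarray(y, float), "y")
    zx = _zscore(np.asarray(x_lagged, float), "x_lagged")
    lag = w.to_dense() @ zx
    slope = float(zy @ lag / (zy @ zy))
    return np.column_stack([lag, zy]), slope


def permutation_inference(y, x_lagged, w: SpatialWeights, n_perm: int = 999,
                          seed: int | None = None, two_sided: bool = True,
                          compute_local: bool = True) -> dict:
    """GeoDa-style pseudo significance.

    Global: x_lagged is shuffled over all units; pseudo p = (#{|I_perm| >=
    |I_obs|} + 1) / (n_perm + 1) (one-sided on the observed sign when
    ``two_sided`` is False).  Local: conditional permutation — unit i's
    own value is held fixed while the remaining values are shuffled onto
    its neighbours.  Deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    zy = _zscore(np.asarray(y, float), "y")
    zx = _zscore(np.asarray(x_lagged, float), "x_lagged")
    n = w.n
    W = w.to_dense()
    s0 = W.sum()
    I_obs = float(zy @ W @ zx / s0)

    # global: vectorized over permutations via I = (Wᵀ z_y) · z_x_perm / S0
    a = W.T @ zy
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    I_perm = zx[perms] @ a / s0
    if two_sided:
        exceed = np.abs(I_perm) >= abs(I_obs) - 1e-14
    else:
        exceed = I_perm >= I_obs - 1e-14 if I_obs >= 0 else I_perm <= I_obs + 1e-14
    p_global = (exceed.sum() + 1) / (n_perm + 1)

    # local: conditional permutation per unit (unit i's value held fixed,
    # the others shuffled onto its neighbour positions)
    local_obs = zy * (W @ zx)
    local_p = np.full(n, np.nan)
    if compute_local:
        idx = {r: k for k, r in enumerate(w.ids)}
        for k, rid in enumerate(w.ids):
            nbrs = [idx[j] for j in w.neighbors.get(rid, [])]
            if not nbrs:
                continue
            wrow = W[k, nbrs]
            others = np.delete(zx, k)
            kn = len(nbrs)
            # sampling without replacement via argsort of uniforms
            picks = np.argsort(rng.random((n_perm, others.size)),
                               axis=1)[:, :kn]
            stat_perm = zy[k] * (others[picks] @ wrow)
            if two_sided:
                ex = np.abs(stat_perm) >= abs(local_obs[k]) - 1e-14
            else:
                ex = (stat_perm >= local_obs[k] - 1e-14 if local_obs[k] >= 0
                      else stat_perm <= local_obs[k] + 1e-14)
            local_p[k] = (ex.sum() + 1) / (n_perm + 1)

    return {"global_I": I_obs, "expected_I": float(I_perm.mean()),
            "p_value": float(p_global), "local_I": local_obs,
            "local_p": local_p}


def lisa_classify(y, x_lagged, w: SpatialWeights, local_p,
                  alpha: float = 0.05) -> list[str]:
    """Quadrant labels for significant units: (z_y, lag z_x) signs map to
    high-high / low-low / high-low / low-high; others not_significant."""
    zy = _zscore(np.asarray(y, float), "y")
    zx = _zscore(np.asarray(x_lagged, float), "x_lagged")
    lag = w.to_dense() @ zx
    local_p = np.asarray(local_p, dtype=float)
    out = []
    for i in range(w.n):
        if not np.isfinite(local_p[i]) or local_p[i] > alpha:
            out.append("not_significant")
        elif zy[i] >= 0:
            out.append("high-high" if lag[i] >= 0 else "high-low")
        else:
            out.append("low-low" if lag[i] < 0 else "low-high")
    return out


def cross_moran(y, x_lagged, w: SpatialWeights, n_perm: int = 999,
                seed: int | None = None, alpha: float = 0.05) -> CrossMoranResult:
    """Full lagged cross-correlation analysis for one variable pair."""
    inf = permutation_inference(y, x_lagged, w, n_perm=n_perm, seed=seed)
    scatter, slope = moran_scatter(y, x_lagged, w)
    cluster = lisa_classify(y, x_lagged, w, inf["local_p"], alpha=alpha)
    return CrossMoranResult(
        ids=list(w.ids), global_I=inf["global_I"], expected_I=inf["expected_I"],
        p_value=inf["p_value"], local_I=inf["local_I"], local_p=inf["local_p"],
        cluster=cluster, scatter=scatter, scatter_slope=slope,
    )


def pearson_lag_matrix(panels: dict[str, PanelTable], le: PanelTable,
                       pairs: list[LagPair]) -> list[dict]:
    """Aspatial Pearson correlations across regions for each lag design.

    Missing cells are pairwise-deleted; a pair with fewer than 3 complete
    observations raises.
    """
    rows = []
    for pair in pairs:
        panel = panels[pair.x_variable]
        x = panel.column(pair.x_time)
        yv = le.column(pair.y_time)
        if panel.region_ids != le.region_ids:
            order = [panel.region_ids.index(r) for r in le.region_ids]
            x = x[order]
        ok = np.isfinite(x) & np.isfinite(yv)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for {pair}")
        r, p = stats.pearsonr(x[ok], yv[ok])
        rows.append({"x_variable": pair.x_variable, "x_time": pair.x_time,
                     "y_variable": pair.y_variable, "y_time": pair.y_time,
                     "m": pair.m, "pearson_r": float(r), "p_value": float(p),
                     "n": int(ok.sum())})
    return rows
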