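"""Synthetic study generator with known ground truth.

Emulates the study design end-to-end: 16 regions on a 4x4 grid, three
census timepoints five years apart, five ecological indicators sharing
one spatially autocorrelated latent "greenness" field, and a life
expectancy (LE) panel driven by the *lagged* composite ecological index.
Because LE is linked to the CEI rather than to any raw indicator, the
whole pipeline — indicators → PCA → CEI → lagged bivariate Moran — is the
recovery path for the planted lag.

Spatial structure comes from the SAR filter g = (I - rho*W)^{-1} eps with
row-standardized queen weights W and i.i.d. standard-normal eps: the
simplest generator with tunable, well-understood Moran's I behaviour.
The per-timepoint latent field is re-standardized so the indicator affine
maps control marginal location/spread exactly; slopes and noise levels
are chosen so each indicator stays inside its observed study-area
envelope (NDVI in [-0.2, 1], LST in [0, 69] degC, GPP >= 0, LAI in
[0, 7]) and so the indicator–latent correlations echo the reported
factor structure (GPP/LAI/NDVI strongly and Wet moderately positive, LST
negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .cei import cei_from_panel
from .data_model import PanelTable, RasterGrid, Region
from .weights import SpatialWeights, queen_contiguity, row_standardize

INDICATORS = ("NDVI", "LAI", "GPP", "LST", "Wet")

#: indicator -> (center, slope on the standardized latent field, noise s.d.)
#: signal-to-noise ratios give latent correlations ~0.96/0.96/0.97/-0.91/0.74
AFFINE_MAPS: dict[str, tuple[float, float, float]] = {
    "NDVI": (0.30, 0.10, 0.030),
    "LAI": (1.50, 0.40, 0.120),
    "GPP": (0.050, 0.012, 0.0030),
    "LST": (45.0, -5.0, 2.30),
    "Wet": (0.050, 0.10, 0.090),
}

#: hard envelopes from the observed study-area extrema
ENVELOPES: dict[str, tuple[float, float]] = {
    "NDVI": (-0.2, 1.0),
    "LAI": (0.0, 7.0),
    "GPP": (0.0, 0.104),
    "LST": (0.0, 69.0),
    "Wet": (-1.0, 0.95),
}


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Defaults mirror the study: 16 regions, census years 2010/2015/2020
    (one 5-year step = one lag unit), strong spatial autocorrelation, and
    a one-step lagged CEI effect on LE of 2 years per CEI s.d. over 0.1
    years of noise.
    """

    n_side: int = 4
    timepoints: list[int] = field(default_factory=lambda: [2010, 2015, 2020])
    rho: float = 0.8
    lag_m: int = 1                  # true LE lag, in timepoint steps
    beta_le: float = 2.0            # years of LE per s.d. of lagged CEI
    noise_sd_le: float = 0.1
    seed: int = 0
    pixels_per_region: int = 4      # raster pixels per region side
    noise_sd_raster: float = 0.0    # within-region pixel noise

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.lag_m >= len(self.timepoints):
            raise ValueError("lag_m must be smaller than the number of timepoints")
        if self.noise_sd_le < 0 or self.noise_sd_raster < 0:
            raise ValueError("noise s.d. must be nonnegative")
        if self.n_side < 2:
            raise ValueError("n_side must be >= 2")


def generate_regions(config: SyntheticConfig) -> list[Region]:
    """n_side x n_side unit squares tiling the plane, ids r0-0, r0-1, ..."""
    regions = []
    for row in range(config.n_side):
        for col in range(config.n_side):
            regions.append(Region(id=f"r{row}-{col}", name=f"Region {row},{col}",
                                  geometry=box(col, row, col + 1, row + 1)))
    return regions


def _sar_field(rng: np.random.Generator, w: SpatialWeights, rho: float) -> np.ndarray:
    """One draw of g = (I - rho W)^{-1} eps, standardized to mean 0, s.d. 1."""
    n = w.n
    eps = rng.standard_normal(n)
    if rho == 0:
        g = eps
    else:
        g = np.linalg.solve(np.eye(n) - rho * w.to_dense(), eps)
    sd = g.std(ddof=0)
    return (g - g.mean()) / (sd if sd > 0 else 1.0)


def generate_indicator_panels(config: SyntheticConfig,
                              w: SpatialWeights) -> dict[str, PanelTable]:
    """Five indicator panels driven by a per-timepoint latent field."""
    if w.standardized != "row":
        raise ValueError("weights must be row-standardized")
    rng = np.random.default_rng(config.seed)
    n, T = w.n, len(config.timepoints)
    latent = np.column_stack([_sar_field(rng, w, config.rho) for _ in range(T)])
    panels = {}
    for name in INDICATORS:
        center, slope, noise_sd = AFFINE_MAPS[name]
        vals = center + slope * latent + noise_sd * rng.standard_normal((n, T))
        lo, hi = ENVELOPES[name]
        vals = np.clip(vals, lo, hi)
        panels[name] = PanelTable(variable=name, region_ids=list(w.ids),
                                  timepoints=list(config.timepoints), values=vals)
    return panels


def generate_cei_panel(config: SyntheticConfig,
                       panels: dict[str, PanelTable]) -> PanelTable:
    """Per-timepoint CEI from the generated indicators (PCA pipeline)."""
    ids = panels[INDICATORS[0]].region_ids
    cols = []
    for t in config.timepoints:
        mat = np.column_stack([panels[v].column(t) for v in INDICATORS])
        res, _ = cei_from_panel(mat, names=list(INDICATORS), year=t)
        cols.append(res.P)
    return PanelTable(variable="CEI", region_ids=list(ids),
                      timepoints=list(config.timepoints),
                      values=np.column_stack(cols))


def generate_le_panel(config: SyntheticConfig, cei: PanelTable) -> PanelTable:
    """LE_i(t) = 73 + beta_le * zscore(CEI_i(t - lag_m)) + noise.

    Timepoints with no lagged predecessor use the earliest CEI column;
    values are clipped to the plausible human range [65, 85].
    """
    for t in config.timepoints:
        if t not in cei.timepoints:
            raise ValueError(f"CEI panel lacks timepoint {t}")
    if config.lag_m >= len(config.timepoints):
        raise ValueError("lag_m must be smaller than the number of timepoints")
    # LE noise uses its own stream so indicator draws are unaffected
    rng = np.random.default_rng((config.seed, 1))
    n, T = cei.n_regions, len(config.timepoints)
    values = np.empty((n, T))
    for k, t in enumerate(config.timepoints):
        src = config.timepoints[max(k - config.lag_m, 0)]
        x = cei.column(src)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / (sd if sd > 0 else 1.0)
        values[:, k] = 73.0 + config.beta_le * z \
            + config.noise_sd_le * rng.standard_normal(n)
    return PanelTable(variable="LE", region_ids=list(cei.region_ids),
                      timepoints=list(config.timepoints),
                      values=np.clip(values, 65.0, 85.0))


def generate_rasters(config: SyntheticConfig, panel: PanelTable,
                     regions: list[Region] | None = None) -> list[RasterGrid]:
    """One raster per timepoint: each region's pixels are the region mean
    plus i.i.d. within-region noise, on a grid aligned with the unit-square
    regions (identity transform)."""
    if config.pixels_per_region < 1:
        raise ValueError("pixels_per_region must be >= 1")
    rng = np.random.default_rng((config.seed, 2))
    p = config.pixels_per_region
    side = config.n_side * p
    rasters = []
    for k, t in enumerate(panel.timepoints):
        grid = np.empty((side, side))
        for row in range(config.n_side):
            for col in range(config.n_side):
                i = panel.region_ids.index(f"r{row}-{col}")
                block = panel.values[i, k] \
                    + config.noise_sd_raster * rng.standard_normal((p, p))
                grid[row * p:(row + 1) * p, col * p:(col + 1) * p] = block
        step = 1.0 / p
        rasters.append(RasterGrid(values=grid, nodata_mask=np.zeros_like(grid, bool),
                                  transform=(step, 0.0, 0.0, 0.0, step, 0.0),
                                  variable=panel.variable, timepoint=t))
    return rasters


def generate_study(config: SyntheticConfig) -> dict:
    """Full synthetic study: regions, weights, indicators, CEI, LE."""
    regions = generate_regions(config)
    w = row_standardize(queen_contiguity(regions))
    panels = generate_indicator_panels(config, w)
    cei_panel = generate_cei_panel(config, panels)
    le = generate_le_panel(config, cei_panel)
    return {"config": config, "regions": regions, "weights": w,
            "panels": panels, "cei": cei_panel, "le": le}
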